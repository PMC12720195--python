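"""Carbonic-equilibrium chemistry: quadratic solver, open systems,
flux-balance estimator and compartment trajectories."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumorph.acidbase import (
    ARTERIAL,
    CarbonicState,
    CompartmentScenario,
    DiffusivityRatios,
    davenport_trajectory,
    flux_balance_estimate,
    henderson_hasselbalch,
    solve_equilibrium,
    solve_open_system,
)

K_M = 10.0**-6.1


class TestSolveEquilibrium:
    def test_full_fermentation_of_arterial_glucose(self):
        """Neutralizing 10 mM lactic acid drives pH to 6.2 with a 14/11.2
        HCO3/CO2 split and unchanged total inorganic carbon."""
        s = solve_equilibrium(strong_acid=10.0)
        assert s.pH == pytest.approx(6.2, abs=0.05)
        assert s.HCO3 == pytest.approx(14.0, abs=0.3)
        assert s.CO2 == pytest.approx(11.2, abs=0.3)
        assert s.TIC == pytest.approx(ARTERIAL.TIC, abs=1e-10)

    def test_closed_respiration_of_dissolved_o2(self):
        """Adding the 0.13 mM CO2 yield of dissolved-O2 respiration raises
        [H+] by ~4 nM (pH 7.4 -> 7.35)."""
        s = solve_equilibrium(tic_shift=0.13)
        assert s.pH == pytest.approx(7.35, abs=0.01)
        assert s.CO2 == pytest.approx(1.33, abs=0.01)
        assert (s.H - ARTERIAL.H) * 1e9 == pytest.approx(4.0, abs=0.5)

    def test_identity_when_nothing_added(self):
        s = solve_equilibrium(0.0, 0.0, ARTERIAL)
        # the textbook arterial triple sits ~0.001 pH off the exact manifold
        assert s.pH == pytest.approx(ARTERIAL.pH, abs=2e-3)
        assert s.is_equilibrated()

    def test_equilibrium_invariant_and_tic_bookkeeping(self):
        s = solve_equilibrium(tic_shift=2.5, strong_acid=4.0)
        assert s.is_equilibrated()
        assert s.TIC == pytest.approx(ARTERIAL.TIC + 2.5, abs=1e-10)

    def test_path_independence_of_equilibration(self):
        """Two half-loads equal one full load (the equilibrium manifold has
        no path memory)."""
        one = solve_equilibrium(strong_acid=8.0)
        half = solve_equilibrium(strong_acid=4.0)
        two = solve_equilibrium(strong_acid=4.0, initial=half)
        assert two.pH == pytest.approx(one.pH, abs=1e-9)
        assert two.CO2 == pytest.approx(one.CO2, abs=1e-9)

    def test_rejects_buffer_exhaustion_and_negative_loads(self):
        with pytest.raises(ValueError, match="buffer exhaustion"):
            solve_equilibrium(strong_acid=25.0)
        with pytest.raises(ValueError):
            solve_equilibrium(strong_acid=-1.0)

    def test_bisection_oracle_reproduces_quadratic_root(self):
        """Brute-force bisection on [H+] matches the analytic root to 1e-9 M
        across 100 random acid/TIC loads."""
        from scipy.optimize import brentq

        rng = np.random.default_rng(42)
        for _ in range(100):
            acid = rng.uniform(0.0, 20.0)
            tic = rng.uniform(0.0, 30.0)
            s = solve_equilibrium(tic_shift=tic, strong_acid=acid)
            B = (ARTERIAL.HCO3 - acid) * 1e-3
            C = (ARTERIAL.CO2 + acid + tic) * 1e-3

            def f(h):
                # total H+ shift x = h - H0 moves HCO3 up, CO2 down
                x = h - ARTERIAL.H
                return h * (B + x) - K_M * (C - x)

            h = brentq(f, 1e-9, 1e-3, xtol=1e-15)
            assert abs(h - s.H) < 1e-9


class TestOpenSystem:
    def test_gas_open_fermentation_endpoint(self):
        """With CO2 clamped at 1.2 mM, 10 mM of lactic acid lowers pH to ~7.2."""
        s = solve_open_system(10.0, 1.2)
        assert s.pH == pytest.approx(7.17, abs=0.01)
        assert s.CO2 == 1.2
        assert s.HCO3 == 14.0

    def test_no_acid_means_no_change(self):
        s = solve_open_system(0.0, 1.2)
        assert s.pH == pytest.approx(ARTERIAL.pH, abs=2e-3)

    def test_direct_henderson_hasselbalch_oracle(self):
        s = solve_open_system(5.0, 1.2)
        assert s.pH == pytest.approx(6.1 + math.log10(19.0 / 1.2), abs=1e-12)


class TestHendersonHasselbalch:
    @pytest.mark.parametrize(
        "co2, hco3, expected",
        [
            (1.2, 24.0, 7.40),
            (3.3, 3.3, 6.10),
            (2.45, 19.0, 6.99),
        ],
    )
    def test_reference_points(self, co2, hco3, expected):
        assert henderson_hasselbalch(co2, hco3) == pytest.approx(expected, abs=0.005)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            henderson_hasselbalch(0.0, 24.0)


class TestFluxBalance:
    def test_full_glucose_gradient_default_ratios(self):
        """Balanced fluxes at a 5 mM glucose gradient predict the acidotic
        steady state 7.0 / 19 mM HCO3 / 2.45 mM CO2."""
        s = flux_balance_estimate(5.0)
        assert s.pH == pytest.approx(7.0, abs=0.02)
        assert s.HCO3 == pytest.approx(19.0, abs=0.1)
        assert s.CO2 == pytest.approx(2.45, abs=0.05)

    def test_zero_gradient_returns_arterial(self):
        s = flux_balance_estimate(0.0)
        assert s.pH == pytest.approx(ARTERIAL.pH, abs=2e-3)
        assert s.HCO3 == pytest.approx(ARTERIAL.HCO3, abs=1e-6)

    def test_half_gradient_hand_computed(self):
        """2.5 mM gradient -> 5 mM lactate -> HCO3 21.5, CO2 1.825, then the
        quadratic correction (hand-derived oracle)."""
        s = flux_balance_estimate(2.5)
        assert s.HCO3 == pytest.approx(21.5, abs=0.01)
        assert s.CO2 == pytest.approx(1.825, abs=0.01)
        assert s.pH == pytest.approx(6.1 + math.log10(21.5 / 1.825), abs=0.01)

    def test_slower_co2_ratio_deepens_hypercapnia(self):
        slow = flux_balance_estimate(5.0, DiffusivityRatios(d_CO2=4.0))
        assert slow.CO2 > flux_balance_estimate(5.0).CO2

    def test_gradient_beyond_available_glucose_rejected(self):
        with pytest.raises(ValueError):
            flux_balance_estimate(6.0)


class TestDavenportTrajectory:
    def test_closed_fermentation_endpoint_and_monotonicity(self):
        traj = davenport_trajectory(CompartmentScenario(), n_steps=21)
        ph = [s.pH for s in traj]
        assert ph[0] == pytest.approx(7.4, abs=0.01)
        assert ph[-1] == pytest.approx(6.2, abs=0.05)
        assert all(a >= b for a, b in zip(ph, ph[1:]))
        # TIC conserved along the whole closed trajectory
        assert all(s.TIC == pytest.approx(ARTERIAL.TIC, abs=1e-9) for s in traj)

    def test_gas_open_fermentation_endpoint(self):
        traj = davenport_trajectory(
            CompartmentScenario(gas_open=True), n_steps=11
        )
        assert traj[-1].pH == pytest.approx(7.17, abs=0.05)
        assert all(s.CO2 == pytest.approx(1.2, abs=1e-12) for s in traj)

    def test_zero_substrate_trajectory_is_constant(self):
        traj = davenport_trajectory(
            CompartmentScenario(glucose0=0.0), n_steps=5
        )
        assert all(s.pH == pytest.approx(traj[0].pH, abs=1e-9) for s in traj)

    def test_respiration_endpoint_matches_direct_solve(self):
        traj = davenport_trajectory(
            CompartmentScenario(metabolic_mode="respiration"), n_steps=7
        )
        direct = solve_equilibrium(tic_shift=0.13)
        assert traj[-1].pH == pytest.approx(direct.pH, abs=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    acid=st.floats(0.0, 20.0),
    tic=st.floats(0.0, 30.0),
)
def test_closed_system_properties(acid, tic):
    """For any admissible load: TIC bookkeeping is exact, the returned state
    is on the equilibrium manifold, and acid always lowers pH."""
    s = solve_equilibrium(tic_shift=tic, strong_acid=acid)
    assert s.TIC == pytest.approx(ARTERIAL.TIC + tic, abs=1e-10)
    assert s.is_equilibrated()
    baseline = solve_equilibrium(0.0, 0.0)
    if acid + tic > 1e-9:
        assert s.pH < baseline.pH + 1e-9


def test_carbonic_state_validates_positivity():
    with pytest.raises(ValueError):
        CarbonicState(pH=7.0, CO2=-1.0, HCO3=24.0)
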