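"""Spheroid diffusion-reaction solver: closed-form oracles, flux balance,
profile structure and grid convergence."""

from __future__ import annotations

import numpy as np
import pytest

from tumorph.params import (
    BufferKinetics,
    CarrierParams,
    MetabolicParams,
    NHEParams,
    SpheroidGeometry,
    TransportParams,
)
from tumorph.spheroid import (
    anoxic_depth,
    flux_balance_report,
    radial_profiles,
    rate_sweep,
    radius_sweep,
    solve_steady_state,
)


def test_zero_metabolism_is_uniform_arterial():
    """Without reactions every field is flat at its boundary value."""
    sol = solve_steady_state(geometry=SpheroidGeometry(n_shells=40))
    assert np.allclose(sol.fields["O2"], 0.13, atol=1e-6)
    assert np.allclose(sol.fields["glc_e"], 5.0, atol=1e-6)
    assert np.allclose(sol.pHe, 7.401, atol=1e-3)
    assert anoxic_depth(sol) is None


def test_constant_consumption_matches_parabolic_profile():
    """With saturation disabled (K_O2 -> 0, K_glucose = 0) O2 consumption is
    uniform and the exact solution is the parabola
    O2(r) = O2_R - (q/6D)(R^2 - r^2); the solver must match to < 1%."""
    R, n = 150.0, 200
    jr = 0.667  # keeps the core oxygenated
    met = MetabolicParams(J_resp_max=jr, K_O2=1e-12, K_glucose=0.0)
    tp = TransportParams()
    sol = solve_steady_state(
        geometry=SpheroidGeometry(radius=R, n_shells=n), metabolism=met, transport=tp
    )
    q = 6.0 * jr * (1.0 - 0.25)  # per total tissue volume
    D = tp.D_O2 * 60.0
    oracle = 0.13 - (q / (6.0 * D)) * (R**2 - sol.r**2)
    err = np.max(np.abs(sol.fields["O2"] - oracle))
    assert err < 0.01 * 0.13


def test_fermentative_core_acidosis(ferm_spheroid):
    """A saturating fermentative spheroid acidifies its core to pHe ~6.9 with
    HCO3- depletion several-fold larger than CO2 accumulation."""
    sol = ferm_spheroid
    assert sol.converged
    assert sol.pHe[0] == pytest.approx(6.9, abs=0.1)
    ratio = (24.0 - sol.fields["hco3_e"][0]) / (sol.fields["CO2"][0] - 1.2)
    assert ratio == pytest.approx(5.0, rel=0.30)
    # profiles acidify monotonically toward the core
    assert np.all(np.diff(sol.pHe) >= -1e-9)


def test_respiratory_spheroid_anoxia_and_mild_acidosis(resp_spheroid):
    """Respiration at 0.67 mM/min leaves the core anoxic beyond ~200 µm depth
    but acidifies by only ~0.05 units (O2-limited CO2 production)."""
    sol = resp_spheroid
    depth = anoxic_depth(sol)
    assert depth == pytest.approx(200.0, abs=30.0)
    assert sol.pHe[0] == pytest.approx(7.35, abs=0.05)
    # HCO3- is not consumed by respiration: no depletion anywhere
    assert sol.fields["hco3_e"].min() > 23.9


def test_surface_flux_balances_integrated_consumption(ferm_spheroid, resp_spheroid):
    """Steady state: boundary influx equals volume-integrated consumption to
    < 1% for glucose, O2, lactate and carbon."""
    for sol in (ferm_spheroid, resp_spheroid):
        report = flux_balance_report(sol)
        for name, mismatch in report.items():
            assert mismatch < 0.01, f"{name} flux mismatch {mismatch:.3%}"


def test_mixed_phenotype_lies_between_pure_profiles(mixed_spheroid):
    """Half-rate mixed metabolism produces pH profiles pointwise between the
    pure fermentative and respiratory ones."""
    geom = SpheroidGeometry(n_shells=60)
    ferm = solve_steady_state(geometry=geom, metabolism=MetabolicParams(J_ferm_max=10.0))
    resp = solve_steady_state(geometry=geom, metabolism=MetabolicParams(J_resp_max=0.67))
    lo = np.minimum(ferm.pHe, resp.pHe) - 0.02
    hi = np.maximum(ferm.pHe, resp.pHe) + 0.02
    assert np.all(mixed_spheroid.pHe >= lo) and np.all(mixed_spheroid.pHe <= hi)


def test_rate_sweep_monotone_and_saturating():
    rates = [0.0, 1.0, 10.0, 100.0]
    df = rate_sweep(rates, "ferm", geometry=SpheroidGeometry(n_shells=40))
    ph = df["core_pHe"].to_numpy()
    assert ph[0] == pytest.approx(7.40, abs=0.01)
    assert np.all(np.diff(ph) <= 1e-6)
    # near-saturation: the last decade of rate moves core pH by little
    assert abs(ph[-1] - ph[-2]) < 0.05


def test_respiratory_plateau_is_shallow():
    """Even a 100 mM/min respiratory ceiling acidifies by only ~0.05 units:
    O2 delivery, not enzyme capacity, limits respiratory acidosis."""
    sol = solve_steady_state(
        geometry=SpheroidGeometry(n_shells=60),
        metabolism=MetabolicParams(J_resp_max=100.0),
    )
    assert 7.4 - sol.pHe[0] == pytest.approx(0.05, abs=0.05)


def test_grid_convergence_of_core_ph():
    """Richardson-style check: the 40->80 shell error contraction implies at
    least first-order convergence, and doubling resolution moves the plateau
    by < 0.005 pH."""
    met = MetabolicParams(J_ferm_max=10.0)
    ph = {}
    for n in (40, 80, 160):
        sol = solve_steady_state(
            geometry=SpheroidGeometry(n_shells=n), metabolism=met
        )
        ph[n] = float(sol.pHe[0])
    e1 = abs(ph[40] - ph[160])
    e2 = abs(ph[80] - ph[160])
    assert e2 < 0.6 * e1 + 1e-6  # order >= 1
    assert abs(ph[160] - ph[80]) < 0.005


def test_radius_sweep_limits():
    """Tiny spheroids stay arterial; respiratory acidification saturates by
    ~200 µm radius; halving the fermentative ceiling raises pH everywhere."""
    df_r = radius_sweep([50, 200, 500], "resp", n_shells=50)
    assert df_r["core_pHe"].iloc[0] == pytest.approx(7.4, abs=0.02)
    # saturation: growing from 200 to 500 µm changes core pH much less than
    # growing from 50 to 200 µm
    d_small = abs(df_r["core_pHe"].iloc[1] - df_r["core_pHe"].iloc[0])
    d_large = abs(df_r["core_pHe"].iloc[2] - df_r["core_pHe"].iloc[1])
    assert d_large < d_small

    geom = SpheroidGeometry(n_shells=40)
    full = solve_steady_state(geometry=geom, metabolism=MetabolicParams(J_ferm_max=10.0))
    half = solve_steady_state(geometry=geom, metabolism=MetabolicParams(J_ferm_max=5.0))
    assert np.all(half.pHe >= full.pHe - 1e-6)


def test_nhe_regulates_phi_but_not_max_phe_drop():
    """pHi regulation clamps pHi near its 7.2 set-point under mild acidosis
    yet leaves the maximal pHe acidification essentially unchanged."""
    geom = SpheroidGeometry(radius=250.0, n_shells=50)
    met = MetabolicParams(J_ferm_max=10.0)
    off = solve_steady_state(geometry=geom, metabolism=met)
    on = solve_steady_state(geometry=geom, metabolism=met, nhe=NHEParams())
    drop_off = 7.4 - off.pHe.min()
    drop_on = 7.4 - on.pHe.min()
    assert abs(drop_on - drop_off) < 0.1
    # at the mildly acidotic surface shells, pHi stays within 0.1 of set-point
    surface = on.pHe > 7.1
    assert np.all(np.abs(on.pHi[surface] - 7.2) < 0.15)


def test_ca_rate_sensitivity_is_negligible():
    """In the catalyzed (equilibrium-limit) regime a further 10-fold CA
    acceleration moves core pH by < 0.01: steady states are set by flux
    balance, not hydration kinetics."""
    geom = SpheroidGeometry(n_shells=40)
    met = MetabolicParams(J_ferm_max=10.0)
    ph = []
    for accel in (1000.0, 10000.0):
        sol = solve_steady_state(
            geometry=geom,
            metabolism=met,
            buffers=BufferKinetics(ca_acceleration=accel, ca_acceleration_ic=accel),
        )
        ph.append(float(sol.pHe[0]))
    assert abs(ph[0] - ph[1]) < 0.01


def test_profiles_table_shape(ferm_spheroid):
    df = radial_profiles(ferm_spheroid)
    assert len(df) == 100
    assert {"r_um", "O2", "CO2", "pHe", "pHi"} <= set(df.columns)
    assert (df.drop(columns=["pHe", "pHi"]).to_numpy() >= 0).all()
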