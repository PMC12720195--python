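"""Carbonic-buffer equilibrium chemistry of closed and gas-open compartments.

The extracellular space is dominated by the CO2/HCO3- buffer, whose
speciation obeys

    K = [H+][HCO3-] / [CO2],     pK = 6.1  (concentrations in M)

Metabolic acid loads perturb this pool in two distinct ways:

* fermentation produces lactic acid, which is neutralized by HCO3- and
  converted one-to-one into CO2 (total inorganic carbon, TIC, conserved in a
  closed system);
* respiration adds CO2 directly, raising TIC.

After either perturbation the pool re-equilibrates by interconverting an
amount ``x`` of CO2 into HCO3- + H+.  In molar units, starting from
([H+]0, B, C) after the stoichiometric shift, ``x`` solves

    (H0 + x)(B + x) = K (C - x)

a quadratic whose physical root keeps all three concentrations positive.

A gas-open compartment (culture dish in an incubator) instead clamps [CO2]
at the atmospheric value; acidification is pure HCO3- depletion and pH
follows Henderson-Hasselbalch directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, Literal

import numpy as np
from scipy.optimize import brentq

from .constants import (
    ARTERIAL_CO2_MM,
    ARTERIAL_GLUCOSE_MM,
    ARTERIAL_HCO3_MM,
    ARTERIAL_O2_MM,
    ARTERIAL_PH,
    K_CARBONIC_M,
    LACTATE_PER_GLUCOSE,
    PK_CARBONIC,
)

__all__ = [
    "CarbonicState",
    "CompartmentScenario",
    "DiffusivityRatios",
    "ARTERIAL",
    "henderson_hasselbalch",
    "solve_equilibrium",
    "solve_open_system",
    "flux_balance_estimate",
    "davenport_trajectory",
]


@dataclass(frozen=True)
class CarbonicState:
    """A pH / [CO2] / [HCO3-] triple (concentrations in mM)."""

    pH: float
    CO2: float
    HCO3: float

    def __post_init__(self) -> None:
        if self.CO2 <= 0 or self.HCO3 <= 0:
            raise ValueError(
                f"CO2 and HCO3 must be positive (got CO2={self.CO2}, HCO3={self.HCO3})"
            )

    @property
    def H(self) -> float:
        """[H+] in M."""
        return 10.0 ** (-self.pH)

    @property
    def TIC(self) -> float:
        """Total inorganic carbon [CO2] + [HCO3-] in mM."""
        return self.CO2 + self.HCO3

    def equilibrium_residual(self) -> float:
        """Relative departure from the carbonic equilibrium ratio."""
        lhs = self.H * (self.HCO3 * 1e-3)
        rhs = K_CARBONIC_M * (self.CO2 * 1e-3)
        return abs(lhs - rhs) / rhs

    def is_equilibrated(self, tol: float = 1e-6) -> bool:
        return self.equilibrium_residual() < tol


ARTERIAL = CarbonicState(pH=ARTERIAL_PH, CO2=ARTERIAL_CO2_MM, HCO3=ARTERIAL_HCO3_MM)


@dataclass(frozen=True)
class CompartmentScenario:
    """A block of tissue/medium cut off from perfusion.

    ``gas_open`` distinguishes a hermetically sealed compartment from one
    that exchanges CO2 (and O2) with a fixed atmosphere.  Fermentation can
    consume all glucose (2 lactic acid per glucose); closed-compartment
    respiration is capped by the dissolved O2 endowment.
    """

    initial: CarbonicState = ARTERIAL
    glucose0: float = ARTERIAL_GLUCOSE_MM
    freeO2_0: float = ARTERIAL_O2_MM
    gas_open: bool = False
    metabolic_mode: Literal["fermentation", "respiration"] = "fermentation"
    respiratory_quotient: float = 1.0

    def __post_init__(self) -> None:
        if self.glucose0 < 0 or self.freeO2_0 < 0:
            raise ValueError("glucose0 and freeO2_0 must be non-negative")


@dataclass(frozen=True)
class DiffusivityRatios:
    """Relative effective diffusivities used by the flux-balance estimator.

    Defaults reproduce the worked steady-state estimate: HCO3- moves twice
    as fast as lactate (small anion, but restricted to the extracellular
    space) and CO2 another 4-fold faster (gas, whole tissue volume), so the
    lactate gradient maps onto HCO3- and CO2 gradients scaled by 1/2 and
    1/8.  Glucose and lactate are taken as equally mobile.
    """

    d_CO2: float = 8.0
    d_HCO3: float = 2.0
    d_lactate: float = 1.0
    d_glucose: float = 1.0

    def __post_init__(self) -> None:
        if min(self.d_CO2, self.d_HCO3, self.d_lactate, self.d_glucose) <= 0:
            raise ValueError("all diffusivity ratios must be positive")


def henderson_hasselbalch(CO2: float, HCO3: float) -> float:
    """pH = pK + log10([HCO3-]/[CO2]); both concentrations in mM."""
    if CO2 <= 0 or HCO3 <= 0:
        raise ValueError(f"CO2 and HCO3 must be positive (got {CO2}, {HCO3})")
    return PK_CARBONIC + math.log10(HCO3 / CO2)


def _equilibrate(H0_M: float, HCO3_mM: float, CO2_mM: float) -> CarbonicState:
    """Re-equilibrate a perturbed carbonic pool.

    Solves (H0+x)(B+x) = K(C-x) for the CO2->HCO3-+H+ interconversion x
    (molar).  The physical root of x^2 + (H0+B+K)x + (H0*B - K*C) = 0 is the
    larger one: the product of roots H0*B - K*C may have either sign but the
    '+' root always keeps H, HCO3 and CO2 positive.
    """
    B = HCO3_mM * 1e-3
    C = CO2_mM * 1e-3
    K = K_CARBONIC_M
    b = H0_M + B + K
    c = H0_M * B - K * C
    disc = b * b - 4.0 * c
    if disc <= 0 or not math.isfinite(disc):  # numerically marginal: bisection
        x = brentq(lambda t: (H0_M + t) * (B + t) - K * (C - t), -min(H0_M, B) * (1 - 1e-12), C)
    else:
        # physical ('+') root via Vieta to avoid cancellation when |x| << b
        x = c / ((-b - math.sqrt(disc)) / 2.0)
    H = H0_M + x
    hco3 = (B + x) * 1e3
    co2 = (C - x) * 1e3
    return CarbonicState(pH=-math.log10(H), CO2=co2, HCO3=hco3)


def solve_equilibrium(
    tic_shift: float = 0.0,
    strong_acid: float = 0.0,
    initial: CarbonicState = ARTERIAL,
) -> CarbonicState:
    """Equilibrium state of a closed compartment after a metabolic load.

    Parameters
    ----------
    tic_shift : mM of CO2 added directly (respiration raises TIC).
    strong_acid : mM of lactic acid neutralized; converts HCO3- to CO2
        one-to-one, leaving TIC unchanged.
    initial : starting carbonic state (arterial plasma by default).
    """
    if tic_shift < 0 or strong_acid < 0:
        raise ValueError("tic_shift and strong_acid must be non-negative")
    if strong_acid > initial.HCO3:
        raise ValueError(
            f"buffer exhaustion: cannot neutralize {strong_acid} mM strong acid "
            f"with only {initial.HCO3} mM HCO3-"
        )
    hco3 = initial.HCO3 - strong_acid
    co2 = initial.CO2 + strong_acid + tic_shift
    return _equilibrate(initial.H, hco3, co2)


def solve_open_system(
    strong_acid: float,
    clamped_CO2: float,
    initial: CarbonicState = ARTERIAL,
) -> CarbonicState:
    """Steady state of a gas-open compartment: CO2 clamped, HCO3- depleted."""
    if strong_acid < 0:
        raise ValueError("strong_acid must be non-negative")
    if clamped_CO2 <= 0:
        raise ValueError("clamped_CO2 must be positive")
    if strong_acid >= initial.HCO3:
        raise ValueError(
            f"buffer exhaustion: {strong_acid} mM strong acid >= {initial.HCO3} mM HCO3-"
        )
    hco3 = initial.HCO3 - strong_acid
    return CarbonicState(
        pH=henderson_hasselbalch(clamped_CO2, hco3), CO2=clamped_CO2, HCO3=hco3
    )


def flux_balance_estimate(
    glucose_gradient: float = ARTERIAL_GLUCOSE_MM,
    ratios: DiffusivityRatios = DiffusivityRatios(),
    arterial: CarbonicState = ARTERIAL,
) -> CarbonicState:
    """Steady-state TME carbonic state implied by balanced diffusive fluxes.

    A blood-tissue glucose gradient ``g`` sustained by full fermentation is
    balanced by a lactate counter-gradient of 2 g (D_glucose = D_lactate by
    default), while the co-produced H+ leaves as an HCO3-/CO2 shuttle.  The
    HCO3- and CO2 gradients are the lactate gradient rescaled by the
    diffusivity ratios; the perturbed pool is then re-equilibrated through
    the closed-system quadratic.
    """
    if glucose_gradient < 0:
        raise ValueError("glucose_gradient must be non-negative")
    if glucose_gradient > ARTERIAL_GLUCOSE_MM:
        raise ValueError(
            f"glucose gradient {glucose_gradient} mM exceeds available arterial "
            f"glucose ({ARTERIAL_GLUCOSE_MM} mM)"
        )
    lactate_gradient = (
        LACTATE_PER_GLUCOSE * glucose_gradient * ratios.d_glucose / ratios.d_lactate
    )
    hco3_drop = lactate_gradient * ratios.d_lactate / ratios.d_HCO3
    co2_rise = lactate_gradient * ratios.d_lactate / ratios.d_CO2
    if hco3_drop >= arterial.HCO3:
        raise ValueError("flux-balance gradient would exhaust the HCO3- pool")
    return _equilibrate(arterial.H, arterial.HCO3 - hco3_drop, arterial.CO2 + co2_rise)


def davenport_trajectory(
    scenario: CompartmentScenario, n_steps: int = 50
) -> list[CarbonicState]:
    """Carbonic-state trajectory as substrate is progressively consumed.

    Parameterized linearly by the fraction of substrate consumed (glucose for
    fermentation; the dissolved-O2 endowment for closed-compartment
    respiration).  Endpoints coincide with ``solve_equilibrium`` /
    ``solve_open_system`` at full consumption.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    fractions = np.linspace(0.0, 1.0, n_steps)
    out: list[CarbonicState] = []
    for f in fractions:
        if scenario.metabolic_mode == "fermentation":
            acid = f * LACTATE_PER_GLUCOSE * scenario.glucose0
            if scenario.gas_open:
                state = solve_open_system(acid, scenario.initial.CO2, scenario.initial)
            else:
                state = solve_equilibrium(0.0, acid, scenario.initial)
        else:  # respiration
            if scenario.gas_open:
                # CO2 escapes as fast as it is made: state pinned at initial.
                state = replace(scenario.initial)
            else:
                co2_added = f * scenario.freeO2_0 * scenario.respiratory_quotient
                state = solve_equilibrium(co2_added, 0.0, scenario.initial)
        out.append(state)
    return out
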