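"""Local reaction and membrane-flux laws.

All rates are mM/min per intracellular volume unless stated otherwise;
[H+] and [O2] arguments of the saturation terms are in M.
"""

from __future__ import annotations

import numpy as np

from .constants import K_CARBONIC_MM
from .params import BufferKinetics, CarrierParams, MetabolicParams, NHEParams

__all__ = [
    "j_ferm",
    "j_resp",
    "j_nhe",
    "co2_hydration_net",
    "carrier_flux",
    "mct_flux",
]


def j_ferm(glucose_i, H_i, p: MetabolicParams):
    """Glucose fermentation rate (mM glucose/min).

    Michaelis-type glucose dependence (K ~ 1 mM) multiplied by a
    cooperative inhibition by intracellular H+ (half-maximal pK 7.1, Hill
    coefficient 2.25, as measured in pancreatic cancer lines).  With
    ``p.ferm_hill`` False the inhibition reverts to the first-order form
    K_an / (H+ + K_an).  Produces 2 lactate + 2 H+ per glucose.
    """
    glucose_i = np.asarray(glucose_i, dtype=float)
    H_i = np.asarray(H_i, dtype=float)
    if np.any(glucose_i < 0):
        raise ValueError("glucose_i must be non-negative")
    if np.any(H_i <= 0):
        raise ValueError("H_i must be positive")
    glc = glucose_i / (glucose_i + p.K_glucose) if p.K_glucose > 0 else np.ones_like(glucose_i)
    if p.ferm_hill:
        h = p.hill_an
        acid = p.K_an**h / (H_i**h + p.K_an**h)
    else:
        acid = p.K_an / (H_i + p.K_an)
    return p.J_ferm_max * glc * acid


def j_resp(glucose_i, O2_i, p: MetabolicParams):
    """Glucose respiration rate (mM glucose/min); CO2 output = 6 * rate * RQ.

    Saturable in glucose (shared K with fermentation) and in O2
    (half-maximal at 1 µM).
    """
    glucose_i = np.asarray(glucose_i, dtype=float)
    O2_i = np.asarray(O2_i, dtype=float)
    if np.any(glucose_i < 0):
        raise ValueError("glucose_i must be non-negative")
    if np.any(O2_i < 0):
        raise ValueError("O2_i must be non-negative")
    glc = glucose_i / (glucose_i + p.K_glucose) if p.K_glucose > 0 else np.ones_like(glucose_i)
    ox = O2_i / (O2_i + p.K_O2)
    return p.J_resp_max * glc * ox


def j_nhe(H_i, p: NHEParams):
    """Na+/H+-exchange acid extrusion (mM H+/min), sigmoidal in [H+]i."""
    H_i = np.asarray(H_i, dtype=float)
    if np.any(H_i < 0):
        raise ValueError("H_i must be non-negative")
    n = p.hill
    return p.J_NHE_max * H_i**n / (H_i**n + p.K_NHE**n)


def co2_hydration_net(CO2, HCO3, H_M, b: BufferKinetics, catalyzed: bool = True):
    """Net CO2 -> HCO3- + H+ hydration flux (mM/min).

    Mass-action form k_f * ([CO2] - [H+][HCO3-]/K) that vanishes exactly at
    the carbonic equilibrium and pushes toward it from either side.
    ``catalyzed`` applies the extracellular carbonic-anhydrase acceleration.
    """
    CO2 = np.asarray(CO2, dtype=float)
    HCO3 = np.asarray(HCO3, dtype=float)
    H_mM = np.asarray(H_M, dtype=float) * 1e3
    k = b.k_hydration * (b.ca_acceleration if catalyzed else 1.0)
    return k * (CO2 - H_mM * HCO3 / K_CARBONIC_MM)


def carrier_flux(c_out, c_in, p: CarrierParams):
    """Symmetric saturable carrier; positive = influx (out -> in), mM/min."""
    c_out = np.asarray(c_out, dtype=float)
    c_in = np.asarray(c_in, dtype=float)
    return p.V_max * (c_out / (c_out + p.K_m) - c_in / (c_in + p.K_m))


def mct_flux(lac_i, H_i_M, lac_e, H_e_M, p: CarrierParams, K_H: float = 1e-7):
    """H+-lactate cotransport (MCT); positive = efflux (cell -> interstitium).

    Reversible bi-substrate carrier: the flux sign always follows the
    thermodynamic drive lac_i*H_i - lac_e*H_e (equimolar H+ travels with
    lactate), the magnitude saturates at V_max, and lactate/H+ binding is
    shared in a symmetric denominator with half-saturation K_m / K_H.
    """
    lac_i = np.asarray(lac_i, dtype=float)
    lac_e = np.asarray(lac_e, dtype=float)
    H_i = np.asarray(H_i_M, dtype=float)
    H_e = np.asarray(H_e_M, dtype=float)
    drive = lac_i * H_i - lac_e * H_e
    denom = p.K_m * K_H * (
        1.0
        + (lac_i + lac_e) / p.K_m
        + (H_i + H_e) / K_H
        + (lac_i * H_i + lac_e * H_e) / (p.K_m * K_H)
    )
    return p.V_max * drive / denom
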