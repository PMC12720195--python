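"""Physical constants and reference states shared across the models.

Concentrations are stored in mM throughout the package.  The carbonic
equilibrium constant is written for molar concentrations (pK 6.1 in the
ratio form [H+][HCO3-]/[CO2]), so ratio checks convert to M where needed.
"""

from __future__ import annotations

#: Carbonic buffer apparent equilibrium constant, molar: [H+][HCO3-]/[CO2].
PK_CARBONIC = 6.1
K_CARBONIC_M = 10.0 ** (-PK_CARBONIC)

#: Same constant when [H+] is expressed in mM like everything else:
#: (H_mM/1000)*HCO3/CO2 = K  ->  H_mM*HCO3/CO2 = K*1000.
K_CARBONIC_MM = K_CARBONIC_M * 1e3

#: Arterial plasma reference state.
ARTERIAL_PH = 7.4
ARTERIAL_HCO3_MM = 24.0
ARTERIAL_CO2_MM = 1.2

#: O2 solubility convention: arterial 13 kPa partial pressure corresponds to
#: 130 uM free O2, i.e. 10 uM per kPa.
O2_SOLUBILITY_MM_PER_KPA = 0.01
ARTERIAL_O2_MM = 0.13

#: Plasma glucose.
ARTERIAL_GLUCOSE_MM = 5.0

#: Hemoglobin-bound O2 reservoir of whole blood (mM O2 equivalents).
HB_O2_CAPACITY_MM = 9.0

#: Stoichiometry: fermentation 1 glucose -> 2 lactate + 2 H+;
#: respiration 1 glucose + 6 O2 -> 6 CO2 (respiratory quotient 1).
LACTATE_PER_GLUCOSE = 2
O2_PER_GLUCOSE = 6
CO2_PER_GLUCOSE = 6


def h_molar_from_ph(ph: float) -> float:
    """[H+] in M for a given pH."""
    return 10.0 ** (-ph)


def ph_from_h_molar(h: float) -> float:
    """pH for [H+] in M."""
    import math

    if h <= 0:
        raise ValueError(f"[H+] must be positive, got {h}")
    return -math.log10(h)
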