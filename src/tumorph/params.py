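"""Validated parameter containers for metabolism, transport and buffering.

Units: concentrations mM, time min, lengths µm unless stated otherwise.
[H+] and the acid dissociation constants that act on it are in M, matching
the convention of the rate laws (pK values quoted on the pH scale).
"""

from __future__ import annotations

from pydantic import BaseModel, Field, model_validator


class MetabolicParams(BaseModel):
    """Maximal rates and half-saturation constants of glucose metabolism.

    ``J_ferm_max`` / ``J_resp_max`` are glucose-consumption rates per
    intracellular volume.  Fermentation yields 2 lactate + 2 H+ per glucose
    and is product-inhibited by intracellular acidity (half-maximal pK 7.1,
    Hill cooperativity 2.25); respiration yields 6 CO2 per glucose (RQ 1)
    and saturates in O2 with K = 1 µM.  The 15-fold ATP-yield difference
    between the two pathways motivates scaling their maximal rates 15:1 when
    comparing iso-energetic phenotypes.
    """

    J_ferm_max: float = Field(default=0.0, ge=0)  # mM glucose / min
    J_resp_max: float = Field(default=0.0, ge=0)  # mM glucose / min
    K_glucose: float = Field(default=1.0, ge=0)  # mM
    K_an: float = Field(default=10.0 ** -7.1, gt=0)  # M, acid inhibition of fermentation
    hill_an: float = Field(default=2.25, gt=0)
    ferm_hill: bool = True  # False recovers first-order H+ inhibition
    K_O2: float = Field(default=1e-6, gt=0)  # M
    atp_yield_ratio: float = Field(default=15.0, gt=0)
    respiratory_quotient: float = Field(default=1.0, gt=0)


class NHEParams(BaseModel):
    """pHi regulation: Na+/H+ exchange balanced by Cl-/HCO3- exchange.

    Acid extrusion J_NHE = J_NHE_max * H_i^2 / (H_i^2 + K_NHE^2) is
    half-maximal at [H+]i = K_NHE (pK 6.7), representative of many cancer
    cells.  An anion exchanger provides the opposing acid-loading flux
    P_ae * ([HCO3-]_i - r_ae * [HCO3-]_e); the Cl--gradient factor r_ae < 1
    lets it export HCO3- at physiological concentrations.  The two fluxes
    null each other near pHi 7.2 (the set-point), and without the loader a
    perpetual extruder would alkalinize the cytosol without bound.
    """

    J_NHE_max: float = Field(default=10.0, ge=0)  # mM/min
    K_NHE: float = Field(default=10.0 ** -6.7, gt=0)  # M
    hill: float = Field(default=2.0, gt=0)
    pHi_setpoint: float = 7.2
    ae_permeability: float = Field(default=0.1, ge=0)  # 1/min
    ae_ratio: float = Field(default=0.3, gt=0)  # Cl--gradient equilibrium factor


class BufferKinetics(BaseModel):
    """CO2 hydration kinetics and non-carbonic buffering.

    The uncatalyzed CO2 + H2O -> HCO3- + H+ step is slow; carbonic
    anhydrases accelerate it by orders of magnitude both in the interstitium
    (exofacial isoforms) and in the cytosol.  Because all reported outcomes
    are steady states near equilibrium, results are insensitive to the
    absolute rate (sensitivity-tested).

    ``intrinsic_buffer_capacity`` is the intracellular non-CO2 buffering
    power (mM per pH unit).  ``conditioning_buffer_e`` is a small linear
    buffering factor applied to extracellular H+ purely to de-stiffen
    pseudo-time integration; linear buffering rescales dH/dt only and leaves
    steady states unchanged.
    """

    k_hydration: float = Field(default=0.15, gt=0)  # 1/min, uncatalyzed
    ca_acceleration: float = Field(default=1000.0, ge=1)  # fold, extracellular
    ca_acceleration_ic: float = Field(default=1000.0, ge=1)  # fold, intracellular
    intrinsic_buffer_capacity: float = Field(default=20.0, gt=0)  # mM / pH
    conditioning_buffer_e: float = Field(default=5.0, gt=0)  # mM / pH


class CarrierParams(BaseModel):
    """Symmetric saturable membrane carrier (GLUT-like or MCT-like)."""

    V_max: float = Field(gt=0)  # mM/min per intracellular volume
    K_m: float = Field(gt=0)  # mM


class TransportParams(BaseModel):
    """Free-solution diffusivities, volume fractions and membrane carriers.

    Diffusivities are free-solution values in µm²/s (converted to µm²/min by
    the solvers).  Gases (O2, CO2) permeate the whole tissue volume;
    extracellular solutes (glucose, lactate, HCO3-) are confined to the
    interstitial fraction v_e, which enters through per-compartment source
    scaling and makes their effective transport v_e-fold slower.  Defaults:
    CO2 and HCO3- at their aqueous 37 °C values, O2 at the upper end of its
    37 °C range, glucose and lactate equally mobile; with v_e = 0.25 the
    effective CO2 : HCO3- : lactate ratio is ~7.6 : 1.2 : 1, i.e. CO2 roughly
    6-fold faster than HCO3- and HCO3- marginally faster than lactate.
    """

    D_CO2: float = Field(default=1900.0, gt=0)
    D_O2: float = Field(default=2500.0, gt=0)
    D_HCO3: float = Field(default=1180.0, gt=0)
    D_lactate: float = Field(default=1000.0, gt=0)
    D_glucose: float = Field(default=1000.0, gt=0)
    v_e: float = Field(default=0.25, gt=0, lt=1)
    glut: CarrierParams = CarrierParams(V_max=50.0, K_m=1.0)
    mct: CarrierParams = CarrierParams(V_max=100.0, K_m=2.0)
    K_H_mct: float = Field(default=1e-7, gt=0)  # M, MCT H+ half-saturation

    @property
    def v_i(self) -> float:
        return 1.0 - self.v_e


class SpheroidGeometry(BaseModel):
    """Radially symmetric spheroid bathed in arterial-like medium."""

    radius: float = Field(default=500.0, gt=0)  # µm
    v_e: float = Field(default=0.25, gt=0, lt=1)
    n_shells: int = Field(default=100, ge=10)


class KroghGeometry(BaseModel):
    """Single capillary supplying a coaxial annulus of tissue."""

    length: float = Field(default=2.0, gt=0)  # mm
    capillary_radius: float = Field(default=5.0, gt=0)  # µm
    tissue_thickness: float = Field(default=250.0, gt=0)  # µm
    blood_velocity: float = Field(default=1.0, gt=0)  # mm/s
    n_axial: int = Field(default=200, ge=8)
    n_radial: int = Field(default=40, ge=5)

    @property
    def transit_time_s(self) -> float:
        return self.length / self.blood_velocity

    @model_validator(mode="after")
    def _check(self) -> "KroghGeometry":
        if self.tissue_thickness < self.capillary_radius:
            raise ValueError("tissue thickness should exceed the capillary radius")
        return self


class BloodParams(BaseModel):
    """Blood-confined O2 carrier and non-carbonic buffer.

    Hb-O2 binding follows a Hill curve (n 2.7, P50 3.6 kPa = 26 µM free O2,
    capacity 9 mM).  The non-carbonic buffer (hemoglobin + plasma proteins)
    is linear with capacity ``buffer_capacity`` mM per pH unit; its default
    is set so that a ~9 mM fermentative lactic-acid load during capillary
    transit splits into ~3 mM HCO3- depletion, ~3 mM CO2 accumulation and a
    venous pH near 6.7-6.8, the composition characteristic of a
    TIC-conserving transit.
    """

    hb_capacity: float = Field(default=9.0, ge=0)  # mM O2
    hill_n: float = Field(default=2.7, gt=0)
    p50_o2: float = Field(default=0.026, gt=0)  # mM free O2
    buffer_capacity: float = Field(default=10.0, ge=0)  # mM / pH
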