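"""Convection-diffusion-reaction model of a perfused capillary (Krogh cylinder).

A capillary (radius 5 µm, length 2 mm, blood velocity 1 mm/s → 2 s transit)
supplies a coaxial annulus of metabolizing tissue (thickness 250 µm).  Blood
is treated as radially well-mixed and advected one-way; the tissue has no
axial diffusion (length >> thickness), so axial positions couple only
through the blood.  The steady state is therefore solved by marching the
blood composition downstream, equilibrating the radial tissue column at
each axial position against the local plasma composition and feeding the
wall exchange back into the blood balance.

Blood chemistry is carried as conserved quantities — total inorganic carbon
(TIC), alkalinity, total O2 (free + Hb-bound) — and re-speciated pointwise:

* carbonic speciation: [HCO3-] + beta*(pH - 7.4) = Alk with
  [HCO3-] = TIC*K/(K+[H+]), where beta is the linear non-carbonic blood
  buffer (hemoglobin + plasma proteins);
* Hb-O2: Hill curve (n = 2.7, P50 = 26 µM free O2, capacity 9 mM).

Wall bookkeeping: CO2 crossing moves TIC only; HCO3- crossing moves TIC and
alkalinity together; lactate leaves the tissue as its anion (its H+
equivalents travel as the HCO3-/CO2 shuttle, which is the only spatial H+
pathway in the tissue), so lactate itself is alkalinity-neutral.  Hb-O2 and
the non-carbonic buffer remain confined to blood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import (
    ARTERIAL_CO2_MM,
    ARTERIAL_GLUCOSE_MM,
    ARTERIAL_HCO3_MM,
    ARTERIAL_O2_MM,
    ARTERIAL_PH,
    K_CARBONIC_M,
)
from .params import (
    BloodParams,
    BufferKinetics,
    KroghGeometry,
    MetabolicParams,
    NHEParams,
    TransportParams,
)
from .steady import ConvergenceError, solve_steady
from .tissue import IDX, N_SOLUTES, SOLUTE_NAMES, TissueProblem

__all__ = [
    "BloodState",
    "KroghSolution",
    "simulate",
    "rate_sweep",
    "geometry_sweep",
    "phi_phe_trajectory",
    "o2_ph_trajectory",
    "hb_saturation",
    "free_o2_from_total",
    "speciate_blood",
]


# ----------------------------------------------------------------------
# blood chemistry
def hb_saturation(free_o2: float | np.ndarray, blood: BloodParams) -> float | np.ndarray:
    """Fractional Hb-O2 saturation at a given free [O2] (mM)."""
    c = np.maximum(free_o2, 0.0)
    return c**blood.hill_n / (c**blood.hill_n + blood.p50_o2**blood.hill_n)


def free_o2_from_total(total_o2: float, blood: BloodParams) -> float:
    """Invert total O2 = free + capacity * S(free) for the free concentration."""
    if total_o2 <= 0:
        return 0.0

    def g(c: float) -> float:
        return c + blood.hb_capacity * hb_saturation(c, blood) - total_o2

    if g(total_o2) <= 0:  # no carrier or unsaturated edge case
        return total_o2
    return brentq(g, 0.0, total_o2, xtol=1e-12)


def speciate_blood(
    tic: float, alk: float, blood: BloodParams
) -> tuple[float, float, float]:
    """Solve carbonic + linear-buffer equilibrium; returns (pH, CO2, HCO3)."""

    def g(ph: float) -> float:
        h = 10.0**-ph
        hco3 = tic * K_CARBONIC_M / (K_CARBONIC_M + h)
        return hco3 + blood.buffer_capacity * (ph - ARTERIAL_PH) - alk

    ph = brentq(g, 4.0, 9.0, xtol=1e-10)
    h = 10.0**-ph
    hco3 = tic * K_CARBONIC_M / (K_CARBONIC_M + h)
    return ph, tic - hco3, hco3


@dataclass
class BloodState:
    """Blood composition at one axial position (mM; conserved + derived)."""

    glucose: float
    lactate: float
    o2_total: float
    tic: float
    alk: float
    pH: float = 0.0
    CO2: float = 0.0
    HCO3: float = 0.0
    o2_free: float = 0.0
    o2_hb: float = 0.0

    def speciate(self, blood: BloodParams) -> "BloodState":
        self.pH, self.CO2, self.HCO3 = speciate_blood(self.tic, self.alk, blood)
        self.o2_free = free_o2_from_total(self.o2_total, blood)
        self.o2_hb = self.o2_total - self.o2_free
        return self


def arterial_blood(blood: BloodParams) -> BloodState:
    total_o2 = ARTERIAL_O2_MM + blood.hb_capacity * float(
        hb_saturation(ARTERIAL_O2_MM, blood)
    )
    return BloodState(
        glucose=ARTERIAL_GLUCOSE_MM,
        lactate=0.0,
        o2_total=total_o2,
        tic=ARTERIAL_CO2_MM + ARTERIAL_HCO3_MM,
        alk=ARTERIAL_HCO3_MM,
    ).speciate(blood)


# ----------------------------------------------------------------------
@dataclass
class KroghSolution:
    """Axial blood profiles plus the axial x radial tissue fields."""

    z: np.ndarray  # axial positions, mm
    blood: pd.DataFrame  # per-z blood composition
    r: np.ndarray  # tissue shell-centre radii, µm
    tissue: dict[str, np.ndarray]  # per-solute (n_axial, n_radial) arrays
    shell_volumes: np.ndarray  # per unit length, µm³/µm
    geometry: KroghGeometry
    max_residual: float
    converged: bool

    @property
    def tissue_pHe(self) -> np.ndarray:
        return -np.log10(np.maximum(self.tissue["h_e"], 1e-12) * 1e-3)

    @property
    def tissue_pHi(self) -> np.ndarray:
        return -np.log10(np.maximum(self.tissue["h_i"], 1e-12) * 1e-3)

    @property
    def mean_tissue_pHe(self) -> float:
        """Volume-weighted mean extracellular tissue pH (length x radius)."""
        w = np.broadcast_to(self.shell_volumes, self.tissue_pHe.shape)
        return float(np.average(self.tissue_pHe, weights=w))

    @property
    def venous(self) -> pd.Series:
        return self.blood.iloc[-1]

    @property
    def arterial(self) -> pd.Series:
        return self.blood.iloc[0]


def _annulus_problem(
    geometry: KroghGeometry,
    metabolism: MetabolicParams,
    transport: TransportParams,
    buffers: BufferKinetics,
    nhe: Optional[NHEParams],
) -> TissueProblem:
    rc = geometry.capillary_radius
    R = rc + geometry.tissue_thickness
    n = geometry.n_radial
    # geometric grading toward the capillary wall resolves the steep O2
    # boundary layer there (growth 5% per shell)
    g = 1.05
    steps = g ** np.arange(n)
    edges = rc + (R - rc) * np.concatenate(([0.0], np.cumsum(steps))) / steps.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    volumes = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)  # per unit length
    face_areas = 2.0 * math.pi * edges[1:-1]
    return TissueProblem(
        r_centers=centers,
        volumes=volumes,
        face_areas=face_areas,
        face_dists=np.diff(centers),
        boundary_dist=centers[0] - rc,
        boundary_area=2.0 * math.pi * rc,
        boundary_side="inner",
        metabolism=metabolism,
        transport=transport,
        buffers=buffers,
        nhe=nhe,
    )


def simulate(
    geometry: KroghGeometry | None = None,
    metabolism: MetabolicParams | None = None,
    transport: TransportParams | None = None,
    buffers: BufferKinetics | None = None,
    nhe: Optional[NHEParams] = None,
    blood_params: BloodParams | None = None,
    tissue_tol: float = 1e-7,
) -> KroghSolution:
    """March the blood downstream, equilibrating the tissue column at each z.

    Raises :class:`tumorph.steady.ConvergenceError` if any tissue column
    fails to reach steady state.
    """
    geometry = geometry or KroghGeometry()
    metabolism = metabolism or MetabolicParams()
    transport = transport or TransportParams()
    buffers = buffers or BufferKinetics()
    blood_params = blood_params or BloodParams()

    prob = _annulus_problem(geometry, metabolism, transport, buffers, nhe)
    n_ax = geometry.n_axial
    dz_um = geometry.length * 1e3 / n_ax
    v_um = geometry.blood_velocity * 1e3 * 60.0  # µm/min
    a_blood = math.pi * geometry.capillary_radius**2  # µm² cross-section

    bs = arterial_blood(blood_params)
    z_grid = np.linspace(0.0, geometry.length, n_ax + 1)
    rows = []
    tissue_fields = {name: np.zeros((n_ax, prob.n_cells)) for name in SOLUTE_NAMES}
    y_warm: Optional[np.ndarray] = None
    max_resid = 0.0

    for i in range(n_ax):
        # tissue column at this z sees the local plasma composition
        prob.boundary = {
            "O2": bs.o2_free,
            "CO2": bs.CO2,
            "glc_e": bs.glucose,
            "lac_e": bs.lactate,
            "hco3_e": bs.HCO3,
            "h_e": 10.0**-bs.pH * 1e3,
        }
        y0 = y_warm if y_warm is not None else prob.initial_state()
        res = solve_steady(
            prob.rhs, y0, N_SOLUTES, tol=tissue_tol, newton_first=y_warm is not None
        )
        y_warm = res.y
        max_resid = max(max_resid, res.residual)
        Y = res.y.reshape(prob.n_cells, N_SOLUTES)
        for name in SOLUTE_NAMES:
            tissue_fields[name][i] = Y[:, IDX[name]]

        rows.append(
            {
                "z_mm": z_grid[i],
                "pH": bs.pH,
                "CO2": bs.CO2,
                "HCO3": bs.HCO3,
                "TIC": bs.tic,
                "alk": bs.alk,
                "glucose": bs.glucose,
                "lactate": bs.lactate,
                "O2_free": bs.o2_free,
                "O2_hb": bs.o2_hb,
                "O2_total": bs.o2_total,
            }
        )

        # wall exchange (flux per unit length into tissue) -> blood update
        bf = prob.boundary_fluxes(res.y)
        scale = dz_um / (v_um * a_blood)
        bs = BloodState(
            glucose=max(bs.glucose - bf["glc_e"] * scale, 0.0),
            lactate=max(bs.lactate - bf["lac_e"] * scale, 0.0),
            o2_total=max(bs.o2_total - bf["O2"] * scale, 0.0),
            tic=bs.tic - (bf["CO2"] + bf["hco3_e"]) * scale,
            alk=bs.alk - bf["hco3_e"] * scale,
        ).speciate(blood_params)

    rows.append(
        {
            "z_mm": z_grid[-1],
            "pH": bs.pH,
            "CO2": bs.CO2,
            "HCO3": bs.HCO3,
            "TIC": bs.tic,
            "alk": bs.alk,
            "glucose": bs.glucose,
            "lactate": bs.lactate,
            "O2_free": bs.o2_free,
            "O2_hb": bs.o2_hb,
            "O2_total": bs.o2_total,
        }
    )

    return KroghSolution(
        z=z_grid,
        blood=pd.DataFrame(rows),
        r=prob.r_centers,
        tissue=tissue_fields,
        shell_volumes=prob.volumes,
        geometry=geometry,
        max_residual=max_resid,
        converged=True,
    )


# ----------------------------------------------------------------------
def rate_sweep(
    phenotype: Literal["ferm", "resp"],
    max_rates: Sequence[float],
    geometry: KroghGeometry | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Tissue-averaged composition versus maximal metabolic rate."""
    rows = []
    for rate in max_rates:
        met = MetabolicParams(
            J_ferm_max=rate if phenotype == "ferm" else 0.0,
            J_resp_max=rate if phenotype == "resp" else 0.0,
        )
        sol = simulate(geometry=geometry, metabolism=met, **kwargs)
        w = np.broadcast_to(sol.shell_volumes, sol.tissue_pHe.shape)
        rows.append(
            {
                "max_rate": rate,
                "mean_tissue_pHe": sol.mean_tissue_pHe,
                "mean_tissue_lactate": float(
                    np.average(sol.tissue["lac_e"], weights=w)
                ),
                "mean_tissue_CO2": float(np.average(sol.tissue["CO2"], weights=w)),
                "venous_pH": float(sol.venous["pH"]),
                "venous_lactate": float(sol.venous["lactate"]),
                "venous_CO2": float(sol.venous["CO2"]),
            }
        )
    return pd.DataFrame(rows)


def geometry_sweep(
    axis: Literal["radius", "length"],
    values: Sequence[float],
    phenotype: Literal["ferm", "resp"] = "ferm",
    ferm_rate: float = 1.0,
    resp_rate: float = 0.067,
    base: KroghGeometry | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Mean tissue pH across Krogh geometries.

    ``radius`` sweeps the tissue annulus thickness at fixed length;
    ``length`` sweeps cylinder length at fixed thickness (default 250 µm for
    length sweeps, per the summary-figure conventions).  Blood velocity is
    held constant, so transit time scales with length.
    """
    base = base or KroghGeometry()
    met = MetabolicParams(
        J_ferm_max=ferm_rate if phenotype == "ferm" else 0.0,
        J_resp_max=resp_rate if phenotype == "resp" else 0.0,
    )
    rows = []
    for val in values:
        if axis == "radius":
            geom = base.model_copy(update={"tissue_thickness": val})
        else:
            geom = base.model_copy(update={"length": val})
        sol = simulate(geometry=geom, metabolism=met, **kwargs)
        rows.append(
            {
                axis: val,
                "mean_tissue_pHe": sol.mean_tissue_pHe,
                "venous_pH": float(sol.venous["pH"]),
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
def phi_phe_trajectory(sol) -> pd.DataFrame:
    """Paired (pHe, pHi) samples across the model domain.

    For a spheroid solution the pairing runs radially from surface to core;
    for a Krogh solution it runs axially using radial-mean tissue pH, which
    exposes the apex (maximal acidification) and the downstream reversal
    caused by glucose depletion.
    """
    from .spheroid import FieldSolution

    if isinstance(sol, FieldSolution):
        return pd.DataFrame(
            {"s": sol.r[::-1], "pHe": sol.pHe[::-1], "pHi": sol.pHi[::-1]}
        )
    w = sol.shell_volumes
    return pd.DataFrame(
        {
            "s": sol.z[:-1],
            "pHe": np.average(sol.tissue_pHe, weights=w, axis=1),
            "pHi": np.average(sol.tissue_pHi, weights=w, axis=1),
        }
    )


def o2_ph_trajectory(sol) -> pd.DataFrame:
    """Paired (O2, pHe) samples across the model domain (mM, pH units)."""
    from .spheroid import FieldSolution

    if isinstance(sol, FieldSolution):
        return pd.DataFrame({"s": sol.r[::-1], "O2": sol.fields["O2"][::-1], "pHe": sol.pHe[::-1]})
    w = sol.shell_volumes
    return pd.DataFrame(
        {
            "s": sol.z[:-1],
            "O2": np.average(sol.tissue["O2"], weights=w, axis=1),
            "pHe": np.average(sol.tissue_pHe, weights=w, axis=1),
        }
    )
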