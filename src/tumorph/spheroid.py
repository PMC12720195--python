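"""Steady-state diffusion-reaction model of a spheroid.

A sphere of tissue (default radius 500 µm, extracellular volume fraction
0.25) is bathed in well-stirred arterial-like medium: the surface clamps
every mobile solute at its arterial value, the centre is a symmetry point,
and intracellular species are reflected (zero flux) everywhere.  The model
predicts the radial profiles of all 10 solutes and the intra/extracellular
pH fields set up by fermentative and/or respiratory glucose metabolism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import PK_CARBONIC
from .params import (
    BufferKinetics,
    MetabolicParams,
    NHEParams,
    SpheroidGeometry,
    TransportParams,
)
from .steady import solve_steady
from .tissue import IDX, N_SOLUTES, SOLUTE_NAMES, TissueProblem, arterial_boundary

__all__ = [
    "FieldSolution",
    "solve_steady_state",
    "flux_balance_report",
    "rate_sweep",
    "radial_profiles",
    "anoxic_depth",
    "radius_sweep",
]

#: O2 below this level counts as anoxia (10 nM, i.e. 1e-8 M).
ANOXIA_THRESHOLD_MM = 1e-5


@dataclass
class FieldSolution:
    """Converged radial fields of a spheroid (or one Krogh tissue slice)."""

    r: np.ndarray  # shell-centre radii, µm
    fields: dict[str, np.ndarray]  # per-solute concentrations, mM
    residual: float
    converged: bool
    geometry: SpheroidGeometry | None = None

    @property
    def pHe(self) -> np.ndarray:
        return -np.log10(np.maximum(self.fields["h_e"], 1e-12) * 1e-3)

    @property
    def pHi(self) -> np.ndarray:
        return -np.log10(np.maximum(self.fields["h_i"], 1e-12) * 1e-3)

    @property
    def core(self) -> dict[str, float]:
        """Solute concentrations and pH at the innermost shell."""
        out = {k: float(v[0]) for k, v in self.fields.items()}
        out["pHe"] = float(self.pHe[0])
        out["pHi"] = float(self.pHi[0])
        return out


def _build_problem(
    geometry: SpheroidGeometry,
    metabolism: MetabolicParams,
    transport: TransportParams,
    buffers: BufferKinetics,
    nhe: Optional[NHEParams],
    boundary: Optional[dict[str, float]],
) -> TissueProblem:
    n = geometry.n_shells
    R = geometry.radius
    dr = R / n
    edges = np.linspace(0.0, R, n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    volumes = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    face_areas = 4.0 * math.pi * edges[1:-1] ** 2
    transport = transport.model_copy(update={"v_e": geometry.v_e})
    return TissueProblem(
        r_centers=centers,
        volumes=volumes,
        face_areas=face_areas,
        face_dists=np.diff(centers),
        boundary_dist=dr / 2.0,
        boundary_area=4.0 * math.pi * R**2,
        boundary_side="outer",
        boundary=boundary or arterial_boundary(),
        metabolism=metabolism,
        transport=transport,
        buffers=buffers,
        nhe=nhe,
    )


def solve_steady_state(
    geometry: SpheroidGeometry | None = None,
    metabolism: MetabolicParams | None = None,
    transport: TransportParams | None = None,
    buffers: BufferKinetics | None = None,
    nhe: Optional[NHEParams] = None,
    boundary: Optional[dict[str, float]] = None,
    tol: float = 1e-8,
    y0: Optional[np.ndarray] = None,
) -> FieldSolution:
    """Solve the spheroid to diffusion-reaction steady state.

    Raises :class:`tumorph.steady.ConvergenceError` (carrying the residual
    history) if the pseudo-time/Newton cascade cannot reach ``tol``.
    """
    geometry = geometry or SpheroidGeometry()
    metabolism = metabolism or MetabolicParams()
    transport = transport or TransportParams()
    buffers = buffers or BufferKinetics()
    prob = _build_problem(geometry, metabolism, transport, buffers, nhe, boundary)
    y_start = prob.initial_state() if y0 is None else y0
    res = solve_steady(prob.rhs, y_start, N_SOLUTES, tol=tol)
    Y = res.y.reshape(prob.n_cells, N_SOLUTES)
    fields = {name: Y[:, IDX[name]].copy() for name in SOLUTE_NAMES}
    sol = FieldSolution(
        r=prob.r_centers,
        fields=fields,
        residual=res.residual,
        converged=res.converged,
        geometry=geometry,
    )
    sol._problem = prob  # kept for flux-balance diagnostics
    sol._y = res.y
    return sol


def flux_balance_report(sol: FieldSolution) -> dict[str, float]:
    """Relative mismatch between surface influx and integrated consumption.

    At steady state the diffusive influx of each consumed solute through the
    surface must equal its volume-integrated metabolic consumption (and
    likewise efflux vs production).  Returns per-solute relative mismatches.
    """
    prob: TissueProblem = sol._problem
    bf = prob.boundary_fluxes(sol._y)
    rx = prob.integrated_reactions(sol._y)
    out: dict[str, float] = {}

    def rel(influx: float, consumption: float) -> float:
        scale = max(abs(influx), abs(consumption), 1e-30)
        return abs(influx - consumption) / scale

    out["glucose"] = rel(bf["glc_e"], rx["glucose_consumed"])
    out["O2"] = rel(bf["O2"], rx["o2_consumed"])
    out["lactate"] = rel(-bf["lac_e"], rx["lactate_produced"])
    # total carbon closure: glucose carbon entering must leave as lactate
    # carbon plus net TIC flux (normalized by the gross glucose carbon flux)
    net = 6.0 * bf["glc_e"] + 3.0 * bf["lac_e"] + bf["CO2"] + bf["hco3_e"]
    out["carbon"] = abs(net) / max(6.0 * abs(bf["glc_e"]), 1e-30)
    return out


def anoxic_depth(sol: FieldSolution) -> Optional[float]:
    """Depth from the surface (µm) beyond which O2 < 10 nM, or None."""
    o2 = sol.fields["O2"]
    R = sol.geometry.radius if sol.geometry is not None else float(sol.r[-1])
    anoxic = o2 < ANOXIA_THRESHOLD_MM
    if not anoxic.any():
        return None
    # shallowest anoxic shell, scanning inward from the surface
    idx = np.where(anoxic)[0].max()
    return float(R - sol.r[idx])


def radial_profiles(sol: FieldSolution) -> pd.DataFrame:
    """Tidy per-shell table of every solute plus pHe/pHi."""
    df = pd.DataFrame({"r_um": sol.r})
    for name in SOLUTE_NAMES:
        df[name] = sol.fields[name]
    df["pHe"] = sol.pHe
    df["pHi"] = sol.pHi
    return df


def rate_sweep(
    max_rates: Sequence[float],
    phenotype: Literal["ferm", "resp"],
    geometry: SpheroidGeometry | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Core solute composition versus maximal metabolic rate.

    Sweeps J_ferm_max (fermentative) or J_resp_max (respiratory) and records
    the spheroid-core state; successive solves are warm-started.
    """
    rows = []
    y0 = None
    for rate in max_rates:
        met = MetabolicParams(
            J_ferm_max=rate if phenotype == "ferm" else 0.0,
            J_resp_max=rate if phenotype == "resp" else 0.0,
        )
        sol = solve_steady_state(geometry=geometry, metabolism=met, y0=y0, **kwargs)
        y0 = sol._y
        row = {"max_rate": rate, **{f"core_{k}": v for k, v in sol.core.items()}}
        row["anoxic_depth_um"] = anoxic_depth(sol)
        rows.append(row)
    return pd.DataFrame(rows)


def radius_sweep(
    radii: Sequence[float],
    phenotype: Literal["ferm", "resp"],
    ferm_rate: float = 10.0,
    resp_rate: float = 0.67,
    n_shells: int = 100,
    **kwargs,
) -> pd.DataFrame:
    """Core and volume-mean extracellular pH versus spheroid radius."""
    met = MetabolicParams(
        J_ferm_max=ferm_rate if phenotype == "ferm" else 0.0,
        J_resp_max=resp_rate if phenotype == "resp" else 0.0,
    )
    rows = []
    for R in radii:
        geom = SpheroidGeometry(radius=R, n_shells=n_shells)
        sol = solve_steady_state(geometry=geom, metabolism=met, **kwargs)
        w = sol._problem.volumes
        rows.append(
            {
                "radius_um": R,
                "core_pHe": float(sol.pHe[0]),
                "mean_pHe": float(np.average(sol.pHe, weights=w)),
            }
        )
    return pd.DataFrame(rows)
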