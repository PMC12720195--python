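"""Shared finite-volume tissue core: 10 solutes on a stack of radial shells.

Solutes and compartments
------------------------
Gases O2 and CO2 penetrate the whole tissue volume (pooled concentration);
glucose and lactate exist in both compartments, crossing the membrane on
saturable carriers (GLUT-like, MCT-like); HCO3-, H+ and lactate partition
between intra- and extracellular spaces.  Extracellular solutes diffuse
through the interstitial fraction v_e only; intracellular solutes have no
spatial flux.  H+ is evolved through the buffer system rather than as a
free-diffusing trace species (its diffusive contribution at nM
concentrations is negligible).

H+ is stored in mM like everything else; rate laws that carry pK-scale
constants receive it converted to M.

The per-compartment bookkeeping: a flux J expressed per intracellular
volume changes the extracellular concentration at J * v_i / v_e.  With
uniform v_e, the compartment volume fraction cancels between diffusive flux
area and storage volume, so diffusion uses free-solution coefficients and
compartmentalization enters through source scaling — which is exactly what
makes extracellular gradients steeper than gas gradients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import kinetics as kin
from .constants import (
    ARTERIAL_CO2_MM,
    ARTERIAL_GLUCOSE_MM,
    ARTERIAL_HCO3_MM,
    ARTERIAL_O2_MM,
    ARTERIAL_PH,
)
from .params import BufferKinetics, MetabolicParams, NHEParams, TransportParams

N_SOLUTES = 10
IDX = {
    "O2": 0,
    "CO2": 1,
    "glc_e": 2,
    "glc_i": 3,
    "lac_e": 4,
    "lac_i": 5,
    "hco3_e": 6,
    "hco3_i": 7,
    "h_e": 8,
    "h_i": 9,
}
SOLUTE_NAMES = list(IDX)

#: Diffusing solutes mapped to the TransportParams attribute holding their
#: free-solution diffusivity (µm²/s).  h_e, and all intracellular species,
#: carry no spatial flux.
DIFFUSING = {
    "O2": "D_O2",
    "CO2": "D_CO2",
    "glc_e": "D_glucose",
    "lac_e": "D_lactate",
    "hco3_e": "D_HCO3",
}

LN10 = math.log(10.0)
_H_FLOOR_MM = 1e-9  # 1 pM; keeps log/ratio terms defined during transients


def arterial_boundary() -> dict[str, float]:
    """Boundary composition equivalent to arterial plasma (mM; H+ in mM)."""
    return {
        "O2": ARTERIAL_O2_MM,
        "CO2": ARTERIAL_CO2_MM,
        "glc_e": ARTERIAL_GLUCOSE_MM,
        "lac_e": 0.0,
        "hco3_e": ARTERIAL_HCO3_MM,
        "h_e": 10.0 ** (-ARTERIAL_PH) * 1e3,
    }


@dataclass
class TissueProblem:
    """Geometry-agnostic RHS builder for the 10-solute reaction-diffusion stack.

    ``volumes`` are shell volumes, ``face_areas`` the n-1 interior face
    areas, and the single open boundary (spheroid surface or capillary wall)
    is described by its area, the Dirichlet values of the diffusing solutes
    there, and which end it sits on.
    """

    r_centers: np.ndarray
    volumes: np.ndarray
    face_areas: np.ndarray  # interior faces, len n-1
    face_dists: np.ndarray  # centre-to-centre distances, len n-1
    boundary_dist: float  # boundary face to adjacent cell centre
    boundary_area: float
    boundary_side: str  # "outer" (spheroid) or "inner" (capillary wall)
    boundary: dict[str, float] = field(default_factory=arterial_boundary)
    metabolism: MetabolicParams = field(default_factory=MetabolicParams)
    transport: TransportParams = field(default_factory=TransportParams)
    buffers: BufferKinetics = field(default_factory=BufferKinetics)
    nhe: Optional[NHEParams] = None

    @property
    def n_cells(self) -> int:
        return self.r_centers.size

    def initial_state(self) -> np.ndarray:
        """Uniform arterial-like start (intracellular pool pre-equilibrated)."""
        y = np.zeros((self.n_cells, N_SOLUTES))
        b = self.boundary
        y[:, IDX["O2"]] = b["O2"]
        y[:, IDX["CO2"]] = b["CO2"]
        y[:, IDX["glc_e"]] = b["glc_e"]
        y[:, IDX["glc_i"]] = b["glc_e"]
        y[:, IDX["lac_e"]] = b["lac_e"]
        y[:, IDX["lac_i"]] = b["lac_e"]
        y[:, IDX["hco3_e"]] = b["hco3_e"]
        y[:, IDX["hco3_i"]] = b["hco3_e"]
        y[:, IDX["h_e"]] = b["h_e"]
        y[:, IDX["h_i"]] = 10.0 ** (-7.2) * 1e3  # typical resting pHi
        return y.ravel()

    # ------------------------------------------------------------------
    def reaction_rates(self, Y: np.ndarray) -> dict[str, np.ndarray]:
        """Pointwise reaction/membrane fluxes for state array (n, 10)."""
        p, tp, bk = self.metabolism, self.transport, self.buffers
        o2 = np.maximum(Y[:, IDX["O2"]], 0.0)
        co2 = np.maximum(Y[:, IDX["CO2"]], 0.0)
        glc_e = np.maximum(Y[:, IDX["glc_e"]], 0.0)
        glc_i = np.maximum(Y[:, IDX["glc_i"]], 0.0)
        lac_e = np.maximum(Y[:, IDX["lac_e"]], 0.0)
        lac_i = np.maximum(Y[:, IDX["lac_i"]], 0.0)
        hco3_e = np.maximum(Y[:, IDX["hco3_e"]], 0.0)
        hco3_i = np.maximum(Y[:, IDX["hco3_i"]], 0.0)
        h_e = np.maximum(Y[:, IDX["h_e"]], _H_FLOOR_MM)
        h_i = np.maximum(Y[:, IDX["h_i"]], _H_FLOOR_MM)
        H_e_M = h_e * 1e-3
        H_i_M = h_i * 1e-3

        J_f = kin.j_ferm(glc_i, H_i_M, p)
        J_r = kin.j_resp(glc_i, o2 * 1e-3, p)
        J_glut = kin.carrier_flux(glc_e, glc_i, tp.glut)
        J_mct = kin.mct_flux(lac_i, H_i_M, lac_e, H_e_M, tp.mct, tp.K_H_mct)
        if self.nhe is not None:
            J_nhe = kin.j_nhe(H_i_M, self.nhe)
            # Cl-/HCO3- exchange: the acid-loading counterpart of NHE
            J_ae = self.nhe.ae_permeability * (
                hco3_i - self.nhe.ae_ratio * hco3_e
            )
        else:
            J_nhe = np.zeros_like(h_i)
            J_ae = np.zeros_like(h_i)
        hyd_e = kin.co2_hydration_net(co2, hco3_e, H_e_M, bk, catalyzed=True)
        k_ic = bk.k_hydration * bk.ca_acceleration_ic
        hyd_i = k_ic * (co2 - h_i * hco3_i / (10.0 ** (-6.1) * 1e3))
        return {
            "J_ferm": J_f,
            "J_resp": J_r,
            "J_glut": J_glut,
            "J_mct": J_mct,
            "J_nhe": J_nhe,
            "J_ae": J_ae,
            "hyd_e": hyd_e,
            "hyd_i": hyd_i,
        }

    def rhs(self, y: np.ndarray) -> np.ndarray:
        """dY/dt for the flattened shell-major state vector."""
        n = self.n_cells
        Y = y.reshape(n, N_SOLUTES)
        dY = np.zeros_like(Y)
        tp, bk = self.transport, self.buffers
        v_e, v_i = tp.v_e, 1.0 - tp.v_e
        R = self.reaction_rates(Y)

        # diffusion (free-solution D; µm²/s -> µm²/min)
        for name, attr in DIFFUSING.items():
            s = IDX[name]
            D = getattr(tp, attr) * 60.0
            C = Y[:, s]
            flux_in = np.zeros(n)
            if n > 1:
                q = D * self.face_areas * (C[1:] - C[:-1]) / self.face_dists
                flux_in[:-1] += q
                flux_in[1:] -= q
            qb = D * self.boundary_area * (self.boundary[name] - (
                C[-1] if self.boundary_side == "outer" else C[0]
            )) / self.boundary_dist
            if self.boundary_side == "outer":
                flux_in[-1] += qb
            else:
                flux_in[0] += qb
            dY[:, s] += flux_in / self.volumes

        ratio = v_i / v_e
        rq = self.metabolism.respiratory_quotient
        dY[:, IDX["O2"]] += -6.0 * R["J_resp"] * v_i
        dY[:, IDX["CO2"]] += (
            6.0 * rq * R["J_resp"] * v_i - R["hyd_e"] * v_e - R["hyd_i"] * v_i
        )
        dY[:, IDX["glc_e"]] += -R["J_glut"] * ratio
        dY[:, IDX["glc_i"]] += R["J_glut"] - R["J_ferm"] - R["J_resp"]
        dY[:, IDX["lac_e"]] += R["J_mct"] * ratio
        dY[:, IDX["lac_i"]] += 2.0 * R["J_ferm"] - R["J_mct"]
        dY[:, IDX["hco3_e"]] += R["hyd_e"] + R["J_ae"] * ratio
        dY[:, IDX["hco3_i"]] += R["hyd_i"] - R["J_ae"]

        h_e = np.maximum(Y[:, IDX["h_e"]], _H_FLOOR_MM)
        h_i = np.maximum(Y[:, IDX["h_i"]], _H_FLOOR_MM)
        phi_e = R["hyd_e"] + (R["J_mct"] + R["J_nhe"]) * ratio
        phi_i = 2.0 * R["J_ferm"] + R["hyd_i"] - R["J_mct"] - R["J_nhe"]
        dY[:, IDX["h_e"]] += LN10 * h_e * phi_e / bk.conditioning_buffer_e
        dY[:, IDX["h_i"]] += LN10 * h_i * phi_i / bk.intrinsic_buffer_capacity
        return dY.ravel()

    # ------------------------------------------------------------------
    def boundary_fluxes(self, y: np.ndarray) -> dict[str, float]:
        """Diffusive flux of each diffusing solute *into* the tissue through
        the open boundary (amount/min; positive = entering tissue).

        Extracellular species cross a v_e fraction of the boundary area;
        gases cross it all.
        """
        Y = y.reshape(self.n_cells, N_SOLUTES)
        v_e = self.transport.v_e
        out: dict[str, float] = {}
        edge = -1 if self.boundary_side == "outer" else 0
        for name, attr in DIFFUSING.items():
            D = getattr(self.transport, attr) * 60.0
            frac = 1.0 if name in ("O2", "CO2") else v_e
            q = (
                frac
                * D
                * self.boundary_area
                * (self.boundary[name] - Y[edge, IDX[name]])
                / self.boundary_dist
            )
            out[name] = float(q)
        return out

    def integrated_reactions(self, y: np.ndarray) -> dict[str, float]:
        """Volume integrals of the reaction terms (amount/min).

        Metabolic/membrane rates are per intracellular volume; hydration per
        its own compartment.  Integration weights each by the corresponding
        compartment volume so totals are comparable with boundary fluxes.
        """
        Y = y.reshape(self.n_cells, N_SOLUTES)
        R = self.reaction_rates(Y)
        v_e = self.transport.v_e
        v_i = 1.0 - v_e
        w_i = self.volumes * v_i
        w_e = self.volumes * v_e
        return {
            "glucose_consumed": float(np.sum((R["J_ferm"] + R["J_resp"]) * w_i)),
            "lactate_produced": float(np.sum(2.0 * R["J_ferm"] * w_i)),
            "o2_consumed": float(np.sum(6.0 * R["J_resp"] * w_i)),
            "co2_produced": float(
                np.sum(
                    6.0 * self.metabolism.respiratory_quotient * R["J_resp"] * w_i
                    - R["hyd_e"] * w_e
                    - R["hyd_i"] * w_i
                )
            ),
            "hco3_consumed": float(-np.sum(R["hyd_e"] * w_e + R["hyd_i"] * w_i)),
        }
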