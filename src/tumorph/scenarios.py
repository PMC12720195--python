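"""Figure-level experiments: named scenario registry, Davenport utilities.

Each registry entry reproduces one of the package's headline experiments —
compartment trajectories, spheroid/Krogh profile runs and sweeps, pH-pH and
O2-pH trajectories — as tidy tables plus a summary of the scenario's
headline numbers.  Tables are the contract; plotting is left to the caller
(all outputs are plain CSV/JSON and headless-safe).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import acidbase, krogh, spheroid
from .acidbase import CarbonicState, CompartmentScenario, henderson_hasselbalch
from .constants import ARTERIAL_CO2_MM, ARTERIAL_HCO3_MM
from .params import KroghGeometry, MetabolicParams, NHEParams, SpheroidGeometry

__all__ = [
    "ScenarioSpec",
    "run_scenario",
    "davenport_points",
    "SCENARIO_REGISTRY",
    "run_registry",
]

#: Mixed phenotypes default to half the pure saturating rates.
SPHEROID_RATES = {"ferm": (10.0, 0.0), "resp": (0.0, 0.67), "mixed": (5.0, 0.33)}
KROGH_RATES = {"ferm": (1.0, 0.0), "resp": (0.0, 0.067), "mixed": (0.5, 0.033)}


class ScenarioSpec(BaseModel):
    """Declarative description of one model run (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    model: Literal["compartment", "spheroid", "krogh"]
    phenotype: Literal["ferm", "resp", "mixed"] = "ferm"
    J_ferm_max: Optional[float] = None  # override phenotype default
    J_resp_max: Optional[float] = None
    gas_open: bool = False  # compartment only
    nhe: bool = False
    n_steps: int = Field(default=50, ge=2)  # compartment trajectory
    radius: Optional[float] = None  # spheroid radius / krogh thickness, µm
    length: Optional[float] = None  # krogh length, mm
    n_shells: int = 100
    n_axial: int = 200
    n_radial: int = 40


def _rates(spec: ScenarioSpec) -> tuple[float, float]:
    table = SPHEROID_RATES if spec.model == "spheroid" else KROGH_RATES
    jf, jr = table[spec.phenotype]
    if spec.J_ferm_max is not None:
        jf = spec.J_ferm_max
    if spec.J_resp_max is not None:
        jr = spec.J_resp_max
    return jf, jr


def run_scenario(spec: ScenarioSpec, out_dir: str | Path | None = None) -> dict:
    """Execute one scenario; returns {"tables": {name: DataFrame}, "summary": dict}.

    With ``out_dir`` the tables are written as CSV and the summary as JSON;
    outputs are deterministic for a fixed spec.
    """
    nhe = NHEParams() if spec.nhe else None
    if spec.model == "compartment":
        mode = "respiration" if spec.phenotype == "resp" else "fermentation"
        scen = CompartmentScenario(gas_open=spec.gas_open, metabolic_mode=mode)
        traj = acidbase.davenport_trajectory(scen, spec.n_steps)
        frac = np.linspace(0.0, 1.0, spec.n_steps)
        table = pd.DataFrame(
            {
                "fraction_consumed": frac,
                "pH": [s.pH for s in traj],
                "CO2_mM": [s.CO2 for s in traj],
                "HCO3_mM": [s.HCO3 for s in traj],
                "TIC_mM": [s.TIC for s in traj],
            }
        )
        end = traj[-1]
        summary = {
            "endpoint_pH": end.pH,
            "endpoint_CO2_mM": end.CO2,
            "endpoint_HCO3_mM": end.HCO3,
            "endpoint_TIC_mM": end.TIC,
        }
        tables = {"trajectory": table}

    elif spec.model == "spheroid":
        jf, jr = _rates(spec)
        geom = SpheroidGeometry(
            radius=spec.radius or 500.0, n_shells=spec.n_shells
        )
        sol = spheroid.solve_steady_state(
            geometry=geom,
            metabolism=MetabolicParams(J_ferm_max=jf, J_resp_max=jr),
            nhe=nhe,
        )
        prof = spheroid.radial_profiles(sol)
        depth = spheroid.anoxic_depth(sol)
        summary = {
            "core_pHe": float(sol.pHe[0]),
            "core_pHi": float(sol.pHi[0]),
            "core_CO2_mM": float(sol.fields["CO2"][0]),
            "core_HCO3_mM": float(sol.fields["hco3_e"][0]),
            "anoxic_depth_um": depth,
            "converged": bool(sol.converged),
        }
        tables = {"profiles": prof}

    else:  # krogh
        jf, jr = _rates(spec)
        geom = KroghGeometry(
            length=spec.length or 2.0,
            tissue_thickness=spec.radius or 250.0,
            n_axial=spec.n_axial,
            n_radial=spec.n_radial,
        )
        sol = krogh.simulate(
            geometry=geom,
            metabolism=MetabolicParams(J_ferm_max=jf, J_resp_max=jr),
            nhe=nhe,
        )
        v = sol.venous
        summary = {
            "mean_tissue_pHe": sol.mean_tissue_pHe,
            "venous_pH": float(v["pH"]),
            "venous_CO2_mM": float(v["CO2"]),
            "venous_HCO3_mM": float(v["HCO3"]),
            "venous_lactate_mM": float(v["lactate"]),
            "venous_glucose_mM": float(v["glucose"]),
            "converged": bool(sol.converged),
        }
        tables = {"blood": sol.blood, "tissue_fields": _tissue_long(sol)}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return {"tables": tables, "summary": summary}


def _tissue_long(sol: krogh.KroghSolution) -> pd.DataFrame:
    """(z, r, solute...) long-format table of the 2-D tissue fields."""
    nz, nr = sol.tissue["O2"].shape
    zz = np.repeat(sol.z[:-1], nr)
    rr = np.tile(sol.r, nz)
    data = {"z_mm": zz, "r_um": rr}
    for name, arr in sol.tissue.items():
        data[name] = arr.ravel()
    data["pHe"] = sol.tissue_pHe.ravel()
    data["pHi"] = sol.tissue_pHi.ravel()
    return pd.DataFrame(data)


# ----------------------------------------------------------------------
def davenport_points(solution) -> pd.DataFrame:
    """(pH, CO2, HCO3) triples for Davenport-diagram plotting.

    Accepts a compartment trajectory (list of CarbonicState), a spheroid
    FieldSolution (points along the radius) or a KroghSolution (points along
    the capillary).  Points are projected onto the carbonic-equilibrium
    manifold: pH is recomputed from each (CO2, HCO3) pair, so every emitted
    triple satisfies the equilibrium ratio exactly.
    """
    if isinstance(solution, (list, tuple)) and solution and isinstance(
        solution[0], CarbonicState
    ):
        co2 = np.array([s.CO2 for s in solution])
        hco3 = np.array([s.HCO3 for s in solution])
    elif isinstance(solution, spheroid.FieldSolution):
        co2 = solution.fields["CO2"][::-1]
        hco3 = solution.fields["hco3_e"][::-1]
    elif isinstance(solution, krogh.KroghSolution):
        co2 = solution.blood["CO2"].to_numpy()
        hco3 = solution.blood["HCO3"].to_numpy()
    else:
        raise TypeError(f"unsupported solution type: {type(solution)!r}")
    ph = np.array([henderson_hasselbalch(c, b) for c, b in zip(co2, hco3)])
    return pd.DataFrame({"pH": ph, "CO2_mM": co2, "HCO3_mM": hco3})


# ----------------------------------------------------------------------
# registry of figure-level experiments; values are (description, callable)
def _fig_compartment(gas_open: bool, mode: str) -> Callable[[], dict]:
    phen = "resp" if mode == "respiration" else "ferm"
    return lambda: run_scenario(
        ScenarioSpec(model="compartment", phenotype=phen, gas_open=gas_open)
    )


def _fig_profiles(model: str, phenotype: str, **kw) -> Callable[[], dict]:
    return lambda: run_scenario(ScenarioSpec(model=model, phenotype=phenotype, **kw))


def _fig_spheroid_rate_sweep() -> dict:
    rates = [0.0, 0.1, 0.33, 1.0, 3.3, 10.0, 33.0, 100.0]
    geom = SpheroidGeometry(n_shells=60)
    tabs = {
        p: spheroid.rate_sweep(rates, p, geometry=geom) for p in ("ferm", "resp")
    }
    summary = {
        "ferm_plateau_core_pHe": float(tabs["ferm"]["core_pHe"].iloc[-1]),
        "resp_plateau_core_pHe": float(tabs["resp"]["core_pHe"].iloc[-1]),
    }
    return {"tables": tabs, "summary": summary}


def _fig_krogh_rate_sweep() -> dict:
    rates = [0.0, 0.01, 0.033, 0.1, 0.33, 1.0, 3.3, 10.0]
    geom = KroghGeometry(n_axial=80, n_radial=24)
    tabs = {
        p: krogh.rate_sweep(p, rates, geometry=geom) for p in ("ferm", "resp")
    }
    summary = {
        "ferm_plateau_mean_pHe": float(tabs["ferm"]["mean_tissue_pHe"].iloc[-1]),
        "resp_plateau_mean_pHe": float(tabs["resp"]["mean_tissue_pHe"].iloc[-1]),
    }
    return {"tables": tabs, "summary": summary}


def _fig_davenport_summary() -> dict:
    closed = acidbase.davenport_trajectory(CompartmentScenario(), 25)
    open_ = acidbase.davenport_trajectory(CompartmentScenario(gas_open=True), 25)
    tabs = {
        "closed_fermentation": davenport_points(closed),
        "open_fermentation": davenport_points(open_),
    }
    summary = {
        "closed_endpoint": (closed[-1].HCO3, closed[-1].CO2),
        "open_endpoint": (open_[-1].HCO3, open_[-1].CO2),
        "arterial": (ARTERIAL_HCO3_MM, ARTERIAL_CO2_MM),
    }
    return {"tables": tabs, "summary": summary}


def _fig_spheroid_radius_sweep() -> dict:
    radii = [50, 100, 150, 200, 300, 400, 500]
    tabs = {
        p: spheroid.radius_sweep(radii, p, n_shells=60) for p in ("ferm", "resp")
    }
    return {"tables": tabs, "summary": {}}


def _fig_krogh_geometry_sweep(axis: str) -> Callable[[], dict]:
    def run() -> dict:
        values = (
            [25, 50, 100, 150, 200, 300, 400, 500]
            if axis == "radius"
            else [0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 5.0]
        )
        base = KroghGeometry(n_axial=60, n_radial=24)
        tabs = {
            p: krogh.geometry_sweep(axis, values, p, base=base)
            for p in ("ferm", "resp")
        }
        ferm = tabs["ferm"]
        nadir = ferm.loc[ferm["mean_tissue_pHe"].idxmin()]
        return {
            "tables": tabs,
            "summary": {
                "ferm_nadir_pHe": float(nadir["mean_tissue_pHe"]),
                f"ferm_nadir_{axis}": float(nadir[axis]),
            },
        }

    return run


def _fig_ph_trajectories(model: str, thickness: float | None = None) -> Callable[[], dict]:
    def run() -> dict:
        tabs = {}
        for phen in ("ferm", "resp"):
            for with_nhe in (False, True):
                if model == "spheroid":
                    jf, jr = SPHEROID_RATES[phen]
                    sol = spheroid.solve_steady_state(
                        geometry=SpheroidGeometry(radius=250.0, n_shells=60),
                        metabolism=MetabolicParams(J_ferm_max=jf, J_resp_max=jr),
                        nhe=NHEParams() if with_nhe else None,
                    )
                else:
                    jf, jr = KROGH_RATES[phen]
                    sol = krogh.simulate(
                        geometry=KroghGeometry(
                            tissue_thickness=thickness or 250.0,
                            n_axial=60,
                            n_radial=24,
                        ),
                        metabolism=MetabolicParams(J_ferm_max=jf, J_resp_max=jr),
                        nhe=NHEParams() if with_nhe else None,
                    )
                key = f"{phen}_{'with' if with_nhe else 'no'}_nhe"
                tabs[key] = krogh.phi_phe_trajectory(sol)
        summary = {
            k: float(df["pHe"].min()) for k, df in tabs.items()
        }
        return {"tables": tabs, "summary": summary}

    return run


def _fig_o2_ph(model: str, thickness: float | None = None) -> Callable[[], dict]:
    def run() -> dict:
        tabs = {}
        for phen in ("ferm", "resp"):
            if model == "spheroid":
                jf, jr = SPHEROID_RATES[phen]
                sol = spheroid.solve_steady_state(
                    geometry=SpheroidGeometry(n_shells=60),
                    metabolism=MetabolicParams(J_ferm_max=jf, J_resp_max=jr),
                )
            else:
                jf, jr = KROGH_RATES[phen]
                sol = krogh.simulate(
                    geometry=KroghGeometry(
                        tissue_thickness=thickness or 250.0, n_axial=60, n_radial=24
                    ),
                    metabolism=MetabolicParams(J_ferm_max=jf, J_resp_max=jr),
                )
            tabs[phen] = krogh.o2_ph_trajectory(sol)
        return {"tables": tabs, "summary": {}}

    return run


SCENARIO_REGISTRY: dict[str, Callable[[], dict]] = {
    "fig1a-closed-vs-open-fermentation": _fig_davenport_summary,
    "fig1b-closed-respiration": _fig_compartment(False, "respiration"),
    "fig3b-spheroid-rate-sweep": _fig_spheroid_rate_sweep,
    "fig3c-spheroid-ferm": _fig_profiles("spheroid", "ferm"),
    "fig3c-spheroid-resp": _fig_profiles("spheroid", "resp"),
    "fig3c-spheroid-mixed": _fig_profiles("spheroid", "mixed"),
    "fig4b-krogh-rate-sweep": _fig_krogh_rate_sweep,
    "fig4c-krogh-ferm": _fig_profiles("krogh", "ferm", n_axial=100, n_radial=30),
    "fig4c-krogh-resp": _fig_profiles("krogh", "resp", n_axial=100, n_radial=30),
    "fig4c-krogh-mixed": _fig_profiles("krogh", "mixed", n_axial=100, n_radial=30),
    "fig5a-davenport-compartment": _fig_davenport_summary,
    "fig5d-spheroid-radius-sweep": _fig_spheroid_radius_sweep,
    "fig5e-krogh-radius-sweep": _fig_krogh_geometry_sweep("radius"),
    "fig5f-krogh-length-sweep": _fig_krogh_geometry_sweep("length"),
    "fig5g-spheroid-ph-trajectories": _fig_ph_trajectories("spheroid"),
    "fig5h-krogh50-ph-trajectories": _fig_ph_trajectories("krogh", 50.0),
    "fig5i-krogh250-ph-trajectories": _fig_ph_trajectories("krogh", 250.0),
    "fig5j-spheroid-o2-ph": _fig_o2_ph("spheroid"),
    "fig5k-krogh50-o2-ph": _fig_o2_ph("krogh", 50.0),
    "fig5l-krogh250-o2-ph": _fig_o2_ph("krogh", 250.0),
}


def run_registry(
    names: list[str] | None = None, out_root: str | Path = "figures"
) -> dict[str, dict]:
    """Run named registry entries (all by default), writing per-figure dirs."""
    out_root = Path(out_root)
    results = {}
    for name in names or list(SCENARIO_REGISTRY):
        fn = SCENARIO_REGISTRY[name]
        res = fn()
        fig_dir = out_root / name
        fig_dir.mkdir(parents=True, exist_ok=True)
        for tname, df in res["tables"].items():
            df.to_csv(fig_dir / f"{tname}.csv", index=False)
        (fig_dir / "summary.json").write_text(
            json.dumps(res["summary"], indent=2, default=str)
        )
        results[name] = res["summary"]
    return results
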