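# tumorph

Models of tumor-microenvironment (TME) acid–base composition: how low can
extracellular pH realistically fall in poorly perfused tumor tissue, what
mix of [CO2] and [HCO3⁻] carries that acidity, and how acidosis couples to
hypoxia.

Solid tumors outgrow their vasculature, so interstitial composition
diverges from plasma: O2 is depleted and metabolic acids accumulate. The
chemistry is governed by the carbonic buffer,

    pH = pK + log10([HCO3⁻]/[CO2]),   pK = 6.1,

perturbed by two metabolic routes: **fermentation** (1 glucose → 2 lactate⁻
+ 2 H⁺; the H⁺ consumes HCO3⁻ and releases CO2, conserving total inorganic
carbon) and **respiration** (1 glucose + 6 O2 → 6 CO2, raising it).
`tumorph` implements a hierarchy of models of these processes:

* `tumorph.acidbase` — closed and gas-open compartment equilibria (the
  quadratic re-equilibration of the carbonic pool), a flux-balance
  steady-state estimator, Davenport trajectories;
* `tumorph.kinetics` — fermentation/respiration Hill kinetics, CO2
  hydration, GLUT/MCT membrane carriers, NHE-based pHi regulation;
* `tumorph.spheroid` — a 10-solute diffusion–reaction steady state on a
  spherical spheroid (radius 500 µm, extracellular volume fraction 0.25);
* `tumorph.krogh` — a convection–diffusion–reaction Krogh cylinder: blood
  advected along a 5 µm capillary (Hb-bound O2 reservoir, non-carbonic
  buffer) exchanging with a 250 µm metabolizing tissue annulus;
* `tumorph.scenarios` — a registry of figure-level experiments emitting
  tidy CSV tables and JSON summaries;
* `tumorph.interactions` — an additive / synergistic / antagonistic
  classifier for dual-stress (acidosis × hypoxia) proteomic responses,
  with a synthetic proteome generator for validation.

The models, parameter choices and limitations are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Desk chemistry first: sealing arterial-like medium (pH 7.4, 24 mM HCO3⁻,
1.2 mM CO2, 5 mM glucose) and fermenting all glucose:

```python
>>> from tumorph import solve_equilibrium, solve_open_system
>>> s = solve_equilibrium(strong_acid=10.0)   # 10 mM lactic acid
>>> round(s.pH, 2), round(s.HCO3, 1), round(s.CO2, 1)
(6.2, 14.0, 11.2)
>>> round(solve_open_system(10.0, 1.2).pH, 2)  # same acid, CO2 vented
7.17
```

A closed compartment ends at pH 6.2 with most of the acidity carried as
hypercapnia (CO2 rises 1.2 → 11.2 mM); venting the CO2 (an incubator dish)
limits the same acid load to pH ~7.2. Neither extreme describes tissue —
for that, the transport models:

```python
>>> from tumorph.spheroid import solve_steady_state, anoxic_depth
>>> from tumorph.params import MetabolicParams
>>> sol = solve_steady_state(metabolism=MetabolicParams(J_ferm_max=10.0))
>>> round(float(sol.pHe[0]), 2)   # extracellular pH at the spheroid core
6.93
>>> resp = solve_steady_state(metabolism=MetabolicParams(J_resp_max=0.67))
>>> round(float(resp.pHe[0]), 2), round(anoxic_depth(resp))
(7.34, 182)
```

A fermentative 500 µm spheroid floors near pH 6.9 at the core — glucose
delivery and acid inhibition of glycolysis, not enzyme capacity, set the
limit. A respiratory spheroid turns anoxic ~180 µm below the surface yet
acidifies by only ~0.06 units, because CO2 production is capped by O2
penetration. Perfusion changes the picture:

```python
>>> from tumorph.krogh import simulate
>>> k = simulate(metabolism=MetabolicParams(J_ferm_max=1.0))
>>> round(k.venous["pH"], 2), round(k.venous["lactate"], 1), round(k.venous["CO2"], 1)
(6.75, 10.0, 4.7)
```

Blood leaving a fermentative Krogh cylinder has consumed essentially all
its glucose and carries ~10 mM lactate; because its inorganic carbon is
trapped during the 2 s transit, the acid appears as combined HCO3⁻
depletion and CO2 accumulation, pH ~6.7. Across the hierarchy the
physiologically realistic TME range comes out as roughly pH 6.7–7.4, with
hypercapnia an under-appreciated component of tumor acidosis.

From a shell:

```bash
tumorph spheroid --jferm 10 --out-dir out/       # profiles.csv + summary.json
tumorph krogh --jferm 1 --out-dir out/           # axial blood + 2-D tissue fields
tumorph compartment --gas-open                   # Davenport trajectory CSV
tumorph classify proteome.tsv                    # interaction class counts
tumorph run-figures --only fig3b-spheroid-rate-sweep
```

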