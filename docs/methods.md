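# Methods

`tumorph` implements a hierarchy of acid–base and metabolite transport
models of poorly perfused tumor tissue, ordered by physiological realism:
well-mixed compartments (closed or gas-open), a spherically symmetric
diffusion–reaction spheroid, and a Krogh-cylinder
convection–diffusion–reaction model of a capillary with its tissue annulus.
A separate module classifies dual-stress (acidosis × hypoxia) omics
responses. This note records the models, their assumptions, the defaults
and why, and the numerical choices.

## Carbonic buffer chemistry

The extracellular space is buffered predominantly by CO2/HCO3⁻ with

    K = [H+][HCO3⁻]/[CO2],  pK = 6.1   (concentrations in M)

Concentrations are stored in mM throughout; the ratio is evaluated in M.
The arterial reference is pH 7.4, [HCO3⁻] 24 mM, [CO2] 1.2 mM (note this
textbook triple sits ~0.001 pH off the exact pK 6.1 manifold; equilibrated
results report 7.401). O2 solubility is fixed at 10 µM/kPa, so arterial
13 kPa ↔ 0.13 mM free O2.

Two acid loads perturb the pool: lactic acid (neutralized by HCO3⁻,
producing equimolar CO2; total inorganic carbon, TIC, conserved) and direct
CO2 addition by respiration (TIC rises). Re-equilibration solves
`(H0+x)(B+x) = K(C−x)` for the CO2↔HCO3⁻+H⁺ interconversion `x`; the
physical root is evaluated via Vieta's formula to avoid cancellation (the
root is often ~10⁻⁹ of the coefficients), with a bisection fallback if the
discriminant is numerically marginal. Gas-open compartments clamp CO2 and
reduce to Henderson–Hasselbalch. Compartment (Davenport) trajectories are
parameterized linearly by the fraction of substrate consumed: glucose for
fermentation (2 lactic acid per glucose, so 5 mM glucose → 10 mM acid), the
dissolved-O2 endowment for closed respiration (0.13 mM CO2 at RQ 1).

The flux-balance estimator converts a sustained blood–tissue glucose
gradient into product counter-gradients: lactate at 2× (equal glucose and
lactate mobility), H⁺ leaving as an HCO3⁻/CO2 shuttle with gradients scaled
by relative effective diffusivities, default CO2 : HCO3⁻ : lactate =
8 : 2 : 1 (HCO3⁻ twice as mobile as lactate; CO2 another 4-fold faster
because it crosses cells). At the full 5 mM gradient this yields the
steady-state estimate pH 7.0 / 19 mM HCO3⁻ / 2.45 mM CO2.

## Metabolic and membrane kinetics

All rates are mM/min per intracellular volume. `J_ferm_max` and
`J_resp_max` are glucose-consumption ceilings; their iso-energetic pairing
is 15 : 1 (2 vs ~30 ATP per glucose). Fermentation is Michaelis in glucose
(K 1 mM) and cooperatively inhibited by intracellular H⁺ (half-maximal
pK 7.1, Hill coefficient 2.25, as measured in pancreatic cancer lines); a
`ferm_hill=False` switch recovers first-order inhibition. Respiration is
Michaelis in glucose and O2 (K 1 µM), producing 6 CO2 per glucose at RQ 1.

CO2 hydration uses the mass-action form k·([CO2] − [H⁺][HCO3⁻]/K), which
vanishes exactly at equilibrium; the uncatalyzed rate 0.15 min⁻¹ is
accelerated 1000-fold by carbonic anhydrase in *both* compartments (cells
express abundant cytosolic CA; with the uncatalyzed rate alone the
intracellular pool would sit far off equilibrium at steady state). In this
catalyzed regime results are hydration-insensitive: a further 10-fold
acceleration moves the fermentative core pH by < 0.01 (tested). Below
~100-fold the extracellular pool is measurably out of equilibrium and core
pH begins to depend on the rate, so the catalyzed default is part of the
model, not a free dial.

Glucose crosses the membrane on a symmetric saturable carrier (K_m 1 mM,
V_max 50 mM/min); lactate with equimolar H⁺ on an MCT-like reversible
bi-substrate carrier (K_m 2 mM, K_H 10⁻⁷ M, V_max 100 mM/min) whose flux
sign always follows the thermodynamic drive `lac_i·H_i − lac_e·H_e`. An
occupancy-product form was rejected: it caps net flux below the
thermodynamic drive and deadlocks lactate export in pHi-regulated
(alkaline) cells. Carrier capacities are high enough that membrane
transport is not rate-limiting (halving V_max moves core pH by < 0.05).

pHi regulation is modeled as the physiological extruder/loader pair: NHE
(J = J_max·H_i²/(H_i²+K²), K = 10⁻⁶·⁷ M, J_max 10 mM/min) opposed by a
Cl⁻/HCO3⁻ anion exchanger `P_ae·([HCO3⁻]_i − r_ae·[HCO3⁻]_e)` with
P_ae 0.1 min⁻¹ and Cl⁻-gradient factor r_ae 0.3, chosen so the two fluxes
null near pHi 7.2 (the set-point) at arterial conditions. A lone extruder
admits no steady state in this network: every extruded H⁺ is regenerated by
intracellular CO2 hydration whose HCO3⁻ by-product would accumulate without
bound.

## Spheroid model

Ten solutes on a radially symmetric sphere (default radius 500 µm,
extracellular volume fraction v_e 0.25, 100 finite-volume shells): pooled
gases O2 and CO2 (whole volume), extracellular glucose, lactate and HCO3⁻
(interstitial fraction only), their intracellular counterparts, and H⁺ in
both compartments. The surface clamps every mobile solute at arterial
values (5 mM glucose, 0.13 mM O2, 0 lactate, pH 7.4 / 24 / 1.2); the
centre is a symmetry point; intracellular species are reflected everywhere.

Compartmentalization is handled by source scaling: with uniform v_e the
volume fraction cancels between diffusive flux area and storage, so each
solute diffuses with its free-solution coefficient while a flux J per cell
volume enters the interstitium as J·v_i/v_e — which is precisely why
extracellular gradients are steeper than gas gradients. Free-solution
diffusivities (µm²/s): CO2 1900 and HCO3⁻ 1180 (aqueous 37 °C values),
O2 2500 (upper aqueous range), glucose = lactate = 1000 (equal mobility of
the glycolytic substrate/product pair). After v_e scaling the effective
CO2 : HCO3⁻ : lactate ratio is ≈ 7.6 : 1.2 : 1. This set reproduces all
four headline spheroid outcomes simultaneously (core pH 6.93 at saturating
fermentation; HCO3⁻-depletion : CO2-rise ≈ 6.4 : 1; respiratory core pH
7.34; anoxic depth 182 µm at J_resp 0.67 mM/min); stricter rounded ratios
(e.g. 10:2:1) push the fermentative core to pH 7.05.

H⁺ is evolved through the buffer system, not as a diffusing trace species
(negligible transport at nM concentrations): dH/dt = ln10·H·φ/β with φ the
net acid flux and β the non-carbonic buffering power — 20 mM/pH
intracellularly, and a small 5 mM/pH *conditioning* factor extracellularly
whose only role is to de-stiffen pseudo-time integration (linear buffering
rescales dH/dt and provably leaves steady states unchanged).

Anoxic depth is the shallowest depth at which O2 < 10 nM.

## Krogh cylinder

A capillary (radius 5 µm, length 2 mm, blood velocity 1 mm/s → 2 s transit)
supplies a coaxial tissue annulus (thickness 250 µm) with the same solute
network as the spheroid. Blood is radially well-mixed and advected one-way;
tissue has no axial diffusion (length ≫ thickness), so axial positions
couple only through blood. The steady state is computed by first-order
upwind marching (200 axial nodes): at each position the radial tissue
column is solved to steady state against the local plasma composition
(Dirichlet at the wall, zero-flux at the outer radius, warm-started from
the previous slice), and the wall exchange feeds the blood balance.

Blood carries conserved quantities — glucose, lactate, total O2, TIC, and
alkalinity — and is re-speciated pointwise: carbonic equilibrium plus a
linear non-carbonic buffer (capacity 10 mM/pH, representing hemoglobin and
plasma proteins; this value is pinned by the fermentative venous
composition, where a ~10 mM lactic-acid load must split into ~3 mM HCO3⁻
depletion and ~3 mM CO2 rise at constant TIC — a 25 mM/pH buffer would cap
venous acidification near pH 7.1). Hb–O2 binding is a Hill curve (n 2.7,
P50 26 µM free O2, capacity 9 mM); Hb-O2 and the buffer are confined to
blood. Wall bookkeeping: CO2 moves TIC only; HCO3⁻ moves TIC and
alkalinity together; lactate leaves the tissue as its anion (its H⁺
equivalents travel exclusively as the HCO3⁻/CO2 shuttle, the only spatial
H⁺ pathway in the tissue), so lactate itself is alkalinity-neutral at the
wall. Blood velocity is held constant across geometry sweeps; tissue
averages are volume-weighted means of pH over length × radius.

The radial mesh is geometrically graded (5 % growth per shell) toward the
capillary wall, where the O2 boundary layer around the 5 µm vessel is
steep; the respiratory venous ΔCO2 converges to ~1.79 mM on the graded
40-shell mesh versus 1.74 on a uniform one.

## Steady-state solver

Shell-major state ordering makes the Jacobian banded with half-bandwidth 10
(the solute count). Steady states are found by stiff pseudo-time
integration (BDF with banded sparsity) followed by damped Newton polish
using a grouped finite-difference banded Jacobian, to a residual below
10⁻⁸ mM/min (10⁻⁷ for Krogh slices, whose blood coupling dominates the
error budget); warm-started Krogh slices usually converge in a few Newton
steps without relaxation. Concentrations are floored at zero between
steps; saturation terms clip their arguments so transients cannot produce
negative-concentration rates. Non-convergence raises an error carrying the
residual history. Grid convergence of the fermentative core pH is at least
first order; 100 shells put the 500 µm spheroid within ~0.005 pH of the
fine-grid limit.

## Interaction classifier and synthetic proteome

For each protein, `delta = r_combo − (r_acid + r_hypoxia)` on log2
responses; `delta > +0.5` is synergistic, `< −0.5` antagonistic, otherwise
additive — unless the record is non-significant. The significance rule of
the original analysis is not published; this package flags a record
non-significant when |r_acid|, |r_hypoxia|, |r_combo| and |delta| are all
below a configurable cutoff (default 0.5), an interpretation stated
prominently here and in the API docs.

The synthetic proteome generator plants known classes (defaults: ~9.4k
proteins, 27.9 % additive / 8.8 % antagonistic / 6.1 % synergistic / 57.2 %
non-significant, the mix of a published SW1222 colorectal screen).
Significant single-stress effects are uniform on ±[0.8, 2.5] log2 units,
planted interactions on ±[0.7, 2.0], non-significant rows live strictly
inside the significance box; optional Gaussian noise is added to all three
channels. At zero noise the classifier recovers planted labels exactly —
which validates the decision rule, not the biology: the generator emulates
the scale and class mix of a real screen, not its correlation structure,
missingness or abundance-dependent variance, so recovery says nothing about
performance on real proteomics where the significance filter upstream
dominates.

## What the synthetic conditions do and do not show

The models are deterministic; "study conditions" are the arterial boundary
composition, the stated geometries, and the metabolic ceilings (spheroid
10 / 0.67 / mixed 5+0.33 mM/min; Krogh 1 / 0.067 / mixed 0.5+0.033).
Passing tests show the transport-reaction hierarchy reproduces the desk
chemistry and the printed field outcomes under these idealized conditions —
uniform v_e, glucose as the only substrate, no electrostatics, no necrosis,
no flow heterogeneity — and not that real tumors behave this way.

## Known limitations

* **Tissue–blood offset at steady state.** Downstream of glucose
  exhaustion the tissue column carries zero reaction flux and therefore
  equilibrates exactly with local blood. Two published observations — a
  fermentative tissue mean ~0.1 below venous blood pH, and a pH-vs-length
  nadir with downstream *recovery* attributed to non-metabolizing tissue
  "diluting" the outflow — describe a tissue–blood offset that a fully
  converged steady state cannot sustain, and this package reproduces
  neither (it finds a monotone length dependence with the venous pH as the
  floor). Both effects are consistent with a long-lived transient: the
  inactive downstream annulus holds ~2600× the blood volume and acidifies
  slowly, so finite-horizon integrations retain near-physiological
  interstitium there.
* The closed-compartment solver assumes instantaneous CA-catalyzed
  equilibration; time-resolved compartment kinetics are not modeled.
* Respiration is glucose-only at RQ 1; fatty acids, ketones, glutamine and
  glycogen are excluded (their carbon flux is an order of magnitude below
  glucose's).
* No Bohr effect on Hb–O2 binding; no temperature dependence of pK.
* The Krogh model is a single straight capillary: no network topology,
  pulsatile flow, red-cell discreteness or lymphatic drainage.
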