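# ghostcore

Quantitative analysis of CT-perfusion **ischemic core overestimation** ("ghost
infarct core") and its relationship to **net water uptake (NWU)** on admission
non-contrast CT — implemented as a reproducible pipeline driven by synthetic
phantoms and simulated cohorts, so that every stage has a recoverable ground
truth without patient data.

## The problem and the models

In acute ischemic stroke, CT perfusion predicts the irreversibly injured
"core" as the tissue with relative cerebral blood flow at or below 20% of the
contralateral side (pCore). This prediction is known to overshoot in some
patients: the final infarct on follow-up CT turns out much smaller than the
admission pCore. Ischemic edema offers a cross-check: infarcting tissue takes
up water and becomes hypodense, quantified by mirror-ROI densitometry as

```
%NWU = (1 − D_ischemic / D_normal) × 100
```

where `D_ischemic` and `D_normal` are the mean Hounsfield-unit densities of
the lesion ROI and of the same ROI mirrored onto the contralateral
hemisphere, both restricted to the 20–80 HU window (excluding CSF and
calcification). Tissue with a large pCore but *low* NWU has not yet developed
edema — exactly the tissue whose core label is likely premature.

The package implements:

* **densitometry** — mirror-ROI %NWU from a CT volume and a lesion mask;
* **volumetrics** — pCore (rCBF ≤ 20%), hypoperfusion (Tmax ≥ 6 s), penumbra
  (hypoperfusion − pCore), lesion growth (`FIV − pCore`), and the
  overestimation classifier (growth < −10 mL);
* **cohort statistics** — per-unit relative risks (RR) of overestimation and
  of 90-day good outcome (mRS 0–2) from a log-binomial GLM (with a
  modified-Poisson fallback and a logit/odds-ratio mode), OLS for the cube
  root of lesion growth, univariable → multivariable model construction, a
  50 mL pCore-stratified sensitivity analysis, and baseline descriptive
  tables (Shapiro–Wilk routing, Wilcoxon rank-sum comparisons);
* **synthetic generators** — an ellipsoidal head-CT/CTP phantom whose lesion
  density encodes a known true NWU, and a cohort simulator whose
  overestimation outcome follows a multiplicative-RR model (so the fitted RRs
  have known truth, e.g. 0.94 per %NWU, 1.02 per mL pCore, 1.28 per ASPECTS
  point) and whose cube-root lesion growth is linear with known slope;
* a **CLI** (`ghostcore`) tying the stages into a seeded pipeline with NIfTI
  image I/O, CSV/JSON tables, and config-hash provenance in every output.

Regression models are scikit-learn-style estimators
(`RelativeRiskRegression`, `LinearEffectsRegression`) and compose with
sklearn tooling; `fit_rr` / `fit_linear` are thin tabular wrappers.

## Worked example

```bash
ghostcore reproduce --out demo --seed 1
```

prints

```
measured phantom NWU 7.26% (truth 7.2%); tables in demo/study
```

i.e. a phantom with a true water uptake of 7.2% and 1.5 HU of added Gaussian
noise was generated, and mirror-ROI densitometry measured 7.26% — the ROI
mean cancels the voxel noise. `demo/phantom_measurement.json` holds the full
per-case row: `d_ischemic` 32.448 HU, `d_normal` 34.988 HU, pCore 11.56 mL,
penumbra 51.88 mL, FIV 32.91 mL, lesion growth +21.35 mL, not overestimated —
each equal (to storage precision) to the generator's truth sidecar.
`demo/study/` contains the simulated-cohort tables: baseline descriptives
stratified by overestimation, univariable and multivariable RR tables for
overestimation and good outcome, the cube-root growth regression, and the
stratified sensitivity tables. For example, the univariable RR per %NWU in
`table2_overestimation.csv` for the default 284-subject cohort is 0.93 —
low water uptake predicts core overestimation, by construction of the
generative model.

The same stages are available as `simulate-phantom`, `simulate-cohort`,
`measure` and `analyze` subcommands, and as library functions
(`generate_phantom`, `compute_nwu`, `compute_pcore`, `simulate_cohort`,
`fit_rr`, `run_study`, ...).

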