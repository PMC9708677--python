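# Methods

## Densitometric net water uptake

Percent net water uptake of an ischemic lesion on non-contrast CT is

    %NWU = (1 − D_ischemic / D_normal) × 100,

with `D_ischemic` the mean Hounsfield density of the lesion ROI and
`D_normal` the mean density of the same ROI reflected across the
midsagittal plane onto the unaffected hemisphere. Both ROIs are restricted
to the inclusive 20–80 HU window before averaging; the window bounds are
inclusive by choice ("between 20 and 80" is ambiguous) and configurable.
Mirroring is a pure voxel-grid reflection about a configured plane — the
deterministic analog of manually placing a symmetric contralateral ROI — 
with an adjustable plane index for off-centre heads; no registration is
attempted. A lesion that touches or crosses the midline is rejected, since
its mirror would overlap ischemic tissue. ROI density defaults to the
arithmetic mean of surviving voxels (a `median` flag is provided; the
choice of summary statistic is a genuine open point and the default is
documented, not asserted as canonical). Negative NWU values, which occur
under noise, are returned unclipped so that recovery statistics remain
unbiased. Densitometry is volumetric (3-D ROI); per-slice variants are out
of scope.

## Perfusion volumetrics and outcomes

* pCore: brain voxels with rCBF ≤ 20% of contralateral (inclusive; the
  threshold is configurable in (0, 100]).
* Hypoperfusion: Tmax ≥ 6 s. The source description is self-contradictory
  ("at least 6 s" vs "> 6 s"); the inclusive convention is the default and
  configurable.
* Penumbra (mismatch) = hypoperfusion − pCore, floored at 0 with a logged
  warning when the predicted core extends beyond the Tmax lesion.
* Lesion growth = FIV − pCore (signed, mL); the final infarct volume comes
  from an input follow-up mask.
* Core overestimation: growth strictly below −10 mL (−10.0 exactly is not
  overestimated).
* Lesion growth is transformed with the signed cube root,
  sign(x)·|x|^(1/3), before linear modelling; the signed extension is the
  standard monotone odd choice for a variable that is negative for the
  overestimated cases.
* pCore voxels are not constrained to lie inside the Tmax lesion.

## Relative-risk regression

Effects on the binary outcomes (core overestimation; 90-day mRS 0–2) are
reported as per-unit relative risks with Wald 95% CIs. The primary model
is the **log-binomial GLM** (binomial family, log link): it is the only
model whose exponentiated coefficients are literally RRs. A "binary
logistic regression reported as RRs" is a contradiction in terms, and this
package resolves it in favour of the reported effect measure; an explicit
`family="logistic"` mode returns odds ratios, flagged as such in the
result scale. Because the log link does not respect the binomial mean
domain, the IRLS fit can fail; the estimator then falls back to the
modified-Poisson RR estimator (Poisson working likelihood, HC1 sandwich
variance), recording the fallback in the result. Fitting is complete-case
per model, with the rows actually used reported as `n_used`; no multiple
testing correction is applied. Univariable screening at p < 0.05 selects
the multivariable model, with forced adjustment covariates (sex for the
90-day outcome model) supplied by configuration.

## Synthetic phantom

The phantom is an ellipsoidal "brain" (uniform 35 HU parenchyma) in a
61×72×40 grid of 2 mm isotropic voxels, midsagittal plane at the central
sagittal slice, with symmetric CSF ventricles (8 HU) and no skull (a
brain-extracted NCCT is assumed), which keeps left-right mirroring exact.
An ellipsoidal lesion confined to one hemisphere carries density
`tissue_HU × (1 − true_NWU/100)` — the generative inverse of the NWU
formula — so noise-free densitometry recovers the true uptake exactly.
Small CSF (8 HU) and calcification (120 HU) inclusions are embedded inside
the lesion ROI to exercise the 20–80 HU filter. Concentric ellipsoids
define the rCBF core (10%), the Tmax lesion (8 s) and the follow-up
infarct; default geometry yields pCore ≈ 11.6 mL, hypoperfusion ≈ 63 mL
and FIV ≈ 33 mL, sized to the analysis cohort's reported medians.
Additive Gaussian HU noise (default 0, typical 1.5) is seeded and applied
to both CT volumes. Phantoms with lesion density below 20 HU
(true NWU > ~43% at 35 HU tissue) are rejected as densitometrically
unmeasurable. The phantom deliberately omits CT texture, beam hardening,
partial-volume effects at tissue boundaries, and anatomical asymmetry —
passing recovery tests therefore demonstrates correctness of the
measurement pipeline, not robustness to real-scanner artifacts.

## Synthetic cohort

Covariates are drawn from right-skewed laws matched to the reported cohort
quartiles: NWU ~ Gamma(1.39, 6.70) (median 7.2%, Q3 12.8%), pCore ~
lognormal(σ = 1.6) truncated at 100 mL by resampling with the scale
calibrated so the truncated median is 11.9 mL, ASPECTS a rounded clipped
normal with median 7–8, onset-to-imaging lognormal with median 3.2 h,
reperfusion success (eTICI 2c/3) at 49.3%. The pCore truncation encodes
that patients with very large baseline cores are excluded from
thrombectomy cohorts; it also keeps the unbounded log-link risk model
inside [0, 1] over the sampled support.

The overestimation outcome is Bernoulli with

    P = clip(baseline × RR_NWU^(NWU−7.2) × RR_pCore^(pCore−11.9)
             × RR_ASPECTS^(ASPECTS−7), 0, 1),

reference values at the cohort medians so that `baseline_risk`
(default 0.16, the observed overestimation rate) is interpretable. A
multiplicative-RR (log-linear) model is used — rather than a logistic
one — precisely so that the log-binomial refit recovers the generative
RRs as its coefficients. Probabilities are clipped to [0, 1]; if more than
1% of subjects clip, a warning with the count is logged (with all default
effects active plus the secondary-outcome model this does occur in the
tails — it is the documented cost of an unbounded link). Cube-root lesion
growth is linear in NWU, pCore, ASPECTS and reperfusion with Gaussian
noise (SD 0.5 on the cube-root scale) and an intercept placed so the
median growth matches the reported 18.4 mL; growth in mL is the cube. The
90-day good outcome follows its own RR model (baseline 0.293; age, NIHSS,
ASPECTS, reperfusion effects), and mRS90 is drawn uniformly within the
good (0–2) or poor (3–6) range. Per-field missingness (mRS90 25%, NIHSS
2%, eTICI 1.4%) mimics registry data and exercises complete-case fitting.

By default the overestimation flag and lesion growth are drawn
*independently*, each from its stated model — their joint law is not
specified by the analysis being emulated, and independent draws keep each
marginal model exactly recoverable. `consistency=True` instead draws
growth from a truncated normal on the cube-root scale so that
growth < −10 mL holds iff the flag is set. In independent mode
`FIV = pCore + growth` may be slightly negative in the tail; this is
accepted rather than floored, as flooring would bias the growth model.

## Numerical and design choices

* Reflection indices are rounded to the nearest voxel, so half-integer
  planes (even-sized axes) reflect exactly.
* Log-binomial fits start from intercept = log(mean outcome), slopes 0.
* Determinism: every stochastic component takes a seed and uses
  `numpy.random.default_rng`; identical config + seed reproduces outputs
  byte for byte, and every written table embeds the config hash, seed and
  package version.
* Problem sizes for the recovery experiments are 50,000 subjects for RR
  recovery, 10,000 for the growth slope, and 100 seeded phantoms for the
  noise study — sizes at which Monte-Carlo error is comfortably inside the
  recovery tolerances (±0.02 RR, ±0.01 slope, 0.5 NWU points).
* Shapiro–Wilk (α = 0.05) routes descriptive summaries to median/IQR vs
  mean/SD; group comparisons use the Wilcoxon rank-sum test; categorical
  fields are reported as proportions; per-field n appears only when values
  are missing.
* Stratified sensitivity analysis splits at pCore 50 mL, the cutoff
  inclusive in the upper stratum.

## Known limitations

* Wald CIs on GLM coefficients may differ slightly from other software's
  profile or score intervals.
* The phantom's uniform-density geometry makes densitometry exactly
  solvable; it cannot detect errors that only manifest with heterogeneous
  tissue or imperfect head symmetry.
* Time-variable RRs near 1.00 per minute are modelled but not recovery
  targets: at printed rounding they are indistinguishable from the null.
* Manual steps of the emulated workflow (lesion segmentation, CBV-guided
  ROI placement, eTICI grading) are inputs here, not algorithms.
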