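"""Simulated stroke cohorts with known generative effect structure.

Each simulated subject carries the clinical and imaging covariates of the
analysis cohort (age, NIHSS, ASPECTS, NWU, pCore, workflow times, eTICI)
drawn from right-skewed laws matched to reported cohort quartiles, plus
three model-driven outcomes:

* ``overestimated`` — Bernoulli under a log-linear (multiplicative
  relative-risk) model, so that a log-binomial GLM fitted to the cohort
  recovers the generative RRs as its coefficients;
* ``lesion_growth_ml`` — drawn on the cube-root scale as a linear model
  plus Gaussian noise, then cubed back to mL;
* ``good_outcome`` / ``mrs90`` — 90-day functional independence under its
  own relative-risk model.

The risk model is log-linear and therefore unbounded; probabilities are
clipped to [0, 1] and a warning is emitted if more than 1% of subjects
clip.  By default the overestimation flag and lesion growth are drawn
independently, each from its own stated model; ``consistency=True``
instead forces growth < -10 mL exactly for flagged subjects (truncated
resampling), coupling the two outcomes the way a shared final infarct
volume would.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CovariateDistributions", "EffectConfig", "simulate_cohort"]

logger = logging.getLogger(__name__)

#: eTICI grades counted as successful reperfusion
ETICI_SUCCESS = ("2c", "3")


@dataclass(frozen=True)
class CovariateDistributions:
    """Sampling laws for the baseline covariates.

    Defaults reproduce the analysis cohort's reported medians and
    interquartile ranges: NWU ~ Gamma (median 7.2%, Q3 12.8%), pCore ~
    lognormal (median 11.9 mL) truncated at ``pcore_max_ml``, onset-to-
    imaging ~ lognormal (median 3.2 h).  pCore truncation reflects that
    patients with very large baseline cores are excluded from
    thrombectomy and hence from such cohorts; it also keeps the log-link
    risk model inside [0, 1] for the default effect sizes.
    """

    age_mean: float = 74.0
    age_sd: float = 11.0
    female_prob: float = 0.48
    nihss_mean: float = 16.0
    nihss_sd: float = 6.0
    aspects_mean: float = 7.5
    aspects_sd: float = 1.8
    nwu_gamma_shape: float = 1.39
    nwu_gamma_scale: float = 6.70
    # lognormal scale calibrated so the 100 mL-truncated median is 11.9 mL
    pcore_lognormal_scale_ml: float = 15.115
    pcore_log_sigma: float = 1.6
    pcore_max_ml: float = 100.0
    onset_imaging_median_min: float = 192.0
    onset_imaging_sigma: float = 0.95
    recanalization_delay_median_min: float = 90.0
    recanalization_delay_sigma: float = 0.4
    iv_alteplase_prob: float = 0.6
    reperfusion_prob: float = 0.493

    def sample(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        age = np.clip(rng.normal(self.age_mean, self.age_sd, n), 18, 100)
        sex = np.where(rng.random(n) < self.female_prob, "F", "M")
        nihss = np.clip(np.round(rng.normal(self.nihss_mean, self.nihss_sd, n)), 0, 42)
        aspects = np.clip(np.round(rng.normal(self.aspects_mean, self.aspects_sd, n)), 0, 10)
        nwu = rng.gamma(self.nwu_gamma_shape, self.nwu_gamma_scale, n)
        # truncated lognormal via resampling (no atom at the bound)
        mu = math.log(self.pcore_lognormal_scale_ml)
        pcore = rng.lognormal(mu, self.pcore_log_sigma, n)
        bad = pcore > self.pcore_max_ml
        while bad.any():
            pcore[bad] = rng.lognormal(mu, self.pcore_log_sigma, int(bad.sum()))
            bad = pcore > self.pcore_max_ml
        oti = rng.lognormal(math.log(self.onset_imaging_median_min),
                            self.onset_imaging_sigma, n)
        otr = oti + rng.lognormal(math.log(self.recanalization_delay_median_min),
                                  self.recanalization_delay_sigma, n)
        iv = rng.random(n) < self.iv_alteplase_prob
        reperf = rng.random(n) < self.reperfusion_prob
        etici = np.where(reperf,
                         rng.choice(ETICI_SUCCESS, n),
                         rng.choice(["0", "1", "2a", "2b"], n))
        return pd.DataFrame({
            "age": age, "sex": sex, "nihss": nihss, "aspects": aspects,
            "nwu_pct": nwu, "pcore_ml": pcore,
            "onset_to_imaging_min": oti, "onset_to_recanalization_min": otr,
            "iv_alteplase": iv, "etici": etici, "reperfusion_success": reperf,
        })


@dataclass(frozen=True)
class EffectConfig:
    """Generative truth for the simulated cohort's outcome models.

    Relative risks are per covariate unit, multiplicative on the
    overestimation probability around ``baseline_risk`` (the probability
    at the reference covariate values, the cohort medians: NWU 7.2%,
    pCore 11.9 mL, ASPECTS 7).  Growth coefficients act on the cube-root
    mL scale.  Defaults encode the adjusted effect estimates of the
    analysis (NWU RR 0.94, pCore RR 1.02, ASPECTS RR 1.28; growth
    beta_NWU 0.06) so that refitting the models is a parameter-recovery
    exercise with known truth.
    """

    n_subjects: int = 284
    seed: int = 0
    baseline_risk: float = 0.16
    rr_nwu_per_pct: float = 0.94
    rr_pcore_per_ml: float = 1.02
    rr_aspects_per_point: float = 1.28
    nwu_ref: float = 7.2
    pcore_ref: float = 11.9
    aspects_ref: float = 7.0
    growth_intercept: float = 5.06
    beta_nwu: float = 0.06
    beta_pcore: float = -0.01
    beta_aspects: float = -0.33
    beta_reperfusion: float = -0.87
    growth_noise_sd: float = 0.5
    # 90-day good outcome (mRS 0-2) risk model
    good_outcome_baseline: float = 0.293
    rr_good_age_per_year: float = 0.97
    rr_good_nihss_per_point: float = 0.93
    rr_good_aspects_per_point: float = 1.18
    rr_good_reperfusion: float = 1.55
    age_ref: float = 76.0
    nihss_ref: float = 15.0
    consistency: bool = False
    covariate_distributions: CovariateDistributions = field(
        default_factory=CovariateDistributions)
    missing_mrs90_prob: float = 0.25
    missing_nihss_prob: float = 0.02
    missing_etici_prob: float = 0.014

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if not 0 < self.baseline_risk < 1:
            raise ValueError("baseline_risk must lie in (0, 1)")
        for name in ("rr_nwu_per_pct", "rr_pcore_per_ml", "rr_aspects_per_point",
                     "rr_good_age_per_year", "rr_good_nihss_per_point",
                     "rr_good_aspects_per_point", "rr_good_reperfusion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.growth_noise_sd < 0:
            raise ValueError("growth_noise_sd must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def _clip_probs(p: np.ndarray, what: str) -> np.ndarray:
    n_clip = int(np.sum((p < 0) | (p > 1)))
    if n_clip > 0.01 * p.size:
        logger.warning(
            "%s risk model left [0, 1] for %d of %d subjects; probabilities clipped",
            what, n_clip, p.size,
        )
    return np.clip(p, 0.0, 1.0)


def overestimation_probability(cfg: EffectConfig, cov: pd.DataFrame) -> np.ndarray:
    """Per-subject overestimation probability under the log-linear RR model."""
    p = (cfg.baseline_risk
         * cfg.rr_nwu_per_pct ** (cov["nwu_pct"].to_numpy() - cfg.nwu_ref)
         * cfg.rr_pcore_per_ml ** (cov["pcore_ml"].to_numpy() - cfg.pcore_ref)
         * cfg.rr_aspects_per_point ** (cov["aspects"].to_numpy() - cfg.aspects_ref))
    return _clip_probs(p, "overestimation")


def _good_outcome_probability(cfg: EffectConfig, cov: pd.DataFrame) -> np.ndarray:
    p = (cfg.good_outcome_baseline
         * cfg.rr_good_age_per_year ** (cov["age"].to_numpy() - cfg.age_ref)
         * cfg.rr_good_nihss_per_point ** (cov["nihss"].to_numpy() - cfg.nihss_ref)
         * cfg.rr_good_aspects_per_point ** (cov["aspects"].to_numpy() - cfg.aspects_ref)
         * cfg.rr_good_reperfusion ** cov["reperfusion_success"].to_numpy().astype(float))
    return _clip_probs(p, "good outcome")


def growth_cbrt_mean(cfg: EffectConfig, cov: pd.DataFrame) -> np.ndarray:
    """Linear predictor of lesion growth on the cube-root scale."""
    return (cfg.growth_intercept
            + cfg.beta_nwu * cov["nwu_pct"].to_numpy()
            + cfg.beta_pcore * cov["pcore_ml"].to_numpy()
            + cfg.beta_aspects * cov["aspects"].to_numpy()
            + cfg.beta_reperfusion * cov["reperfusion_success"].to_numpy().astype(float))


def simulate_cohort(config: EffectConfig) -> pd.DataFrame:
    """Draw a cohort table with the configured generative effect structure.

    Returns one row per subject with covariates, outcomes, and the latent
    per-subject outcome probability ``p_overest_true`` (ground truth for
    Monte-Carlo checks).  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    cov = config.covariate_distributions.sample(config.n_subjects, rng)
    n = config.n_subjects

    p_over = overestimation_probability(config, cov)
    overest = rng.random(n) < p_over

    mean_cbrt = growth_cbrt_mean(config, cov)
    if config.consistency:
        # growth conditioned on the flag: truncated normal on the cube-root
        # scale, below cbrt(-10) for flagged subjects and above it otherwise
        cutoff_cbrt = np.cbrt(-10.0)
        sd = config.growth_noise_sd
        if sd == 0:
            raise ValueError("consistency mode requires growth_noise_sd > 0")
        a = np.where(overest, -np.inf, (cutoff_cbrt - mean_cbrt) / sd)
        b = np.where(overest, (cutoff_cbrt - mean_cbrt) / sd, np.inf)
        cbrt = stats.truncnorm.rvs(a, b, loc=mean_cbrt, scale=sd, random_state=rng)
    else:
        cbrt = mean_cbrt + rng.normal(0.0, config.growth_noise_sd, n)
    growth = cbrt ** 3

    fiv = cov["pcore_ml"].to_numpy() + growth  # may dip below 0 in independent mode

    p_good = _good_outcome_probability(config, cov)
    good = rng.random(n) < p_good
    mrs90 = np.where(good, rng.integers(0, 3, n), rng.integers(3, 7, n)).astype(float)

    df = cov.copy()
    df["p_overest_true"] = p_over
    df["overestimated"] = overest
    df["lesion_growth_ml"] = growth
    df["fiv_ml"] = fiv
    df["mrs90"] = mrs90
    df["good_outcome"] = good

    # per-field missingness, as in clinical registries
    df["good_outcome"] = df["good_outcome"].astype(float)
    df["reperfusion_success"] = df["reperfusion_success"].astype(float)
    for col, prob in (("mrs90", config.missing_mrs90_prob),
                      ("nihss", config.missing_nihss_prob),
                      ("etici", config.missing_etici_prob)):
        if prob > 0:
            miss = rng.random(n) < prob
            df.loc[miss, col] = np.nan if col != "etici" else None
            if col == "mrs90":
                df.loc[miss, "good_outcome"] = np.nan
            if col == "etici":
                df.loc[miss, "reperfusion_success"] = np.nan
    df.insert(0, "case_id", [f"case{i:05d}" for i in range(n)])
    return df
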