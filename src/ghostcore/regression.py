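"""Relative-risk and linear-effects regression for cohort analysis.

The primary effect measure here is the relative risk (RR) per covariate
unit, reported with Wald 95% confidence intervals.  A logistic regression
exponentiates to odds ratios, not RRs; the only GLM whose coefficients
exponentiate to RRs is the binomial model with a log link (log-binomial).
`RelativeRiskRegression` therefore fits a log-binomial GLM by default and,
because the log link does not respect the [0, 1] mean constraint and can
fail to converge, falls back to the modified-Poisson estimator (Poisson
working model with robust sandwich variance), flagging the fallback in
the fitted attributes.  A logit family is available for odds-ratio
comparison.

Estimators follow scikit-learn conventions (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) so
they compose with sklearn model selection; the module-level ``fit_rr`` /
``fit_linear`` helpers wrap them for tabular cohort workflows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "RegressionResult",
    "RelativeRiskRegression",
    "LinearEffectsRegression",
    "fit_rr",
    "fit_linear",
    "build_multivariable",
    "stratified_sensitivity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionResult:
    """One predictor's effect estimate: a Table-2/Table-3 style cell."""

    predictor: str
    estimate: float          # RR (ratio scale) or beta (linear scale)
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    model_tag: str           # "univariable" | "multivariable"
    scale: str               # "relative_risk" | "odds_ratio" | "beta"
    fallback: bool = False   # True if the robust-Poisson fallback was used

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_used": self.n_used,
            "model_tag": self.model_tag,
            "scale": self.scale,
            "fallback": self.fallback,
        }


def _validate_design(X: np.ndarray, names: list[str]) -> None:
    for j, name in enumerate(names):
        col = X[:, j]
        if np.ptp(col) == 0:
            raise ValueError(f"predictor '{name}' is constant in the analysis sample")


def _as_matrix(X, feature_names=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        return X.to_numpy(dtype=float), names
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = feature_names or [f"x{j}" for j in range(X.shape[1])]
    return X, list(names)


class RelativeRiskRegression(BaseEstimator):
    """Binary-outcome regression reporting per-unit relative risks.

    Parameters
    ----------
    family : {"log-binomial", "poisson-robust", "logistic"}
        "log-binomial" (default) fits a binomial GLM with log link, whose
        exponentiated coefficients are relative risks; "poisson-robust" is
        the modified-Poisson RR estimator; "logistic" fits a logit model
        (estimates are odds ratios, flagged as such).
    alpha : float
        Two-sided miscoverage of the Wald confidence intervals.
    fallback : bool
        If the log-binomial fit fails or does not converge, refit with
        the robust Poisson approximation instead of raising.

    Attributes
    ----------
    coef_ : ndarray, log-scale coefficients per feature.
    intercept_ : float, log baseline risk (or log odds for logistic).
    rr_ : ndarray, exp(coef_) — relative risks (odds ratios for logistic).
    conf_int_ : (n_features, 2) ndarray of CI bounds on the ratio scale.
    pvalues_ : ndarray of Wald p-values per feature.
    n_used_ : int, rows used after complete-case filtering.
    used_fallback_ : bool, whether the robust-Poisson fallback was taken.
    """

    def __init__(self, family: str = "log-binomial", alpha: float = 0.05,
                 max_iter: int = 200, fallback: bool = True):
        self.family = family
        self.alpha = alpha
        self.max_iter = max_iter
        self.fallback = fallback

    def _fit_glm(self, y, Xd, family_name):
        if family_name == "log-binomial":
            start = np.zeros(Xd.shape[1])
            start[0] = np.log(max(y.mean(), 1e-6))
            with warnings.catch_warnings():
                # statsmodels warns that the log link does not respect the
                # binomial domain; that is exactly the model we want
                warnings.simplefilter("ignore")
                fam = sm.families.Binomial(link=sm.families.links.Log())
                model = sm.GLM(y, Xd, family=fam)
                res = model.fit(start_params=start, maxiter=self.max_iter)
            return res, res.bse
        if family_name == "poisson-robust":
            model = sm.GLM(y, Xd, family=sm.families.Poisson())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(cov_type="HC1", maxiter=self.max_iter)
            return res, res.bse
        if family_name == "logistic":
            model = sm.GLM(y, Xd, family=sm.families.Binomial())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(maxiter=self.max_iter)
            return res, res.bse
        raise ValueError(f"unknown family '{family_name}'")

    def fit(self, X, y, feature_names=None):
        X, names = _as_matrix(X, feature_names)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        keep = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
        X, y = X[keep], y[keep]
        classes = np.unique(y)
        if not np.all(np.isin(classes, [0.0, 1.0])):
            raise ValueError("outcome must be binary 0/1")
        if classes.size < 2:
            raise ValueError("outcome has a single class in the analysis sample")
        if X.shape[0] < X.shape[1] + 10:
            raise ValueError("fewer complete-case rows than predictors + 10")
        _validate_design(X, names)

        Xd = sm.add_constant(X, has_constant="add")
        self.used_fallback_ = False
        try:
            res, bse = self._fit_glm(y, Xd, self.family)
            converged = getattr(res, "converged", True)
            bad = (not converged or not np.all(np.isfinite(res.params))
                   or not np.all(np.isfinite(bse)))
        except (ValueError, np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
            res, bad = None, True
            if self.family != "log-binomial" or not self.fallback:
                raise ValueError(
                    f"model fit failed for predictors {names}: {exc}"
                ) from exc
        if bad:
            if self.family == "log-binomial" and self.fallback:
                logger.warning(
                    "log-binomial fit did not converge for %s; "
                    "falling back to robust-Poisson RR estimation", names)
                res, bse = self._fit_glm(y, Xd, "poisson-robust")
                self.used_fallback_ = True
            elif res is None:
                raise ValueError(f"model fit failed for predictors {names}")

        z = stats.norm.ppf(1 - self.alpha / 2)
        params = np.asarray(res.params)
        bse = np.asarray(res.bse)
        self.feature_names_in_ = names
        self.n_features_in_ = len(names)
        self.intercept_ = float(params[0])
        self.coef_ = params[1:]
        self.se_ = bse[1:]
        self.rr_ = np.exp(self.coef_)
        self.conf_int_ = np.column_stack([
            np.exp(self.coef_ - z * self.se_),
            np.exp(self.coef_ + z * self.se_),
        ])
        self.pvalues_ = np.asarray(res.pvalues)[1:]
        self.n_used_ = int(y.shape[0])
        self._result = res
        return self

    def predict_risk(self, X) -> np.ndarray:
        """Predicted outcome probability per row (clipped to [0, 1])."""
        check_is_fitted(self, "coef_")
        X, _ = _as_matrix(X)
        eta = self.intercept_ + X @ self.coef_
        if self.family == "logistic":
            return 1.0 / (1.0 + np.exp(-eta))
        return np.clip(np.exp(eta), 0.0, 1.0)

    def predict(self, X) -> np.ndarray:
        """Most likely class (risk >= 0.5) per row."""
        return (self.predict_risk(X) >= 0.5).astype(int)

    def results_(self, model_tag: str = "univariable") -> list[RegressionResult]:
        check_is_fitted(self, "coef_")
        scale = "odds_ratio" if self.family == "logistic" else "relative_risk"
        return [
            RegressionResult(
                predictor=name,
                estimate=float(self.rr_[j]),
                ci_low=float(self.conf_int_[j, 0]),
                ci_high=float(self.conf_int_[j, 1]),
                p_value=float(self.pvalues_[j]),
                n_used=self.n_used_,
                model_tag=model_tag,
                scale=scale,
                fallback=self.used_fallback_,
            )
            for j, name in enumerate(self.feature_names_in_)
        ]


class LinearEffectsRegression(BaseEstimator):
    """Ordinary least squares with Wald CIs, for cube-root growth models."""

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y, feature_names=None):
        X, names = _as_matrix(X, feature_names)
        y = np.asarray(y, dtype=float)
        keep = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
        X, y = X[keep], y[keep]
        if X.shape[0] < X.shape[1] + 10:
            raise ValueError("fewer complete-case rows than predictors + 10")
        if np.ptp(y) == 0:
            # degenerate but well-defined: flat response, zero slopes
            self.feature_names_in_ = names
            self.intercept_ = float(y[0]) if y.size else 0.0
            self.coef_ = np.zeros(len(names))
            self.se_ = np.zeros(len(names))
            self.conf_int_ = np.zeros((len(names), 2))
            self.pvalues_ = np.ones(len(names))
            self.n_used_ = int(y.shape[0])
            return self
        _validate_design(X, names)
        res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
        ci = res.conf_int(alpha=self.alpha)
        self.feature_names_in_ = names
        self.n_features_in_ = len(names)
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params)[1:]
        self.se_ = np.asarray(res.bse)[1:]
        self.conf_int_ = np.asarray(ci)[1:]
        self.pvalues_ = np.asarray(res.pvalues)[1:]
        self.n_used_ = int(y.shape[0])
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X, _ = _as_matrix(X)
        return self.intercept_ + X @ self.coef_

    def results_(self, model_tag: str = "univariable") -> list[RegressionResult]:
        check_is_fitted(self, "coef_")
        return [
            RegressionResult(
                predictor=name,
                estimate=float(self.coef_[j]),
                ci_low=float(self.conf_int_[j, 0]),
                ci_high=float(self.conf_int_[j, 1]),
                p_value=float(self.pvalues_[j]),
                n_used=self.n_used_,
                model_tag=model_tag,
                scale="beta",
            )
            for j, name in enumerate(self.feature_names_in_)
        ]


def _prepare(cohort: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Numeric view of the requested columns (bools to 0/1), NaN for missing."""
    out = pd.DataFrame(index=cohort.index)
    for c in cols:
        if c not in cohort.columns:
            raise KeyError(f"cohort table has no column '{c}'")
        s = cohort[c]
        if s.dtype == object:
            s = s.map(lambda v: np.nan if v is None or (isinstance(v, float) and np.isnan(v))
                      else float(v))
        out[c] = pd.to_numeric(s, errors="raise").astype(float)
    return out


def fit_rr(cohort: pd.DataFrame, outcome: str, predictors: list[str],
           multivariable: bool = False, family: str = "log-binomial",
           alpha: float = 0.05) -> list[RegressionResult]:
    """Relative-risk regression of a binary cohort outcome on predictors.

    Univariable mode (default) fits one single-predictor model per entry
    in ``predictors``; multivariable mode fits them jointly.  Rows with a
    missing outcome or predictor are dropped per model (complete-case),
    with the rows used reported in ``n_used``.
    """
    tag = "multivariable" if multivariable else "univariable"
    data = _prepare(cohort, [outcome] + list(predictors))
    y = data[outcome]
    results: list[RegressionResult] = []
    if multivariable:
        est = RelativeRiskRegression(family=family, alpha=alpha)
        est.fit(data[list(predictors)], y)
        return est.results_(tag)
    for pred in predictors:
        est = RelativeRiskRegression(family=family, alpha=alpha)
        est.fit(data[[pred]], y)
        results.extend(est.results_(tag))
    return results


def fit_linear(cohort: pd.DataFrame, response: str, predictors: list[str],
               multivariable: bool = False, alpha: float = 0.05) -> list[RegressionResult]:
    """OLS of a continuous response (e.g. cube-root growth) on predictors."""
    tag = "multivariable" if multivariable else "univariable"
    data = _prepare(cohort, [response] + list(predictors))
    y = data[response]
    if multivariable:
        est = LinearEffectsRegression(alpha=alpha)
        est.fit(data[list(predictors)], y)
        return est.results_(tag)
    results: list[RegressionResult] = []
    for pred in predictors:
        est = LinearEffectsRegression(alpha=alpha)
        est.fit(data[[pred]], y)
        results.extend(est.results_(tag))
    return results


def build_multivariable(univariable: list[RegressionResult], alpha: float = 0.05,
                        forced: tuple[str, ...] = ()) -> list[str]:
    """Select predictors for the multivariable model.

    Keeps predictors significant in univariable regression (p < alpha),
    plus any ``forced`` adjustment covariates (e.g. sex for the 90-day
    outcome model), preserving input order.
    """
    if not univariable:
        raise ValueError("no univariable results supplied")
    selected = [r.predictor for r in univariable if r.p_value < alpha]
    for f in forced:
        if f not in selected:
            selected.append(f)
    if not selected:
        logger.warning("no univariable predictor reached p < %.3g; "
                       "multivariable model is empty", alpha)
    return selected


def stratified_sensitivity(cohort: pd.DataFrame, outcome: str, predictors: list[str],
                           cutoff_ml: float = 50.0, stratify_on: str = "pcore_ml",
                           kind: str = "rr", **kwargs) -> dict[str, list[RegressionResult]]:
    """Refit the models separately below/at-or-above a pCore volume cutoff.

    Strata: ``"lt"`` (< cutoff) and ``"ge"`` (>= cutoff, inclusive upper
    stratum).  ``kind`` selects ``fit_rr`` or ``fit_linear``.
    """
    vals = pd.to_numeric(cohort[stratify_on], errors="raise")
    strata = {"lt": cohort[vals < cutoff_ml], "ge": cohort[vals >= cutoff_ml]}
    for name, sub in strata.items():
        if sub.empty:
            raise ValueError(
                f"stratum '{name}' ({stratify_on} {'<' if name == 'lt' else '>='} "
                f"{cutoff_ml} mL) is empty")
    fitter = fit_rr if kind == "rr" else fit_linear
    return {name: fitter(sub, outcome, predictors, **kwargs)
            for name, sub in strata.items()}
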