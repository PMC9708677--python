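"""Relative-risk and linear regression: recovery, oracle agreement, edge cases."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import ghostcore as g
from conftest import single_effect_config


def _bernoulli_loglik_log_link(params, X, y):
    eta = params[0] + X @ params[1:]
    p = np.exp(eta)
    if np.any(p >= 1) or np.any(p <= 0):
        return 1e12
    return -np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))


class TestRelativeRiskRegression:
    def test_agrees_with_brute_force_ml(self):
        """Log-binomial fit matches direct likelihood maximisation (2 predictors, n=200)."""
        rng = np.random.default_rng(12)
        n = 200
        X = np.column_stack([rng.normal(0, 1, n), rng.normal(0, 1, n)])
        p = np.clip(0.25 * np.exp(0.20 * X[:, 0] - 0.15 * X[:, 1]), 0, 1)
        y = (rng.random(n) < p).astype(float)
        est = g.RelativeRiskRegression().fit(X, y)
        direct = optimize.minimize(
            _bernoulli_loglik_log_link, x0=[np.log(y.mean()), 0.0, 0.0],
            args=(X, y), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 20000})
        assert direct.success
        np.testing.assert_allclose(
            np.r_[est.intercept_, est.coef_], direct.x, atol=1e-3)

    @pytest.mark.parametrize("rr,covariate", [
        (0.90, "nwu_pct"),
        (0.94, "nwu_pct"),
        (1.00, "nwu_pct"),
        (1.02, "pcore_ml"),
        (1.28, "aspects"),
    ])
    def test_rr_point_recovery_large_n(self, rr, covariate):
        """Fitted RR lands within 0.02 of the generative RR at n=50,000."""
        key = {"nwu_pct": "rr_nwu_per_pct", "pcore_ml": "rr_pcore_per_ml",
               "aspects": "rr_aspects_per_point"}[covariate]
        cfg = single_effect_config(50000, seed=21, **{key: rr})
        df = g.simulate_cohort(cfg)
        res = g.fit_rr(df, "overestimated", [covariate])[0]
        assert abs(res.estimate - rr) < 0.02
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_ci_coverage_under_truth(self):
        """95% Wald CI covers the generative RR in >=90 of 100 replicates."""
        hits = 0
        for seed in range(100):
            df = g.simulate_cohort(single_effect_config(4000, seed=seed,
                                                        rr_nwu_per_pct=0.94))
            res = g.fit_rr(df, "overestimated", ["nwu_pct"])[0]
            hits += res.ci_low <= 0.94 <= res.ci_high
        assert hits >= 90

    def test_null_model_ci_covers_one(self):
        """Under a null simulation the CI covers RR=1 at nominal rate."""
        hits = 0
        for seed in range(100):
            df = g.simulate_cohort(single_effect_config(800, seed=1000 + seed))
            res = g.fit_rr(df, "overestimated", ["nwu_pct"])[0]
            hits += res.ci_low <= 1.0 <= res.ci_high
        assert hits >= 93

    def test_constant_predictor_raises_with_name(self, small_cohort):
        df = small_cohort.assign(flat=1.0)
        with pytest.raises(ValueError, match="flat"):
            g.fit_rr(df, "overestimated", ["flat"])

    def test_single_class_outcome_raises(self, small_cohort):
        df = small_cohort.assign(never=0.0)
        with pytest.raises(ValueError, match="single class"):
            g.fit_rr(df, "never", ["nwu_pct"])

    def test_complete_case_rows_reported(self, small_cohort):
        res = g.fit_rr(small_cohort, "good_outcome", ["nwu_pct"])[0]
        n_complete = small_cohort.dropna(subset=["good_outcome", "nwu_pct"]).shape[0]
        assert res.n_used == n_complete < len(small_cohort)

    def test_logistic_mode_reports_odds_ratio_scale(self, small_cohort):
        res = g.fit_rr(small_cohort, "overestimated", ["nwu_pct"],
                       family="logistic")[0]
        assert res.scale == "odds_ratio"

    def test_predict_risk_matches_generative_probability(self):
        df = g.simulate_cohort(single_effect_config(50000, seed=2,
                                                    rr_nwu_per_pct=0.94))
        est = g.RelativeRiskRegression().fit(df[["nwu_pct"]],
                                             df["overestimated"].astype(float))
        pred = est.predict_risk(df[["nwu_pct"]])
        np.testing.assert_allclose(pred, df["p_overest_true"], atol=0.02)

    def test_sklearn_get_set_params_roundtrip(self):
        est = g.RelativeRiskRegression(alpha=0.1)
        est2 = g.RelativeRiskRegression(**est.get_params())
        assert est2.get_params() == est.get_params()


class TestLinearEffectsRegression:
    def test_beta_recovery(self):
        cfg = single_effect_config(10000, seed=13, beta_pcore=0.0,
                                   beta_aspects=0.0, beta_reperfusion=0.0,
                                   growth_intercept=2.2)
        df = g.simulate_cohort(cfg)
        df["cbrt_growth"] = g.cubic_root_transform(df["lesion_growth_ml"].to_numpy())
        res = g.fit_linear(df, "cbrt_growth", ["nwu_pct"])[0]
        assert abs(res.estimate - 0.06) < 0.01

    def test_zero_noise_exact_recovery(self):
        cfg = single_effect_config(500, seed=14, growth_noise_sd=0.0,
                                   beta_reperfusion=0.0, growth_intercept=2.2)
        df = g.simulate_cohort(cfg)
        df["cbrt_growth"] = g.cubic_root_transform(df["lesion_growth_ml"].to_numpy())
        res = g.fit_linear(df, "cbrt_growth",
                           ["nwu_pct", "pcore_ml", "aspects"], multivariable=True)
        by_name = {r.predictor: r.estimate for r in res}
        assert by_name["nwu_pct"] == pytest.approx(0.06, abs=1e-8)
        assert by_name["pcore_ml"] == pytest.approx(-0.01, abs=1e-8)
        assert by_name["aspects"] == pytest.approx(-0.33, abs=1e-8)

    def test_constant_response_gives_zero_slopes(self, small_cohort):
        df = small_cohort.assign(const_resp=3.0)
        res = g.fit_linear(df, "const_resp", ["nwu_pct"])[0]
        assert res.estimate == 0.0 and res.p_value == 1.0


class TestModelConstruction:
    def test_significant_predictors_selected(self):
        results = [
            g.RegressionResult("a", 1.1, 1.0, 1.2, 0.03, 100, "univariable", "relative_risk"),
            g.RegressionResult("b", 1.0, 0.9, 1.1, 0.20, 100, "univariable", "relative_risk"),
            g.RegressionResult("c", 1.3, 1.1, 1.5, 0.001, 100, "univariable", "relative_risk"),
        ]
        assert g.build_multivariable(results) == ["a", "c"]

    def test_forced_adjustment_appended(self):
        results = [g.RegressionResult("a", 1.1, 1.0, 1.2, 0.03, 100,
                                      "univariable", "relative_risk")]
        assert g.build_multivariable(results, forced=("sex_female",)) == \
            ["a", "sex_female"]

    def test_none_significant_warns_and_returns_empty(self, caplog):
        results = [g.RegressionResult("a", 1.0, 0.9, 1.1, 0.8, 100,
                                      "univariable", "relative_risk")]
        with caplog.at_level("WARNING"):
            assert g.build_multivariable(results) == []
        assert "no univariable predictor" in caplog.text

    def test_generative_effects_recovered_by_selection(self):
        """Univariable screening keeps the truly nonzero risk effects."""
        df = g.simulate_cohort(g.EffectConfig(n_subjects=20000, seed=17))
        uni = g.fit_rr(df, "overestimated", ["nwu_pct", "pcore_ml", "aspects", "age"])
        selected = g.build_multivariable(uni)
        assert {"nwu_pct", "pcore_ml", "aspects"} <= set(selected)
        assert "age" not in selected


class TestStratifiedSensitivity:
    def test_boundary_assignment_at_cutoff(self):
        df = pd.DataFrame({
            "pcore_ml": [10.0, 49.9, 50.0, 70.0],
            "overestimated": [0, 1, 0, 1],
        })
        vals = df["pcore_ml"]
        assert ((vals < 50).sum(), (vals >= 50).sum()) == (2, 2)

    def test_single_stratum_cohort_raises(self, small_cohort):
        low = small_cohort[small_cohort["pcore_ml"] < 50]
        with pytest.raises(ValueError, match="stratum"):
            g.stratified_sensitivity(low, "overestimated", ["nwu_pct"])

    def test_per_stratum_recovery(self):
        """Each stratum refit recovers the shared generative NWU effect."""
        df = g.simulate_cohort(single_effect_config(50000, seed=19,
                                                    rr_nwu_per_pct=0.94))
        out = g.stratified_sensitivity(df, "overestimated", ["nwu_pct"])
        assert set(out) == {"lt", "ge"}
        for stratum in out.values():
            assert abs(stratum[0].estimate - 0.94) < 0.04
        n_lt = out["lt"][0].n_used
        assert n_lt == (df["pcore_ml"] < 50).sum()
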