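import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.interpolate import BSpline

from bpcentiles import distributions, gamlss
from bpcentiles.gamlss import Control, ModelSpec, centile, fit, predict_params, sbc, select_model


def _iid_frame(params, n, seed):
    rng = np.random.default_rng(seed)
    y = distributions.sample(n, params, seed + 1)
    return pd.DataFrame(dict(bp=y, age=rng.uniform(3, 17, n),
                             height_cm=rng.uniform(95, 180, n)))


class TestSBC:
    def test_formula(self):
        assert sbc(-100, 5, 100) == pytest.approx(200 + 5 * np.log(100), abs=1e-10)
        assert sbc(-100, 5, 100) == pytest.approx(223.0259, abs=1e-4)

    def test_zero_df(self):
        assert sbc(-50, 0, 10) == 100.0

    def test_monotone_in_df(self):
        vals = [sbc(-100, df, 500) for df in range(6)]
        assert np.all(np.diff(vals) > 0)


class TestFit:
    def test_intercept_only_parameter_recovery(self):
        df = _iid_frame(distributions.BCCGParams(100, 0.1, 0.3), 20000, 2)
        fr = fit(df, "bp", ModelSpec(mu="1", sigma="1", nu="1"))
        pars, _ = predict_params(fr, 10.0, 140.0)
        assert pars["mu"][0] == pytest.approx(100, abs=0.5)
        assert pars["sigma"][0] == pytest.approx(0.1, abs=0.005)
        assert pars["nu"][0] == pytest.approx(0.3, abs=0.15)

    def test_normal_limit_matches_closed_form(self):
        df = _iid_frame(distributions.BCCGParams(100, 0.1, 1.0), 20000, 4)
        fr = fit(df, "bp", ModelSpec(mu="1", sigma="1", nu="1"))
        pars, _ = predict_params(fr, 8.0, 130.0)
        assert pars["nu"][0] == pytest.approx(1.0, abs=0.15)
        p90 = centile(fr, 8.0, 130.0, 0.9)
        target = 100 + 10 * stats.norm.ppf(0.9)
        assert p90[0] == pytest.approx(target, abs=0.3)

    def test_refit_deterministic(self, analysis_small, quick_control):
        boys = analysis_small[analysis_small.sex == "M"]
        a = fit(boys, "sbp", ModelSpec(), quick_control)
        b = fit(boys, "sbp", ModelSpec(), quick_control)
        assert a.logL == pytest.approx(b.logL, abs=1e-8)
        assert a.sbc == b.sbc

    def test_sbc_recomputable_from_fields(self, fit_small_sbp):
        fr = fit_small_sbp
        assert fr.sbc == pytest.approx(-2 * fr.logL + fr.df * np.log(fr.n), abs=1e-9)
        assert fr.df >= 3

    def test_nested_model_loglik_never_decreases(self, analysis_small, quick_control):
        boys = analysis_small[analysis_small.sex == "M"]
        simple = fit(boys, "sbp", ModelSpec(mu="1", sigma="1", nu="1"), quick_control)
        richer = fit(boys, "sbp", ModelSpec(mu="1 + age", sigma="1", nu="1"), quick_control)
        assert richer.logL >= simple.logL - 1e-4

    def test_too_few_records_rejected(self):
        df = _iid_frame(distributions.BCCGParams(100, 0.1, 0.3), 20, 6)
        with pytest.raises(ValueError):
            fit(df, "bp", ModelSpec(mu="1", sigma="1", nu="1"))

    def test_bcpe_tau_recovery(self):
        df = _iid_frame(distributions.BCPEParams(70, 0.12, 1.0, 1.5), 20000, 8)
        fr = fit(df, "bp", ModelSpec(family="BCPE", mu="1", sigma="1", nu="1"))
        tau = float(np.exp(fr.tau_eta))
        assert tau == pytest.approx(1.5, abs=0.25)


class TestModelSpec:
    def test_intercept_required(self):
        with pytest.raises(ValueError):
            ModelSpec(mu="age")

    def test_bccg_carries_no_tau_predictor(self):
        with pytest.raises(ValueError):
            ModelSpec(family="BCCG", tau="1 + age")

    def test_formula_parsing(self):
        terms = gamlss.parse_terms("1 + age + s(height, df=3)")
        assert terms == [("intercept",), ("linear", "age"), ("smooth", "height", 3.0)]


class TestSelectModel:
    def test_single_candidate_returned(self, analysis_small, quick_control):
        boys = analysis_small[analysis_small.sex == "M"]
        spec = ModelSpec(mu="1", sigma="1", nu="1")
        fr = select_model(boys, "sbp", [spec], quick_control)
        assert fr.spec == spec

    def test_duplicate_candidates_first_wins(self, analysis_small, quick_control):
        boys = analysis_small[analysis_small.sex == "M"]
        spec = ModelSpec(mu="1", sigma="1", nu="1")
        fr = select_model(boys, "sbp", [spec, spec], quick_control)
        assert fr.leaderboard[0]["index"] == 0
        assert [e["sbc"] for e in fr.leaderboard][0] == pytest.approx(
            fr.leaderboard[1]["sbc"], abs=1e-6)

    def test_strong_age_slope_selects_covariate_model(self, quick_control):
        # data simulated with mu strongly linear in age: the covariate-bearing
        # candidate must win on SBC in every replicate
        wins = 0
        for rep in range(5):
            rng = np.random.default_rng(100 + rep)
            age = rng.uniform(3, 17, 2000)
            mu = 90 * np.exp(0.012 * (age - 10))
            y = mu * np.exp(0.095 * rng.normal(size=2000))
            df = pd.DataFrame(dict(bp=y, age=age, height_cm=rng.uniform(95, 180, 2000)))
            best = select_model(df, "bp", [ModelSpec(mu="1", sigma="1", nu="1"),
                                           ModelSpec(mu="1 + age", sigma="1", nu="1")],
                                quick_control)
            wins += best.spec.mu == "1 + age"
        assert wins == 5


class TestPredictAndCentile:
    def test_intercept_only_constant_everywhere(self):
        df = _iid_frame(distributions.BCCGParams(100, 0.1, 0.3), 5000, 10)
        fr = fit(df, "bp", ModelSpec(mu="1", sigma="1", nu="1"))
        a, _ = predict_params(fr, 4.0, 100.0)
        b, _ = predict_params(fr, 16.0, 175.0)
        for k in ("mu", "sigma", "nu"):
            assert a[k][0] == pytest.approx(b[k][0], abs=1e-12)

    def test_median_centile_equals_fitted_mu(self, fit_small_sbp):
        pars, _ = predict_params(fit_small_sbp, 10.0, 140.0)
        assert centile(fit_small_sbp, 10.0, 140.0, 0.5)[0] == pytest.approx(
            pars["mu"][0], abs=1e-9)

    def test_centile_ordering(self, fit_small_sbp):
        ages = np.repeat(np.arange(4.0, 17.0), 3)
        heights = np.tile([120.0, 140.0, 160.0], 13)
        p50 = centile(fit_small_sbp, ages, heights, 0.5)
        p90 = centile(fit_small_sbp, ages, heights, 0.9)
        p95 = centile(fit_small_sbp, ages, heights, 0.95)
        assert np.all(p50 < p90) and np.all(p90 < p95)

    def test_far_extrapolation_flagged(self, fit_small_sbp):
        _, flag = predict_params(fit_small_sbp, 30.0, 140.0)
        assert flag[0]
        _, flag = predict_params(fit_small_sbp, 10.0, 140.0)
        assert not flag[0]

    def test_serialization_roundtrip_preserves_predictions(self, fit_small_sbp):
        clone = gamlss.FitResult.from_json(fit_small_sbp.to_json())
        ages = np.linspace(4, 16, 7)
        heights = np.linspace(105, 170, 7)
        np.testing.assert_allclose(
            centile(clone, ages, heights, 0.9),
            centile(fit_small_sbp, ages, heights, 0.9), rtol=0, atol=1e-12)


class TestSmoothBasis:
    def test_basis_matches_cox_de_boor_recursion_on_toy_knots(self):
        # independent hand evaluation of cubic B-splines on a 5-knot toy
        x = np.linspace(0.0, 10.0, 41)
        basis = gamlss._SmoothBasis(x, n_knots=5, degree=3)
        t = basis.knots

        def cox_de_boor(x0, i, d):
            if d == 0:
                return 1.0 if (t[i] <= x0 < t[i + 1]) else 0.0
            left = 0.0
            if t[i + d] != t[i]:
                left = (x0 - t[i]) / (t[i + d] - t[i]) * cox_de_boor(x0, i, d - 1)
            right = 0.0
            if t[i + d + 1] != t[i + 1]:
                right = ((t[i + d + 1] - x0) / (t[i + d + 1] - t[i + 1])
                         * cox_de_boor(x0, i + 1, d - 1))
            return left + right

        n_basis = len(t) - 4
        for x0 in (0.7, 3.3, 6.1, 9.2):  # interior points between knots
            hand = np.array([cox_de_boor(x0, i, 3) for i in range(n_basis)])
            lib = BSpline.design_matrix(np.array([x0]), t, 3).toarray()[0]
            np.testing.assert_allclose(lib, hand, atol=1e-12)

    def test_lambda_edf_calibration_monotone(self):
        x = np.random.default_rng(0).uniform(0, 1, 500)
        basis = gamlss._SmoothBasis(x, n_knots=12, degree=3)
        lams = [basis.lambda_for_edf(e, 1.0) for e in (2, 3, 5, 8)]
        assert np.all(np.diff(lams) < 0)  # more df -> less penalty
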