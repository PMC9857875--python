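"""Cox machinery, LASSO selection, tRF score, KM/log-rank, time-dependent AUC."""

import logging

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from trfscape.prognosis import (
    breslow_loglik,
    compare_predictors,
    compute_trf_score,
    cox_score_test,
    efron_loglik_grad,
    km_logrank,
    lasso_cox_select,
    multivariate_cox_refit,
    survival_probability,
    time_dependent_auc,
    univariate_cox,
    _fit_cox,
)

logging.getLogger("trfscape.prognosis").setLevel(logging.ERROR)


def _surv_frame(rng, n=150, beta=0.0, censor=0.3):
    x = rng.normal(size=n)
    t = rng.exponential(20 * np.exp(-beta * x))
    c = rng.uniform(0, np.quantile(t, 1 - censor) * 2, size=n)
    return pd.DataFrame({"x": x, "time": np.minimum(t, c), "event": (t <= c).astype(int)})


class TestScoreTest:
    def test_equals_classical_logrank_without_ties(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 60
            t = r.exponential(10, n)
            e = r.integers(0, 2, n)
            g = r.integers(0, 2, n).astype(float)
            if e.sum() == 0 or len(np.unique(g)) < 2:
                continue
            _, p = cox_score_test(g.reshape(-1, 1), t, e)
            ref = logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
            assert p == pytest.approx(ref.p_value, abs=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            cox_score_test(np.ones((4, 1)), np.arange(4.0), np.zeros(4, dtype=int))


class TestCoxFit:
    def test_gradient_vanishes_at_estimate(self, rng):
        df = _surv_frame(rng, beta=0.6)
        fit = _fit_cox(df, "time", "event")
        assert fit.grad_inf_norm < 1e-6
        assert fit.converged

    def test_matches_lifelines_coefficient(self, rng):
        from lifelines import CoxPHFitter

        df = _surv_frame(rng, beta=0.5)
        fit = _fit_cox(df, "time", "event")
        ll = CoxPHFitter().fit(df, "time", "event")
        assert fit.summary["coef"].iloc[0] == pytest.approx(
            ll.summary["coef"].iloc[0], abs=1e-3
        )

    def test_constant_feature_degenerate_path(self, rng):
        df = _surv_frame(rng)
        fit, cand = univariate_cox(
            pd.Series(np.ones(len(df))), df["time"], df["event"]
        )
        assert fit.summary["coef"].iloc[0] == 0.0
        assert fit.summary["wald_p"].iloc[0] == 1.0
        assert not cand

    def test_planted_beta_in_ci(self, rng):
        df = _surv_frame(rng, n=400, beta=0.7)
        fit, cand = univariate_cox(df["x"], df["time"], df["event"])
        lo = np.log(fit.summary["ci_lower"].iloc[0])
        hi = np.log(fit.summary["ci_upper"].iloc[0])
        assert lo < 0.7 < hi
        assert cand

    def test_multivariate_orthogonal_matches_univariate(self, rng):
        n = 500
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        t = rng.exponential(20 * np.exp(-(0.3 * X["a"] - 0.25 * X["b"])))
        e = pd.Series(np.ones(n, dtype=int))
        t = pd.Series(t)
        joint, _ = multivariate_cox_refit(X, t, e)
        ua, _ = univariate_cox(X["a"], t, e)
        ub, _ = univariate_cox(X["b"], t, e)
        assert joint.coefficients["a"] == pytest.approx(ua.coefficients.iloc[0], abs=0.05)
        assert joint.coefficients["b"] == pytest.approx(ub.coefficients.iloc[0], abs=0.05)

    def test_empty_selection_rejected(self, rng):
        df = _surv_frame(rng)
        with pytest.raises(ValueError):
            multivariate_cox_refit(df[[]], df["time"], df["event"])


class TestLasso:
    def test_infinite_penalty_empty_selection(self, rng):
        df = _surv_frame(rng, n=100, beta=0.8)
        X = pd.DataFrame({"x": df["x"], "y": rng.normal(size=100)})
        selected, _ = lasso_cox_select(
            X, df["time"], df["event"], folds=5, alphas=[1e6]
        )
        assert selected == []

    def test_zero_penalty_matches_unpenalized(self, rng):
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        n = 300
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        t = pd.Series(rng.exponential(20 * np.exp(-0.6 * X["a"])))
        e = pd.Series(np.ones(n, dtype=int))
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[1e-9], tol=1e-9,
                                   fit_baseline_model=False)
        m.fit(X.to_numpy(), Surv.from_arrays(e.astype(bool), t))
        fit, _ = multivariate_cox_refit(X, t, e)
        # Breslow (coxnet) vs Efron (refit): no ties here, so they agree
        assert np.allclose(m.coef_.ravel(), fit.coefficients.to_numpy(), atol=1e-4)

    def test_planted_features_selected(self, rng):
        n, p = 300, 30
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])
        lp = 0.9 * X["f0"] + 0.8 * X["f1"] - 0.9 * X["f2"]
        t = pd.Series(rng.exponential(20 * np.exp(-lp)))
        e = pd.Series(np.ones(n, dtype=int))
        selected, path = lasso_cox_select(X, t, e, folds=5, seed=0)
        assert {"f0", "f1", "f2"} <= set(selected)
        assert path["mean_cv_deviance"].notna().all()


class TestTRFScore:
    def test_single_feature_identity(self, rng):
        X = pd.DataFrame({"f": rng.normal(size=20)})
        ts, groups = compute_trf_score(X, pd.Series({"f": 1.0}))
        assert np.allclose(ts, X["f"])
        assert set(groups.unique()) == {"low", "high"}

    def test_all_zero_coefficients_degenerate(self, rng, caplog):
        X = pd.DataFrame({"f": rng.normal(size=10)})
        with caplog.at_level("WARNING", logger="trfscape.prognosis"):
            ts, groups = compute_trf_score(X, pd.Series({"f": 0.0}))
        assert (ts == 0).all()

    def test_median_split_balanced(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=101), "b": rng.normal(size=101)})
        ts, groups = compute_trf_score(X, pd.Series({"a": 0.5, "b": -0.3}))
        assert abs((groups == "low").sum() - (groups == "high").sum()) <= 1

    def test_affine_equivariance(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        ts1, _ = compute_trf_score(X, pd.Series({"a": 0.8, "b": 0.2}))
        X2 = X.copy()
        X2["a"] = X2["a"] * 4.0
        ts2, _ = compute_trf_score(X2, pd.Series({"a": 0.2, "b": 0.2}))
        assert np.allclose(ts1, ts2)


class TestKMLogrank:
    def test_identical_groups_p_one(self, rng):
        t = pd.Series(np.concatenate([rng.exponential(10, 30)] * 2))
        e = pd.Series(np.ones(60, dtype=int))
        groups = pd.Series(["a"] * 30 + ["b"] * 30)
        # group b duplicates group a's data exactly
        res = km_logrank(groups, t, e)
        assert res["p_value"] == pytest.approx(1.0)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_six_subject_fixture(self):
        """Log-rank statistic equals the explicit risk-table arithmetic."""
        times = pd.Series([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        events = pd.Series([1, 1, 0, 1, 1, 1])
        groups = pd.Series(["A", "A", "A", "B", "B", "B"])
        # oracle: iterate event times, accumulate observed-expected and
        # hypergeometric variance for group A
        data = sorted(zip(times, events, groups))
        o_minus_e, var = 0.0, 0.0
        for t_i, d_i, g_i in data:
            if d_i == 0:
                continue
            at_risk = [(t, e, g) for t, e, g in data if t >= t_i]
            n = len(at_risk)
            n_a = sum(1 for _, _, g in at_risk if g == "A")
            d = sum(1 for t, e, _ in at_risk if t == t_i and e == 1)
            o_a = sum(1 for t, e, g in at_risk if t == t_i and e == 1 and g == "A")
            o_minus_e += o_a - d * n_a / n
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        expected_stat = o_minus_e**2 / var
        res = km_logrank(groups, times, events)
        assert res["statistic"] == pytest.approx(expected_stat)

    def test_logrank_equals_cox_score_test(self, rng):
        t = rng.exponential(10, 80)
        e = rng.integers(0, 2, 80)
        g = rng.integers(0, 2, 80)
        res = km_logrank(
            pd.Series(np.where(g == 1, "hi", "lo")), pd.Series(t), pd.Series(e)
        )
        _, p = cox_score_test(g.astype(float).reshape(-1, 1), t, e)
        assert res["p_value"] == pytest.approx(p, abs=1e-6)

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            km_logrank(pd.Series(["a"] * 5), pd.Series(np.ones(5)), pd.Series(np.ones(5, dtype=int)))


class TestTimeDependentAUC:
    def test_uncensored_equals_plain_auc(self, rng):
        from trfscape.stats import roc_auc

        n = 200
        s = rng.normal(size=n)
        t = rng.exponential(30 * np.exp(-0.7 * s))
        e = pd.Series(np.ones(n, dtype=int))
        for h in (12.0, 36.0):
            ipcw = time_dependent_auc(pd.Series(s), pd.Series(t), e, (h,))[h]
            plain = roc_auc(s, (t <= h).astype(int)).auc
            assert ipcw == pytest.approx(plain, abs=1e-12)

    def test_perfect_score(self, rng):
        t = rng.exponential(30, 100)
        auc = time_dependent_auc(
            pd.Series(-t), pd.Series(t), pd.Series(np.ones(100, dtype=int)), (12.0,)
        )[12.0]
        assert auc == 1.0

    def test_uninformative_score_near_half(self, rng):
        aucs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 300
            t = r.exponential(30, n)
            s = r.normal(size=n)
            aucs.append(
                time_dependent_auc(
                    pd.Series(s), pd.Series(t), pd.Series(np.ones(n, dtype=int)), (24.0,)
                )[24.0]
            )
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_horizon_beyond_followup_flagged(self, rng):
        t = rng.uniform(0, 10, 50)
        out = time_dependent_auc(
            pd.Series(rng.normal(size=50)), pd.Series(t),
            pd.Series(np.ones(50, dtype=int)), (50.0,)
        )
        assert np.isnan(out[50.0])


class TestComparePredictors:
    def test_redundant_added_score(self, rng):
        n = 250
        gs = rng.integers(6, 11, n).astype(float)
        t = rng.exponential(40 * np.exp(-0.4 * (gs - 8)))
        res = compare_predictors(
            pd.Series(t), pd.Series(np.ones(n, dtype=int)),
            pd.Series(gs), pd.Series(gs.copy()), horizons=(36.0,), n_boot=60, seed=0,
        )
        assert res["auc_combined"].iloc[0] == pytest.approx(res["auc_base"].iloc[0])
        assert res["p_improvement"].iloc[0] == pytest.approx(1.0)

    def test_informative_added_score_detected(self, rng):
        n = 300
        gs = rng.integers(6, 11, n).astype(float)
        extra = rng.normal(size=n)
        t = rng.exponential(40 * np.exp(-(0.4 * (gs - 8) + 0.9 * extra)))
        res = compare_predictors(
            pd.Series(t), pd.Series(np.ones(n, dtype=int)),
            pd.Series(gs), pd.Series(extra), horizons=(36.0,), n_boot=120, seed=0,
        )
        assert res["auc_combined"].iloc[0] > res["auc_base"].iloc[0]
        assert res["p_improvement"].iloc[0] < 0.05


class TestSurvivalProbability:
    def test_time_zero_probability_one(self, rng):
        df = _surv_frame(rng, beta=0.5)
        fit = _fit_cox(df, "time", "event")
        probs = survival_probability(fit, df[["x"]], horizons=(0.0, 12.0))
        assert np.allclose(probs[0.0], 1.0)

    def test_mean_covariate_equals_baseline(self, rng):
        df = _surv_frame(rng, n=300, beta=0.5)
        fit = _fit_cox(df, "time", "event")
        at_mean = pd.DataFrame({"x": [df["x"].mean()]})
        probs = survival_probability(fit, at_mean, horizons=(12.0,))
        base = fit.model.baseline_survival_.iloc[:, 0]
        below = base[base.index <= 12.0].iloc[-1]
        above = base[base.index >= 12.0].iloc[0]
        assert above <= probs[12.0].iloc[0] <= below

    def test_matches_exponential_closed_form(self, rng):
        n = 1000
        x = rng.normal(size=n)
        lam0, beta = 1 / 40.0, 0.6
        t = rng.exponential(1 / (lam0 * np.exp(beta * x)))
        df = pd.DataFrame({"x": x, "time": t, "event": 1})
        fit = _fit_cox(df, "time", "event")
        grid = pd.DataFrame({"x": [-1.0, 0.0, 1.0]})
        probs = survival_probability(fit, grid, horizons=(24.0,))
        analytic = np.exp(-lam0 * 24.0 * np.exp(beta * grid["x"].to_numpy()))
        assert np.all(np.abs(probs[24.0].to_numpy() - analytic) < 0.05)


def test_efron_loglik_matches_breslow_without_ties(rng):
    n = 60
    X = rng.normal(size=(n, 2))
    t = rng.exponential(10, n)
    e = rng.integers(0, 2, n)
    beta = np.array([0.4, -0.2])
    le, _ = efron_loglik_grad(X, t, e, beta)
    lb = breslow_loglik(X, t, e, beta)
    assert le == pytest.approx(lb, abs=1e-8)
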