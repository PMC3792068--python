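"""Kaplan-Meier, log-rank, and Cox proportional-hazards implementation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from glycoserum.survival import (
    ConvergenceError,
    cox_fit,
    diagnostic_accuracy,
    dichotomize,
    km_by_group,
    km_estimate,
    logrank_test,
    multivariate_cox,
    univariate_screen,
)


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        assert list(km["survival"]) == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert list(km["n_risk"]) == [3, 2, 1]

    def test_no_events_survival_stays_one(self):
        km = km_estimate([5, 7, 9], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_censoring_reduces_risk_set_not_survival(self):
        km = km_estimate([1, 2, 3], [1, 0, 1]).set_index("time")
        assert km.loc[1.0, "survival"] == pytest.approx(2 / 3)
        assert km.loc[2.0, "survival"] == pytest.approx(2 / 3)
        assert km.loc[3.0, "survival"] == pytest.approx(0.0)

    def test_negative_times_raise(self):
        with pytest.raises(ValueError, match="negative"):
            km_estimate([-1, 2], [1, 1])

    def test_equals_empirical_survivor_function_without_censoring(self, rng):
        times = rng.exponential(10, size=60).round(1)  # rounding forces ties
        km = km_estimate(times, np.ones_like(times))
        for t, s in zip(km["time"], km["survival"]):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_by_group_keys(self):
        out = km_by_group([1, 2, 3, 4], [1, 1, 1, 0], ["a", "a", "b", "b"])
        assert set(out) == {"a", "b"}


class TestLogrank:
    def test_separated_groups_have_power(self, rng):
        n = 100
        rejected = 0
        for _ in range(20):
            t1 = rng.exponential(1.0, n)
            t2 = rng.exponential(5.0, n)
            time = np.r_[t1, t2]
            event = np.ones(2 * n)
            group = np.r_[np.zeros(n), np.ones(n)]
            _, p = logrank_test(time, event, group)
            rejected += p < 0.001
        assert rejected >= 19

    def test_null_p_values_are_uniform(self, rng):
        time = rng.exponential(10, 100)
        event = rng.uniform(size=100) < 0.7
        ps = []
        for _ in range(300):
            group = rng.permutation(np.r_[np.zeros(50), np.ones(50)])
            ps.append(logrank_test(time, event.astype(int), group)[1])
        stat, ks_p = sps.kstest(ps, "uniform")
        assert ks_p > 0.01

    def test_single_event_boundary(self):
        chi2, p = logrank_test([1, 2, 3, 4], [1, 0, 0, 0], ["a", "a", "b", "b"])
        assert np.isfinite(chi2) and 0 < p <= 1

    def test_one_group_empty_raises(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], ["a", "a"])


def sim_cox(rng, n=200, beta=np.log(2), censor_scale=10.0):
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / (0.1 * np.exp(beta * x)))
    c = rng.exponential(censor_scale, n)
    return np.minimum(t, c), (t <= c).astype(int), pd.DataFrame({"x": x})


class TestCox:
    def test_null_covariate_coefficient_near_zero(self, rng):
        time, event, X = sim_cox(rng, n=400, beta=0.0)
        res = cox_fit(time, event, X)
        assert abs(res.summary.loc["x", "coef"]) < 3 * res.summary.loc["x", "se"]

    def test_recovers_true_hazard_ratio(self, rng):
        time, event, X = sim_cox(rng, n=800, beta=np.log(2))
        res = cox_fit(time, event, X)
        assert 1.7 < res.summary.loc["x", "hr"] < 2.35

    def test_wald_ci_straddles_hr(self, rng):
        time, event, X = sim_cox(rng)
        row = cox_fit(time, event, X).summary.loc["x"]
        assert row["hr_low"] < row["hr"] < row["hr_high"]

    def test_agreement_with_lifelines_breslow(self, rng):
        lifelines = pytest.importorskip("lifelines")
        for _ in range(5):
            n = int(rng.integers(30, 70))
            p = int(rng.integers(1, 4))
            X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)])
            beta = rng.normal(scale=0.5, size=p)
            t = rng.exponential(1 / (0.1 * np.exp(X.to_numpy() @ beta)))
            c = rng.exponential(10, n)
            time, event = np.minimum(t, c), (t <= c).astype(int)
            ours = cox_fit(time, event, X).summary["coef"]
            cph = lifelines.CoxPHFitter().fit(X.assign(T=time, E=event), "T", "E")
            assert np.max(np.abs(ours.values - cph.params_.values)) < 1e-4

    def test_efron_ties_match_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        time = rng.integers(1, 8, 80).astype(float)  # heavy ties
        x = rng.normal(size=80)
        event = (rng.uniform(size=80) < 0.7).astype(int)
        X = pd.DataFrame({"x": x})
        ours = cox_fit(time, event, X, ties="efron").summary.loc["x", "coef"]
        cph = lifelines.CoxPHFitter().fit(X.assign(T=time, E=event), "T", "E")
        assert ours == pytest.approx(float(cph.params_.iloc[0]), abs=1e-6)

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="at least one event"):
            cox_fit([1, 2], [0, 0], pd.DataFrame({"x": [0.0, 1.0]}))

    def test_constant_covariate_raises(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3], [1, 1, 0], pd.DataFrame({"x": [1.0, 1.0, 1.0]}))

    def test_perfect_separation_flagged_not_silent(self):
        # covariate perfectly ordered with event times: monotone likelihood
        time = np.arange(1, 21, dtype=float)
        event = np.ones(20, dtype=int)
        X = pd.DataFrame({"x": np.arange(20, dtype=float)})
        with pytest.raises(ConvergenceError):
            cox_fit(time, event, X)


class TestScreenAndMultivariate:
    def test_entry_p_one_selects_all(self, rng):
        time, event, X = sim_cox(rng)
        X["noise"] = rng.normal(size=len(X))
        _, selected = univariate_screen(time, event, X, entry_p=1.0)
        assert selected == ["x", "noise"]

    def test_planted_covariate_always_selected(self, rng):
        for _ in range(5):
            time, event, X = sim_cox(rng, n=300, beta=np.log(3))
            _, selected = univariate_screen(time, event, X, entry_p=0.1)
            assert "x" in selected

    def test_identical_covariates_one_dropped(self, rng):
        time, event, X = sim_cox(rng)
        X["x_copy"] = X["x"]
        res = multivariate_cox(time, event, X)
        assert len(res.dropped) == 1
        assert list(res.summary.index) == [c for c in ["x", "x_copy"] if c not in res.dropped]

    def test_uncorrelated_covariates_none_dropped(self, rng):
        time, event, X = sim_cox(rng)
        X["z"] = rng.normal(size=len(X))
        res = multivariate_cox(time, event, X)
        assert res.dropped == ()
        assert list(res.summary.index) == ["x", "z"]

    def test_correlated_pair_keeps_smaller_univariate_p(self, rng):
        time, event, X = sim_cox(rng, n=300, beta=np.log(3))
        X["proxy"] = X["x"] + rng.normal(scale=0.3, size=len(X))  # r > 0.7, weaker signal
        uni, _ = univariate_screen(time, event, X, entry_p=np.inf)
        res = multivariate_cox(time, event, X)
        assert res.dropped == (uni["p"].idxmax(),)

    def test_single_covariate_equals_univariate_fit(self, rng):
        time, event, X = sim_cox(rng)
        multi = multivariate_cox(time, event, X[["x"]])
        uni = cox_fit(time, event, X[["x"]])
        assert multi.summary.loc["x", "coef"] == pytest.approx(uni.summary.loc["x", "coef"])


class TestDichotomize:
    def test_median_rule(self):
        high, cutoff = dichotomize([1, 2, 3, 4], "median")
        assert cutoff == 2.5
        assert list(high) == [False, False, True, True]

    def test_quantile_025_on_75_values_gives_19_low(self, rng):
        vals = rng.normal(size=75)  # continuous: no ties at the cutoff
        high, _ = dichotomize(vals, 0.25)
        assert int((~high).sum()) == 19

    def test_value_equal_to_cutoff_is_low(self):
        high, cutoff = dichotomize([1, 2, 2, 3], "median")
        assert cutoff == 2.0
        assert list(high) == [False, False, False, True]

    def test_all_equal_raises(self):
        with pytest.raises(ValueError, match="distinct"):
            dichotomize([2, 2, 2])


class TestDiagnosticAccuracy:
    def test_perfect_marker(self):
        sens, spec = diagnostic_accuracy([True, True, False], [True, True, False])
        assert (sens, spec) == (1.0, 1.0)

    def test_all_high(self):
        sens, spec = diagnostic_accuracy([True] * 4, [True, False, True, False])
        assert (sens, spec) == (1.0, 0.0)

    def test_no_events_gives_nan_sensitivity(self):
        sens, spec = diagnostic_accuracy([True, False], [False, False])
        assert np.isnan(sens) and spec == 0.5

    def test_independent_flag_matches_prevalence(self, rng):
        n = 20000
        high = rng.uniform(size=n) < 0.4
        event = rng.uniform(size=n) < 0.3
        sens, spec = diagnostic_accuracy(high, event)
        assert sens == pytest.approx(0.4, abs=0.02)
        assert spec == pytest.approx(0.6, abs=0.02)
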