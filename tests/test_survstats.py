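"""Survival-statistics core against brute-force and lifelines oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ypstage import survstats as ss
from ypstage.exceptions import ConvergenceError, DomainError, UndefinedResultError

from conftest import (
    cox_partial_loglik_oracle,
    harrell_c_oracle,
    km_oracle,
    logrank_oracle,
    trend_logrank_oracle,
)


# ---------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------
class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self):
        km = ss.km_estimate([3.0, 8.0, 12.0], [0, 0, 0])
        assert km.event_times.size == 0
        assert ss.survival_at(km, 100.0) == 1.0

    def test_single_death_among_two(self):
        km = ss.km_estimate([5.0, 9.0], [1, 0])
        assert ss.survival_at(km, 5.0) == pytest.approx(0.5)

    def test_eight_subject_hand_example(self):
        """Censored subjects at an event time stay at risk for that time."""
        times = [1, 2, 2, 3, 4, 5, 5, 6]
        events = [1, 0, 1, 1, 0, 1, 0, 0]
        km = ss.km_estimate(times, events)
        assert km.event_times.tolist() == [1, 2, 3, 5]
        assert km.survival == pytest.approx([0.875, 0.75, 0.6, 0.4])

    def test_matches_loop_oracle_on_random_data(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(20, 60).round(1) + 0.1
        e = rng.integers(0, 2, 60)
        km = ss.km_estimate(t, e)
        ot, osurv = km_oracle(t, e)
        assert km.event_times == pytest.approx(ot)
        assert km.survival == pytest.approx(osurv, abs=1e-12)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(8)
        t = rng.exponential(20, 100) + 0.1
        e = rng.integers(0, 2, 100)
        km = ss.km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for q in (5.0, 15.0, 40.0):
            assert ss.survival_at(km, q) == pytest.approx(
                float(kmf.predict(q)), abs=1e-10)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 50) + 0.1
        km = ss.km_estimate(t, np.ones(50))
        for q in np.quantile(t, [0.2, 0.5, 0.9]):
            assert ss.survival_at(km, q) == pytest.approx((t > q).mean())

    @given(st.integers(0, 2**31 - 1))
    def test_survival_monotone_and_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        t = rng.exponential(20, n) + 0.01
        e = rng.integers(0, 2, n)
        km = ss.km_estimate(t, e)
        assert np.all(np.diff(km.survival) <= 1e-15)
        assert np.all((km.survival >= 0) & (km.survival <= 1))
        assert np.all(np.diff(km.at_risk) <= 0)

    def test_survival_at_step_conventions(self):
        km = ss.km_estimate([5.0, 9.0], [1, 1])
        assert ss.survival_at(km, 0.0) == 1.0
        assert ss.survival_at(km, 4.999) == 1.0
        assert ss.survival_at(km, 5.0) == pytest.approx(0.5)  # post-jump
        value, extrapolated = ss.survival_at(km, 50.0, return_flag=True)
        assert extrapolated and value == pytest.approx(0.0)

    def test_median_survival(self):
        km = ss.km_estimate([2.0, 4.0, 6.0, 8.0], [1, 1, 1, 1])
        assert ss.median_survival(km) == 4.0
        km2 = ss.km_estimate([2.0, 4.0, 6.0], [1, 0, 0])
        assert ss.median_survival(km2) == np.inf

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            ss.km_estimate([], [])


# ---------------------------------------------------------------------
# log-rank family
# ---------------------------------------------------------------------
class TestLogRank:
    def test_identical_groups_give_zero_chi2(self):
        t = [3.0, 5.0, 7.0, 3.0, 5.0, 7.0]
        e = [1, 0, 1, 1, 0, 1]
        res = ss.logrank([0, 0, 0, 1, 1, 1], t, e)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_six_subject_example_matches_oracle(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        e = [1, 1, 0, 1, 1, 1]
        g = ["a", "a", "a", "b", "b", "b"]
        res = ss.logrank(g, t, e)
        assert res.chi2 == pytest.approx(logrank_oracle(g, t, e), abs=1e-12)
        assert res.p == pytest.approx(stats.chi2.sf(res.chi2, 1))

    def test_observed_equals_expected_in_total(self):
        rng = np.random.default_rng(12)
        g = rng.integers(0, 3, 80)
        t = rng.exponential(20, 80) + 0.1
        e = rng.integers(0, 2, 80)
        res = ss.logrank(g, t, e)
        assert res.observed.sum() == pytest.approx(res.expected.sum(), abs=1e-9)
        assert res.df == 2

    def test_matches_lifelines_multigroup(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(21)
        g = rng.integers(0, 3, 120)
        t = rng.exponential(30 * np.exp(-0.3 * g)) + 0.1
        e = rng.integers(0, 2, 120)
        res = ss.logrank(g, t, e)
        ref = multivariate_logrank_test(t, g, e)
        assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)

    def test_time_unit_invariance(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 2, 50)
        t = rng.exponential(20, 50) + 0.1
        e = rng.integers(0, 2, 50)
        a = ss.logrank(g, t, e)
        b = ss.logrank(g, t * 30.4, e)  # months -> days
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(DomainError):
            ss.logrank([1, 1, 1], [1.0, 2.0, 3.0], [1, 1, 1])


class TestTrendLogRank:
    def test_two_groups_equal_ordinary_logrank(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 2, 60)
        t = rng.exponential(20 * np.exp(-0.5 * g)) + 0.1
        e = np.ones(60, int)
        assert ss.trend_logrank(g, t, e).chi2 == pytest.approx(
            ss.logrank(g, t, e).chi2, rel=1e-12)

    def test_affine_score_invariance(self):
        rng = np.random.default_rng(7)
        g = rng.integers(0, 3, 90)
        t = rng.exponential(25 * np.exp(-0.4 * g)) + 0.1
        e = rng.integers(0, 2, 90)
        base = ss.trend_logrank(g, t, e, scores=[0, 1, 2]).chi2
        flipped = ss.trend_logrank(g, t, e, scores=[7, 4, 1]).chi2
        assert base == pytest.approx(flipped, rel=1e-9)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(9)
        g = rng.integers(0, 3, 40)
        t = rng.exponential(20, 40) + 0.1
        e = rng.integers(0, 2, 40)
        res = ss.trend_logrank(g, t, e)
        assert res.chi2 == pytest.approx(
            trend_logrank_oracle(g, t, e, [0, 1, 2]), abs=1e-10)
        assert res.df == 1

    def test_monotone_ordering_scores_higher_than_permuted(self):
        rng = np.random.default_rng(10)
        g = rng.integers(0, 3, 600)
        t = rng.exponential(30 * np.exp(-0.45 * g)) + 0.01
        e = np.ones(600, int)
        monotone = ss.trend_logrank(g, t, e).chi2
        permuted = ss.trend_logrank(g, t, e, scores=[1, 0, 2]).chi2
        assert monotone > permuted


# ---------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------
class TestCox:
    def test_null_model_logliks_coincide(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 30) + 0.1
        e = np.ones(30, int)
        m = ss.cox_fit(np.empty((30, 0)), t, e)
        assert m.loglik == m.loglik_null
        assert m.n_params == 0

    def test_single_binary_covariate_matches_bruteforce(self, small_survival):
        """Newton fit equals a bounded scalar maximiser of the explicit
        partial likelihood on untied data, to 1e-6."""
        from scipy.optimize import minimize_scalar

        x, t, e = small_survival
        m = ss.cox_fit(x[:, None], t, e)
        res = minimize_scalar(
            lambda b: -cox_partial_loglik_oracle(b, x, t, e),
            bounds=(-6, 6), method="bounded", options={"xatol": 1e-10})
        assert m.coef[0] == pytest.approx(res.x, abs=1e-6)
        assert m.loglik == pytest.approx(-res.fun, abs=1e-9)

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(13)
        n = 120
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(size=n)
        t = np.ceil(rng.exponential(20 * np.exp(-0.6 * x1 - 0.3 * x2)))
        e = rng.integers(0, 2, n)
        e[:5] = 1
        m = ss.cox_fit(np.column_stack([x1, x2]), t, e)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"x1": x1, "x2": x2, "t": t, "e": e}), "t", "e")
        assert m.coef == pytest.approx(cph.params_.to_numpy(), abs=1e-6)
        assert m.loglik == pytest.approx(cph.log_likelihood_, abs=1e-8)
        assert m.se == pytest.approx(cph.standard_errors_.to_numpy(), abs=1e-6)

    def test_duplicating_subjects_leaves_coefficient_unchanged(self):
        # replication invariance is exact for the Breslow tie handling
        # (Efron redistributes within the artificial ties)
        rng = np.random.default_rng(14)
        x = rng.integers(0, 2, 40).astype(float)
        t = rng.exponential(15 * np.exp(-0.5 * x)) + 0.1
        e = np.ones(40, int)
        m1 = ss.cox_fit(x[:, None], t, e, ties="breslow")
        m2 = ss.cox_fit(np.tile(x, 2)[:, None], np.tile(t, 2), np.tile(e, 2),
                        ties="breslow")
        assert m2.coef[0] == pytest.approx(m1.coef[0], abs=1e-7)

    def test_separation_raises_naming_covariate(self):
        # covariate perfectly orders the failures: monotone likelihood
        t = np.arange(1.0, 21.0)
        e = np.ones(20, int)
        x = np.arange(20.0)[::-1]
        with pytest.raises(ConvergenceError, match="risky"):
            ss.cox_fit(x[:, None], t, e, names=["risky"])

    def test_constant_column_rejected(self):
        with pytest.raises(DomainError, match="flat"):
            ss.cox_fit(np.ones((10, 1)), np.arange(1.0, 11.0),
                       np.ones(10, int), names=["flat"])

    def test_hazard_ratio_ordering_matches_km_separation(self):
        rng = np.random.default_rng(15)
        g = rng.integers(0, 3, 900)
        t = rng.exponential(30 * np.exp(-0.5 * g)) + 0.01
        e = np.ones(900, int)
        X = np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
        m = ss.cox_fit(X, t, e)
        assert 0 < m.coef[0] < m.coef[1]


class TestLikelihoodMetrics:
    def test_null_model_lr_zero(self):
        rng = np.random.default_rng(16)
        t = rng.exponential(10, 25) + 0.1
        m = ss.cox_fit(np.empty((25, 0)), t, np.ones(25, int))
        assert ss.lr_chi2(m) == 0.0

    def test_aic_formula(self):
        m = ss.CoxModel(np.zeros(3), np.eye(3), -100.0, -110.0, 3, "efron",
                        1, True, ["a", "b", "c"], np.eye(3))
        assert ss.aic(m) == pytest.approx(206.0)
        assert ss.lr_chi2(m) == pytest.approx(20.0)

    def test_nested_coarsening_never_beats_finer_model(self):
        rng = np.random.default_rng(17)
        g = rng.integers(0, 3, 400)
        t = rng.exponential(25 * np.exp(-0.4 * g)) + 0.01
        e = rng.integers(0, 2, 400)
        e[:5] = 1
        fine = np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
        coarse = (g > 0).astype(float)[:, None]
        lr_fine = ss.lr_chi2(ss.cox_fit(fine, t, e))
        lr_coarse = ss.lr_chi2(ss.cox_fit(coarse, t, e))
        assert lr_fine >= lr_coarse - 1e-9


# ---------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------
class TestHarrellC:
    def test_perfectly_anti_ordered_scores_give_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert ss.harrell_c(-t, t, np.ones(4, int)).c == 1.0

    def test_perfectly_ordered_scores_give_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert ss.harrell_c(t, t, np.ones(4, int)).c == 0.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(18)
        sc = rng.normal(size=20)
        t = rng.exponential(20, 20) + 0.1
        e = rng.integers(0, 2, 20)
        e[0] = 1
        res = ss.harrell_c(sc, t, e)
        assert res.c == pytest.approx(harrell_c_oracle(sc, t, e), abs=1e-12)
        assert res.concordant + res.discordant + res.tied_risk == res.comparable

    @given(st.integers(0, 2**31 - 1))
    def test_rank_invariance_under_increasing_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        sc = rng.normal(size=n)
        t = rng.exponential(20, n) + 0.01
        e = rng.integers(0, 2, n)
        e[int(rng.integers(n))] = 1
        c1 = ss.harrell_c(sc, t, e).c
        c2 = ss.harrell_c(np.exp(3 * sc) + 7, t, e).c
        assert c1 == pytest.approx(c2, abs=1e-15)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(UndefinedResultError):
            ss.harrell_c([1.0, 2.0], [5.0, 5.0], [1, 1])


# ---------------------------------------------------------------------
# proportional-hazards diagnostic
# ---------------------------------------------------------------------
class TestSchoenfeld:
    def test_subject_order_invariance(self):
        rng = np.random.default_rng(19)
        n = 100
        x = rng.normal(size=(n, 2))
        t = rng.exponential(20 * np.exp(-0.4 * x[:, 0])) + 0.1
        e = rng.integers(0, 2, n)
        e[:5] = 1
        m = ss.cox_fit(x, t, e)
        r1 = ss.schoenfeld_global_test(m, x, t, e)
        perm = rng.permutation(n)
        m2 = ss.cox_fit(x[perm], t[perm], e[perm])
        r2 = ss.schoenfeld_global_test(m2, x[perm], t[perm], e[perm])
        assert r1.chi2 == pytest.approx(r2.chi2, rel=1e-8)

    def test_detects_crossing_hazards(self):
        """Strong time-varying effect: p < 0.05 in >=80% of 200 runs."""
        rej = 0
        for rep in range(200):
            rng = np.random.default_rng(30_000 + rep)
            n = 500
            x = rng.integers(0, 2, n).astype(float)
            t = np.empty(n)
            for i in range(n):
                if x[i] == 0:
                    t[i] = rng.exponential(40.0)
                else:  # early excess hazard, late deficit: curves cross
                    first = rng.exponential(20.0)
                    t[i] = first if first < 20 else 20 + rng.exponential(100.0)
            cens = rng.uniform(40, 120, n)
            e = (t <= cens).astype(int)
            tt = np.maximum(np.minimum(t, cens), 1e-6)
            m = ss.cox_fit(x[:, None], tt, e)
            rej += ss.schoenfeld_global_test(m, x[:, None], tt, e).p < 0.05
        assert rej / 200 >= 0.80


# ---------------------------------------------------------------------
# time-dependent AUC
# ---------------------------------------------------------------------
class TestTdAUC:
    def test_perfect_separation_gives_auc_one(self):
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.ones(6, int)
        score = -t  # perfectly ranks early failures higher
        curve = ss.td_auc(score, t, e, [5.0])
        assert curve.defined[0]
        assert curve.auc[0] == pytest.approx(1.0)

    def test_no_censoring_weights_collapse_to_empirical_auc(self):
        rng = np.random.default_rng(20)
        n = 200
        sc = rng.normal(size=n)
        t = rng.exponential(30 * np.exp(-0.7 * sc)) + 0.01
        e = np.ones(n, int)
        horizon = float(np.median(t))
        curve = ss.td_auc(sc, t, e, [horizon])
        case = t <= horizon
        wins = ties = 0
        for i in np.flatnonzero(case):
            for j in np.flatnonzero(~case):
                wins += sc[i] > sc[j]
                ties += sc[i] == sc[j]
        plain = (wins + 0.5 * ties) / (case.sum() * (~case).sum())
        assert curve.auc[0] == pytest.approx(plain, abs=1e-12)

    def test_grid_point_without_controls_flagged_not_raised(self):
        t = np.array([1.0, 2.0, 3.0])
        curve = ss.td_auc([3.0, 2.0, 1.0], t, np.ones(3, int), [10.0])
        assert not curve.defined[0]
        assert np.isnan(curve.auc[0])


class TestCompareAUC:
    def _data(self, seed=1, n=150):
        rng = np.random.default_rng(seed)
        t = rng.exponential(50, n)
        cens = rng.uniform(20, 150, n)
        e = (t <= cens).astype(int)
        return np.minimum(t, cens) + 1e-9, e, rng

    def test_self_comparison_gives_p_one(self):
        t, e, rng = self._data()
        sc = rng.normal(size=t.size)
        a = ss.td_auc(sc, t, e, [36.0])
        b = ss.td_auc(sc, t, e, [36.0])
        assert ss.compare_auc(a, b, 36.0, n_boot=200, seed=0) == 1.0

    def test_mismatched_cohorts_rejected(self):
        t, e, rng = self._data(1)
        t2, e2, _ = self._data(2)
        a = ss.td_auc(rng.normal(size=t.size), t, e, [36.0])
        b = ss.td_auc(rng.normal(size=t2.size), t2, e2, [36.0])
        with pytest.raises(DomainError):
            ss.compare_auc(a, b, 36.0)

    def test_informative_score_beats_random_score(self):
        rng = np.random.default_rng(2)
        n = 1000
        risk = rng.normal(size=n)
        t = np.maximum(rng.exponential(50 * np.exp(-risk)), 1e-6)
        cens = rng.uniform(20, 150, n)
        e = (t <= cens).astype(int)
        t = np.minimum(t, cens)
        a = ss.td_auc(risk, t, e, [36.0])
        b = ss.td_auc(rng.normal(size=n), t, e, [36.0])
        assert ss.compare_auc(a, b, 36.0, n_boot=500, seed=3) < 0.05

    def test_null_rejection_rate_calibrated(self):
        """Two independent random scorings: ~5% rejections at alpha=.05."""
        rej = 0
        for rep in range(200):
            t, e, rng = self._data(40_000 + rep)
            a = ss.td_auc(rng.normal(size=t.size), t, e, [36.0])
            b = ss.td_auc(rng.normal(size=t.size), t, e, [36.0])
            rej += ss.compare_auc(a, b, 36.0, n_boot=200, seed=rep) < 0.05
        assert 0.02 <= rej / 200 <= 0.09
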