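"""Survival and categorical statistics against independent oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from survpanel import (
    DegenerateGroupsError,
    SurvivalRecord,
    cox_fit,
    cox_score_test,
    fisher_exact_2x2,
    km_estimate,
    logrank_test,
    wilcoxon_rank_sum,
)


def rec(time, event, sid=None, **cov):
    return SurvivalRecord(
        sample_id=sid or f"s{time}-{event}", time=time, event=event, covariates=cov
    )


def brute_logrank_chi2(group_a, group_b):
    """Naive per-event-time O-E/V computation, independent of the
    vectorized implementation."""
    pooled = [(r.time, r.event, 0) for r in group_a] + [
        (r.time, r.event, 1) for r in group_b
    ]
    event_times = sorted({t for t, e, _ in pooled if e == 1})
    oe, var = 0.0, 0.0
    for t in event_times:
        at_risk = [(tt, ee, g) for tt, ee, g in pooled if tt >= t]
        n = len(at_risk)
        n1 = sum(1 for _, _, g in at_risk if g == 1)
        d = sum(1 for tt, ee, _ in at_risk if tt == t and ee == 1)
        d1 = sum(1 for tt, ee, g in at_risk if tt == t and ee == 1 and g == 1)
        oe += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return oe * oe / var


class TestKaplanMeier:
    def test_all_events_distinct_times(self):
        km = km_estimate([rec(1, 1), rec(2, 1), rec(3, 1)])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert np.array_equal(km.event_times, [1, 2, 3])

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([rec(1, 0), rec(2, 0)])
        assert len(km.event_times) == 0
        assert km.survival_at(100.0) == 1.0

    def test_hand_product_limit_with_censoring(self):
        # event at 1 (3 at risk), censored at 2, event at 3 (1 at risk)
        km = km_estimate([rec(1, 1), rec(2, 0), rec(3, 1)])
        assert np.allclose(km.survival, [2 / 3, 0.0])
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(3) == 0.0

    def test_matches_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10, size=50)
        km = km_estimate([rec(t, 1, sid=str(i)) for i, t in enumerate(times)])
        # no censoring: S at the k-th event time is 1 - k/n
        assert np.allclose(km.survival, 1 - np.arange(1, 51) / 50)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            rec(-1.0, 1)


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        grp = [rec(1, 1), rec(2, 0), rec(3, 1)]
        res = logrank_test(grp, list(grp))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_patient_hand_oracle(self):
        a = [rec(1, 1), rec(3, 1), rec(5, 0)]
        b = [rec(2, 1), rec(4, 0), rec(6, 1)]
        res = logrank_test(a, b)
        assert res.statistic == pytest.approx(brute_logrank_chi2(a, b), rel=1e-12)
        assert sum(res.observed) == 4  # total events

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_lifelines_on_random_data(self, seed):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(seed)
        ta, tb = rng.exponential(10, 40), rng.exponential(14, 35)
        ea, eb = rng.integers(0, 2, 40), rng.integers(0, 2, 35)
        ea[0] = eb[0] = 1
        a = [rec(t, int(e), sid=f"a{i}") for i, (t, e) in enumerate(zip(ta, ea))]
        b = [rec(t, int(e), sid=f"b{i}") for i, (t, e) in enumerate(zip(tb, eb))]
        ours = logrank_test(a, b)
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_invariant_under_relabeling_and_monotone_time_transform(self):
        rng = np.random.default_rng(9)
        a = [rec(t, int(e), sid=f"a{i}") for i, (t, e) in
             enumerate(zip(rng.exponential(5, 30), rng.integers(0, 2, 30)))]
        b = [rec(t, int(e), sid=f"b{i}") for i, (t, e) in
             enumerate(zip(rng.exponential(9, 30), rng.integers(0, 2, 30)))]
        base = logrank_test(a, b)
        swapped = logrank_test(b, a)
        assert swapped.statistic == pytest.approx(base.statistic, rel=1e-12)
        squared = logrank_test(
            [rec(r.time**2, r.event, sid=r.sample_id) for r in a],
            [rec(r.time**2, r.event, sid=r.sample_id) for r in b],
        )
        assert squared.statistic == pytest.approx(base.statistic, rel=1e-12)

    def test_degenerate_inputs_signalled(self):
        grp = [rec(1, 1)]
        with pytest.raises(DegenerateGroupsError):
            logrank_test(grp, [])
        with pytest.raises(DegenerateGroupsError):
            logrank_test([rec(1, 0)], [rec(2, 0)])


class TestCox:
    def test_duplicated_data_gives_null_coefficient(self):
        base = [rec(t, 1, sid=f"x{t}", grp=0.0) for t in (1.0, 2.5, 4.0, 7.0)]
        dup = [
            SurvivalRecord(f"y{r.time}", r.time, r.event, {"grp": 1.0}) for r in base
        ]
        fit = cox_fit(base + dup, ["grp"])
        assert fit.coefficients["grp"] == pytest.approx(0.0, abs=1e-6)
        assert fit.hazard_ratios["grp"] == pytest.approx(1.0, abs=1e-6)

    def test_confidence_interval_coverage_at_true_hazard_ratio(self):
        # two-group exponential with true HR 0.5; Wald 95% CI should cover
        # log-HR in roughly 95% of replicates
        true_hr = 0.5
        covered = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            x = np.repeat([0.0, 1.0], 250)
            t = rng.exponential(1.0 / (0.1 * true_hr**x))
            recs = [
                rec(tt, 1, sid=str(i), grp=float(xx))
                for i, (tt, xx) in enumerate(zip(t, x))
            ]
            fit = cox_fit(recs, ["grp"])
            if fit.ci_lower["grp"] <= true_hr <= fit.ci_upper["grp"]:
                covered += 1
        assert 0.88 <= covered / reps <= 1.0

    def test_score_test_at_zero_equals_logrank_without_ties(self):
        rng = np.random.default_rng(4)
        n = 60
        x = (rng.random(n) < 0.4).astype(float)
        time = rng.exponential(1.0 / (0.08 * 0.4**x))
        event = np.ones(n, dtype=int)
        a = [rec(t, 1, sid=f"a{i}") for i, t in enumerate(time[x == 0])]
        b = [rec(t, 1, sid=f"b{i}") for i, t in enumerate(time[x == 1])]
        lr = logrank_test(a, b)
        score = cox_score_test(time, event, x)
        assert score == pytest.approx(lr.statistic, rel=1e-9)

    def test_constant_covariate_named_in_error(self):
        recs = [rec(t, 1, sid=str(t), flat=1.0) for t in (1.0, 2.0, 3.0)]
        with pytest.raises(ValueError, match="flat"):
            cox_fit(recs, ["flat"])

    def test_hazard_ratio_sign_agrees_with_km_separation(self):
        rng = np.random.default_rng(12)
        fast = [rec(t, 1, sid=f"f{i}", grp=1.0)
                for i, t in enumerate(rng.exponential(2, 80))]
        slow = [rec(t, 1, sid=f"s{i}", grp=0.0)
                for i, t in enumerate(rng.exponential(10, 80))]
        fit = cox_fit(fast + slow, ["grp"])
        km_fast, km_slow = km_estimate(fast), km_estimate(slow)
        t_mid = float(np.median([r.time for r in fast + slow]))
        assert km_fast.survival_at(t_mid) < km_slow.survival_at(t_mid)
        assert fit.hazard_ratios["grp"] > 1.0


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by direct hypergeometric enumeration over all
    tables with the observed margins."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    pmf = sps.hypergeom(n, col1, row1).pmf
    p_obs = pmf(a)
    return sum(
        float(pmf(k))
        for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
        if pmf(k) <= p_obs * (1 + 1e-9)
    )


class TestFisher:
    def test_perfect_association_five_five(self):
        p = fisher_exact_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, rel=1e-9)
        assert p == pytest.approx(fisher_enumeration_oracle([[5, 0], [0, 5]]), rel=1e-9)

    def test_proportional_rows_give_p_one(self):
        assert fisher_exact_2x2([[4, 9], [4, 9]]) == pytest.approx(1.0)

    def test_icb_progressive_disease_table_matches_enumeration(self):
        # 15/30 wild-type vs 1/7 mutant progressive-disease counts
        table = [[15, 15], [1, 6]]
        assert fisher_exact_2x2(table) == pytest.approx(
            fisher_enumeration_oracle(table), rel=1e-9
        )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])


class TestWilcoxon:
    def test_identical_multisets_give_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_exact_small_sample_separation(self):
        # complete separation of {1,2,3} and {4,5,6}: 2 of C(6,3)=20
        # equally likely assignments are at least as extreme
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_degenerate_constant_data_flagged(self):
        with pytest.warns(UserWarning, match="identical"):
            assert wilcoxon_rank_sum([2, 2], [2, 2, 2]) == 1.0

    def test_large_shift_is_overwhelming(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 400)
        y = rng.normal(3, 1, 400)
        assert wilcoxon_rank_sum(x, y) < 1e-6

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])
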