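"""Survival, exact-test, kinetics and design statistics against independent
oracles (lifelines, scipy, statsmodels, simulation)."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from xenoresponse.curve_prep import OBSERVED, DailySeries, interpolate_daily
from xenoresponse.growth_io import (
    AnimalCourse,
    Endpoint,
    Measurement,
    ValidationError,
)
from xenoresponse.stats import (
    PowerSpec,
    SurvivalRecord,
    anova_dunnett,
    compare_slopes,
    delta_percent,
    fisher_exact_2x2,
    km_estimate,
    logrank_test,
    power_two_sample_t,
    proportion_summary,
    rank_sum_test,
    sample_size_two_t,
    slope_fit,
    time_to_event,
)


def daily(volumes, start_day=0):
    return DailySeries(start_day, np.asarray(volumes, float),
                       np.array([OBSERVED] * len(volumes), dtype=object))


class TestTimeToEvent:
    def _course(self, pairs, endpoint=None):
        return AnimalCourse(
            "a1", "M1", "treated",
            [Measurement(d, v) for d, v in pairs], endpoint=endpoint,
        )

    def test_resected_is_event(self):
        c = self._course([(0, 50), (20, 600)], endpoint=Endpoint(22, "resected"))
        rec = time_to_event(c)
        assert (rec.time, rec.event) == (22.0, True)

    def test_cap_crossing_counts_as_event_not_censored(self):
        c = self._course([(0, 50), (24, 700), (26, 920)])
        rec = time_to_event(c)
        # interpolated daily series first strictly exceeds 800 on day 25
        assert (rec.time, rec.event) == (25.0, True)

    def test_below_cap_censored_at_last_day(self):
        c = self._course([(0, 50), (28, 400)])
        rec = time_to_event(c)
        assert (rec.time, rec.event) == (28.0, False)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(10, size=25).round(3) + 0.001
        recs = [SurvivalRecord(t, True) for t in times]
        km = km_estimate(recs)
        for _, row in km.iterrows():
            if row["time"] > 0:
                assert row["survival"] == pytest.approx(
                    np.mean(times > row["time"]), abs=1e-12
                )

    def test_product_limit_by_hand(self):
        recs = [SurvivalRecord(3, True), SurvivalRecord(5, False),
                SurvivalRecord(7, True)]
        km = km_estimate(recs).set_index("time")["survival"]
        assert km[3.0] == pytest.approx(2 / 3)
        assert km[5.0] == pytest.approx(2 / 3)
        assert km[7.0] == pytest.approx(0.0)

    def test_all_censored_survival_one(self):
        recs = [SurvivalRecord(t, False) for t in (2, 4, 6)]
        assert (km_estimate(recs)["survival"] == 1.0).all()

    def test_matches_lifelines(self, rng):
        times = rng.exponential(10, size=40) + 0.01
        events = rng.random(40) < 0.7
        recs = [SurvivalRecord(t, bool(e)) for t, e in zip(times, events)]
        km = km_estimate(recs)
        kmf = KaplanMeierFitter().fit(times, events)
        for _, row in km.iterrows():
            assert row["survival"] == pytest.approx(
                float(kmf.predict(row["time"])), abs=1e-9
            )


class TestLogrank:
    def test_worked_four_subject_example(self):
        a = [SurvivalRecord(1, True, "a"), SurvivalRecord(2, True, "a")]
        b = [SurvivalRecord(3, True, "b"), SurvivalRecord(4, True, "b")]
        res = logrank_test([a, b])
        # O-E = 7/6 over the four event times, hypergeometric variance 17/36
        assert res.statistic == pytest.approx((7 / 6) ** 2 / (17 / 36), abs=1e-6)

    def test_identical_groups_null(self):
        g = [SurvivalRecord(t, True) for t in (2, 5, 9)]
        res = logrank_test([g, list(g)])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_single_event_mild_p(self):
        a = [SurvivalRecord(5, True, "a"), SurvivalRecord(9, False, "a")]
        b = [SurvivalRecord(7, False, "b"), SurvivalRecord(8, False, "b")]
        res = logrank_test([a, b])
        assert res.p_value > 0.3

    def test_label_swap_invariant(self, rng):
        a = [SurvivalRecord(t, True) for t in rng.exponential(5, 12) + 0.01]
        b = [SurvivalRecord(t, True) for t in rng.exponential(9, 12) + 0.01]
        assert logrank_test([a, b]).statistic == pytest.approx(
            logrank_test([b, a]).statistic
        )

    def test_no_events_warns_p_one(self):
        a = [SurvivalRecord(3, False)]
        b = [SurvivalRecord(4, False)]
        with pytest.warns(UserWarning, match="no events"):
            res = logrank_test([a, b])
        assert res.p_value == 1.0

    def test_matches_lifelines_three_groups(self, rng):
        times, events, labels = [], [], []
        for i, h in enumerate([0.1, 0.2, 0.4]):
            t = rng.exponential(1 / h, 15) + 0.01
            e = rng.random(15) < 0.8
            times += list(t)
            events += list(e)
            labels += [i] * 15
        groups = [
            [SurvivalRecord(t, bool(e)) for t, e, g in zip(times, events, labels)
             if g == i]
            for i in range(3)
        ]
        res = logrank_test(groups)
        ll = multivariate_logrank_test(times, labels, events)
        assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ll.p_value, rel=1e-9)


class TestSlopes:
    def test_identity_exact_line(self):
        slope, stderr = slope_fit(daily([10 + 2 * t for t in range(6)]),
                                  transform="identity")
        assert slope == pytest.approx(2.0)
        assert stderr == pytest.approx(0.0, abs=1e-12)

    def test_cube_transform_linearizes(self):
        vols = [(5 * t + 1) ** (1 / 3) for t in range(6)]
        slope, _ = slope_fit(daily(vols), transform="cube")
        assert slope == pytest.approx(5.0)

    def test_constant_series_zero_slope(self):
        slope, _ = slope_fit(daily([7.0] * 5), transform="identity")
        assert slope == pytest.approx(0.0)

    def test_log_transform_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            slope_fit(DailySeries(0, [1.0, -1.0, 2.0],
                                  np.array([OBSERVED] * 3, dtype=object)), "log")

    def test_equal_slopes_null(self, rng):
        groups = [
            [daily(10 + 2 * np.arange(8) + rng.normal(0, .01, 8)) for _ in range(5)]
            for _ in range(2)
        ]
        res = compare_slopes(groups, transform="identity")
        assert res.p_value > 0.2

    def test_different_slopes_detected(self, rng):
        g1 = [daily(10 + 2 * np.arange(8) + rng.normal(0, 0.5, 8)) for _ in range(10)]
        g2 = [daily(10 + 4 * np.arange(8) + rng.normal(0, 0.5, 8)) for _ in range(10)]
        res = compare_slopes([g1, g2], transform="identity")
        assert res.p_value < 0.01

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_slopes([[daily([1, 2, 3])]])

    def test_degenerate_zero_residual_flagged(self):
        g1 = [daily(10 + 2 * np.arange(5)) for _ in range(2)]
        g2 = [daily(10 + 4 * np.arange(5)) for _ in range(2)]
        res = compare_slopes([g1, g2], transform="identity")
        assert res.note is not None
        assert 0 < res.p_value < 1e-200


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            (((2, 0), (0, 2)), 1 / 3),
            (((1, 1), (1, 1)), 1.0),
            (((4, 0), (2, 23)), 15 / 23751),
        ],
    )
    def test_worked_values(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-9)

    def test_zero_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_exact_2x2(((0, 0), (3, 4))) == 1.0

    def test_matches_scipy_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            ours = fisher_exact_2x2(((a, b), (c, d)))
            theirs = sps.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2(((-1, 2), (3, 4)))


class TestRankSum:
    def test_worked_exact_values(self):
        assert rank_sum_test([1, 2], [3, 4], mode="exact").p_value == pytest.approx(1 / 3)
        assert rank_sum_test(list(range(1, 11)), list(range(11, 21)),
                             mode="exact").p_value == pytest.approx(
            2 / math.comb(20, 10)
        )

    def test_identical_multisets_p_one(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3], mode="exact").p_value == 1.0

    def test_exact_matches_brute_force_with_ties(self, rng):
        for m, n in [(3, 3), (4, 3), (5, 4), (6, 6)]:
            vals = rng.integers(0, 5, size=m + n).astype(float)  # heavy ties
            x, y = vals[:m], vals[m:]
            ours = rank_sum_test(x, y, mode="exact").p_value
            ranks = sps.rankdata(vals)
            mu = m * ranks.mean()
            w_obs = ranks[:m].sum()
            count = sum(
                1
                for idx in itertools.combinations(range(m + n), m)
                if abs(ranks[list(idx)].sum() - mu) >= abs(w_obs - mu) - 1e-9
            )
            assert ours == pytest.approx(count / math.comb(m + n, m), rel=1e-12)

    def test_approx_close_to_exact(self, rng):
        x = rng.normal(0, 1, 9)
        y = rng.normal(0.5, 1, 8)
        p_exact = rank_sum_test(x, y, mode="exact").p_value
        p_approx = rank_sum_test(x, y, mode="approx").p_value
        assert abs(p_exact - p_approx) < 0.01

    def test_auto_switches(self):
        small = rank_sum_test([1, 2, 3], [4, 5, 6], mode="auto")
        assert small.mode == "exact"
        big = rank_sum_test(list(range(30)), list(range(30, 60)), mode="auto")
        assert big.mode == "approx"

    def test_exact_cap_error_suggests_approx(self):
        with pytest.raises(ValidationError, match="approx"):
            rank_sum_test(list(range(30)), list(range(30, 60)), mode="exact",
                          exact_cap=1000)

    def test_approx_type_one_error_calibrated(self, rng):
        # nominal 0.05 two-sided level, n = 10 per arm, Gaussian null
        x = rng.normal(size=(2000, 10))
        y = rng.normal(size=(2000, 10))
        rejections = np.mean(
            [rank_sum_test(a, b, mode="approx").p_value < 0.05
             for a, b in zip(x, y)]
        )
        assert 0.035 <= rejections <= 0.065


class TestDunnett:
    def test_identical_constant_groups_p_one(self):
        res = anova_dunnett([5.0, 5.0, 5.0], [[5.0, 5.0], [5.0, 5.0]])
        assert res.p_adjusted == (1.0, 1.0)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValidationError, match="zero pooled variance"):
            anova_dunnett([1.0, 1.0], [[2.0, 2.0]])

    def test_single_comparison_reduces_to_t_test(self, rng):
        c = rng.normal(0, 1, 10)
        g = rng.normal(1.2, 1, 10)
        res = anova_dunnett(c, [g], n_mc=200_000, seed=5)
        t_p = sps.ttest_ind(g, c).pvalue
        assert res.t_statistics[0] == pytest.approx(sps.ttest_ind(g, c).statistic)
        assert res.p_adjusted[0] == pytest.approx(t_p, abs=0.004)

    def test_matches_scipy_dunnett_balanced(self, rng):
        c = rng.normal(0, 1, 12)
        groups = [rng.normal(mu, 1, 12) for mu in (0.3, 0.9, 1.5)]
        res = anova_dunnett(c, groups, n_mc=200_000, seed=6)
        ref = sps.dunnett(*groups, control=c)
        for p_ours, p_ref in zip(res.p_adjusted, ref.pvalue):
            assert p_ours == pytest.approx(p_ref, abs=0.01)


class TestSummariesAndDesign:
    @pytest.mark.parametrize(
        "treated, control, expected", [(32, 40, -8), (55, 55, 0), (100, 0, 100)]
    )
    def test_delta_percent(self, treated, control, expected):
        assert delta_percent(treated, control) == expected

    def test_delta_percent_range_checked(self):
        with pytest.raises(ValidationError):
            delta_percent(120, 10)

    @pytest.mark.parametrize(
        "pos, tot, pct", [(16, 102, 16), (8, 16, 50), (17738, 25464, 70), (0, 10, 0)]
    )
    def test_proportion_rounding_half_away_from_zero(self, pos, tot, pct):
        s = proportion_summary(pos, tot)
        assert s.percent == pct
        assert s.percent_exact == pytest.approx(100 * pos / tot)

    def test_proportion_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            proportion_summary(0, 0)

    def test_sample_size_worked_values(self):
        assert sample_size_two_t(PowerSpec(1.5, 0.05, 0.70)) == 7
        assert sample_size_two_t(PowerSpec(1.0, 0.05, 0.80)) == 17

    def test_sample_size_floor_two(self):
        assert sample_size_two_t(PowerSpec(10.0, 0.05, 0.01)) == 2

    def test_sample_size_monotonicity(self):
        # non-increasing in d and alpha, non-decreasing in power
        n_d = [sample_size_two_t(PowerSpec(d, 0.05, 0.8)) for d in (0.5, 1.0, 1.5)]
        assert n_d == sorted(n_d, reverse=True)
        n_a = [sample_size_two_t(PowerSpec(1.0, a, 0.8)) for a in (0.01, 0.05, 0.1)]
        assert n_a == sorted(n_a, reverse=True)
        n_p = [sample_size_two_t(PowerSpec(1.0, 0.05, p)) for p in (0.5, 0.7, 0.9)]
        assert n_p == sorted(n_p)

    def test_matches_statsmodels_power(self):
        from statsmodels.stats.power import TTestIndPower

        n_sm = TTestIndPower().solve_power(effect_size=1.5, alpha=0.05, power=0.70)
        assert sample_size_two_t(PowerSpec(1.5, 0.05, 0.70)) == math.ceil(n_sm)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            PowerSpec(-1.0, 0.05, 0.8)
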