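import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest

import respnovel as rn
from respnovel.evaluate import (
    AllDaysMissingError,
    EPS,
    EvaluationError,
    MeanRoc,
    NoveltyLimits,
    RocCurve,
    _period_stat,
    benjamini_yekutieli,
    classify_day,
    classify_period,
    compare_methods,
    compute_limits,
    mean_roc,
    roc_curve,
    sensitivity_at_specificity,
)
from respnovel.telemetry import TestPeriod

from conftest import build_recording, day_date


class TestLimits:
    def test_mean_and_sd(self):
        lim = compute_limits([0.0, 2.0, 4.0])
        assert lim.m_b == pytest.approx(2.0)
        assert lim.s_b == pytest.approx(2.0)

    def test_constant_scores_floor_the_sd(self):
        assert compute_limits([1.0, 1.0, 1.0]).s_b == EPS

    def test_single_score_rejected(self):
        with pytest.raises(EvaluationError):
            compute_limits([1.0])


class TestClassifyDay:
    def test_score_at_mean_is_normal(self):
        lim = NoveltyLimits(2.0, 0.5)
        for k in (0.0, 1.0, 5.0):
            assert classify_day(2.0, lim, k) == "normal"

    def test_threshold_arithmetic(self):
        lim = NoveltyLimits(1.0, 0.2)
        assert classify_day(1.41, lim, 2.0) == "atypical"
        assert classify_day(1.39, lim, 2.0) == "normal"

    def test_exact_boundary_is_normal(self):
        lim = NoveltyLimits(1.0, 0.2)
        assert classify_day(1.0 + 2 * 0.2, lim, 2.0) == "normal"

    def test_missing_score_propagates(self):
        assert classify_day(None, NoveltyLimits(1.0, 1.0), 0.0) == "missing"


class TestClassifyPeriod:
    def test_single_atypical_day_flags_at_n1_not_n2(self):
        labels = ["atypical", "normal", "normal", "normal"]
        assert classify_period(labels, 1) == "pre-exacerbation"
        assert classify_period(labels, 2) == "stable"

    def test_unreachable_n_with_missing_days(self):
        labels = ["atypical", "atypical", "atypical", "missing"]
        assert classify_period(labels, 4) == "stable"

    def test_all_missing_raises_signal(self):
        with pytest.raises(AllDaysMissingError):
            classify_period(["missing"] * 4, 1)

    def test_matches_exhaustive_enumeration(self):
        # oracle: count atypical among non-missing, compare to n
        for labels in itertools.product(["normal", "atypical", "missing"], repeat=4):
            labels = list(labels)
            n_atyp = labels.count("atypical")
            n_present = 4 - labels.count("missing")
            for n in (1, 2, 3, 4):
                if n_present == 0:
                    with pytest.raises(AllDaysMissingError):
                        classify_period(labels, n)
                else:
                    expected = "pre-exacerbation" if n_atyp >= n else "stable"
                    assert classify_period(labels, n) == expected


def _make_test_set(pos_stats, neg_stats):
    """Periods with one scored day each, plus score/limit mappings."""
    scores, periods = {}, []
    limits = {}
    for i, (stat, truth) in enumerate(
        [(s, "pre-exacerbation") for s in pos_stats]
        + [(s, "stable") for s in neg_stats]
    ):
        rid = f"r{i}"
        date = day_date(15)
        periods.append(TestPeriod(rid, [date], truth))
        scores[(rid, date)] = stat
        limits[rid] = NoveltyLimits(0.0, 1.0)
    return periods, scores, limits


class TestRocCurve:
    def test_separable_scores_reach_perfect_corner(self):
        periods, scores, limits = _make_test_set([5.0, 6.0, 7.0], [0.0, 0.5, 1.0])
        curve = roc_curve(periods, scores, limits, n=1)
        assert any(np.allclose(p, [0.0, 1.0]) for p in curve.points)
        assert rn.auc(curve) == pytest.approx(1.0)

    def test_endpoints_always_present(self):
        periods, scores, limits = _make_test_set([1.0, 2.0], [0.5, 1.5])
        curve = roc_curve(periods, scores, limits, n=1)
        assert np.allclose(curve.points[0], [0.0, 0.0])
        assert np.allclose(curve.points[-1], [1.0, 1.0])

    def test_tpr_nondecreasing_in_fpr(self, rng):
        periods, scores, limits = _make_test_set(
            rng.normal(size=20), rng.normal(size=30)
        )
        curve = roc_curve(periods, scores, limits, n=1)
        assert np.all(np.diff(curve.tpr) >= -1e-12)
        assert np.all((curve.points >= 0) & (curve.points <= 1))

    def test_label_independent_scores_give_chance_auc(self, rng):
        stats = rng.normal(size=200)
        periods, scores, limits = _make_test_set(stats[:100], stats[100:])
        curve = roc_curve(periods, scores, limits, n=1)
        assert rn.auc(curve) == pytest.approx(0.5, abs=0.1)

    def test_period_stat_is_nth_largest_z(self):
        rid = "r0"
        dates = [day_date(d) for d in (15, 16, 17)]
        period = TestPeriod(rid, dates, "stable")
        scores = {(rid, dates[0]): 3.0, (rid, dates[1]): 1.0, (rid, dates[2]): None}
        limits = {rid: NoveltyLimits(1.0, 2.0)}
        assert _period_stat(period, scores, limits, 1) == pytest.approx(1.0)
        assert _period_stat(period, scores, limits, 2) == pytest.approx(0.0)
        assert _period_stat(period, scores, limits, 3) == -np.inf

    def test_empty_test_set_rejected(self):
        with pytest.raises(EvaluationError):
            roc_curve([], {}, {}, n=1)


class TestAuc:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([(0, 0), (0, 1), (1, 1)], 1.0),
            ([(0, 0), (1, 1)], 0.5),
            ([(0, 0), (0.5, 0.8), (1, 1)], 0.65),
        ],
    )
    def test_trapezoid_values(self, points, expected):
        curve = RocCurve(np.asarray(points, dtype=float))
        assert rn.auc(curve) == pytest.approx(expected)


class TestMeanRoc:
    def _curve(self, mid_tpr):
        return RocCurve(np.array([[0.0, 0.0], [0.5, mid_tpr], [1.0, 1.0]]))

    def test_identical_curves_have_zero_width_band(self):
        m = mean_roc([self._curve(0.7)] * 5)
        assert m.ci_lower == pytest.approx(m.mean_tpr)
        assert m.ci_upper == pytest.approx(m.mean_tpr)
        assert np.interp(0.5, m.fpr_grid, m.mean_tpr) == pytest.approx(0.7)

    def test_two_curves_average_pointwise(self):
        m = mean_roc([self._curve(0.4), self._curve(0.6)])
        assert np.interp(0.5, m.fpr_grid, m.mean_tpr) == pytest.approx(0.5)

    def test_band_brackets_the_mean(self, rng):
        curves = [self._curve(t) for t in rng.uniform(0.3, 0.9, size=10)]
        m = mean_roc(curves)
        assert np.all(m.ci_lower <= m.mean_tpr + 1e-12)
        assert np.all(m.mean_tpr <= m.ci_upper + 1e-12)

    def test_single_curve_rejected(self):
        with pytest.raises(EvaluationError):
            mean_roc([self._curve(0.5)])


class TestSensitivityAtSpecificity:
    def test_point_lookup(self):
        m = mean_roc([RocCurve(np.array([[0, 0], [0.5, 0.73], [1, 1]]))] * 2)
        assert sensitivity_at_specificity(m, 0.5) == pytest.approx(0.73)

    def test_diagonal_curve(self):
        m = mean_roc([RocCurve(np.array([[0.0, 0.0], [1.0, 1.0]]))] * 2)
        assert sensitivity_at_specificity(m, 0.5) == pytest.approx(0.5)

    def test_linear_interpolation_between_neighbors(self):
        m = MeanRoc(
            fpr_grid=np.array([0.4, 0.6]),
            mean_tpr=np.array([0.6, 0.8]),
            ci_lower=np.zeros(2),
            ci_upper=np.ones(2),
        )
        assert sensitivity_at_specificity(m, 0.5) == pytest.approx(0.7)


class TestCompareMethods:
    def test_identical_columns_give_p_one(self, rng):
        col = rng.uniform(0.4, 0.6, size=20)
        df = pd.DataFrame({"a": col, "b": col})
        comp = compare_methods(df)
        assert comp.raw_p.loc["a", "b"] == 1.0
        assert comp.adjusted_p.loc["a", "b"] == 1.0

    def test_adjusted_never_below_raw(self, rng):
        df = pd.DataFrame(rng.uniform(0.3, 0.9, size=(20, 4)), columns=list("abcd"))
        comp = compare_methods(df)
        mask = ~comp.raw_p.isna()
        assert np.all(
            comp.adjusted_p.values[mask.values] >= comp.raw_p.values[mask.values] - 1e-12
        )

    def test_clearly_better_method_detected(self, rng):
        base = rng.uniform(0.45, 0.55, size=50)
        df = pd.DataFrame({"good": base + 0.2, "bad": base})
        comp = compare_methods(df)
        assert comp.adjusted_p.loc["good", "bad"] < 0.001
        assert comp.adjusted_p.loc["bad", "good"] > 0.5

    def test_mismatched_repeat_counts_rejected(self):
        df = pd.DataFrame({"a": [0.5, 0.6, np.nan], "b": [0.5, 0.6, 0.7]})
        with pytest.raises(EvaluationError):
            compare_methods(df)


class TestBenjaminiYekutieli:
    def test_hand_computed_example(self):
        # p * m * c(m) / rank with c(3) = 1 + 1/2 + 1/3, then step-up
        adjusted = benjamini_yekutieli(np.array([0.01, 0.02, 0.04]))
        assert adjusted == pytest.approx([0.055, 0.055, 0.0733], abs=1e-4)

    def test_monotone_under_permutation(self, rng):
        p = rng.uniform(size=12)
        perm = rng.permutation(12)
        direct = benjamini_yekutieli(p)[perm]
        permuted = benjamini_yekutieli(p[perm])
        assert permuted == pytest.approx(direct)

    def test_never_exceeds_one(self):
        assert np.all(benjamini_yekutieli(np.array([0.5, 0.8, 0.9])) <= 1.0)


class TestBuildTestSets:
    def _cohort(self):
        case = build_recording(35, onsets=[20], recording_id="case")
        ctrl = build_recording(35, recording_id="ctrl")
        return [case, ctrl]

    def test_requested_number_of_repeats(self):
        sets = rn.build_test_sets(self._cohort(), repeats=50, seed=1)
        assert len(sets) == 50
        for ts in sets:
            truths = sorted(p.truth for p in ts)
            assert truths == ["pre-exacerbation", "stable"]

    def test_pre_exacerbation_periods_fixed_across_repeats(self):
        sets = rn.build_test_sets(self._cohort(), repeats=10, seed=1)
        pre = [
            tuple(p.dates) for ts in sets for p in ts if p.truth == "pre-exacerbation"
        ]
        assert len(set(pre)) == 1

    def test_reproducible_from_seed(self):
        a = rn.build_test_sets(self._cohort(), repeats=5, seed=9)
        b = rn.build_test_sets(self._cohort(), repeats=5, seed=9)
        assert [[p.dates for p in ts] for ts in a] == [[p.dates for p in ts] for ts in b]

    def test_cohort_without_controls_rejected(self):
        with pytest.raises(EvaluationError):
            rn.build_test_sets([build_recording(35, onsets=[20])], repeats=5, seed=0)
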