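"""ROC curves, locked thresholds, and prevalence-adjusted predictive values."""

import dataclasses
import math

import numpy as np
import pytest

import methpanel as mp
from methpanel.roc import (
    bootstrap_auc_ci,
    candidate_thresholds,
    confusion_at,
    delong_auc_ci,
)


class TestRocCurve:
    def test_disjoint_supports_perfect_point(self):
        curve = mp.roc_curve([9, 20], [1, 7])
        assert 8.0 in curve.thresholds
        i = list(curve.thresholds).index(8.0)
        assert curve.sensitivity[i] == 1.0 and curve.specificity[i] == 1.0

    def test_identical_groups_on_diagonal(self):
        scores = [1.0, 2.0, 3.0, 4.0]
        curve = mp.roc_curve(scores, scores)
        # every point sits on the diagonal: sensitivity = 1 - specificity
        assert np.allclose(curve.sensitivity, 1.0 - curve.specificity)
        assert curve.auc() == pytest.approx(0.5)

    def test_endpoints_present(self):
        curve = mp.roc_curve([3, 5], [1, 2])
        assert (curve.sensitivity[0], curve.specificity[0]) == (0.0, 1.0)
        assert (curve.sensitivity[-1], curve.specificity[-1]) == (1.0, 0.0)

    def test_monotone_as_threshold_decreases(self):
        rng = np.random.default_rng(1)
        curve = mp.roc_curve(rng.normal(1, 1, 20), rng.normal(0, 1, 25))
        assert (np.diff(curve.sensitivity) >= 0).all()
        assert (np.diff(curve.specificity) <= 0).all()

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_threshold_sweep_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 15, rng.integers(2, 10)).astype(float)
        neg = rng.integers(0, 15, rng.integers(2, 10)).astype(float)
        curve = mp.roc_curve(pos, neg)
        for t, se, sp in zip(curve.thresholds, curve.sensitivity, curve.specificity):
            assert se == pytest.approx(np.mean([p >= t for p in pos]))
            assert sp == pytest.approx(np.mean([n < t for n in neg]))

    def test_empty_group_rejected(self):
        with pytest.raises(mp.ValidationError):
            mp.roc_curve([], [1.0])


class TestAuc:
    def test_disjoint_supports(self):
        assert mp.auc([10, 11], [1, 2]) == 1.0

    @pytest.mark.parametrize("seed", range(50))
    def test_equals_u_over_n1n2(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 8, 7).astype(float)  # ties across classes likely
        neg = rng.integers(0, 8, 9).astype(float)
        u = mp.mann_whitney(pos, neg).u_statistic
        assert mp.auc(pos, neg) == pytest.approx(u / (7 * 9), abs=1e-12)


class TestLockThreshold:
    def test_exhaustive_candidate_example(self):
        locked = mp.lock_threshold([30, 40, 50], [0, 10], specificity_floor=0.9)
        assert locked.value == 20.0
        assert locked.training_sensitivity == 1.0
        assert locked.training_specificity == 1.0

    def test_perfect_separation(self):
        locked = mp.lock_threshold([10, 12], [2, 4], specificity_floor=0.9)
        assert locked.value == 7.0
        assert locked.training_sensitivity == locked.training_specificity == 1.0

    def test_degenerate_floor_zero(self):
        # floor 0 makes every candidate feasible; sensitivity 1 is reached at
        # the largest threshold below all positives (ties break conservatively)
        locked = mp.lock_threshold([5, 6], [1, 9], specificity_floor=0.0)
        assert locked.value == 3.0
        assert locked.training_sensitivity == 1.0
        assert locked.training_specificity == 0.5
        # with all negatives above the positives the cutoff drops below all scores
        locked = mp.lock_threshold([5, 6], [7, 9], specificity_floor=0.0)
        assert locked.value == -math.inf
        assert locked.training_sensitivity == 1.0
        assert locked.training_specificity == 0.0

    @pytest.mark.parametrize("seed", range(100))
    def test_specificity_floor_always_respected(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(2, 2, rng.integers(3, 25))
        neg = rng.normal(0, 2, rng.integers(3, 25))
        floor = float(rng.choice([0.0, 0.5, 0.8, 0.9, 0.95, 1.0]))
        locked = mp.lock_threshold(pos, neg, specificity_floor=floor)
        assert locked.training_specificity >= floor
        # no feasible threshold is more sensitive
        curve = mp.roc_curve(pos, neg)
        ok = curve.specificity >= floor
        assert locked.training_sensitivity == pytest.approx(
            curve.sensitivity[ok].max()
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_integer_scores_give_half_or_whole_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(20, 200, 15).astype(float)
        neg = rng.integers(0, 60, 15).astype(float)
        locked = mp.lock_threshold(pos, neg)
        if np.isfinite(locked.value):
            assert (2 * locked.value) == int(2 * locked.value)

    def test_locked_threshold_is_immutable(self):
        locked = mp.lock_threshold([5], [1])
        with pytest.raises(dataclasses.FrozenInstanceError):
            locked.value = 0.0


class TestPredictiveValues:
    @pytest.mark.parametrize(
        "se,sp,prev,expected",
        [
            (1.0, 1.0, 0.01, (100.0, 100.0, 100.0)),
            (1.0, 0.96, 0.01, (20.161290322580644, 100.0, 96.04)),
            (0.5, 0.5, 0.5, (50.0, 50.0, 50.0)),
            (0.8, 0.8, 0.5, (80.0, 80.0, 80.0)),
        ],
    )
    def test_formula_evaluation(self, se, sp, prev, expected):
        pv = mp.predictive_values(se, sp, prev)
        assert (pv.ppv, pv.npv, pv.accuracy) == pytest.approx(expected)

    def test_ppv_undefined_at_zero_sensitivity_full_specificity(self):
        pv = mp.predictive_values(0.0, 1.0, 0.01)
        assert not pv.ppv_defined and math.isnan(pv.ppv)
        assert pv.npv_defined

    def test_out_of_range_rejected(self):
        with pytest.raises(mp.ValidationError):
            mp.predictive_values(1.2, 0.5, 0.01)


class TestConfidenceIntervals:
    def test_clopper_pearson_contains_point_estimate(self):
        for k, n in [(0, 10), (5, 10), (10, 10), (29, 30)]:
            lo, hi = mp.clopper_pearson(k, n)
            assert lo <= k / n <= hi

    def test_clopper_pearson_exact_endpoints(self):
        assert mp.clopper_pearson(0, 5)[0] == 0.0
        assert mp.clopper_pearson(5, 5)[1] == 1.0

    def test_delong_degenerate_perfect_auc(self):
        a, ci = delong_auc_ci([10.0, 11.0, 12.0], [1.0, 2.0])
        assert a == 1.0 and ci == (1.0, 1.0)

    def test_delong_and_bootstrap_agree_roughly(self):
        rng = np.random.default_rng(5)
        pos, neg = rng.normal(1.2, 1, 40), rng.normal(0, 1, 40)
        a1, ci1 = delong_auc_ci(pos, neg)
        a2, ci2 = bootstrap_auc_ci(pos, neg, seed=1)
        assert a1 == pytest.approx(a2)
        assert ci1[0] == pytest.approx(ci2[0], abs=0.06)
        assert ci1[1] == pytest.approx(ci2[1], abs=0.06)


class TestEvaluateLocked:
    def test_report_at_known_operating_point(self):
        # 25 negatives with exactly one above the threshold -> specificity 0.96
        locked = mp.LockedThreshold(5.0, 0.9, 1.0, 1.0)
        pos = [6.0, 7.0, 8.0]
        neg = [1.0] * 24 + [9.0]
        report = mp.evaluate_locked(pos, neg, locked, prevalence=0.01)
        assert report.sensitivity == 1.0
        assert report.specificity == pytest.approx(0.96)
        assert report.ppv == pytest.approx(20.161290322580644)
        assert report.npv == pytest.approx(100.0)
        assert report.accuracy == pytest.approx(96.04)
        assert report.confusion == mp.ConfusionCounts(tp=3, fp=1, tn=24, fn=0)

    def test_cis_contain_point_estimates(self):
        rng = np.random.default_rng(9)
        locked = mp.LockedThreshold(0.5, 0.9, 1.0, 1.0)
        report = mp.evaluate_locked(
            rng.normal(1, 1, 30), rng.normal(0, 1, 30), locked
        )
        assert report.sensitivity_ci[0] <= report.sensitivity <= report.sensitivity_ci[1]
        assert report.specificity_ci[0] <= report.specificity <= report.specificity_ci[1]
        assert report.auc_ci[0] <= report.auc <= report.auc_ci[1]

    def test_threshold_used_verbatim(self):
        locked = mp.LockedThreshold(100.0, 0.9, 1.0, 1.0)
        report = mp.evaluate_locked([1.0, 2.0], [0.5], locked)
        assert report.threshold == 100.0 and report.sensitivity == 0.0

    def test_bad_prevalence_rejected(self):
        locked = mp.LockedThreshold(1.0, 0.9, 1.0, 1.0)
        with pytest.raises(mp.ValidationError):
            mp.evaluate_locked([2.0], [0.0], locked, prevalence=0.0)


def test_confusion_counts_partition_samples():
    cc = confusion_at([5, 1], [0, 9], 3.0)
    assert (cc.tp + cc.fn, cc.tn + cc.fp) == (2, 2)
    assert cc == mp.ConfusionCounts(tp=1, fp=1, tn=1, fn=1)


def test_candidate_thresholds_are_midpoints_with_sentinels():
    thr = candidate_thresholds([1.0, 3.0], [2.0])
    assert thr[0] == math.inf and thr[-1] == -math.inf
    assert set(thr[1:-1]) == {2.5, 1.5}
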