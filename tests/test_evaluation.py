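"""Confusion metrics, MCC, ROC/AUC and cross-validation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nabind.evaluation import (
    ConfusionCounts,
    EvaluationError,
    auc_trapezoid,
    classification_metrics,
    confusion_counts,
    cross_validate,
    evaluate_at_threshold,
    matthews_cc,
    roc_points,
)
from nabind.model import KernelParams


def pairwise_auc_oracle(labels, scores):
    """O(n^2) Mann-Whitney concordance count, ties worth one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionCounts:
    def test_hand_counted_example(self):
        labels = [1, 1, 1, 1, -1, -1, -1, -1, -1]
        scores = [1, 1, 1, -1, -1, -1, -1, -1, 1]  # predictions at t=0
        c = confusion_counts(labels, scores, threshold=0.0)
        assert (c.tp, c.fn, c.tn, c.fp) == (3, 1, 4, 1)

    def test_saturated_positive_case(self):
        c = confusion_counts([1] * 5, [2.0] * 5, threshold=0.0)
        assert (c.tp, c.tn, c.fp, c.fn) == (5, 0, 0, 0)

    def test_threshold_above_all_scores_calls_nothing(self):
        c = confusion_counts([1, -1], [0.2, 0.3], threshold=10.0)
        assert c.tp == 0 and c.fp == 0

    def test_tie_at_threshold_counts_as_positive_call(self):
        c = confusion_counts([1], [0.5], threshold=0.5)
        assert c.tp == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(EvaluationError):
            confusion_counts([1, -1], [0.1], 0.0)


class TestClassificationMetrics:
    def test_direct_arithmetic(self):
        m = classification_metrics(ConfusionCounts(tp=3, tn=4, fp=1, fn=1))
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(0.8)
        assert m.strength == pytest.approx(0.775)
        assert m.accuracy == pytest.approx(7 / 9)

    def test_strength_is_mean_of_sensitivity_and_specificity(self):
        # the published operating point of the best DNA-binding classifier
        m = classification_metrics(
            ConfusionCounts(tp=773, fn=227, tn=793, fp=207)
        )
        assert m.sensitivity == pytest.approx(0.773)
        assert m.specificity == pytest.approx(0.793)
        assert m.strength == pytest.approx(0.783)

    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionCounts(tp=10, tn=20, fp=0, fn=0))
        assert (m.accuracy, m.sensitivity, m.specificity, m.strength) == (
            1.0, 1.0, 1.0, 1.0,
        )

    def test_zero_denominator_flagged_not_raised(self):
        m = classification_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert m.sensitivity == 0.0
        assert m.degenerate

    def test_empty_table_rejected(self):
        with pytest.raises(EvaluationError):
            classification_metrics(ConfusionCounts(0, 0, 0, 0))


class TestMatthewsCC:
    def test_perfect_and_inverted(self):
        assert matthews_cc(ConfusionCounts(tp=5, tn=5, fp=0, fn=0)) == 1.0
        assert matthews_cc(ConfusionCounts(tp=0, tn=0, fp=5, fn=5)) == -1.0

    def test_direct_formula_example(self):
        # (3*4 - 1*1) / sqrt(4*4*5*5) = 11/20
        assert matthews_cc(ConfusionCounts(tp=3, tn=4, fp=1, fn=1)) == \
            pytest.approx(0.55)

    def test_zero_factor_convention(self):
        assert matthews_cc(ConfusionCounts(tp=0, tn=5, fp=0, fn=3)) == 0.0

    def test_matches_direct_arithmetic_on_random_tables(self, rng):
        import math

        for _ in range(100):
            tp, tn, fp, fn = rng.integers(0, 50, size=4)
            c = ConfusionCounts(int(tp), int(tn), int(fp), int(fn))
            denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
            expected = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
            assert matthews_cc(c) == pytest.approx(expected, abs=1e-12)


class TestROC:
    def test_perfect_separation(self):
        roc = roc_points([1, 1, -1, -1], [0.9, 0.8, 0.2, 0.1])
        assert roc.auc == pytest.approx(1.0)
        # the curve must pass through the (0, 1) corner
        assert any(f == 0.0 and t == 1.0 for f, t in zip(roc.fpr, roc.tpr))

    def test_uninformative_scores_give_half(self):
        roc = roc_points([1, 1, -1, -1], [0.5] * 4)
        assert roc.auc == pytest.approx(0.5)

    def test_partial_overlap_example(self):
        # 3 of 4 positive/negative pairs concordant
        roc = roc_points([1, 1, -1, -1], [0.8, 0.3, 0.5, 0.1])
        assert roc.auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_points([1, 1], [0.1, 0.2])

    def test_curve_endpoints_and_monotonicity(self, rng):
        labels = rng.choice([1, -1], size=80)
        labels[:2] = [1, -1]
        scores = np.round(rng.random(80), 1)  # force ties
        roc = roc_points(labels, scores)
        assert (roc.tpr[0], roc.fpr[0]) == (1.0, 1.0)
        assert (roc.tpr[-1], roc.fpr[-1]) == (0.0, 0.0)
        assert np.all(np.diff(roc.tpr) <= 1e-12)
        assert np.all(np.diff(roc.fpr) <= 1e-12)

    def test_trapezoid_equals_pairwise_oracle(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 50))
            labels = rng.choice([1, -1], size=n)
            labels[:2] = [1, -1]
            scores = np.round(rng.normal(size=n), 1)
            roc = roc_points(labels, scores)
            assert auc_trapezoid(roc) == pytest.approx(
                pairwise_auc_oracle(labels, scores), abs=1e-9
            )

    def test_agrees_with_reference_implementation(self, rng):
        from sklearn.metrics import roc_auc_score

        labels = rng.choice([1, -1], size=200)
        labels[:2] = [1, -1]
        scores = np.round(rng.normal(size=200), 1)
        assert roc_points(labels, scores).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_metrics_invariant_under_permutation(self, rng):
        labels = rng.choice([1, -1], size=60)
        labels[:2] = [1, -1]
        scores = rng.normal(size=60)
        order = rng.permutation(60)
        m1 = evaluate_at_threshold(labels, scores, 0.1)
        m2 = evaluate_at_threshold(labels[order], scores[order], 0.1)
        assert m1 == m2
        assert roc_points(labels, scores).auc == pytest.approx(
            roc_points(labels[order], scores[order]).auc
        )

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_threshold_sweep_monotone(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.choice([1, -1], size=30)
        labels[:2] = [1, -1]
        scores = np.round(rng.normal(size=30), 1)
        sweep = [evaluate_at_threshold(labels, scores, t)
                 for t in np.sort(np.unique(scores))]
        sens = [m.sensitivity for m in sweep]
        spec = [m.specificity for m in sweep]
        assert all(a >= b - 1e-12 for a, b in zip(sens, sens[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(spec, spec[1:]))
        for m in sweep:
            assert m.strength == pytest.approx(
                (m.sensitivity + m.specificity) / 2
            )


class TestCrossValidate:
    def test_partition_arithmetic_and_determinism(self, small_instances):
        labels, scores, folds, models = cross_validate(
            small_instances, KernelParams(), k=5, seed=17
        )
        assert len(scores) == len(small_instances)
        assert sorted(np.unique(folds)) == [0, 1, 2, 3, 4]
        counts = np.bincount(folds)
        assert counts.max() - counts.min() <= 1
        # stratification keeps the fold-level class balance close to global
        global_rate = np.mean(small_instances.y == 1)
        for f in range(5):
            rate = np.mean(small_instances.y[folds == f] == 1)
            assert abs(rate - global_rate) < 0.05

        _, scores2, folds2, _ = cross_validate(
            small_instances, KernelParams(), k=5, seed=17
        )
        assert np.array_equal(folds, folds2)
        assert np.allclose(scores, scores2)

    def test_small_class_rejected(self, small_instances):
        from nabind.encoding import InstanceSet

        idx = np.concatenate([
            np.nonzero(small_instances.y == 1)[0][:3],
            np.nonzero(small_instances.y == -1)[0][:50],
        ])
        tiny = InstanceSet(
            small_instances.X[idx], small_instances.y[idx],
            [small_instances.sequence_ids[i] for i in idx],
            small_instances.positions[idx], small_instances.descriptor,
        )
        with pytest.raises(EvaluationError):
            cross_validate(tiny, k=5)

    def test_group_by_sequence_keeps_windows_together(self, small_instances):
        _, _, folds, _ = cross_validate(
            small_instances, KernelParams(), k=3, seed=1,
            group_by_sequence=True,
        )
        ids = np.array(small_instances.sequence_ids)
        for seq_id in np.unique(ids):
            assert len(np.unique(folds[ids == seq_id])) == 1
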