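"""Cross-validation and performance measures for residue classifiers.

Hard predictions at a threshold ``t`` use the rule score >= t (ties count
as positive calls).  Besides accuracy, sensitivity and specificity, two
summary measures matter for the heavily imbalanced binding-residue
problem: *strength*, the average of sensitivity and specificity, and the
Matthews correlation coefficient.  The ROC curve is produced by sweeping
the classifier output threshold over all observed scores; its area equals
the probability that a random positive outscores a random negative
(ties counting one half).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise EvaluationError("negative confusion count")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    strength: float
    mcc: float | None = None
    degenerate: bool = False  # some denominator was zero


def confusion_counts(labels, scores, threshold: float) -> ConfusionCounts:
    """Count TP/TN/FP/FN for the rule ``score >= threshold`` => positive."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise EvaluationError("labels and scores differ in length")
    if labels.size == 0:
        raise EvaluationError("no instances to evaluate")
    pred_pos = scores >= threshold
    actual_pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred_pos & actual_pos)),
        tn=int(np.sum(~pred_pos & ~actual_pos)),
        fp=int(np.sum(pred_pos & ~actual_pos)),
        fn=int(np.sum(~pred_pos & actual_pos)),
    )


def _ratio(num: int, den: int) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def classification_metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, sensitivity, specificity and strength from a confusion table.

    Zero-denominator cases yield the value 0 and set the ``degenerate``
    flag rather than raising, so full threshold sweeps never abort.
    """
    if c.total == 0:
        raise EvaluationError("empty confusion table")
    sens, d1 = _ratio(c.tp, c.tp + c.fn)
    spec, d2 = _ratio(c.tn, c.tn + c.fp)
    return MetricSet(
        accuracy=(c.tp + c.tn) / c.total,
        sensitivity=sens,
        specificity=spec,
        strength=(sens + spec) / 2.0,
        degenerate=d1 or d2,
    )


def matthews_cc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 by convention when any
    denominator factor vanishes."""
    num = c.tp * c.tn - c.fp * c.fn
    factors = [c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn]
    if any(f == 0 for f in factors):
        return 0.0
    return num / float(np.sqrt(np.prod([float(f) for f in factors])))


def evaluate_at_threshold(labels, scores, threshold: float) -> MetricSet:
    c = confusion_counts(labels, scores, threshold)
    m = classification_metrics(c)
    return MetricSet(m.accuracy, m.sensitivity, m.specificity, m.strength,
                     mcc=matthews_cc(c), degenerate=m.degenerate)


@dataclass
class ROCCalibration:
    """Threshold table for ROC analysis, threshold selection and
    confidence scoring.

    ``thresholds`` ascend and include a +inf sentinel; ``tpr``/``fpr`` are
    the rates of the rule score >= threshold, so both are non-increasing
    in the threshold, starting at (1, 1) and ending at (0, 0).  The
    empirical positive and negative score distributions are retained for
    downstream confidence estimates.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    pos_scores: np.ndarray = field(repr=False)
    neg_scores: np.ndarray = field(repr=False)

    @property
    def sensitivity(self) -> np.ndarray:
        return self.tpr

    @property
    def specificity(self) -> np.ndarray:
        return 1.0 - self.fpr


def roc_points(labels, scores) -> ROCCalibration:
    """Build the empirical ROC staircase from pooled labels and scores.

    One point per unique score value plus sentinels at both extremes;
    tied scores are grouped so the curve is a valid staircase.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels != 1])
    if pos.size == 0 or neg.size == 0:
        raise EvaluationError("ROC undefined: need both classes")

    uniq = np.unique(scores)
    thresholds = np.concatenate([[-np.inf], uniq, [np.inf]])
    # score >= t counts: positions found by binary search on sorted scores
    tpr = 1.0 - np.searchsorted(pos, thresholds, side="left") / pos.size
    fpr = 1.0 - np.searchsorted(neg, thresholds, side="left") / neg.size
    auc = auc_trapezoid_raw(fpr, tpr)
    return ROCCalibration(thresholds, tpr, fpr, auc, pos, neg)


def auc_trapezoid_raw(fpr, tpr) -> float:
    # integrate along the curve in traversal order: sorting by FPR would
    # mis-pair endpoints inside tied-FPR blocks
    x = np.asarray(fpr, dtype=float)
    y = np.asarray(tpr, dtype=float)
    if x.size >= 2 and x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    return float(np.trapezoid(y, x))


def auc_trapezoid(roc: ROCCalibration) -> float:
    """Trapezoidal area under the ROC curve over FPR in [0, 1]."""
    return auc_trapezoid_raw(roc.fpr, roc.tpr)


def cross_validate(
    instances,
    params=None,
    k: int = 5,
    seed: int = 0,
    group_by_sequence: bool = False,
    class_weight_ratio: float | None = None,
):
    """Stratified k-fold cross-validation at the instance level.

    Instances are distributed randomly into ``k`` folds, stratified on the
    label so each fold keeps the dataset's class balance; each instance is
    scored exactly once by the model trained without its fold, and the
    pooled (labels, scores) from all folds feed metrics and ROC curves.
    With ``group_by_sequence`` all windows of one sequence go to the same
    fold, preventing overlapping windows from straddling a train/test
    split.

    Returns ``(labels, scores, fold_assignment, models)`` with pooled
    arrays in the original instance order.
    """
    from .model import KernelParams, train_classifier

    params = params or KernelParams()
    if class_weight_ratio is not None:
        params = KernelParams(params.gamma, params.C, class_weight_ratio)
    y = instances.y
    for cls in (1, -1):
        if int(np.sum(y == cls)) < k:
            raise EvaluationError(
                f"class {cls:+d} has fewer than k={k} members"
            )
    if group_by_sequence:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(instances.X, y, groups=instances.sequence_ids)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(instances.X, y)

    scores = np.empty(len(instances), dtype=float)
    fold_of = np.empty(len(instances), dtype=int)
    models = []
    for fold, (train_idx, test_idx) in enumerate(splits):
        sub = _subset(instances, train_idx)
        model = train_classifier(sub, params, seed=seed + fold)
        scores[test_idx] = model.decision_values(_subset(instances, test_idx))
        fold_of[test_idx] = fold
        models.append(model)
    return y.copy(), scores, fold_of, models


def _subset(instances, idx):
    from .encoding import InstanceSet

    return InstanceSet(
        instances.X[idx],
        instances.y[idx],
        [instances.sequence_ids[i] for i in idx],
        instances.positions[idx],
        instances.descriptor,
    )


def write_metrics_tsv(path, metrics: MetricSet, extra: dict | None = None) -> None:
    rows = {
        "accuracy": metrics.accuracy,
        "sensitivity": metrics.sensitivity,
        "specificity": metrics.specificity,
        "strength": metrics.strength,
    }
    if metrics.mcc is not None:
        rows["mcc"] = metrics.mcc
    rows.update(extra or {})
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for name, value in rows.items():
            fh.write(f"{name}\t{value:.6f}\n")


def write_roc_tsv(path, roc: ROCCalibration) -> None:
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for x, y in zip(roc.fpr, roc.tpr):
            fh.write(f"{x:.6f}\t{y:.6f}\n")
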