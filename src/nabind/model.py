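"""RBF-kernel max-margin classifier for windowed residue instances.

The kernel is K(x1, x2) = exp(-gamma * ||x1 - x2||^2); gamma controls the
smoothness of the decision boundary and the regularization factor C trades
training error against margin.  Fitting is delegated to an established
quadratic-programming solver (scikit-learn's SVC); this module owns the
contract around it: real-valued decision outputs, an encoding descriptor
that must match between training and scoring, grid search over (gamma, C)
by cross-validated strength or AUC, and model persistence.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .encoding import EncodingDescriptor, InstanceSet

MODEL_FORMAT_VERSION = 1


class TrainingError(ValueError):
    pass


class DescriptorMismatchError(ValueError):
    """Instances were encoded differently from the model's training data."""


@dataclass(frozen=True)
class KernelParams:
    gamma: float = 0.05
    C: float = 2.0
    class_weight_ratio: float = 1.0  # weight of +1 class relative to -1

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.C <= 0 or self.class_weight_ratio <= 0:
            raise TrainingError("gamma, C and class_weight_ratio must be > 0")


def rbf_kernel(x1, x2, gamma: float) -> float:
    """exp(-gamma * ||x1 - x2||^2); 1 iff x1 == x2 for gamma > 0."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError(f"dimension mismatch: {x1.shape} vs {x2.shape}")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return float(np.exp(-gamma * np.sum((x1 - x2) ** 2)))


def kernel_matrix(X, gamma: float) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    return np.exp(-gamma * np.maximum(d2, 0.0))


@dataclass
class TrainedClassifier:
    params: KernelParams
    descriptor: EncodingDescriptor
    estimator: SVC = field(repr=False)
    metadata: dict = field(default_factory=dict)

    def decision_values(self, instances: InstanceSet | np.ndarray) -> np.ndarray:
        """Real-valued SVM outputs, higher = more binding-like.

        Refuses instance sets whose encoding descriptor differs from the
        one the model was trained with.
        """
        if isinstance(instances, InstanceSet):
            if instances.descriptor.to_dict() != self.descriptor.to_dict():
                raise DescriptorMismatchError(
                    f"model trained on {self.descriptor.to_dict()}, "
                    f"got {instances.descriptor.to_dict()}"
                )
            X = instances.X
        else:
            X = np.asarray(instances, dtype=float)
        return self.estimator.decision_function(X)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "params": self.params,
                "descriptor": self.descriptor.to_dict(),
                "estimator": self.estimator,
                "metadata": self.metadata,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        payload = joblib.load(path)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model archive: {path}")
        return cls(
            params=payload["params"],
            descriptor=EncodingDescriptor.from_dict(payload["descriptor"]),
            estimator=payload["estimator"],
            metadata=payload["metadata"],
        )


def train_classifier(
    instances: InstanceSet, params: KernelParams | None = None, seed: int = 0
) -> TrainedClassifier:
    """Fit the RBF-kernel classifier on encoded instances.

    Requires both classes present; the fit is deterministic given the data
    and solver tolerance (1e-3).
    """
    params = params or KernelParams()
    classes = np.unique(instances.y)
    if len(classes) < 2:
        raise TrainingError(f"training data has a single class: {classes}")
    estimator = SVC(
        kernel="rbf",
        gamma=params.gamma,
        C=params.C,
        class_weight={1: params.class_weight_ratio, -1: 1.0},
        tol=1e-3,
        cache_size=200,
        random_state=seed,
    )
    estimator.fit(instances.X, instances.y)
    meta = {
        "dataset_hash": hashlib.sha256(
            np.ascontiguousarray(instances.X).tobytes()
            + instances.y.tobytes()
        ).hexdigest()[:16],
        "n_instances": len(instances),
        "seed": seed,
        "trained_at": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    return TrainedClassifier(params, instances.descriptor, estimator, meta)


def grid_search(
    instances: InstanceSet,
    gamma_grid=(0.01, 0.05, 0.1, 0.5, 1.0),
    C_grid=(0.5, 1.0, 2.0, 5.0, 10.0),
    folds: int = 5,
    criterion: str = "strength",
    seed: int = 0,
) -> tuple[KernelParams, pd.DataFrame]:
    """Exhaustive (gamma, C) search by cross-validated strength or AUC.

    Strength is evaluated at threshold 0.  Returns the best parameters and
    the full score table for audit; ties go to smaller C, then smaller
    gamma.
    """
    from .evaluation import cross_validate, evaluate_at_threshold, roc_points

    if criterion not in ("strength", "auc"):
        raise ValueError(f"criterion must be 'strength' or 'auc': {criterion}")
    if not len(tuple(gamma_grid)) or not len(tuple(C_grid)):
        raise ValueError("empty parameter grid")

    rows = []
    for gamma in gamma_grid:
        for C in C_grid:
            params = KernelParams(gamma=gamma, C=C)
            labels, scores, _, _ = cross_validate(
                instances, params, k=folds, seed=seed
            )
            if criterion == "strength":
                value = evaluate_at_threshold(labels, scores, 0.0).strength
            else:
                value = roc_points(labels, scores).auc
            rows.append({"gamma": gamma, "C": C, criterion: value})
    table = pd.DataFrame(rows)
    # argmax with documented tie-break: smaller C, then smaller gamma
    best = table.sort_values(
        [criterion, "C", "gamma"], ascending=[False, True, True], kind="stable"
    ).iloc[0]
    return KernelParams(gamma=float(best["gamma"]), C=float(best["C"])), table
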