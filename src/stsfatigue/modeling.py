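"""Cross-validated fatigue classifiers and their evaluation metrics.

Five classifier families are supported (random forest, RBF support vector
machine, multilayer perceptron, logistic regression, k-nearest neighbours),
each with study defaults. Evaluation is seeded k-fold cross-validation
(default k = 6, so a 660-register dataset gives folds of 110); per fold a
3x3 confusion matrix is stored with predictions on rows and true labels on
columns, from which accuracy = trace/N, per-class precision TP/(TP+FP),
recall TP/(TP+FN) and F = 2PR/(P+R) are derived. Macro averages over the
three classes are the headline numbers; micro averages are also emitted.
Random-forest runs additionally accumulate impurity-based feature
importances (averaged across folds, summing to one).

Fold assignment is register-level by default; ``group_by_participant`` keeps
each subject's registers in a single fold to avoid leaking subjects across
the train/test split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dataset_builder import LABELS, FatigueDataset

__all__ = [
    "ModelSpec",
    "ConfusionMatrix",
    "CVResult",
    "DEFAULT_HYPERPARAMETERS",
    "make_estimator",
    "kfold_split",
    "confusion_metrics",
    "cross_validate",
    "rf_feature_importance",
    "stratified_eval",
]

logger = logging.getLogger(__name__)

#: Study defaults per family. The KNN neighbour count follows the text
#: (k = 12); 27 is a documented alternative from the same source table.
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "RF": {"n_estimators": 60},
    "SVM": {"kernel": "rbf", "C": 2.0, "class_weight": "balanced"},
    "ANN": {
        "activation": "relu",
        "solver": "adam",
        "hidden_layer_sizes": (100, 20, 100),
        "alpha": 0.05,
        "learning_rate": "adaptive",
        "max_iter": 1000,
    },
    "LR": {"solver": "lbfgs", "C": 1000.0, "max_iter": 2000},
    "KNN": {"n_neighbors": 12},
}


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.family not in DEFAULT_HYPERPARAMETERS:
            raise ValueError(
                f"unknown family {self.family!r}; expected one of "
                f"{sorted(DEFAULT_HYPERPARAMETERS)}"
            )

    def resolved_hyperparameters(self) -> dict:
        params = dict(DEFAULT_HYPERPARAMETERS[self.family])
        params.update(self.hyperparameters)
        return params


def make_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn estimator for a model spec."""
    params = spec.resolved_hyperparameters()
    if spec.family == "RF":
        est = RandomForestClassifier(random_state=spec.seed, **params)
    elif spec.family == "SVM":
        est = SVC(random_state=spec.seed, **params)
    elif spec.family == "ANN":
        est = MLPClassifier(random_state=spec.seed, **params)
    elif spec.family == "LR":
        est = LogisticRegression(**params)
    else:
        est = KNeighborsClassifier(**params)
    if spec.standardize:
        return make_pipeline(StandardScaler(), est)
    return est


@dataclass
class ConfusionMatrix:
    """3x3 counts with predictions on rows and true labels on columns."""

    counts: np.ndarray
    labels: tuple[str, ...] = LABELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"confusion counts must be {k}x{k}")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray,
        labels: Sequence[str] = LABELS,
    ) -> "ConfusionMatrix":
        # sklearn puts true labels on rows; transpose to predicted-on-rows
        counts = _sk_confusion(y_true, y_pred, labels=list(labels)).T
        return cls(counts=counts, labels=tuple(labels))


def kfold_split(n: int, k: int = 6, seed: int = 0) -> list[np.ndarray]:
    """Seeded shuffle of ``range(n)`` into ``k`` groups of near-equal size."""
    if n < k:
        raise ValueError(f"cannot split {n} items into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(group) for group in np.array_split(perm, k)]


def confusion_metrics(matrix: ConfusionMatrix) -> dict[str, float]:
    """Accuracy and per-class / macro / micro precision, recall and F-score.

    A class never predicted (TP+FP = 0) gets precision 0 (with a warning);
    the same convention applies to recall and F for empty denominators.
    """
    counts = matrix.counts
    total = matrix.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts).astype(float)
    predicted = counts.sum(axis=1).astype(float)  # TP + FP per class
    actual = counts.sum(axis=0).astype(float)  # TP + FN per class

    precision = np.zeros(len(tp))
    recall = np.zeros(len(tp))
    for i, label in enumerate(matrix.labels):
        if predicted[i] == 0:
            logger.warning("class %s never predicted; precision set to 0",
                           label)
        else:
            precision[i] = tp[i] / predicted[i]
        if actual[i] == 0:
            logger.warning("class %s absent from the fold; recall set to 0",
                           label)
        else:
            recall[i] = tp[i] / actual[i]
    with np.errstate(invalid="ignore"):
        f_score = np.where(
            precision + recall > 0,
            2 * precision * recall / (precision + recall),
            0.0,
        )

    accuracy = float(tp.sum() / total)
    metrics: dict[str, float] = {"accuracy": accuracy}
    for i, label in enumerate(matrix.labels):
        metrics[f"precision_{label}"] = float(precision[i])
        metrics[f"recall_{label}"] = float(recall[i])
        metrics[f"f_score_{label}"] = float(f_score[i])
    metrics["precision"] = float(precision.mean())
    metrics["recall"] = float(recall.mean())
    metrics["f_score"] = float(f_score.mean())
    # micro averages collapse to accuracy for single-label multiclass
    metrics["precision_micro"] = accuracy
    metrics["recall_micro"] = accuracy
    metrics["f_score_micro"] = accuracy
    return metrics


@dataclass
class CVResult:
    fold_matrices: list[ConfusionMatrix]
    fold_metrics: list[dict[str, float]]
    mean_metrics: dict[str, float]
    feature_importances: dict[str, float] | None = None
    skipped_folds: list[int] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return self.mean_metrics["accuracy"]

    def pooled_matrix(self) -> ConfusionMatrix:
        counts = sum(m.counts for m in self.fold_matrices)
        return ConfusionMatrix(counts=counts,
                               labels=self.fold_matrices[0].labels)


def cross_validate(
    dataset: FatigueDataset,
    spec: ModelSpec,
    k: int = 6,
    seed: int = 0,
    group_by_participant: bool = False,
) -> CVResult:
    """k-fold cross-validation of one model spec over the dataset.

    Folds lacking a class in their training part are skipped with a warning
    and listed in ``skipped_folds``. Fixed seeds make runs reproducible.
    """
    X, y = dataset.design_matrix()
    present = set(y)
    if present != set(LABELS):
        raise ValueError(
            f"dataset must contain all three classes; found {sorted(present)}"
        )

    if group_by_participant:
        pids = np.array([r.participant_id for r in dataset.registers])
        unique = np.array(sorted(set(pids)))
        groups = kfold_split(len(unique), k=k, seed=seed)
        folds = [
            np.flatnonzero(np.isin(pids, unique[g])) for g in groups
        ]
    else:
        folds = kfold_split(len(y), k=k, seed=seed)

    fold_matrices: list[ConfusionMatrix] = []
    fold_metrics: list[dict[str, float]] = []
    importances: list[np.ndarray] = []
    skipped: list[int] = []
    for i, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        y_train = y[train_mask]
        if set(y_train) != set(LABELS):
            logger.warning("fold %d training part lacks a class; skipped", i)
            skipped.append(i)
            continue
        est = make_estimator(spec)
        est.fit(X[train_mask], y_train)
        y_pred = est.predict(X[test_idx])
        matrix = ConfusionMatrix.from_predictions(y[test_idx], y_pred)
        fold_matrices.append(matrix)
        fold_metrics.append(confusion_metrics(matrix))
        if spec.family == "RF" and not spec.standardize:
            importances.append(est.feature_importances_)
        elif spec.family == "RF":
            importances.append(est[-1].feature_importances_)

    if not fold_matrices:
        raise ValueError("every fold was skipped; cannot evaluate")
    mean_metrics = {
        key: float(np.mean([m[key] for m in fold_metrics]))
        for key in fold_metrics[0]
    }
    imp = None
    if importances:
        mean_imp = np.mean(importances, axis=0)
        mean_imp = mean_imp / mean_imp.sum()
        imp = dict(zip(dataset.feature_names, mean_imp.astype(float)))
    return CVResult(
        fold_matrices=fold_matrices,
        fold_metrics=fold_metrics,
        mean_metrics=mean_metrics,
        feature_importances=imp,
        skipped_folds=skipped,
    )


def rf_feature_importance(result: CVResult) -> list[tuple[str, float]]:
    """Fold-averaged impurity importances, ranked descending (sums to 1)."""
    if result.feature_importances is None:
        raise ValueError(
            "feature importances are only available for random-forest runs"
        )
    return sorted(
        result.feature_importances.items(), key=lambda kv: -kv[1]
    )


def stratified_eval(
    dataset: FatigueDataset,
    spec: ModelSpec,
    by: str = "sex",
    k: int = 6,
    seed: int = 0,
) -> dict[str, CVResult]:
    """Run cross-validation independently within each participant stratum."""
    if not dataset.participants:
        raise ValueError("dataset carries no participant metadata")
    sample = next(iter(dataset.participants.values()))
    if not hasattr(sample, by):
        raise ValueError(f"unknown participant field {by!r}")

    strata: dict[str, FatigueDataset] = {}
    for register in dataset.registers:
        participant = dataset.participants[register.participant_id]
        key = str(getattr(participant, by))
        sub = strata.setdefault(
            key, FatigueDataset(feature_names=dataset.feature_names)
        )
        sub.registers.append(register)
        sub.participants[participant.id] = participant
    return {
        key: cross_validate(sub, spec, k=k, seed=seed)
        for key, sub in sorted(strata.items())
    }
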