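"""Leave-one-out cross-validation, accuracy and ROC/AUC reporting.

Every fold refits the whole pipeline — gene filter, discretization cuts,
interval filtering, mining and pruning — on the remaining samples, so the
held-out sample never influences what is learned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn import metrics

from .data import ExpressionMatrix, ValidationError
from .pipeline import BinaryModel, RunConfig, fit

__all__ = ["EvaluationReport", "loocv", "compare_to_baseline", "fit_fold"]

log = logging.getLogger("ivclass")


@dataclass
class EvaluationReport:
    sample_ids: list[str]
    true_labels: list[str]
    predicted_labels: list[str]
    decision_statistics: list[float] | None  # binary problems only
    accuracy: float
    positive_class: str | None = None
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(self.true_labels) != n or len(self.predicted_labels) != n:
            raise ValidationError("report fields differ in length")

    def to_rows(self) -> list[tuple]:
        stats = self.decision_statistics or [float("nan")] * len(self.sample_ids)
        return list(zip(self.sample_ids, self.true_labels, self.predicted_labels, stats))


def fit_fold(matrix: ExpressionMatrix, held_out: int, config: RunConfig):
    """Train on every sample except *held_out*; exposed for the
    no-leakage property tests."""
    train_idx = [i for i in range(matrix.n_samples) if i != held_out]
    return fit(matrix.subset_samples(train_idx), config)


def _roc(y_true: np.ndarray, stat: np.ndarray, positive: str) -> tuple[list, float]:
    y = (y_true == positive).astype(int)
    if y.min() == y.max():  # single class present; ROC undefined
        return [], float("nan")
    fpr, tpr, _ = metrics.roc_curve(y, stat)
    return list(zip(fpr.tolist(), tpr.tolist())), float(metrics.roc_auc_score(y, stat))


def loocv(matrix: ExpressionMatrix, config: RunConfig) -> EvaluationReport:
    """Full-pipeline leave-one-out cross-validation.

    Binary problems additionally report the per-sample decision statistic
    ``S(u, positive) - S(u, negative)`` with a threshold-sweep ROC curve
    and its trapezoidal AUC (ties rank-averaged).  The positive class
    defaults to the lexicographically last label.
    """
    classes = matrix.classes
    if len(classes) < 2:
        raise ValidationError("LOOCV requires at least 2 classes")
    counts = matrix.class_counts()
    small = [c for c in classes if counts[c] < 3]
    if small:
        raise ValidationError(f"every class needs >= 3 samples for LOOCV, too few in {small}")

    binary = len(classes) == 2
    positive = None
    if binary:
        positive = config.positive_class or classes[-1]
        if positive not in classes:
            raise ValidationError(f"unknown positive class {positive!r}")

    preds: list[str] = []
    stats: list[float] = []
    for j in range(matrix.n_samples):
        model = fit_fold(matrix, j, config)
        test = matrix.subset_samples([j])
        pred, _ = model.predict_matrix(test)
        preds.append(str(pred[0]))
        if binary:
            assert isinstance(model, BinaryModel)
            stats.append(float(model.decision_statistic(test, positive)[0]))
        if (j + 1) % 25 == 0:
            log.info("loocv: %d/%d folds done", j + 1, matrix.n_samples)

    y_true = matrix.label_array()
    accuracy = float((np.array(preds, dtype=object) == y_true).mean())
    roc_points: list[tuple[float, float]] = []
    auc = None
    if binary:
        roc_points, auc = _roc(y_true, np.array(stats), positive)
    return EvaluationReport(
        sample_ids=list(matrix.sample_ids),
        true_labels=[str(v) for v in y_true],
        predicted_labels=preds,
        decision_statistics=stats if binary else None,
        accuracy=accuracy,
        positive_class=positive,
        roc_points=roc_points,
        auc=auc,
    )


def compare_to_baseline(
    matrix: ExpressionMatrix,
    config: RunConfig,
    baseline_discretizer: str = "ternary",
) -> tuple[EvaluationReport, EvaluationReport]:
    """LOOCV under the primary configuration and under the same
    configuration with the baseline discretizer (interval-superiority
    experiment); returns (primary, baseline) reports."""
    primary = loocv(matrix, config)
    baseline = loocv(matrix, replace(config, discretizer=baseline_discretizer))
    return primary, baseline
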