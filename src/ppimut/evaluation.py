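"""Leave-one-out evaluation and classification metrics.

For each class i of a problem, recall, precision and the f-measure

    f_i = 2 * recall_i * precision_i / (recall_i + precision_i)

are computed from the held-out confusion matrix.  Two aggregates summarize
a classifier on a problem:

    f_W  = sum_i N_i * f_i / sum_i N_i        (class-size-weighted f)
    Acc  = sum_i NC_i   / sum_i N_i           (overall fraction correct)

with N_i the class size and NC_i the number of correctly identified class
members.  The Matthews correlation coefficient uses the multi-category
covariance-based generalization, which reduces to the familiar 2x2 formula
for binary problems.  Rank agreement between predicted scores and
experimental affinity changes is measured with the Pearson correlation and
the tie-corrected Kendall tau-b.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import (
    LearnerConfig,
    ProblemSpec,
    TrainedModel,
    predict,
    project_labels,
    train,
    train_binary_models,
)
from .features import FeatureTable

logger = logging.getLogger(__name__)


class MetricError(ValueError):
    """A metric's preconditions are violated."""


@dataclass
class ConfusionMatrix:
    """Integer count matrix; rows are true classes, columns predictions."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise MetricError(f"count matrix must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise MetricError("counts must be non-negative")

    @classmethod
    def from_predictions(
        cls, true: Sequence[str], predicted: Sequence[str], classes: Sequence[str]
    ) -> "ConfusionMatrix":
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(true, predicted, strict=True):
            counts[index[t], index[p]] += 1
        return cls(tuple(classes), counts)

    @property
    def class_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def recalls(self) -> np.ndarray:
        sizes = self.class_sizes
        with np.errstate(invalid="ignore"):
            r = np.where(sizes > 0, np.diag(self.counts) / np.maximum(sizes, 1), 0.0)
        return r

    def precisions(self) -> np.ndarray:
        pred_sizes = self.counts.sum(axis=0)
        return np.where(pred_sizes > 0, np.diag(self.counts) / np.maximum(pred_sizes, 1), 0.0)

    def f_measures(self) -> np.ndarray:
        return np.array(
            [f_measure(r, p) for r, p in zip(self.recalls(), self.precisions())]
        )


def f_measure(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision; 0 when both vanish."""
    if recall + precision == 0:
        return 0.0
    return 2.0 * recall * precision / (recall + precision)


def weighted_f(per_class_f: Sequence[float], class_sizes: Sequence[float]) -> float:
    """Class-size-weighted mean of per-class f-measures."""
    f = np.asarray(per_class_f, dtype=float)
    n = np.asarray(class_sizes, dtype=float)
    if f.shape != n.shape:
        raise MetricError("per-class f and sizes must align")
    if (n < 0).any() or n.sum() <= 0:
        raise MetricError("class sizes must be non-negative with positive total")
    return float((f * n).sum() / n.sum())


def average_accuracy(per_class_recall: Sequence[float], class_sizes: Sequence[float]) -> float:
    """Overall fraction correct: sum_i recall_i * N_i / sum_i N_i."""
    r = np.asarray(per_class_recall, dtype=float)
    n = np.asarray(class_sizes, dtype=float)
    if r.shape != n.shape:
        raise MetricError("recalls and sizes must align")
    if (n < 0).any() or n.sum() <= 0:
        raise MetricError("class sizes must be non-negative with positive total")
    return float((r * n).sum() / n.sum())


def mcc(matrix: ConfusionMatrix) -> float:
    """Matthews correlation coefficient, multi-category generalization.

    cov(t, p) / sqrt(cov(t, t) * cov(p, p)) written in terms of the
    confusion matrix C: (c*s - sum_k t_k*p_k) / sqrt((s^2 - sum_k p_k^2) *
    (s^2 - sum_k t_k^2)) with c the trace, s the total, t_k row sums and
    p_k column sums.  A degenerate denominator yields 0 by convention.
    """
    C = matrix.counts.astype(float)
    s = C.sum()
    if s <= 0:
        raise MetricError("confusion matrix is empty")
    c = np.trace(C)
    t = C.sum(axis=1)
    p = C.sum(axis=0)
    num = c * s - (t * p).sum()
    den = math.sqrt((s**2 - (p**2).sum()) * (s**2 - (t**2).sum()))
    if den == 0:
        return 0.0
    return float(num / den)


def relative_gain(before: float, after: float) -> float:
    """Percent change from a positive baseline: 100*(after-before)/before."""
    if before <= 0:
        raise MetricError(f"baseline must be positive, got {before}")
    return 100.0 * (after - before) / before


def pearson_score_vs_ddg(
    preserving_scores: Sequence[float], ddg_values: Sequence[float]
) -> float:
    """Pearson correlation between preserving-class scores and measured ddG."""
    x = np.asarray(preserving_scores, dtype=float)
    y = np.asarray(ddg_values, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise MetricError("need two aligned vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise MetricError("zero variance on one side")
    return float(stats.pearsonr(x, y).statistic)


def kendall_tau(predicted_scores: Sequence[float], experimental: Sequence[float]) -> float:
    """Tie-corrected Kendall tau-b between score and experimental rankings."""
    x = np.asarray(predicted_scores, dtype=float)
    y = np.asarray(experimental, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise MetricError("need two aligned vectors of length >= 2")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise MetricError("all-tied input has no defined rank correlation")
    return float(stats.kendalltau(x, y, variant="b").statistic)


@dataclass
class EvaluationReport:
    """Per-class and aggregate metrics for one classifier on one problem."""

    confusion: ConfusionMatrix
    recall: dict[str, float]
    precision: dict[str, float]
    f_measure: dict[str, float]
    weighted_f: float
    average_accuracy: float
    mcc: float
    pearson_r: float | None = None
    kendall_tau: float | None = None
    n_folds: int = 0
    config: dict = field(default_factory=dict)

    @classmethod
    def from_confusion(cls, matrix: ConfusionMatrix, **kwargs) -> "EvaluationReport":
        classes = matrix.classes
        recalls = matrix.recalls()
        precisions = matrix.precisions()
        fs = matrix.f_measures()
        sizes = matrix.class_sizes
        return cls(
            confusion=matrix,
            recall=dict(zip(classes, map(float, recalls))),
            precision=dict(zip(classes, map(float, precisions))),
            f_measure=dict(zip(classes, map(float, fs))),
            weighted_f=weighted_f(fs, sizes),
            average_accuracy=average_accuracy(recalls, sizes),
            mcc=mcc(matrix),
            **kwargs,
        )

    def to_dict(self) -> dict:
        return {
            "classes": list(self.confusion.classes),
            "confusion": self.confusion.counts.tolist(),
            "recall": self.recall,
            "precision": self.precision,
            "f_measure": self.f_measure,
            "weighted_f": self.weighted_f,
            "average_accuracy": self.average_accuracy,
            "mcc": self.mcc,
            "pearson_r": self.pearson_r,
            "kendall_tau": self.kendall_tau,
            "n_folds": self.n_folds,
            "config": self.config,
        }


Trainer = Callable[[FeatureTable, FeatureTable | None, ProblemSpec, LearnerConfig], TrainedModel]


class FoldTrainingError(RuntimeError):
    def __init__(self, fold: int, cause: Exception):
        self.fold = fold
        super().__init__(f"training failed in fold {fold}: {cause}")


def loo_cv(
    table: FeatureTable,
    problem: ProblemSpec,
    config: LearnerConfig,
    unlabeled: FeatureTable | None = None,
    trainer: Trainer | None = None,
    stacking_leaky: bool = False,
) -> tuple[EvaluationReport, pd.DataFrame]:
    """Leave-one-out cross-validation of one learner on one problem.

    Each fold trains on all labeled rows but one (the fixed unlabeled set,
    if any, is reused in every fold) and predicts the held-out row; the
    confusion matrix aggregates all held-out predictions.  For the stacked
    3-class learner the two binary feature-generating models are refit
    inside every fold without the held-out example; ``stacking_leaky=True``
    instead fits them once on the full labeled set (documented shortcut
    that risks optimistic results).

    Returns the report and a per-example frame (id, fold, true label,
    predicted label, per-class scores).
    """
    table = project_labels(table, problem)
    y = table.labels.astype(str).to_numpy()
    for c in problem.classes:
        if (y == c).sum() < 2:
            raise MetricError(f"need >= 2 examples of class {c!r} for LOO")
    n = len(table)

    leaky_binaries = None
    if config.kind == "rf_sl_2f" and stacking_leaky:
        leaky_binaries = train_binary_models(table, config, unlabeled)

    def default_trainer(fold_table, fold_unlabeled, fold_problem, fold_config):
        return train(fold_table, fold_problem, fold_config, unlabeled=fold_unlabeled,
                     binary_models=leaky_binaries)

    fit = trainer if trainer is not None else default_trainer

    rows = []
    true_labels, pred_labels = [], []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fold_table = table.select(mask)
        try:
            model = fit(fold_table, unlabeled, problem, config)
            result = predict(model, table.select(~mask))[0]
        except Exception as exc:  # abort with the fold id, per contract
            raise FoldTrainingError(i, exc) from exc
        true_labels.append(y[i])
        pred_labels.append(result.predicted_class)
        row = {"id": result.example_id, "fold": i, "true_label": y[i],
               "predicted_label": result.predicted_class}
        row.update({f"score_{c}": s for c, s in result.scores.items()})
        rows.append(row)

    matrix = ConfusionMatrix.from_predictions(true_labels, pred_labels, problem.classes)
    report = EvaluationReport.from_confusion(
        matrix,
        n_folds=n,
        config={"kind": config.kind, "seed": config.seed, "problem": problem.problem_id,
                "stacking_leaky": stacking_leaky},
    )
    frame = pd.DataFrame(rows)

    # rank agreement against latent/experimental ddG, when the table has it
    if table.ddg is not None and problem.positive_class is not None:
        score_col = f"score_{problem.positive_class}"
        scores = frame[score_col].to_numpy()
        ddg_vals = table.ddg.to_numpy(dtype=float)
        try:
            report.pearson_r = pearson_score_vs_ddg(scores, ddg_vals)
            report.kendall_tau = kendall_tau(scores, ddg_vals)
        except MetricError:
            logger.info("degenerate score/ddG vectors; correlation omitted")
    return report, frame
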