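"""Learners for the three interaction-effect classification problems.

Four families are provided:

* supervised random forest and SVM (linear / polynomial / RBF kernels);
* a self-learning random forest: a supervised forest pseudo-labels every
  unlabeled mutation, the pseudo-labeled set is merged with the labeled
  one, and the forest is refit once on the union;
* a low-density-separation (LDS) classifier: a k-nearest-neighbor graph is
  built over labeled and unlabeled points, a soft path metric

      d_rho(i, j) = (1/rho) * ln(1 + min over paths p of
                                  sum over edges e in p of (exp(rho*|e|) - 1))

  emphasizes low-density regions between clusters (shortest-path distance
  as rho -> 0, bottleneck-edge distance as rho -> inf), the squared
  distances are double-centered into a kernel whose negative eigenvalues
  are clipped to zero, and a maximum-margin classifier is fit on the
  labeled block of the resulting embedding;
* a stacked 3-class forest whose feature vector is augmented with the two
  binary classifiers' scaled prediction scores (33 + 2 features).

All learners are deterministic given their configuration seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra, shortest_path
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import kneighbors_graph
from sklearn.svm import SVC

from .affinity import (
    BENEFICIAL,
    DETRIMENTAL,
    DISRUPTIVE,
    NEUTRAL,
    PRESERVING,
    PROBLEM1_MAP,
    PROBLEM2_MAP,
    STRENGTHENING,
    WEAKENING,
)
from .features import FEATURE_NAMES, FeatureTable, SchemaError

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


class ConfigurationError(ValueError):
    """A learner configuration or training set violates its contract."""


class DisconnectedGraphError(RuntimeError):
    """The k-NN graph splits into several components."""

    def __init__(self, labels: np.ndarray):
        self.component_labels = labels
        n = labels.max() + 1
        sizes = np.bincount(labels)
        super().__init__(
            f"k-NN graph has {n} connected components (sizes {sizes.tolist()}); "
            "increase the neighbor count"
        )


@dataclass(frozen=True)
class ProblemSpec:
    """One of the three classification problems."""

    problem_id: int
    classes: tuple[str, ...]
    positive_class: str | None = None

    def __post_init__(self) -> None:
        if self.problem_id in (1, 2) and len(self.classes) != 2:
            raise ConfigurationError("binary problems need exactly 2 classes")
        if self.problem_id == 3 and len(self.classes) != 3:
            raise ConfigurationError("the 3-class problem needs exactly 3 classes")
        if self.positive_class is not None and self.positive_class not in self.classes:
            raise ConfigurationError("positive class must be one of the problem's classes")


PROBLEM_1 = ProblemSpec(1, (STRENGTHENING, WEAKENING), STRENGTHENING)
PROBLEM_2 = ProblemSpec(2, (PRESERVING, DISRUPTIVE), PRESERVING)
PROBLEM_3 = ProblemSpec(3, (BENEFICIAL, NEUTRAL, DETRIMENTAL))


def problem_spec(problem_id: int) -> ProblemSpec:
    try:
        return {1: PROBLEM_1, 2: PROBLEM_2, 3: PROBLEM_3}[problem_id]
    except KeyError:
        raise ConfigurationError(f"problem id must be 1, 2 or 3, got {problem_id}") from None


@dataclass(frozen=True)
class LearnerConfig:
    """Hyperparameters for one learner; every field has a working default.

    ``kind`` selects the family: ``rf``, ``svm``, ``rf_sl`` (self-learning
    forest), ``lds``, or ``rf_sl_2f`` (stacked 3-class forest).
    """

    kind: str = "rf"
    seed: int = 0
    # random forest
    n_trees: int = 100
    max_features: str | int | float = "sqrt"
    # SVM
    kernel: str = "poly"
    degree: int = 3
    gamma: str | float = "scale"
    C: float = 1.0
    # LDS
    k_neighbors: int = 5
    rho: float = 1.0
    spectral_correction: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("rf", "svm", "rf_sl", "lds", "rf_sl_2f"):
            raise ConfigurationError(f"unknown learner kind {self.kind!r}")
        if self.n_trees < 1:
            raise ConfigurationError("need at least one tree")
        if self.degree < 1:
            raise ConfigurationError("polynomial degree must be >= 1")
        if self.k_neighbors < 1:
            raise ConfigurationError("neighbor count must be >= 1")
        if self.rho <= 0:
            raise ConfigurationError("rho must be positive")
        if self.kernel not in ("linear", "poly", "rbf"):
            raise ConfigurationError(f"unsupported SVM kernel {self.kernel!r}")


@dataclass(frozen=True)
class PredictionResult:
    """One classified example with its per-class score vector."""

    example_id: str
    predicted_class: str
    scores: dict[str, float]


@dataclass
class TrainedModel:
    """A fitted classifier bound to its problem and configuration."""

    problem: ProblemSpec
    config: LearnerConfig
    class_order: tuple[str, ...]
    input_names: tuple[str, ...]
    training_summary: dict
    _impl: object = field(repr=False, default=None)


# --- label projection -------------------------------------------------------


def project_labels(table: FeatureTable, problem: ProblemSpec) -> FeatureTable:
    """Map 3-class labels onto a problem's classes, dropping out-of-scope rows.

    For problem 1 neutral mutations are excluded; for problem 2 beneficial
    and neutral collapse into the preserving class.  Tables already labeled
    in the target problem's classes pass through unchanged.
    """
    labels = table.labels
    if labels is None:
        raise ConfigurationError("cannot project an unlabeled table")
    values = labels.astype(str)
    if set(values.unique()) <= set(problem.classes):
        return table
    mapping = {1: PROBLEM1_MAP, 2: PROBLEM2_MAP, 3: None}[problem.problem_id]
    if mapping is None:
        return table
    keep = values.isin(mapping).to_numpy()
    frame = table.frame.loc[keep].copy().reset_index(drop=True)
    frame["label"] = values[keep].map(mapping).to_numpy()
    return FeatureTable(frame)


def _check_labels(table: FeatureTable, problem: ProblemSpec) -> np.ndarray:
    labels = table.labels
    if labels is None:
        raise ConfigurationError("training table carries no labels")
    y = labels.astype(str).to_numpy()
    unknown = set(y) - set(problem.classes)
    if unknown:
        raise ConfigurationError(f"labels {sorted(unknown)} not in problem classes")
    missing = [c for c in problem.classes if c not in set(y)]
    if missing:
        raise ConfigurationError(f"class(es) absent from training data: {missing}")
    return y


# --- implementation backends ------------------------------------------------


def _normalize_rows(S: np.ndarray) -> np.ndarray:
    S = np.clip(S, 0.0, None)
    sums = S.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return S / sums


class _ForestImpl:
    def __init__(self, forest: RandomForestClassifier, names: tuple[str, ...],
                 class_order: tuple[str, ...]):
        self.forest = forest
        self.names = names
        self.class_order = class_order

    def _matrix(self, table: FeatureTable) -> np.ndarray:
        return table.frame[list(self.names)].to_numpy(dtype=float)

    def scores(self, table: FeatureTable) -> np.ndarray:
        proba = self.forest.predict_proba(self._matrix(table))
        cols = {c: i for i, c in enumerate(self.forest.classes_)}
        out = np.zeros((proba.shape[0], len(self.class_order)))
        for i, c in enumerate(self.class_order):
            if c in cols:
                out[:, i] = proba[:, cols[c]]
        return _normalize_rows(out)


class _SvmImpl:
    def __init__(self, mean, std, svc: SVC, names, class_order):
        self.mean, self.std = mean, std
        self.svc = svc
        self.names = names
        self.class_order = class_order

    def scores(self, table: FeatureTable) -> np.ndarray:
        X = (table.frame[list(self.names)].to_numpy(dtype=float) - self.mean) / self.std
        return _decision_to_scores(self.svc, X, self.class_order)


def _decision_to_scores(svc: SVC, X: np.ndarray, class_order: tuple[str, ...]) -> np.ndarray:
    """Deterministic score calibration from SVM decision values.

    Binary: logistic squashing of the signed margin.  Multi-class: softmax
    over one-vs-rest decision values.  Scores sum to one per row.
    """
    dec = svc.decision_function(X)
    classes = list(svc.classes_)
    if dec.ndim == 1:  # binary; positive margin favors classes_[1]
        p1 = 1.0 / (1.0 + np.exp(-dec))
        by_class = {classes[0]: 1.0 - p1, classes[1]: p1}
    else:
        z = dec - dec.max(axis=1, keepdims=True)
        soft = np.exp(z)
        soft /= soft.sum(axis=1, keepdims=True)
        by_class = {c: soft[:, i] for i, c in enumerate(classes)}
    out = np.column_stack([by_class[c] for c in class_order])
    return _normalize_rows(out)


class _StackedImpl:
    def __init__(self, binary_models: tuple[TrainedModel, TrainedModel],
                 forest_impl: _ForestImpl, base_names: tuple[str, ...]):
        self.binary_models = binary_models
        self.forest_impl = forest_impl
        self.names = base_names  # what callers must supply

    def scores(self, table: FeatureTable) -> np.ndarray:
        aug = augment_with_stacked_features(table, self.binary_models)
        return self.forest_impl.scores(aug)


class _LdsImpl:
    """Transductive LDS state plus a Nystroem out-of-sample extension."""

    def __init__(self, mean, std, points, ids, k_eff, rho, eigvecs, eigvals,
                 embedding, sq_col_means, sq_grand_mean, svc, names, class_order):
        self.mean, self.std = mean, std
        self.points = points            # standardized graph nodes
        self.id_index = {i: j for j, i in enumerate(ids)}
        self.k_eff = k_eff
        self.rho = rho
        self.eigvecs = eigvecs          # n x m, clipped-positive components
        self.eigvals = eigvals          # m
        self.embedding = embedding      # n x m
        self.sq_col_means = sq_col_means
        self.sq_grand_mean = sq_grand_mean
        self.svc = svc
        self.names = names
        self.class_order = class_order

    def _embed_new(self, x: np.ndarray) -> np.ndarray:
        """Embed one standardized point by grafting it onto the graph."""
        d_new = _rho_path_from_new_point(self.points, x, self.k_eff, self.rho)
        sq = d_new ** 2
        k_vec = -0.5 * (sq - sq.mean() - self.sq_col_means + self.sq_grand_mean)
        return (self.eigvecs.T @ k_vec) / np.sqrt(self.eigvals)

    def scores(self, table: FeatureTable) -> np.ndarray:
        X = (table.frame[list(self.names)].to_numpy(dtype=float) - self.mean) / self.std
        emb = np.empty((len(X), self.embedding.shape[1]))
        for r, ex_id in enumerate(table.ids):
            j = self.id_index.get(ex_id)
            emb[r] = self.embedding[j] if j is not None else self._embed_new(X[r])
        return _decision_to_scores(self.svc, emb, self.class_order)


# --- supervised learners ----------------------------------------------------


def _fit_forest(X: np.ndarray, y: np.ndarray, config: LearnerConfig) -> RandomForestClassifier:
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        random_state=config.seed,
    )
    forest.fit(X, y)
    return forest


def train_supervised(
    table: FeatureTable, problem: ProblemSpec, config: LearnerConfig
) -> TrainedModel:
    """Fit a supervised forest or SVM on a labeled feature table."""
    if config.kind not in ("rf", "svm"):
        raise ConfigurationError(f"train_supervised expects kind rf|svm, got {config.kind!r}")
    y = _check_labels(table, problem)
    names = _input_names(table)
    X = table.frame[list(names)].to_numpy(dtype=float)
    summary = {"labeled_size": len(table), "unlabeled_size": 0}
    if config.kind == "rf":
        impl = _ForestImpl(_fit_forest(X, y, config), names, problem.classes)
    else:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0  # constant columns tolerated
        svc = SVC(
            kernel=config.kernel,
            degree=config.degree,
            gamma=config.gamma,
            C=config.C,
            decision_function_shape="ovr",
            random_state=config.seed,
        )
        svc.fit((X - mean) / std, y)
        impl = _SvmImpl(mean, std, svc, names, problem.classes)
    return TrainedModel(problem, config, problem.classes, names, summary, impl)


def _input_names(table: FeatureTable) -> tuple[str, ...]:
    """Feature columns of a (possibly augmented) table, schema first."""
    extra = [
        c
        for c in table.frame.columns
        if c not in ("id", "label", "ddg") and c not in FEATURE_NAMES
    ]
    return tuple(FEATURE_NAMES) + tuple(extra)


# --- self-learning random forest -------------------------------------------


def train_self_learning_rf(
    labeled: FeatureTable,
    unlabeled: FeatureTable | None,
    problem: ProblemSpec,
    config: LearnerConfig,
) -> TrainedModel:
    """One round of forest self-learning.

    Protocol: fit a supervised forest on the labeled set; let it assign a
    class to every unlabeled mutation; merge the pseudo-labeled rows with
    the labeled ones at equal weight; refit the forest once on the union.
    With no unlabeled data this degenerates to the plain supervised forest.
    """
    if len(labeled) == 0:
        raise ConfigurationError("self-learning requires a labeled set")
    y = _check_labels(labeled, problem)
    names = _input_names(labeled)
    X_lab = labeled.frame[list(names)].to_numpy(dtype=float)
    summary = {
        "labeled_size": len(labeled),
        "unlabeled_size": 0 if unlabeled is None else len(unlabeled),
        "pseudo_label_counts": {},
    }
    if unlabeled is None or len(unlabeled) == 0:
        forest = _fit_forest(X_lab, y, config)
        return TrainedModel(problem, config, problem.classes, names, summary,
                            _ForestImpl(forest, names, problem.classes))
    if unlabeled.labels is not None:
        raise ConfigurationError("the unlabeled table must not carry labels")
    missing = [n for n in names if n not in unlabeled.frame.columns]
    if missing:
        raise SchemaError(f"unlabeled table missing feature columns: {missing}")
    base = _fit_forest(X_lab, y, config)
    X_unl = unlabeled.frame[list(names)].to_numpy(dtype=float)
    pseudo = base.predict(X_unl)
    counts = {c: int((pseudo == c).sum()) for c in problem.classes}
    summary["pseudo_label_counts"] = counts
    X_merged = np.vstack([X_lab, X_unl])
    y_merged = np.concatenate([y, pseudo])
    final = _fit_forest(X_merged, y_merged, config)
    return TrainedModel(problem, config, problem.classes, names, summary,
                        _ForestImpl(final, names, problem.classes))


# --- rho-path distances and the LDS classifier ------------------------------


def _knn_graph(points: np.ndarray, k: int) -> csr_matrix:
    k = min(k, len(points) - 1)
    W = kneighbors_graph(points, n_neighbors=k, mode="distance", include_self=False)
    return W.maximum(W.T)  # symmetrize


def _softened(W: csr_matrix, rho: float) -> csr_matrix:
    Wt = W.copy()
    Wt.data = np.expm1(rho * Wt.data)
    return Wt


def rho_path_distance(points: Sequence[Sequence[float]], k: int, rho: float) -> np.ndarray:
    """Soft connectivity distance matrix on the symmetrized k-NN graph.

    d_rho(i,j) = (1/rho) ln(1 + min over paths of sum(exp(rho*|e|) - 1)).
    Because the per-edge transform exp(rho*|e|) - 1 is positive, the inner
    minimum is an ordinary shortest-path problem on transformed weights.
    As rho -> 0 the metric approaches Euclidean shortest-path distance; as
    rho -> inf it approaches the bottleneck (minimax-edge) path length.
    """
    if rho <= 0:
        raise ConfigurationError("rho must be positive")
    if k < 1:
        raise ConfigurationError("neighbor count must be >= 1")
    points = np.asarray(points, dtype=float)
    W = _knn_graph(points, k)
    n_comp, labels = connected_components(W, directed=False)
    if n_comp > 1:
        raise DisconnectedGraphError(labels)
    sp = shortest_path(_softened(W, rho), method="D", directed=False)
    D = np.log1p(sp) / rho
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0  # exact symmetry despite float noise


def _rho_path_from_new_point(points: np.ndarray, x: np.ndarray, k: int, rho: float) -> np.ndarray:
    """rho-path distances from a new point grafted onto an existing graph."""
    n = len(points)
    W = _knn_graph(points, k)
    Wt = _softened(W, rho).tolil()
    Wt.resize((n + 1, n + 1))
    d_euclid = np.linalg.norm(points - x, axis=1)
    nearest = np.argsort(d_euclid)[: min(k, n)]
    for j in nearest:
        w = np.expm1(rho * d_euclid[j])
        Wt[n, j] = Wt[j, n] = max(w, 1e-300)
    sp = dijkstra(Wt.tocsr(), directed=False, indices=n)[:n]
    return np.log1p(sp) / rho


def _center_and_clip(D: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Classical-scaling kernel from squared distances, clipped to PSD."""
    sq = D ** 2
    n = len(D)
    col_means = sq.mean(axis=0)
    grand = sq.mean()
    B = -0.5 * (sq - col_means[None, :] - col_means[:, None] + grand)
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    keep = eigvals > max(1e-10, 1e-12 * eigvals.max())
    return eigvecs[:, keep], eigvals[keep], col_means, grand


def train_lds(
    labeled: FeatureTable,
    unlabeled: FeatureTable | None,
    problem: ProblemSpec,
    config: LearnerConfig,
) -> TrainedModel:
    """Fit the low-density-separation classifier.

    A k-NN graph over labeled plus unlabeled points yields rho-path
    distances; classical scaling of the squared distances with negative
    eigenvalues clipped to zero gives a positive-semidefinite connectivity
    kernel, on whose labeled block a maximum-margin classifier is trained.
    If the graph is disconnected at the configured k, k is raised to the
    smallest value restoring connectivity (logged).
    """
    if config.kind != "lds":
        raise ConfigurationError(f"train_lds expects kind 'lds', got {config.kind!r}")
    y = _check_labels(labeled, problem)
    if unlabeled is not None and unlabeled.labels is not None:
        raise ConfigurationError("the unlabeled table must not carry labels")
    names = _input_names(labeled)
    X_lab = labeled.frame[list(names)].to_numpy(dtype=float)
    ids = list(labeled.ids)
    if unlabeled is not None and len(unlabeled):
        X_all = np.vstack([X_lab, unlabeled.frame[list(names)].to_numpy(dtype=float)])
        ids += list(unlabeled.ids)
    else:
        X_all = X_lab
    mean = X_all.mean(axis=0)
    std = X_all.std(axis=0)
    std[std == 0] = 1.0
    Z = (X_all - mean) / std

    k = config.k_neighbors
    while True:
        try:
            D = rho_path_distance(Z, k, config.rho)
            break
        except DisconnectedGraphError:
            if k >= len(Z) - 1:
                raise
            k += 1
    if k != config.k_neighbors:
        logger.info("k-NN graph disconnected at k=%d; raised to k=%d", config.k_neighbors, k)

    eigvecs, eigvals, col_means, grand = _center_and_clip(D)
    embedding = eigvecs * np.sqrt(eigvals)
    svc = SVC(kernel="linear", C=config.C, decision_function_shape="ovr",
              random_state=config.seed)
    svc.fit(embedding[: len(labeled)], y)
    summary = {
        "labeled_size": len(labeled),
        "unlabeled_size": len(Z) - len(labeled),
        "k_effective": k,
        "n_components": int(embedding.shape[1]),
    }
    impl = _LdsImpl(mean, std, Z, ids, k, config.rho, eigvecs, eigvals,
                    embedding, col_means, grand, svc, names, problem.classes)
    return TrainedModel(problem, config, problem.classes, names, summary, impl)


# --- stacking ---------------------------------------------------------------


def stacked_feature(binary_model: TrainedModel, table: FeatureTable) -> np.ndarray:
    """Scaled prediction value of a binary classifier, one per row in [0,1].

    The value is the classifier's prediction score when the prediction is
    positive, and one minus the prediction score when it is negative, so
    that larger values always favor the designated positive class.
    """
    if len(binary_model.class_order) != 2 or binary_model.problem.positive_class is None:
        raise ConfigurationError("stacked_feature requires a binary model with a positive class")
    results = predict(binary_model, table)
    pos = binary_model.problem.positive_class
    out = np.empty(len(results))
    for i, r in enumerate(results):
        if r.predicted_class == pos:
            out[i] = r.scores[pos]
        else:
            out[i] = 1.0 - r.scores[r.predicted_class]
    return out


STACKED_COLUMNS = ("problem1 score", "problem2 score")


def augment_with_stacked_features(
    table: FeatureTable, binary_models: tuple[TrainedModel, TrainedModel]
) -> FeatureTable:
    """Append the two binary classifiers' scaled scores as extra features."""
    frame = table.frame.copy()
    for col, model in zip(STACKED_COLUMNS, binary_models):
        frame[col] = stacked_feature(model, table)
    return FeatureTable(frame)


def train_stacked_3class(
    labeled: FeatureTable,
    unlabeled: FeatureTable | None,
    problem3: ProblemSpec,
    binary_models: tuple[TrainedModel, TrainedModel],
    config: LearnerConfig,
) -> TrainedModel:
    """Self-learning forest on the 33+2 augmented feature vector.

    The two extra features are the scaled prediction scores of the binary
    strengthening/weakening and preserving/disruptive classifiers.
    """
    if problem3.problem_id != 3:
        raise ConfigurationError("stacking targets the 3-class problem")
    aug_labeled = augment_with_stacked_features(labeled, binary_models)
    aug_unlabeled = (
        augment_with_stacked_features(unlabeled, binary_models)
        if unlabeled is not None and len(unlabeled)
        else None
    )
    inner = train_self_learning_rf(aug_labeled, aug_unlabeled, problem3, config)
    impl = _StackedImpl(binary_models, inner._impl, tuple(FEATURE_NAMES))
    summary = dict(inner.training_summary)
    summary["stacked_feature_names"] = list(STACKED_COLUMNS)
    return TrainedModel(problem3, config, problem3.classes, tuple(FEATURE_NAMES),
                        summary, impl)


def train(
    labeled: FeatureTable,
    problem: ProblemSpec,
    config: LearnerConfig,
    unlabeled: FeatureTable | None = None,
    binary_models: tuple[TrainedModel, TrainedModel] | None = None,
) -> TrainedModel:
    """Dispatch to the learner family named by ``config.kind``.

    For the stacked 3-class learner, binary models are built from the same
    labeled table (projected onto problems 1 and 2 and trained with the
    self-learning forest) unless prebuilt models are passed in.
    """
    labeled = project_labels(labeled, problem)
    if config.kind in ("rf", "svm"):
        return train_supervised(labeled, problem, config)
    if config.kind == "rf_sl":
        return train_self_learning_rf(labeled, unlabeled, problem, config)
    if config.kind == "lds":
        return train_lds(labeled, unlabeled, problem, config)
    # rf_sl_2f
    if binary_models is None:
        binary_models = train_binary_models(labeled, config, unlabeled)
    return train_stacked_3class(labeled, unlabeled, problem, binary_models, config)


def train_binary_models(
    labeled3: FeatureTable,
    config: LearnerConfig,
    unlabeled: FeatureTable | None = None,
) -> tuple[TrainedModel, TrainedModel]:
    """Self-learning binary forests for problems 1 and 2 from 3-class data."""
    models = []
    for offset, problem in ((1, PROBLEM_1), (2, PROBLEM_2)):
        sub_config = replace(config, kind="rf_sl", seed=(config.seed + offset) % (2**31))
        table = project_labels(labeled3, problem)
        models.append(train_self_learning_rf(table, unlabeled, problem, sub_config))
    return tuple(models)


# --- prediction -------------------------------------------------------------


def predict(model: TrainedModel, table: FeatureTable) -> list[PredictionResult]:
    """Classify every row of a feature table.

    Scores are non-negative and sum to one per row; the predicted class is
    the argmax with ties broken by the problem's class order.
    """
    required = [n for n in model.input_names if n not in STACKED_COLUMNS]
    missing = [n for n in required if n not in table.frame.columns]
    if missing:
        raise SchemaError(f"prediction table missing feature columns: {missing}")
    S = model._impl.scores(table)
    results = []
    for ex_id, row in zip(table.ids, S):
        idx = int(np.argmax(row))  # first max -> class-order tie-break
        results.append(
            PredictionResult(
                example_id=ex_id,
                predicted_class=model.class_order[idx],
                scores={c: float(v) for c, v in zip(model.class_order, row)},
            )
        )
    return results


def predictions_frame(results: Sequence[PredictionResult]) -> pd.DataFrame:
    """Tabulate predictions: id, predicted_label, one score column per class."""
    rows = []
    for r in results:
        row = {"id": r.example_id, "predicted_label": r.predicted_class}
        row.update({f"score_{c}": s for c, s in r.scores.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# --- serialization ----------------------------------------------------------


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a model with a versioned metadata header."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "metadata": {
            "problem_id": model.problem.problem_id,
            "classes": list(model.class_order),
            "kind": model.config.kind,
            "seed": model.config.seed,
            "input_names": list(model.input_names),
        },
        "model": model,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ConfigurationError(
            f"model file format version {version} unsupported (expected {MODEL_FORMAT_VERSION})"
        )
    return payload["model"]
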