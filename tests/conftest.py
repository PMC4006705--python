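"""Shared fixtures: small synthetic datasets and minimal model stubs."""

from __future__ import annotations

import numpy as np
import pytest

from ppimut.classifiers import LearnerConfig, ProblemSpec, TrainedModel
from ppimut.features import FEATURE_NAMES, N_FEATURES, FeatureTable
from ppimut.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def separable_dataset():
    """Well-separated 3-class data with an unlabeled pool (linear regime)."""
    return generate(
        GeneratorConfig(n_mutations=120, separability=3.0, seed=11, unlabeled_multiplier=2)
    )


@pytest.fixture(scope="session")
def hard_dataset():
    """Moderate-difficulty 3-class data resembling the curated-set imbalance."""
    return generate(
        GeneratorConfig(n_mutations=150, separability=0.8, seed=13, unlabeled_multiplier=1)
    )


@pytest.fixture()
def two_blob_tables():
    """Two dense 33-dim clusters with one labeled point each."""
    rng = np.random.default_rng(0)
    n = 40
    X = rng.normal(0, 0.3, (2 * n, N_FEATURES))
    X[:n] -= 1.0
    X[n:] += 1.0
    ids = [f"p{i}" for i in range(2 * n)]
    labeled = FeatureTable.from_arrays([ids[0], ids[n]], X[[0, n]], labels=["left", "right"])
    rest = [i for i in range(2 * n) if i not in (0, n)]
    unlabeled = FeatureTable.from_arrays([ids[i] for i in rest], X[rest])
    membership = {ids[i]: ("left" if i < n else "right") for i in range(2 * n)}
    return labeled, unlabeled, membership


class FixedScoreImpl:
    """Model backend that returns a constant score vector for every row."""

    def __init__(self, scores: np.ndarray):
        self._scores = np.asarray(scores, dtype=float)

    def scores(self, table: FeatureTable) -> np.ndarray:
        return np.tile(self._scores, (len(table), 1))


def make_stub_model(problem: ProblemSpec, scores) -> TrainedModel:
    """A TrainedModel whose predictions are fully controlled by the test."""
    return TrainedModel(
        problem=problem,
        config=LearnerConfig(kind="rf", seed=0),
        class_order=problem.classes,
        input_names=tuple(FEATURE_NAMES),
        training_summary={},
        _impl=FixedScoreImpl(scores),
    )
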