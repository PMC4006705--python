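"""Synthetic affinity-mutagenesis data with known ground truth.

The generator emulates the structure of a curated mutagenesis compendium:
mutations grouped by complex, a latent binding free-energy change per
mutation drawn from a three-component mixture (one component per effect
class, truncated at the class thresholds so labels and ddG are exactly
consistent), feature vectors in the 33-term schema whose informativeness
about ddG is controlled, and a larger unlabeled pool whose latent truth is
retained on the side for testing semi-supervised learners.

Two feature regimes are provided: ``linear`` makes each informative
feature a noisy linear readout of the latent ddG (what self-learning
forests need), while ``cluster`` places class-specific Gaussian centroids
separated in proportion to the separability knob, creating the low-density
gaps that graph-based semi-supervised methods exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .affinity import (
    AMINO_ACIDS,
    LABELS,
    ThresholdConfig,
    assign_label,
)
from .classifiers import PredictionResult
from .features import FEATURE_NAMES, N_FEATURES, FeatureTable

#: Class proportions of the reference curated dataset (208/670/1076).
DEFAULT_PROPORTIONS = (208 / 1954, 670 / 1954, 1076 / 1954)

_EDGE_EPS = 1e-9


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic mutagenesis generator.

    ``separability`` scales the informative loadings (linear regime) or the
    class-centroid spacing (cluster regime); 0 means label-free noise.
    ``n_mutations``, when set, overrides the complex-count bookkeeping and
    fixes the labeled-set size exactly.
    """

    n_complexes: int = 30
    mutations_per_complex: tuple[int, int] = (3, 7)
    n_mutations: int | None = None
    class_proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS
    ddg_means: tuple[float, float, float] = (-1.5, 0.0, 2.0)
    ddg_sds: tuple[float, float, float] = (0.4, 0.2, 1.0)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    n_informative_features: int = 8
    noise_sd: float = 1.0
    separability: float = 1.0
    regime: str = "linear"
    unlabeled_multiplier: int = 2
    complex_intercept_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class proportions must be 3 non-negative reals summing to 1")
        if not 1 <= self.n_informative_features <= N_FEATURES:
            raise ValueError(f"informative feature count must be in [1, {N_FEATURES}]")
        if self.noise_sd < 0 or self.separability < 0:
            raise ValueError("noise_sd and separability must be non-negative")
        if self.regime not in ("linear", "cluster"):
            raise ValueError(f"regime must be 'linear' or 'cluster', got {self.regime!r}")
        if self.unlabeled_multiplier < 0:
            raise ValueError("unlabeled multiplier must be >= 0")
        if self.mutations_per_complex[0] < 1 or (
            self.mutations_per_complex[0] > self.mutations_per_complex[1]
        ):
            raise ValueError("mutations_per_complex must be a non-empty integer range")


@dataclass
class SyntheticDataset:
    """Labeled and unlabeled tables plus the hidden truth sidecar."""

    labeled: FeatureTable
    unlabeled: FeatureTable
    truth: pd.DataFrame  # id, latent_label, latent_ddg (labeled + unlabeled)
    informative_features: tuple[str, ...]
    config: GeneratorConfig

    def truth_for(self, ids: Sequence[str]) -> pd.Series:
        lookup = self.truth.set_index("id")["latent_label"]
        missing = [i for i in ids if i not in lookup.index]
        if missing:
            raise KeyError(f"unknown example id(s): {missing[:5]}")
        return lookup.loc[list(ids)]


def _draw_ddg(rng: np.random.Generator, classes: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """ddG per example from its class component truncated to the class interval."""
    lo, hi = config.thresholds.lower, config.thresholds.upper
    bounds = (
        (-np.inf, lo - _EDGE_EPS),  # beneficial: strictly below the lower threshold
        (lo, hi),                   # neutral: the closed band
        (hi + _EDGE_EPS, np.inf),   # detrimental: strictly above the upper threshold
    )
    out = np.empty(len(classes))
    for cls in range(3):
        idx = np.flatnonzero(classes == cls)
        if len(idx) == 0:
            continue
        mu, sd = config.ddg_means[cls], config.ddg_sds[cls]
        a, b = bounds[cls]
        dist = stats.truncnorm((a - mu) / sd, (b - mu) / sd, loc=mu, scale=sd)
        out[idx] = dist.rvs(size=len(idx), random_state=rng)
    return out


def _mutation_id(rng: np.random.Generator, complex_idx: int, position: int) -> str:
    wt, mut = rng.choice(list(AMINO_ACIDS), size=2, replace=False)
    chain = "AB"[int(rng.integers(2))]
    return f"CPX{complex_idx:03d}:{wt}{chain}{position}{mut}"


def _complex_sizes(rng: np.random.Generator, config: GeneratorConfig) -> list[int]:
    lo, hi = config.mutations_per_complex
    if config.n_mutations is None:
        return [int(rng.integers(lo, hi + 1)) for _ in range(config.n_complexes)]
    sizes: list[int] = []
    remaining = config.n_mutations
    while remaining > 0:
        s = min(int(rng.integers(lo, hi + 1)), remaining)
        sizes.append(s)
        remaining -= s
    return sizes


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Draw a labeled table, an unlabeled pool, and the truth sidecar.

    Fully reproducible from ``config.seed``; the unlabeled table never
    exposes its latent class or ddG.
    """
    rng = np.random.default_rng(config.seed)

    # fixed generator geometry, shared by labeled and unlabeled draws
    informative = np.sort(rng.choice(N_FEATURES, config.n_informative_features, replace=False))
    signs = rng.choice([-1.0, 1.0], size=config.n_informative_features)
    loadings = config.separability * signs * rng.uniform(0.8, 1.2, config.n_informative_features)
    # per-dimension class offsets scale with separability so that cluster
    # structure survives per-feature standardization downstream
    centroids = config.separability * rng.normal(size=(3, config.n_informative_features))

    sizes = _complex_sizes(rng, config)
    n_labeled = sum(sizes)
    n_unlabeled = n_labeled * config.unlabeled_multiplier

    def draw_block(n: int, complex_of: Sequence[int], intercepts: Mapping[int, float],
                   start_positions: dict[int, int]) -> tuple[list[str], np.ndarray, np.ndarray, list[str]]:
        ids: list[str] = []
        classes = rng.choice(3, size=n, p=np.asarray(config.class_proportions))
        ddg = _draw_ddg(rng, classes, config)
        X = rng.normal(0.0, 1.0, size=(n, N_FEATURES))
        if config.regime == "linear":
            X[:, informative] = (
                np.outer(ddg, loadings)
                + rng.normal(0.0, config.noise_sd, size=(n, len(informative)))
            )
        else:
            X[:, informative] = (
                centroids[classes]
                + rng.normal(0.0, config.noise_sd, size=(n, len(informative)))
            )
        for i, cx in enumerate(complex_of):
            pos = start_positions.get(cx, 1)
            start_positions[cx] = pos + 1
            ids.append(_mutation_id(rng, cx, pos))
            if config.complex_intercept_sd > 0:
                X[i, informative] += intercepts[cx]
        labels = [LABELS[int(c)] for c in classes]
        return ids, X, ddg, labels

    intercepts = {
        cx: rng.normal(0.0, config.complex_intercept_sd) if config.complex_intercept_sd > 0 else 0.0
        for cx in range(len(sizes) * 2)
    }
    positions: dict[int, int] = {}

    complex_of_labeled = [cx for cx, s in enumerate(sizes) for _ in range(s)]
    lab_ids, lab_X, lab_ddg, lab_labels = draw_block(
        n_labeled, complex_of_labeled, intercepts, positions
    )
    labeled = FeatureTable.from_arrays(lab_ids, lab_X, labels=lab_labels, ddg=lab_ddg)

    # unlabeled mutations live on the same complexes, round-robin
    complex_of_unl = [i % max(len(sizes), 1) for i in range(n_unlabeled)]
    unl_ids, unl_X, unl_ddg, unl_labels = draw_block(
        n_unlabeled, complex_of_unl, intercepts, positions
    )
    unlabeled = FeatureTable.from_arrays(unl_ids, unl_X)

    truth = pd.DataFrame(
        {
            "id": lab_ids + unl_ids,
            "latent_label": lab_labels + unl_labels,
            "latent_ddg": np.concatenate([lab_ddg, unl_ddg]),
        }
    )
    # labels must re-derive from the latent ddG under the thresholds in force
    recomputed = [assign_label(v, config.thresholds) for v in truth["latent_ddg"]]
    assert recomputed == list(truth["latent_label"])

    return SyntheticDataset(labeled, unlabeled, truth, tuple(FEATURE_NAMES[j] for j in informative), config)


def truth_accuracy(
    predictions: Sequence[PredictionResult] | Mapping[str, str],
    dataset: SyntheticDataset,
) -> float:
    """Fraction of predictions agreeing with the latent truth."""
    if isinstance(predictions, Mapping):
        items = list(predictions.items())
    else:
        items = [(p.example_id, p.predicted_class) for p in predictions]
    if not items:
        raise ValueError("no predictions supplied")
    truth = dataset.truth_for([ex_id for ex_id, _ in items])
    hits = sum(1 for (ex_id, pred), true in zip(items, truth) if pred == true)
    return hits / len(items)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Emit the feature-TSV dialect plus a truth/ sidecar never read by learners."""
    from .features import write_feature_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    paths = {
        "labeled": out / "labeled.tsv",
        "unlabeled": out / "unlabeled.tsv",
        "truth": out / "truth" / "truth.tsv",
    }
    write_feature_table(dataset.labeled, paths["labeled"])
    write_feature_table(dataset.unlabeled, paths["unlabeled"])
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
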