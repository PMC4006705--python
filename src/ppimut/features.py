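"""The 33-feature representation of a mutation and its bookkeeping.

Each mutation in a complex is described by the difference between energetic
and structural terms computed on the wild-type structure and on the modeled
mutant structure: 22 empirical force-field energy terms, three orientation-
dependent statistical-potential terms, the accessible surface area of the
mutated residue, the inter-chain interaction energy of the mutated chain,
three all-atom statistical-potential terms, a geometric interface score,
and two distance-dependent potential scores.  The package treats the term
producers as external adapters: they deliver per-state term tables and this
module differences them (wild type minus mutant), reads/writes the feature
TSV dialect, and ranks features by information gain about the class label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed, ordered 33-feature schema.
FEATURE_NAMES: tuple[str, ...] = (
    # 22 force-field energy terms
    "Total energy",
    "Backbone Hbond",
    "Sidechain Hbond",
    "Van der Waals",
    "Electrostatics",
    "Solvation Polar",
    "Solvation Hydrophobic",
    "Van der Waals clashes",
    "entropy sidechain",
    "entropy mainchain",
    "sloop_entropy",
    "mloop_entropy",
    "cis_bond",
    "torsional clash",
    "backbone clash",
    "helix dipole",
    "water bridge",
    "disulfide",
    "electrostatic kon",
    "partial covalent bonds",
    "Energy Ionisation",
    "Entropy Complex",
    # orientation-dependent statistical potential
    "OPUS term 1",
    "OPUS term 2",
    "OPUS term 3",
    # solvent accessibility of the mutated residue
    "ASA",
    # inter-chain interaction energy of the mutated chain
    "Interaction energy",
    # all-atom statistical potentials
    "Goap term 1",
    "Goap term 2",
    "Goap term 3",
    "Geometric score",
    "Dfire2 term",
    "Dcomplex term",
)

N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 33

ID_COLUMN = "id"
LABEL_COLUMN = "label"
DDG_COLUMN = "ddg"


class SchemaError(ValueError):
    """A table does not conform to the 33-feature contract."""


class FeatureParseError(ValueError):
    """A feature file contains a malformed cell."""


@dataclass
class FeatureTable:
    """Rows of 33 wild-type-minus-mutant feature differences.

    Wraps a DataFrame whose columns are ``id``, the 33 schema names, and
    optionally ``label`` and ``ddg`` (the latter carried only by synthetic
    data, where the latent truth is known).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.frame.columns)
        if ID_COLUMN not in cols:
            raise SchemaError("feature table lacks an 'id' column")
        missing = [n for n in FEATURE_NAMES if n not in cols]
        if missing:
            raise SchemaError(f"feature table missing schema columns: {missing}")
        if self.frame[ID_COLUMN].duplicated().any():
            dupes = self.frame[ID_COLUMN][self.frame[ID_COLUMN].duplicated()].tolist()
            raise SchemaError(f"duplicate example identifiers: {dupes[:5]}")
        block = self.frame[list(FEATURE_NAMES)]
        if block.isna().any().any():
            raise SchemaError("feature table contains missing values")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> list[str]:
        return self.frame[ID_COLUMN].astype(str).tolist()

    @property
    def X(self) -> np.ndarray:
        """n x 33 float matrix in schema order."""
        return self.frame[list(FEATURE_NAMES)].to_numpy(dtype=float)

    @property
    def labels(self) -> pd.Series | None:
        return self.frame[LABEL_COLUMN] if LABEL_COLUMN in self.frame.columns else None

    @property
    def ddg(self) -> pd.Series | None:
        return self.frame[DDG_COLUMN] if DDG_COLUMN in self.frame.columns else None

    @classmethod
    def from_arrays(
        cls,
        ids: Sequence[str],
        X: np.ndarray,
        labels: Sequence[str] | None = None,
        ddg: Sequence[float] | None = None,
    ) -> "FeatureTable":
        X = np.asarray(X, dtype=float)
        if X.shape != (len(ids), N_FEATURES):
            raise SchemaError(f"feature matrix must be (n, {N_FEATURES}), got {X.shape}")
        frame = pd.DataFrame(X, columns=list(FEATURE_NAMES))
        frame.insert(0, ID_COLUMN, list(ids))
        if labels is not None:
            frame[LABEL_COLUMN] = list(labels)
        if ddg is not None:
            frame[DDG_COLUMN] = list(ddg)
        return cls(frame)

    def select(self, mask: Sequence[bool] | np.ndarray) -> "FeatureTable":
        return FeatureTable(self.frame.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True))

    def drop_labels(self) -> "FeatureTable":
        cols = [c for c in self.frame.columns if c not in (LABEL_COLUMN, DDG_COLUMN)]
        return FeatureTable(self.frame[cols].copy())


@dataclass
class TermTable:
    """Raw term values for one structure state (wild type or mutant).

    ``values`` maps example id -> {feature name: value}; ``failed`` lists
    examples for which an external term producer did not deliver.
    """

    state: str  # "wt" | "mut"
    values: dict[str, dict[str, float]]
    failed: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.state not in ("wt", "mut"):
            raise SchemaError(f"state must be 'wt' or 'mut', got {self.state!r}")
        for key, terms in self.values.items():
            missing = [n for n in FEATURE_NAMES if n not in terms]
            if missing and key not in self.failed:
                raise SchemaError(f"example {key!r} missing terms {missing[:3]} (mark it failed)")


def diff_features(wild_type: TermTable, mutant: TermTable) -> FeatureTable:
    """Difference paired term tables into a feature table (wt - mut).

    Examples flagged as failed in either state are dropped and logged; a
    key present in one table but not the other is a structured error.
    """
    wt_keys, mut_keys = set(wild_type.values), set(mutant.values)
    if wt_keys != mut_keys:
        raise SchemaError(
            "term tables cover different examples; "
            f"only-wt={sorted(wt_keys - mut_keys)[:5]} only-mut={sorted(mut_keys - wt_keys)[:5]}"
        )
    failed = wild_type.failed | mutant.failed
    kept = [k for k in wild_type.values if k not in failed]
    if failed:
        logger.info("dropping %d example(s) with failed terms", len(failed & wt_keys))
    X = np.array(
        [
            [wild_type.values[k][n] - mutant.values[k][n] for n in FEATURE_NAMES]
            for k in kept
        ],
        dtype=float,
    ).reshape(len(kept), N_FEATURES)
    return FeatureTable.from_arrays(kept, X)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write the tab-separated feature dialect (id, 33 terms[, label, ddg])."""
    cols = [ID_COLUMN, *FEATURE_NAMES]
    for extra in (LABEL_COLUMN, DDG_COLUMN):
        if extra in table.frame.columns:
            cols.append(extra)
    table.frame[cols].to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature TSV, enforcing the schema.

    Extra columns beyond the contract are tolerated and logged; a missing
    schema column or a non-numeric feature cell is an error naming the
    offender.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [n for n in (ID_COLUMN, *FEATURE_NAMES) if n not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    extras = [
        c
        for c in frame.columns
        if c not in (ID_COLUMN, LABEL_COLUMN, DDG_COLUMN) and c not in FEATURE_NAMES
    ]
    if extras:
        logger.info("%s: ignoring extra columns %s", path.name, extras)
        frame = frame.drop(columns=extras)
    numeric = list(FEATURE_NAMES) + ([DDG_COLUMN] if DDG_COLUMN in frame.columns else [])
    for col in numeric:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise FeatureParseError(
                f"{path.name}: non-numeric value {frame[col][bad].iloc[0]!r} "
                f"in column {col!r} at line {row}"
            )
        frame[col] = converted
    return FeatureTable(frame)


# --- information-gain feature ranking --------------------------------------


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count vector."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _equal_frequency_bins(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Assign each value to one of <= n_bins equal-frequency bins."""
    # rank-based binning: deterministic and invariant to monotone transforms
    quantiles = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(quantiles)
    return np.searchsorted(edges, values, side="left")


def info_gain_ranking(
    table: FeatureTable, n_bins: int = 10
) -> list[tuple[str, float]]:
    """Rank the 33 features by information gain about the label, in bits.

    Each feature is discretized into ``n_bins`` equal-frequency bins and
    scored as H(label) - H(label | bin).  Output is sorted by descending
    score with ties broken by schema order.  A single-class table scores
    every feature 0.
    """
    labels = table.labels
    if labels is None:
        raise SchemaError("info_gain_ranking requires a labeled table")
    y = labels.to_numpy()
    classes, y_idx = np.unique(y, return_inverse=True)
    n = len(y)
    if len(classes) < 2:
        scored = [(name, 0.0) for name in FEATURE_NAMES]
        return scored
    if n < 10:
        raise SchemaError(f"need >= 10 rows to rank features, got {n}")
    h_label = _entropy(np.bincount(y_idx))
    X = table.X
    scores: list[float] = []
    for j in range(N_FEATURES):
        bins = _equal_frequency_bins(X[:, j], n_bins)
        cond = 0.0
        for b in np.unique(bins):
            in_bin = bins == b
            cond += in_bin.sum() / n * _entropy(np.bincount(y_idx[in_bin]))
        scores.append(max(0.0, h_label - cond))
    order = sorted(range(N_FEATURES), key=lambda j: (-scores[j], j))
    return [(FEATURE_NAMES[j], scores[j]) for j in order]
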