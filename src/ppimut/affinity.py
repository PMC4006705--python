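"""Binding-affinity thermodynamics and interaction-effect labeling.

A single missense substitution in a structurally resolved protein--protein
complex changes the binding free energy by

    ddG = dG(mutant) - dG(wild type),      dG = R * T * ln(Kd)

with R the gas constant in kcal/(mol K) and Kd the equilibrium dissociation
constant.  More negative dG means tighter binding, so positive ddG
destabilizes the interaction.  Mutations are assigned one of three
interaction-effect classes by thresholding ddG:

    beneficial   ddG <  lower      (binding significantly strengthened)
    neutral      lower <= ddG <= upper
    detrimental  ddG >  upper      (interaction disrupted)

with +/-0.5 kcal/mol as the community-standard band and +/-2.0 kcal/mol as a
more conservative alternative.  The three classes induce two binary
problems: strengthening vs weakening (beneficial vs detrimental) and
preserving vs disruptive (beneficial+neutral vs detrimental).

This module parses SKEMPI-style affinity tables, computes ddG, assigns
labels, removes redundant entries, enumerates the 18-residue complement of
unlabeled mutations at each characterized site, and assembles the three
problem datasets.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, one-letter codes, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872e-3

#: Standard-state temperature used when a record carries none.
DEFAULT_TEMPERATURE_K = 298.0

BENEFICIAL = "beneficial"
NEUTRAL = "neutral"
DETRIMENTAL = "detrimental"
LABELS = (BENEFICIAL, NEUTRAL, DETRIMENTAL)

STRENGTHENING = "strengthening"
WEAKENING = "weakening"
PRESERVING = "preserving"
DISRUPTIVE = "disruptive"

#: 3-class label -> problem 1 class (neutral mutations are excluded).
PROBLEM1_MAP = {BENEFICIAL: STRENGTHENING, DETRIMENTAL: WEAKENING}
#: 3-class label -> problem 2 class.
PROBLEM2_MAP = {BENEFICIAL: PRESERVING, NEUTRAL: PRESERVING, DETRIMENTAL: DISRUPTIVE}


class InvalidInputError(ValueError):
    """Raised when a value violates a physical or format precondition."""


class MultipleMutationsError(InvalidInputError):
    """Raised for mutation strings describing more than one substitution."""


_MUTATION_RE = re.compile(r"^([A-Z])([A-Za-z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class MutationSpec:
    """A single amino-acid substitution at one position of one chain."""

    chain: str
    position: int
    wild_type: str
    mutant: str

    def __post_init__(self) -> None:
        if len(self.chain) != 1:
            raise InvalidInputError(f"chain must be a single character, got {self.chain!r}")
        if self.position < 1:
            raise InvalidInputError(f"position must be >= 1, got {self.position}")
        for role, aa in (("wild_type", self.wild_type), ("mutant", self.mutant)):
            if aa not in AMINO_ACIDS:
                raise InvalidInputError(f"{role} residue {aa!r} is not a standard amino acid")
        if self.wild_type == self.mutant:
            raise InvalidInputError(
                f"wild-type and mutant residues are identical ({self.wild_type})"
            )

    def __str__(self) -> str:
        return f"{self.wild_type}{self.chain}{self.position}{self.mutant}"


def parse_mutation(token: str) -> MutationSpec:
    """Parse one compact SKEMPI-style mutation token, e.g. ``RA123G``.

    The dialect is ``<wt><chain><position><mut>`` with one-letter residue
    codes and a single-character chain identifier.
    """
    m = _MUTATION_RE.match(token.strip())
    if m is None:
        raise InvalidInputError(
            f"cannot parse mutation token {token!r}; expected <wt><chain><pos><mut> like RA123G"
        )
    wt, chain, pos, mut = m.groups()
    return MutationSpec(chain=chain, position=int(pos), wild_type=wt, mutant=mut)


def parse_mutation_string(text: str) -> MutationSpec:
    """Parse a mutation field, rejecting multi-substitution entries.

    SKEMPI separates simultaneous substitutions with commas; only single
    substitutions are in scope, so anything else raises
    :class:`MultipleMutationsError`.
    """
    tokens = [t for t in re.split(r"[,;]", text.strip()) if t]
    if not tokens:
        raise InvalidInputError("empty mutation string")
    if len(tokens) > 1:
        raise MultipleMutationsError(f"entry contains {len(tokens)} substitutions: {text!r}")
    return parse_mutation(tokens[0])


@dataclass(frozen=True)
class AffinityRecord:
    """One experimentally characterized mutation with binding affinities.

    Either a dissociation constant (mol/L) or a binding free energy
    (kcal/mol) must be present for each of the wild-type and mutant states.
    """

    complex_id: str
    mutation: MutationSpec
    kd_wild_type: float | None = None
    kd_mutant: float | None = None
    dg_wild_type: float | None = None
    dg_mutant: float | None = None
    temperature: float = DEFAULT_TEMPERATURE_K
    pdb_id: str | None = None
    reference: str = ""

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise InvalidInputError(f"temperature must be positive, got {self.temperature}")
        for name, kd in (("kd_wild_type", self.kd_wild_type), ("kd_mutant", self.kd_mutant)):
            if kd is not None and kd <= 0:
                raise InvalidInputError(f"{name} must be strictly positive, got {kd}")
        if self.kd_wild_type is None and self.dg_wild_type is None:
            raise InvalidInputError("record lacks both Kd and dG for the wild type")
        if self.kd_mutant is None and self.dg_mutant is None:
            raise InvalidInputError("record lacks both Kd and dG for the mutant")

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        """Identity key used for redundancy removal (reference excluded)."""
        m = self.mutation
        return (self.complex_id, m.chain, m.position, m.wild_type, m.mutant)

    def dg(self, state: str) -> float:
        """Binding free energy for ``state`` in {"wild_type", "mutant"}."""
        if state == "wild_type":
            given, kd = self.dg_wild_type, self.kd_wild_type
        elif state == "mutant":
            given, kd = self.dg_mutant, self.kd_mutant
        else:
            raise ValueError(f"unknown state {state!r}")
        if given is not None:
            return given
        return binding_free_energy(kd, self.temperature)


@dataclass(frozen=True)
class ThresholdConfig:
    """ddG thresholds (kcal/mol) bounding the neutral band."""

    lower: float = -0.5
    upper: float = 0.5

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise InvalidInputError(
                f"lower threshold must be below upper ({self.lower} vs {self.upper})"
            )


@dataclass(frozen=True)
class LabeledMutation:
    """An affinity record with its computed ddG and effect class."""

    record: AffinityRecord
    ddg: float
    label: str


def binding_free_energy(kd: float, temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """dG = R*T*ln(Kd) in kcal/mol; negative for sub-molar Kd."""
    if kd is None or kd <= 0:
        raise InvalidInputError(f"Kd must be strictly positive, got {kd}")
    if temperature <= 0:
        raise InvalidInputError(f"temperature must be positive, got {temperature}")
    return GAS_CONSTANT_KCAL * temperature * math.log(kd)


def ddg(dg_mutant: float, dg_wild_type: float) -> float:
    """ddG = dG(mutant) - dG(wild type); positive destabilizes binding."""
    if not (math.isfinite(dg_mutant) and math.isfinite(dg_wild_type)):
        raise InvalidInputError("binding free energies must be finite")
    return dg_mutant - dg_wild_type


def assign_label(ddg_value: float, thresholds: ThresholdConfig = ThresholdConfig()) -> str:
    """Map ddG to {beneficial, neutral, detrimental}.

    The neutral band is the closed interval [lower, upper]; values strictly
    below are beneficial (tighter binding), strictly above detrimental.
    """
    if not math.isfinite(ddg_value):
        raise InvalidInputError(f"ddG must be finite, got {ddg_value}")
    if ddg_value > thresholds.upper:
        return DETRIMENTAL
    if ddg_value < thresholds.lower:
        return BENEFICIAL
    return NEUTRAL


def label_record(
    record: AffinityRecord, thresholds: ThresholdConfig = ThresholdConfig()
) -> LabeledMutation:
    """Compute ddG from a record's affinities and assign its class."""
    value = ddg(record.dg("mutant"), record.dg("wild_type"))
    return LabeledMutation(record=record, ddg=value, label=assign_label(value, thresholds))


def deduplicate(records: Iterable[AffinityRecord]) -> list[AffinityRecord]:
    """Drop redundant records (same mutation in the same complex).

    Redundant entries are the same mutation reported by different
    references; the first occurrence in input order is kept.
    """
    seen: set[tuple] = set()
    out: list[AffinityRecord] = []
    for rec in records:
        if rec.key not in seen:
            seen.add(rec.key)
            out.append(rec)
    return out


def enumerate_complement(mutation: MutationSpec) -> list[MutationSpec]:
    """All 18 other substitutions at the same site, alphabetical by mutant.

    Excludes the wild-type residue and the characterized mutant; these
    complement mutations have no measured affinity and supply the unlabeled
    pool for semi-supervised training.
    """
    excluded = {mutation.wild_type, mutation.mutant}
    return [
        replace(mutation, mutant=aa)
        for aa in AMINO_ACIDS
        if aa not in excluded
    ]


@dataclass
class ProblemDatasets:
    """The three classification datasets induced by the 3-class labels.

    ``problem1``..``problem3`` map each example to its class name for that
    problem; ``unlabeled`` holds (complex_id, MutationSpec) pairs with no
    experimental label.
    """

    problem1: list[tuple[LabeledMutation, str]] = field(default_factory=list)
    problem2: list[tuple[LabeledMutation, str]] = field(default_factory=list)
    problem3: list[tuple[LabeledMutation, str]] = field(default_factory=list)
    unlabeled: list[tuple[str, MutationSpec]] = field(default_factory=list)

    @staticmethod
    def _counts(pairs: Sequence[tuple[LabeledMutation, str]]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, cls in pairs:
            counts[cls] = counts.get(cls, 0) + 1
        return counts

    def class_counts(self, problem_id: int) -> dict[str, int]:
        return self._counts(getattr(self, f"problem{problem_id}"))


def build_problem_datasets(
    labeled: Sequence[LabeledMutation],
    unlabeled: Sequence[tuple[str, MutationSpec]] = (),
) -> ProblemDatasets:
    """Assemble the three problem datasets from labeled mutations.

    Problem 1 keeps beneficial (strengthening) and detrimental (weakening)
    mutations; problem 2 groups beneficial+neutral as preserving against
    detrimental as disruptive; problem 3 is the full 3-class partition.
    """
    ds = ProblemDatasets(unlabeled=list(unlabeled))
    labeled_keys = {lm.record.key for lm in labeled}
    for cid, spec in ds.unlabeled:
        key = (cid, spec.chain, spec.position, spec.wild_type, spec.mutant)
        if key in labeled_keys:
            raise InvalidInputError(f"unlabeled mutation {cid}:{spec} also appears labeled")
    for lm in labeled:
        if lm.label in PROBLEM1_MAP:
            ds.problem1.append((lm, PROBLEM1_MAP[lm.label]))
        ds.problem2.append((lm, PROBLEM2_MAP[lm.label]))
        ds.problem3.append((lm, lm.label))
    return ds


# --- SKEMPI-style TSV I/O ---------------------------------------------------

AFFINITY_COLUMNS = (
    "complex_id",
    "pdb_id",
    "chains",
    "mutation",
    "kd_wt",
    "kd_mut",
    "dg_wt",
    "dg_mut",
    "temperature",
    "reference",
)


@dataclass
class ParseSummary:
    """Bookkeeping from reading an affinity table."""

    n_rows: int = 0
    n_parsed: int = 0
    n_multi_mutation: int = 0
    n_invalid: int = 0
    n_duplicates: int = 0
    messages: list[str] = field(default_factory=list)


def _opt_float(cell: str) -> float | None:
    cell = cell.strip()
    return float(cell) if cell else None


def read_affinity_table(path: str | Path) -> tuple[list[AffinityRecord], ParseSummary]:
    """Read a tab-separated affinity table; skip and log bad rows.

    Multi-mutation entries and rows violating record invariants are skipped
    with a message in the summary rather than aborting the whole file.
    Scientific notation is accepted for Kd.  Duplicates are *not* removed
    here; call :func:`deduplicate` on the result.
    """
    path = Path(path)
    records: list[AffinityRecord] = []
    summary = ParseSummary()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(AFFINITY_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise InvalidInputError(f"affinity table missing columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            summary.n_rows += 1
            try:
                spec = parse_mutation_string(row["mutation"])
                temp = _opt_float(row["temperature"])
                records.append(
                    AffinityRecord(
                        complex_id=row["complex_id"].strip(),
                        pdb_id=row["pdb_id"].strip() or None,
                        mutation=spec,
                        kd_wild_type=_opt_float(row["kd_wt"]),
                        kd_mutant=_opt_float(row["kd_mut"]),
                        dg_wild_type=_opt_float(row["dg_wt"]),
                        dg_mutant=_opt_float(row["dg_mut"]),
                        temperature=temp if temp is not None else DEFAULT_TEMPERATURE_K,
                        reference=row["reference"].strip(),
                    )
                )
                summary.n_parsed += 1
            except MultipleMutationsError as exc:
                summary.n_multi_mutation += 1
                summary.messages.append(f"line {lineno}: skipped ({exc})")
                logger.info("line %d: skipped multi-mutation entry", lineno)
            except (InvalidInputError, ValueError) as exc:
                summary.n_invalid += 1
                summary.messages.append(f"line {lineno}: skipped ({exc})")
                logger.info("line %d: skipped invalid row: %s", lineno, exc)
    return records, summary


def write_labeled_table(labeled: Sequence[LabeledMutation], path: str | Path) -> None:
    """Write labeled mutations as TSV: input columns plus ddg and label."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(AFFINITY_COLUMNS + ("ddg", "label"))
        for lm in labeled:
            r = lm.record
            writer.writerow(
                [
                    r.complex_id,
                    r.pdb_id or "",
                    r.mutation.chain,
                    str(r.mutation),
                    "" if r.kd_wild_type is None else repr(r.kd_wild_type),
                    "" if r.kd_mutant is None else repr(r.kd_mutant),
                    "" if r.dg_wild_type is None else repr(r.dg_wild_type),
                    "" if r.dg_mutant is None else repr(r.dg_mutant),
                    repr(r.temperature),
                    r.reference,
                    repr(lm.ddg),
                    lm.label,
                ]
            )
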