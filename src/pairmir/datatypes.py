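"""Domain containers and validation for the paired plasma miRNA pipeline.

Every container validates its invariants at construction time, so malformed
inputs are rejected before any computation stage sees them.  Identifier
matching throughout the package is case-sensitive exact string match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """A domain object violates one of its structural invariants."""


class ParseError(ValueError):
    """A file could not be parsed into a domain object."""


SCALES = ("linear", "log2")
COMPARTMENTS = ("arterial", "venous")


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    dups: set[str] = set()
    for i in ids:
        if i in seen:
            dups.add(i)
        seen.add(i)
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(dups)[:5]}")


@dataclass
class ExpressionMatrix:
    """miRNA x sample intensity table with a declared scale.

    Parameters
    ----------
    values
        DataFrame with miRNA ids as the index and sample ids as columns.
        Must be complete (no missing cells); values must be non-negative
        when ``scale == "linear"``.
    scale
        ``"linear"`` or ``"log2"``.
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(self.values.index.astype(str), "miRNA ids")
        _check_unique(self.values.columns.astype(str), "sample ids")
        try:
            self.values = self.values.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric expression values: {exc}") from exc
        if self.values.isna().any().any():
            bad = self.values.isna().any(axis=1)
            raise ValidationError(
                f"missing values in rows {list(self.values.index[bad])[:5]}"
            )
        if self.scale == "linear" and (self.values.values < 0).any():
            raise ValidationError("negative values in a linear-scale matrix")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_mirnas(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_log2(self, offset: float = 1.0) -> "ExpressionMatrix":
        """Return a log2-scale copy; linear values are transformed as log2(x + offset)."""
        if self.scale == "log2":
            return ExpressionMatrix(self.values.copy(), "log2")
        return ExpressionMatrix(np.log2(self.values + offset), "log2")


@dataclass(frozen=True)
class SamplePair:
    individual: str
    arterial: str
    venous: str


@dataclass
class PairedDesign:
    """One arterial and one venous sample per individual."""

    pairs: list[SamplePair]

    def __post_init__(self) -> None:
        self.pairs = [
            p if isinstance(p, SamplePair) else SamplePair(*p) for p in self.pairs
        ]
        if not self.pairs:
            raise ValidationError("design contains no pairs")
        _check_unique((p.individual for p in self.pairs), "individual ids")
        samples = [s for p in self.pairs for s in (p.arterial, p.venous)]
        _check_unique(samples, "sample ids (each sample may appear in one pair and one role)")

    @property
    def individuals(self) -> list[str]:
        return [p.individual for p in self.pairs]

    @property
    def arterial_samples(self) -> list[str]:
        return [p.arterial for p in self.pairs]

    @property
    def venous_samples(self) -> list[str]:
        return [p.venous for p in self.pairs]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def check_against(self, matrix: ExpressionMatrix) -> None:
        """Raise if any design sample is absent from the matrix."""
        missing = [
            s
            for s in self.arterial_samples + self.venous_samples
            if s not in matrix.values.columns
        ]
        if missing:
            raise ValidationError(f"design samples absent from matrix: {missing}")


CATEGORIES = ("function", "disease", "gene_function")


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str
    category: str
    members: frozenset[str]


@dataclass
class AnnotationCollection:
    """Term -> member-set annotation (miRNA function/disease or gene function).

    ``parent_map`` optionally maps a term id to its parent term ids and must
    be acyclic; ``universe`` optionally fixes an explicit member universe
    (default: the union of all member sets).
    """

    terms: list[Term]
    parent_map: Optional[dict[str, frozenset[str]]] = None
    universe: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        _check_unique((t.term_id for t in self.terms), "term ids")
        for t in self.terms:
            if not t.members:
                raise ValidationError(f"term {t.term_id} has an empty member set")
            if t.category not in CATEGORIES:
                raise ValidationError(
                    f"term {t.term_id}: category {t.category!r} not in {CATEGORIES}"
                )
        if self.parent_map is not None:
            known = {t.term_id for t in self.terms}
            self.parent_map = {k: frozenset(v) for k, v in self.parent_map.items()}
            for child, parents in self.parent_map.items():
                unknown = ({child} | parents) - known
                if unknown:
                    raise ValidationError(
                        f"parent_map references unknown terms: {sorted(unknown)}"
                    )
            _check_acyclic(self.parent_map)
        if self.universe is not None:
            self.universe = frozenset(self.universe)

    @property
    def member_universe(self) -> frozenset[str]:
        if self.universe is not None:
            return self.universe
        out: set[str] = set()
        for t in self.terms:
            out |= t.members
        return frozenset(out)

    def get(self, term_id: str) -> Term:
        for t in self.terms:
            if t.term_id == term_id:
                return t
        raise KeyError(term_id)


def _check_acyclic(parent_map: Mapping[str, frozenset[str]]) -> None:
    """DFS cycle detection over the child -> parent relation."""
    WHITE, GREY, BLACK = 0, 1, 2
    color: dict[str, int] = {}

    def visit(node: str) -> None:
        color[node] = GREY
        for parent in parent_map.get(node, ()):  # noqa: B905
            c = color.get(parent, WHITE)
            if c == GREY:
                raise ValidationError(f"parent relation contains a cycle through {parent!r}")
            if c == WHITE:
                visit(parent)
        color[node] = BLACK

    for n in parent_map:
        if color.get(n, WHITE) == WHITE:
            visit(n)


@dataclass
class TargetMap:
    """miRNA -> target records with evidence fields.

    ``records`` columns: mirna, target, validated (bool), n_predictions (int >= 0).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["mirna", "target", "validated", "n_predictions"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ValidationError(f"target map missing columns: {missing}")
        self.records = self.records[required].copy()
        self.records["validated"] = self.records["validated"].astype(bool)
        self.records["n_predictions"] = self.records["n_predictions"].astype(int)
        if (self.records["n_predictions"] < 0).any():
            raise ValidationError("n_predictions must be non-negative")
        if self.records.duplicated(["mirna", "target"]).any():
            dup = self.records[self.records.duplicated(["mirna", "target"])]
            raise ValidationError(
                f"duplicate (mirna, target) records: {dup.head(3).values.tolist()}"
            )

    def passing(self, min_predictions: int = 3) -> pd.DataFrame:
        """Records passing the evidence filter: validated OR >= min_predictions predictions."""
        ok = self.records["validated"] | (
            self.records["n_predictions"] >= min_predictions
        )
        return self.records[ok]

    def targets_of(self, mirnas: Iterable[str], min_predictions: int = 3) -> set[str]:
        df = self.passing(min_predictions)
        return set(df.loc[df["mirna"].isin(set(mirnas)), "target"])


@dataclass
class TissueAtlas:
    """Tissue x miRNA expression with per-tissue enriched-miRNA lists."""

    expression: pd.DataFrame  # tissues as rows, miRNAs as columns
    enriched: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.expression.index.astype(str), "tissue ids")
        _check_unique(self.expression.columns.astype(str), "atlas miRNA ids")
        self.expression = self.expression.astype(float)
        universe = set(self.expression.columns)
        self.enriched = {k: frozenset(v) for k, v in self.enriched.items()}
        for tissue, members in self.enriched.items():
            extra = members - universe
            if extra:
                raise ValidationError(
                    f"enriched list for {tissue} outside atlas universe: {sorted(extra)[:5]}"
                )

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.expression.index)

    def enriched_tissues_of(self, mirna: str) -> list[str]:
        return [t for t in self.tissue_ids if mirna in self.enriched.get(t, frozenset())]


@dataclass
class OrthologMap:
    """Partial rat -> human miRNA id mapping."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        for rat, human in self.mapping.items():
            if rat == human:
                raise ValidationError(f"self-referential ortholog entry: {rat!r}")
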