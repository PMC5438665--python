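"""Over-representation analysis with empirical random-set calibration.

Implements the annotation side of the pipeline: hypergeometric
over-representation of a query set against GMT-style term collections,
Benjamini-Hochberg correction, best-per-parent redundancy filtering,
rat-to-human ortholog mapping, the evidence-filtered partition of miRNA
targets into exclusive/shared sets, and an empirical calibration that asks
how often equally sized uniform-random sets reproduce each significant
term.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AnnotationCollection,
    OrthologMap,
    TargetMap,
    ValidationError,
)

_ARM_SUFFIX = re.compile(r"-(5p|3p)$")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    category: str
    raw_p: float  # hypergeometric upper-tail probability
    contributing_members: frozenset[str]  # query ∩ term
    adjusted_p: Optional[float] = None  # BH-corrected, when requested
    random_hit_count: Optional[int] = None  # filled by random_set_calibration
    empirical_p: Optional[float] = None  # (hits + 1) / (n_sets + 1)


@dataclass(frozen=True)
class TargetSets:
    """Evidence-filtered targets partitioned by which miRNA group hits them."""

    arterial_exclusive: frozenset[str]
    venous_exclusive: frozenset[str]
    shared: frozenset[str]

    def __post_init__(self) -> None:
        if (
            self.arterial_exclusive & self.venous_exclusive
            or self.arterial_exclusive & self.shared
            or self.venous_exclusive & self.shared
        ):
            raise ValidationError("target partitions must be pairwise disjoint")

    @property
    def all_targets(self) -> frozenset[str]:
        return self.arterial_exclusive | self.venous_exclusive | self.shared


def collapse_family(mirna_id: str) -> str:
    """Strip the -5p/-3p arm suffix so query ids match family-level annotation."""
    return _ARM_SUFFIX.sub("", mirna_id)


def map_orthologs(
    ids: Iterable[str],
    orthologs: Optional[OrthologMap] = None,
    prefix_fallback: bool = True,
    prefixes: tuple[str, str] = ("rno-", "hsa-"),
) -> tuple[set[str], list[str]]:
    """Map rat miRNA ids to human orthologs.

    Explicit table entries win; otherwise (with ``prefix_fallback``) the
    species prefix is substituted.  Unmapped ids are returned, never
    silently dropped.
    """
    table = orthologs.mapping if orthologs is not None else {}
    src, dst = prefixes
    mapped: set[str] = set()
    unmapped: list[str] = []
    for i in ids:
        if i in table:
            mapped.add(table[i])
        elif prefix_fallback and i.startswith(src):
            mapped.add(dst + i[len(src):])
        else:
            unmapped.append(i)
    return mapped, sorted(unmapped)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted P-values (capped at 1).

    Output is order-preserving: the i-th adjusted value belongs to the i-th
    input P-value.
    """
    p = np.asarray(list(pvalues), float)
    if p.size == 0:
        return []
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("P-values must lie in (0, 1]")
    return list(_bh_rows(p[None, :])[0])


def _bh_rows(p: np.ndarray) -> np.ndarray:
    """Row-wise BH step-up on a 2-D array of P-values."""
    n = p.shape[1]
    order = np.argsort(p, axis=1)
    ranked = np.take_along_axis(p, order, axis=1) * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[:, ::-1], axis=1)[:, ::-1]
    adj = np.clip(adj, None, 1.0)
    out = np.empty_like(p)
    np.put_along_axis(out, order, adj, axis=1)
    return out


def _prepare_terms(
    annotation: AnnotationCollection,
    universe: frozenset[str],
    category: Optional[str],
) -> list:
    terms = [
        t
        for t in annotation.terms
        if (category is None or t.category == category)
    ]
    return [(t, t.members & universe) for t in terms]


def ora(
    query: Iterable[str],
    annotation: AnnotationCollection,
    universe: Optional[Iterable[str]] = None,
    alpha: float = 0.01,
    category: Optional[str] = None,
    adjust: Optional[str] = None,
    collapse_families: bool = False,
    return_all: bool = False,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation of ``query`` per term.

    For overlap k between query (size s) and a term (size K) within a
    universe of size M, the raw P is P(X >= k) for
    X ~ Hypergeometric(M, K, s).  Terms are intersected with the universe
    before testing; query ids outside the universe are ignored.  With
    ``adjust="bh"`` significance is judged on BH-adjusted values computed
    across all tested terms; default is the raw P (one-sided test only).
    Returns significant terms ascending by raw P (all terms when
    ``return_all``).
    """
    if adjust not in (None, "bh"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    uni = frozenset(universe) if universe is not None else annotation.member_universe
    if not uni:
        raise ValidationError("empty universe")
    q = set(query)
    if collapse_families:
        q = {collapse_family(i) for i in q}
    q &= uni
    if not q:
        return []
    M, s = len(uni), len(q)
    prepared = [(t, members) for t, members in _prepare_terms(annotation, uni, category) if members]
    if not prepared:
        return []
    K = np.array([len(members) for _, members in prepared])
    k = np.array([len(q & members) for _, members in prepared])
    raw = stats.hypergeom.sf(k - 1, M, K, s)
    raw = np.clip(raw, np.finfo(float).tiny, 1.0)
    adj = _bh_rows(raw[None, :])[0] if adjust == "bh" else None
    results = []
    for i, (t, members) in enumerate(prepared):
        res = EnrichmentResult(
            term_id=t.term_id,
            term_name=t.name,
            category=t.category,
            raw_p=float(raw[i]),
            contributing_members=frozenset(q & members),
            adjusted_p=float(adj[i]) if adj is not None else None,
        )
        crit = res.adjusted_p if adjust == "bh" else res.raw_p
        if return_all or crit < alpha:
            results.append(res)
    results.sort(key=lambda r: (r.raw_p, r.term_id))
    return results


def random_set_calibration(
    observed_terms: Sequence[EnrichmentResult],
    set_size: int,
    annotation: AnnotationCollection,
    universe: Optional[Iterable[str]] = None,
    alpha: float = 0.01,
    n_sets: int = 1000,
    seed: int = 0,
    category: Optional[str] = None,
    adjust: Optional[str] = None,
) -> list[EnrichmentResult]:
    """Count random uniform query sets for which each observed term stays significant.

    Draws ``n_sets`` sets of ``set_size`` ids uniformly without replacement
    from the universe, re-runs the over-representation test for each (with
    the same ``adjust`` mode used for the observed analysis) and fills each
    observed term's ``random_hit_count`` and add-one empirical P-value
    ``(hits + 1) / (n_sets + 1)``.
    """
    if n_sets < 1:
        raise ValidationError("n_sets must be >= 1")
    uni_set = frozenset(universe) if universe is not None else annotation.member_universe
    uni = sorted(uni_set)
    M = len(uni)
    if set_size > M:
        raise ValidationError(f"set_size {set_size} exceeds universe size {M}")
    prepared = [(t, members) for t, members in _prepare_terms(annotation, uni_set, category) if members]
    term_ids = [t.term_id for t, _ in prepared]
    idx_of = {tid: i for i, tid in enumerate(term_ids)}
    for res in observed_terms:
        if res.term_id not in idx_of:
            raise ValidationError(f"observed term {res.term_id} not in annotation")

    # membership indicator (n_terms x M)
    pos = {u: j for j, u in enumerate(uni)}
    T = np.zeros((len(prepared), M), dtype=np.int8)
    for i, (_, members) in enumerate(prepared):
        T[i, [pos[m] for m in members]] = 1

    rng = np.random.default_rng(seed)
    K = T.sum(axis=1)
    hits = np.zeros(len(prepared), dtype=int)
    batch = max(1, min(n_sets, 512))
    done = 0
    while done < n_sets:
        b = min(batch, n_sets - done)
        Q = np.zeros((b, M), dtype=np.int8)
        for r in range(b):
            Q[r, rng.choice(M, size=set_size, replace=False)] = 1
        overlaps = Q @ T.T  # (b, n_terms)
        raw = stats.hypergeom.sf(overlaps - 1, M, K[None, :], set_size)
        raw = np.clip(raw, np.finfo(float).tiny, 1.0)
        crit = _bh_rows(raw) if adjust == "bh" else raw
        hits += (crit < alpha).sum(axis=0)
        done += b

    out = []
    for res in observed_terms:
        c = int(hits[idx_of[res.term_id]])
        out.append(
            dataclasses.replace(
                res, random_hit_count=c, empirical_p=(c + 1) / (n_sets + 1)
            )
        )
    return out


def build_target_sets(
    arterial_mirnas: Iterable[str],
    venous_mirnas: Iterable[str],
    targets: TargetMap,
    min_predictions: int = 3,
) -> TargetSets:
    """Partition evidence-filtered targets into exclusive and shared sets.

    A target passes the evidence filter iff it is experimentally validated
    or supported by at least ``min_predictions`` independent predictions.
    """
    art = set(arterial_mirnas)
    ven = set(venous_mirnas)
    if art & ven:
        raise ValidationError(f"miRNA groups overlap: {sorted(art & ven)[:5]}")
    t_art = targets.targets_of(art, min_predictions)
    t_ven = targets.targets_of(ven, min_predictions)
    return TargetSets(
        arterial_exclusive=frozenset(t_art - t_ven),
        venous_exclusive=frozenset(t_ven - t_art),
        shared=frozenset(t_art & t_ven),
    )


def best_per_parent(
    results: Sequence[EnrichmentResult],
    parent_map: Optional[dict[str, frozenset[str]]],
) -> list[EnrichmentResult]:
    """Redundancy filter: keep the most significant term per ontology parent.

    Among significant terms sharing a parent, only the one with the
    smallest raw P (term id as tie-break) is retained; a term with several
    parents survives if it wins any of its sibling groups.  Parentless
    terms are always retained.
    """
    if not parent_map:
        return list(results)
    from .datatypes import _check_acyclic

    _check_acyclic(parent_map)
    groups: dict[str, list[EnrichmentResult]] = {}
    for res in results:
        for parent in parent_map.get(res.term_id, ()):  # noqa: B905
            groups.setdefault(parent, []).append(res)
    keep_ids = {
        res.term_id for res in results if not parent_map.get(res.term_id)
    }
    for members in groups.values():
        best = min(members, key=lambda r: (r.raw_p, r.term_id))
        keep_ids.add(best.term_id)
    return [r for r in results if r.term_id in keep_ids]


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Flat TSV-ready view of enrichment results."""
    return pd.DataFrame(
        [
            {
                "term": r.term_id,
                "name": r.term_name,
                "category": r.category,
                "raw_p": r.raw_p,
                "adjusted_p": r.adjusted_p,
                "contributors": ",".join(sorted(r.contributing_members)),
                "random_hits": r.random_hit_count,
                "empirical_p": r.empirical_p,
            }
            for r in results
        ],
        columns=[
            "term", "name", "category", "raw_p", "adjusted_p",
            "contributors", "random_hits", "empirical_p",
        ],
    )
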