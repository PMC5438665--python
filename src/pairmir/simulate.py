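"""Synthetic matched-pair plasma miRNA data with planted, recoverable structure.

The generators emulate the study design this package analyzes: a small
cohort of individuals each contributing one arterial and one venous plasma
sample profiled on a ~758-miRNA array, a handful of miRNAs with small but
highly reproducible compartment differences (linear fold changes in the
1.01-1.44 range), annotation collections with planted over-representation,
a 20-tissue expression atlas with graded plasma-tissue correlation (highest
for a liver-like tissue, lowest for brain-like tissues and testicle), and
spike-in-normalized qPCR Ct tables for a larger confirmation cohort.

Noise model of the paired profiles: the log2 value of miRNA g in individual
i and compartment c is

    mu_g + a_{g,i} + (delta_g / 2) * s_c + eps

with a per-miRNA baseline mu_g ~ N(mu_mean, mu_sd), an individual effect
a_{g,i} ~ N(0, sigma_ind) shared by both samples of individual i (this is
what makes the two samples of one individual cluster together), a signed
compartment effect delta_g (zero except for planted miRNAs; s_c = +1 in the
miRNA's high compartment, -1 in the other) and technical noise
eps ~ N(0, sigma_eps) independent per measurement.

The default sigma_eps = 0.01 is calibrated so that planted fold changes in
the observed 1.01-1.44 range reach the observed significance range under a
three-pair paired t-test: a printed (fold change, P) pair implies a
difference sd of sqrt(n)*log2(FC)/t_quantile(P/2, df=n-1), and the median
implied per-sample sd across the study's discovery table is 0.009.  Larger
per-sample noise is mathematically incompatible with fold changes near 1.01
being significant, let alone sign-consistent, in three pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AnnotationCollection,
    ExpressionMatrix,
    PairedDesign,
    SamplePair,
    Term,
    TissueAtlas,
    ValidationError,
)

# Planted linear fold changes emulating the observed discovery table:
# 10 arterial-high and 14 venous-high miRNAs, fold changes 1.01-1.44.
DEFAULT_DE_FOLD_CHANGES: tuple[tuple[str, float], ...] = (
    ("arterial", 1.180), ("arterial", 1.011), ("arterial", 1.439),
    ("arterial", 1.103), ("arterial", 1.048), ("arterial", 1.019),
    ("arterial", 1.070), ("arterial", 1.020), ("arterial", 1.045),
    ("arterial", 1.035),
    ("venous", 1.050), ("venous", 1.060), ("venous", 1.020),
    ("venous", 1.056), ("venous", 1.044), ("venous", 1.095),
    ("venous", 1.032), ("venous", 1.027), ("venous", 1.019),
    ("venous", 1.024), ("venous", 1.043), ("venous", 1.083),
    ("venous", 1.062), ("venous", 1.039),
)

DEFAULT_SIGMA_IND = 0.5
DEFAULT_SIGMA_EPS = 0.01  # per-sample log2 sd; see module docstring

DEFAULT_TISSUES = (
    "Liver", "Kidney", "Heart", "Muscle", "Lung", "Spleen", "Thymus",
    "Pancreas", "Adrenal", "Intestine", "Stomach_G", "Stomach_nonG",
    "Eye", "Skin", "Cerebrum", "Cerebellum", "Brainstem", "Hippocampus",
    "DRG", "Testicle",
)

# Target Spearman correlation of each tissue profile with the plasma
# profile: liver-like maximum, brain-like tissues and testicle lowest,
# everything above 0.25.
DEFAULT_TISSUE_RHO: dict[str, float] = {
    "Liver": 0.60, "Kidney": 0.50, "Heart": 0.48, "Muscle": 0.45,
    "Lung": 0.47, "Spleen": 0.46, "Thymus": 0.42, "Pancreas": 0.44,
    "Adrenal": 0.43, "Intestine": 0.45, "Stomach_G": 0.41,
    "Stomach_nonG": 0.40, "Eye": 0.38, "Skin": 0.39, "Cerebrum": 0.30,
    "Cerebellum": 0.29, "Brainstem": 0.31, "Hippocampus": 0.28,
    "DRG": 0.32, "Testicle": 0.27,
}


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic dataset.

    ``de_mirnas`` maps each planted miRNA id to (high compartment, signed
    log2 effect delta: positive = arterial-high); ``enriched_terms`` holds
    term ids with planted over-representation; ``tissue_rho`` the target
    plasma-tissue Spearman correlations.
    """

    de_mirnas: dict[str, tuple[str, float]] = field(default_factory=dict)
    enriched_terms: frozenset[str] = frozenset()
    tissue_rho: dict[str, float] = field(default_factory=dict)

    def group_of(self, mirna: str) -> Optional[str]:
        entry = self.de_mirnas.get(mirna)
        return entry[0] if entry else None

    @property
    def arterial_mirnas(self) -> set[str]:
        return {m for m, (g, _) in self.de_mirnas.items() if g == "arterial"}

    @property
    def venous_mirnas(self) -> set[str]:
        return {m for m, (g, _) in self.de_mirnas.items() if g == "venous"}


def default_de_spec() -> list[tuple[str, float]]:
    """Default planted effects as (group, log2 delta) pairs."""
    return [(g, math.log2(fc)) for g, fc in DEFAULT_DE_FOLD_CHANGES]


def generate_paired_profiles(
    m: int = 758,
    n_pairs: int = 3,
    de_spec: Optional[Sequence[tuple[str, float]]] = None,
    sigma_ind: float = DEFAULT_SIGMA_IND,
    sigma_eps: float = DEFAULT_SIGMA_EPS,
    mu_mean: float = 8.0,
    mu_sd: float = 2.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PairedDesign, GroundTruth]:
    """Generate a log2 expression matrix for matched arterial/venous pairs.

    Planted miRNAs are placed at seed-determined positions; everything is
    bit-reproducible from ``seed``.
    """
    if de_spec is None:
        de_spec = default_de_spec()
    de_spec = list(de_spec)
    if m <= len(de_spec):
        raise ValidationError(f"m={m} must exceed the number of planted effects {len(de_spec)}")
    if sigma_ind < 0 or sigma_eps < 0:
        raise ValidationError("sigma_ind and sigma_eps must be non-negative")
    for group, delta in de_spec:
        if group not in ("arterial", "venous"):
            raise ValidationError(f"unknown group {group!r} in de_spec")
        if delta <= 0:
            raise ValidationError("planted log2 effects must be positive")
    rng = np.random.default_rng(seed)

    mirnas = [f"rno-miR-sim-{i:04d}" for i in range(m)]
    de_idx = rng.choice(m, size=len(de_spec), replace=False)
    signed = np.zeros(m)
    truth = GroundTruth()
    for idx, (group, delta) in zip(de_idx, de_spec):
        signed[idx] = delta if group == "arterial" else -delta
        truth.de_mirnas[mirnas[idx]] = (group, delta if group == "arterial" else -delta)

    mu = rng.normal(mu_mean, mu_sd, size=m) if mu_sd > 0 else np.full(m, mu_mean)
    a = rng.normal(0.0, sigma_ind, size=(m, n_pairs)) if sigma_ind > 0 else np.zeros((m, n_pairs))
    eps = rng.normal(0.0, sigma_eps, size=(m, n_pairs, 2)) if sigma_eps > 0 else np.zeros((m, n_pairs, 2))

    base = mu[:, None] + a
    arterial = base + signed[:, None] / 2.0 + eps[:, :, 0]
    venous = base - signed[:, None] / 2.0 + eps[:, :, 1]

    columns: dict[str, np.ndarray] = {}
    pairs = []
    for i in range(n_pairs):
        columns[f"A{i + 1}"] = arterial[:, i]
        columns[f"V{i + 1}"] = venous[:, i]
        pairs.append(SamplePair(f"rat{i + 1}", f"A{i + 1}", f"V{i + 1}"))
    matrix = ExpressionMatrix(pd.DataFrame(columns, index=mirnas), "log2")
    return matrix, PairedDesign(pairs), truth


def generate_annotation(
    n_terms: int,
    universe: Sequence[str],
    enriched_spec: Optional[Sequence[int]] = None,
    query: Optional[Sequence[str]] = None,
    term_size_range: tuple[int, int] = (5, 50),
    category: str = "function",
    seed: int = 0,
) -> tuple[AnnotationCollection, GroundTruth]:
    """Generate an annotation collection with optional planted enrichment.

    Non-enriched terms are uniform draws from ``universe``.  Each entry of
    ``enriched_spec`` plants one term whose overlap with ``query`` exceeds
    the uniform expectation by that many members.
    """
    universe = sorted(set(universe))
    if not universe:
        raise ValidationError("universe must be non-empty")
    enriched_spec = list(enriched_spec or [])
    if enriched_spec and not query:
        raise ValidationError("enriched_spec requires a designated query set")
    query_set = sorted(set(query or []))
    if set(query_set) - set(universe):
        raise ValidationError("query must be a subset of the universe")
    rng = np.random.default_rng(seed)
    M = len(universe)
    lo, hi = term_size_range
    hi = min(hi, M)
    lo = min(lo, hi)

    terms: list[Term] = []
    enriched_ids: set[str] = set()
    non_query = [u for u in universe if u not in set(query_set)]
    for t in range(n_terms):
        term_id = f"T{t + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        if t < len(enriched_spec):
            excess = int(enriched_spec[t])
            expected = round(size * len(query_set) / M)
            overlap = expected + excess
            if overlap > min(size, len(query_set)):
                raise ValidationError(
                    f"term {term_id}: overlap excess {excess} exceeds term/query size"
                )
            if size - overlap > len(non_query):
                raise ValidationError(f"term {term_id}: size {size} too large for universe")
            inside = rng.choice(len(query_set), size=overlap, replace=False)
            outside = rng.choice(len(non_query), size=size - overlap, replace=False)
            members = {query_set[i] for i in inside} | {non_query[i] for i in outside}
            enriched_ids.add(term_id)
        else:
            members = {universe[i] for i in rng.choice(M, size=size, replace=False)}
        terms.append(Term(term_id, f"synthetic term {t + 1}", category, frozenset(members)))
    truth = GroundTruth(enriched_terms=frozenset(enriched_ids))
    return AnnotationCollection(terms, universe=frozenset(universe)), truth


def generate_tissue_atlas(
    plasma_profile: pd.Series,
    tissue_rho: Optional[dict[str, float]] = None,
    enriched_frac: float = 0.05,
    seed: int = 0,
) -> TissueAtlas:
    """Generate a tissue x miRNA atlas with graded plasma correlation.

    Each tissue profile is drawn from a Gaussian copula against the plasma
    profile's normal scores with latent Pearson r = 2*sin(pi*rho/6), so the
    realized Spearman correlation targets ``tissue_rho`` (within about
    +/-0.1 for >= 500 miRNAs).  Per-tissue enriched lists are the
    ``enriched_frac`` fraction of miRNAs most elevated in that tissue
    relative to the across-tissue mean.
    """
    if tissue_rho is None:
        tissue_rho = dict(DEFAULT_TISSUE_RHO)
    for tissue, rho in tissue_rho.items():
        if not -1.0 < rho < 1.0:
            raise ValidationError(f"target correlation for {tissue} must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    m = len(plasma_profile)
    ranks = stats.rankdata(plasma_profile.to_numpy(float))
    z = stats.norm.ppf(ranks / (m + 1))

    rows = {}
    for tissue in tissue_rho:
        r = 2.0 * math.sin(math.pi * tissue_rho[tissue] / 6.0)
        latent = r * z + math.sqrt(1.0 - r * r) * rng.standard_normal(m)
        rows[tissue] = 8.0 + 2.0 * latent  # arbitrary log-expression-like scale
    expr = pd.DataFrame.from_dict(rows, orient="index", columns=list(plasma_profile.index))

    k = max(1, int(math.ceil(enriched_frac * m)))
    centered = expr - expr.mean(axis=0)
    enriched = {
        tissue: frozenset(centered.loc[tissue].nlargest(k).index)
        for tissue in expr.index
    }
    return TissueAtlas(expr, enriched)


def generate_qpcr(
    de_truth: GroundTruth,
    n_rats: int = 8,
    ct_noise: float = 0.1,
    mirnas: Optional[Sequence[str]] = None,
    spike_in_id: str = "cel-miR-39-3p",
    spike_ct: float = 20.0,
    base_dct: float = 5.0,
    seed: int = 0,
):
    """Generate a long-format qPCR Ct table for a confirmation cohort.

    Ct values are constructed so that the expected per-individual
    2^-ddCt (arterial vs venous reference) equals the planted linear fold
    change 2^delta of each miRNA; ``ct_noise`` is the sd of each individual
    Ct measurement (spike-in wells included).
    """
    from .qpcr import QpcrTable

    if n_rats < 2:
        raise ValidationError("qPCR cohort needs >= 2 rats")
    if ct_noise < 0:
        raise ValidationError("ct_noise must be non-negative")
    if mirnas is None:
        mirnas = sorted(de_truth.de_mirnas)
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_rats):
        individual = f"rat{i + 1}"
        for compartment, sign in (("arterial", +1.0), ("venous", -1.0)):
            ct_spike = spike_ct + (rng.normal(0.0, ct_noise) if ct_noise > 0 else 0.0)
            records.append((individual, compartment, spike_in_id, ct_spike))
            for mirna in mirnas:
                _, delta = de_truth.de_mirnas[mirna]
                # higher expression -> lower Ct
                dct = base_dct - sign * delta / 2.0
                ct = spike_ct + dct + (rng.normal(0.0, ct_noise) if ct_noise > 0 else 0.0)
                records.append((individual, compartment, mirna, ct))
    df = pd.DataFrame(records, columns=["individual", "compartment", "mirna", "ct"])
    return QpcrTable(df, spike_in_id=spike_in_id)
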