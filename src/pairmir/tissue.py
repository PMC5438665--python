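"""Plasma-tissue expression correlation and tissue-enriched intersection.

Compares a per-compartment mean plasma miRNA profile with each tissue
profile of a body-atlas resource by Spearman correlation over the miRNAs
shared between the two platforms, and reports which discovered miRNAs
appear in the atlas's tissue-enriched lists.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, PairedDesign, TissueAtlas, ValidationError
from .de import DEResult


@dataclass(frozen=True)
class TissueCorrelation:
    tissue_id: str
    rho: float
    p: float
    n_common: int  # shared miRNAs entering the correlation

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0 + 1e-12:
            raise ValidationError(f"rho out of range: {self.rho}")
        if self.n_common < 3:
            raise ValidationError("tissue correlation needs >= 3 shared miRNAs")


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation P for Spearman's rho (small n only)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    n = len(rx)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = ry[list(perm)]
        rho = float(np.dot(rx, (r - r.mean()) / r.std()) / n)
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho with a t-approximation P, exact permutation P when n < 10."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("Spearman undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    if len(x) < 10:
        p = _exact_spearman_p(x, y, rho)
    return float(rho), float(p)


def mean_compartment_profile(
    matrix: ExpressionMatrix, design: PairedDesign, compartment: str
) -> pd.Series:
    """Mean profile of one compartment across individuals (one value per miRNA)."""
    design.check_against(matrix)
    if compartment == "arterial":
        cols = design.arterial_samples
    elif compartment == "venous":
        cols = design.venous_samples
    else:
        raise ValidationError(f"unknown compartment {compartment!r}")
    return matrix.values[cols].mean(axis=1)


def correlate_plasma_tissue(
    plasma: pd.Series, atlas: TissueAtlas
) -> list[TissueCorrelation]:
    """Spearman correlation of a plasma profile with every atlas tissue.

    Only miRNAs present on both platforms enter each correlation (their
    count is reported as ``n_common``); tissues are returned in descending
    rho order with ties broken by tissue id.
    """
    results = []
    plasma_ids = set(plasma.index)
    for tissue in atlas.tissue_ids:
        common = sorted(plasma_ids & set(atlas.expression.columns))
        if len(common) < 3:
            raise ValidationError(
                f"tissue {tissue}: only {len(common)} miRNAs shared with the plasma profile"
            )
        rho, p = spearman_with_p(
            plasma[common].to_numpy(), atlas.expression.loc[tissue, common].to_numpy()
        )
        results.append(TissueCorrelation(tissue, rho, p, len(common)))
    results.sort(key=lambda r: (-r.rho, r.tissue_id))
    return results


def tissue_enriched_intersection(
    de_results: Sequence[DEResult], atlas: TissueAtlas
) -> pd.DataFrame:
    """Discovered miRNAs appearing in at least one tissue-enriched list.

    Returns one record per such miRNA with columns mirna, group, tissues
    (comma-joined, atlas order); miRNAs in no enriched list are omitted.
    """
    rows = []
    for r in de_results:
        tissues = atlas.enriched_tissues_of(r.mirna_id)
        if tissues:
            rows.append(
                {"mirna": r.mirna_id, "group": r.group, "tissues": ", ".join(tissues)}
            )
    return pd.DataFrame(rows, columns=["mirna", "group", "tissues"])


def tissue_correlation_table(
    per_compartment: dict[str, list[TissueCorrelation]]
) -> pd.DataFrame:
    """Wide per-tissue view with one rho/p column pair per compartment."""
    frames = {}
    for compartment, results in per_compartment.items():
        frames[compartment] = pd.DataFrame(
            {
                "tissue": [r.tissue_id for r in results],
                f"rho_{compartment}": [r.rho for r in results],
                f"p_{compartment}": [r.p for r in results],
                "n_common": [r.n_common for r in results],
            }
        ).set_index("tissue")
    out = pd.concat(frames.values(), axis=1)
    out = out.loc[:, ~out.columns.duplicated()]
    return out.reset_index()
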