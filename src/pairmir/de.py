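"""Paired differential expression between arterial and venous plasma.

The core comparison is a per-miRNA paired t-test across individuals on
(quantile-normalized, log2) intensities, with fold changes reported on the
linear scale as larger-mean over smaller-mean and a consistency flag marking
miRNAs whose arterial-venous difference has the same strict sign in every
individual.  No multiplicity adjustment is applied by default: the matched
design is deliberately tested at a raw two-sided P cutoff (default 0.025)
and the discovery count is calibrated separately against a shuffle null
(see :mod:`pairmir.nullcount`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, PairedDesign, ValidationError


@dataclass(frozen=True)
class DEResult:
    """One differentially expressed miRNA (one row of the discovery table)."""

    mirna_id: str
    group: str  # compartment with the larger mean: "arterial" | "venous"
    fold_change: float  # linear ratio >= 1, larger mean over smaller
    p_value: float
    consistent: bool


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample's value distribution to the mean sorted distribution.

    After normalization every column's sorted values equal the across-sample
    mean of sorted values; ties within a sample receive the mean of the
    reference quantile values they span.
    """
    if matrix.n_samples < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    values = matrix.values.to_numpy(float)
    order = np.sort(values, axis=0)
    reference = order.mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        # positions of each value in the sorted column
        sorter = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[sorter] = reference
        # average the reference values across tied positions
        s = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = s.to_numpy()
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.scale,
    )


def _paired_t_arrays(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-sample t on difference rows; zero-variance rows get t=0, P=1."""
    diffs = np.atleast_2d(diffs)
    n = diffs.shape[1]
    if n < 2:
        raise ValidationError("paired test needs >= 2 pairs")
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    t = np.zeros(diffs.shape[0])
    p = np.ones(diffs.shape[0])
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    return t, np.clip(p, np.finfo(float).tiny, 1.0)


def paired_t(arterial: Sequence[float], venous: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test; returns (t, P) with df = n - 1.

    All-equal pairs (zero-variance differences) return (0.0, 1.0) rather than
    dividing by zero, so degenerate miRNAs are never called significant.
    """
    a = np.asarray(arterial, float)
    v = np.asarray(venous, float)
    if a.shape != v.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {v.shape}")
    t, p = _paired_t_arrays((a - v)[None, :])
    return float(t[0]), float(p[0])


def fold_change(
    arterial: Sequence[float], venous: Sequence[float], scale: str = "log2"
) -> tuple[float, str]:
    """Linear fold change (>= 1) and the compartment with the larger mean.

    For log2 inputs the ratio is the antilog of the difference of mean log2
    values (a geometric-mean ratio); for linear inputs it is the ratio of
    arithmetic means.  Equal means return (1.0, "tie").
    """
    a = np.asarray(arterial, float)
    v = np.asarray(venous, float)
    if a.shape != v.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {v.shape}")
    if scale == "log2":
        d = a.mean() - v.mean()
        if d == 0:
            return 1.0, "tie"
        return float(2.0 ** abs(d)), "arterial" if d > 0 else "venous"
    ma, mv = a.mean(), v.mean()
    if ma == mv:
        return 1.0, "tie"
    if min(ma, mv) <= 0:
        raise ValidationError("fold change undefined: non-positive group mean on linear scale")
    return float(max(ma, mv) / min(ma, mv)), "arterial" if ma > mv else "venous"


def consistency(arterial: Sequence[float], venous: Sequence[float]) -> bool:
    """True iff every per-pair arterial-venous difference has the same strict sign."""
    d = np.asarray(arterial, float) - np.asarray(venous, float)
    return bool((d > 0).all() or (d < 0).all())


def call_de(
    matrix: ExpressionMatrix,
    design: PairedDesign,
    alpha: float = 0.025,
    adjust: Optional[str] = None,
) -> list[DEResult]:
    """Call differentially expressed miRNAs between the two compartments.

    Runs a per-miRNA two-sided paired t-test across individuals and returns
    one :class:`DEResult` for every miRNA whose (optionally BH-adjusted)
    P-value is below ``alpha`` and whose group is not a tie, sorted arterial
    group first, then ascending P, then miRNA id.
    """
    if not 0 <= alpha <= 1:
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    if design.n_pairs < 2:
        raise ValidationError("paired test needs >= 2 pairs")
    if adjust not in (None, "bh"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    design.check_against(matrix)
    A = matrix.values[design.arterial_samples].to_numpy(float)
    V = matrix.values[design.venous_samples].to_numpy(float)
    diffs = A - V
    _, p = _paired_t_arrays(diffs)
    if adjust == "bh":
        from .enrichment import bh_adjust

        p_sel = np.asarray(bh_adjust(list(p)))
    else:
        p_sel = p
    mean_d = A.mean(axis=1) - V.mean(axis=1)
    consistent = (diffs > 0).all(axis=1) | (diffs < 0).all(axis=1)
    if matrix.scale == "log2":
        fc = 2.0 ** np.abs(mean_d)
    else:
        ma, mv = A.mean(axis=1), V.mean(axis=1)
        hi = np.maximum(ma, mv)
        lo = np.minimum(ma, mv)
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(lo > 0, hi / np.where(lo > 0, lo, 1.0), np.inf)
    results = []
    ids = matrix.mirna_ids
    for i in np.nonzero((p_sel < alpha) & (mean_d != 0))[0]:
        group = "arterial" if mean_d[i] > 0 else "venous"
        results.append(
            DEResult(ids[i], group, float(fc[i]), float(p[i]), bool(consistent[i]))
        )
    results.sort(key=lambda r: (r.group != "arterial", r.p_value, r.mirna_id))
    return results


def de_table(results: Sequence[DEResult]) -> pd.DataFrame:
    """Discovery-table DataFrame (mirna, group, fold_change, p_value, consistent)."""
    return pd.DataFrame(
        [
            {
                "mirna": r.mirna_id,
                "group": r.group,
                "fold_change": r.fold_change,
                "p_value": r.p_value,
                "consistent": r.consistent,
            }
            for r in results
        ],
        columns=["mirna", "group", "fold_change", "p_value", "consistent"],
    )


def profile_correlation(
    matrix: ExpressionMatrix, design: PairedDesign, method: str = "mean"
) -> tuple[float, float]:
    """Spearman correlation between the arterial and venous expression profiles.

    ``method="mean"`` correlates the per-compartment mean profile across
    miRNAs (one value per miRNA per compartment); ``method="pooled"`` stacks
    every individual's paired profiles and correlates the pooled vectors.
    """
    design.check_against(matrix)
    if matrix.n_mirnas < 3:
        raise ValidationError("profile correlation needs >= 3 miRNAs")
    A = matrix.values[design.arterial_samples].to_numpy(float)
    V = matrix.values[design.venous_samples].to_numpy(float)
    if method == "mean":
        x, y = A.mean(axis=1), V.mean(axis=1)
    elif method == "pooled":
        x, y = A.ravel(order="F"), V.ravel(order="F")
    else:
        raise ValidationError(f"unknown method {method!r}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("profile correlation undefined for a constant profile")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
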