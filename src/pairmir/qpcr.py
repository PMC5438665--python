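"""Spike-in-normalized relative quantification (2^-ddCt) for qPCR tables.

Each sample's target Ct is normalized against an exogenous spike-in
control; per-individual ddCt values compare the test compartment with the
reference compartment, folds are antilogged base 2, and significance comes
from a two-sided paired t-test on the per-individual dCt pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import COMPARTMENTS, ValidationError
from .de import DEResult, paired_t


@dataclass
class QpcrTable:
    """Long-format Ct records: (individual, compartment, mirna, ct)."""

    records: pd.DataFrame
    spike_in_id: str = "cel-miR-39-3p"

    def __post_init__(self) -> None:
        required = ["individual", "compartment", "mirna", "ct"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ValidationError(f"qPCR table missing columns: {missing}")
        self.records = self.records[required].copy()
        self.records["ct"] = self.records["ct"].astype(float)
        bad = ~self.records["compartment"].isin(COMPARTMENTS)
        if bad.any():
            raise ValidationError(
                f"unknown compartments: {sorted(self.records.loc[bad, 'compartment'].unique())}"
            )
        if (self.records["ct"] <= 0).any():
            raise ValidationError("Ct values must be positive")
        if self.records.duplicated(["individual", "compartment", "mirna"]).any():
            raise ValidationError("duplicate (individual, compartment, mirna) Ct records")
        for (ind, comp), grp in self.records.groupby(["individual", "compartment"]):
            if self.spike_in_id not in set(grp["mirna"]):
                raise ValidationError(
                    f"missing spike-in {self.spike_in_id} Ct for sample ({ind}, {comp})"
                )

    @property
    def individuals(self) -> list[str]:
        return sorted(self.records["individual"].unique())

    @property
    def target_mirnas(self) -> list[str]:
        return sorted(set(self.records["mirna"]) - {self.spike_in_id})

    def ct_of(self, individual: str, compartment: str, mirna: str) -> float:
        sel = self.records[
            (self.records["individual"] == individual)
            & (self.records["compartment"] == compartment)
            & (self.records["mirna"] == mirna)
        ]
        if len(sel) != 1:
            raise ValidationError(f"no Ct for ({individual}, {compartment}, {mirna})")
        return float(sel["ct"].iloc[0])


@dataclass(frozen=True)
class DdctResult:
    mirna_id: str
    folds: tuple[float, ...]  # per-individual 2^-ddCt
    fold: float  # geometric mean of per-individual folds
    p_value: float
    direction: str  # compartment with the smaller mean dCt (higher expression)
    reference_compartment: str

    @property
    def stars(self) -> str:
        for stars, cutoff in (("***", 0.001), ("**", 0.01), ("*", 0.05)):
            if self.p_value < cutoff:
                return stars
        return ""


def ddct(
    table: QpcrTable,
    target: str,
    reference_compartment: str = "venous",
    paired: bool = True,
) -> DdctResult:
    """Relative expression of ``target`` by the 2^-ddCt method.

    dCt = Ct(target) - Ct(spike-in) per sample; per-individual
    ddCt = dCt(test) - dCt(reference); fold = 2^-ddCt, summarized as the
    geometric mean.  Significance is a two-sided paired t-test on the
    per-individual dCt pairs (set ``paired=False`` for the unpaired
    alternative).
    """
    if reference_compartment not in COMPARTMENTS:
        raise ValidationError(f"unknown compartment {reference_compartment!r}")
    test = "arterial" if reference_compartment == "venous" else "venous"
    dct = {c: [] for c in COMPARTMENTS}
    for ind in table.individuals:
        for comp in COMPARTMENTS:
            value = table.ct_of(ind, comp, target) - table.ct_of(
                ind, comp, table.spike_in_id
            )
            dct[comp].append(value)
    d_test = np.array(dct[test])
    d_ref = np.array(dct[reference_compartment])
    ddct_per_ind = d_test - d_ref
    folds = 2.0 ** (-ddct_per_ind)
    fold = float(2.0 ** (-ddct_per_ind.mean()))  # geometric mean of folds
    if paired:
        _, p = paired_t(d_test, d_ref)
    else:
        from scipy import stats

        if d_test.std(ddof=1) == 0 and d_ref.std(ddof=1) == 0:
            p = 1.0
        else:
            _, p = stats.ttest_ind(d_test, d_ref)
    mean_diff = d_test.mean() - d_ref.mean()
    if mean_diff < 0:
        direction = test  # lower dCt = higher expression
    elif mean_diff > 0:
        direction = reference_compartment
    else:
        direction = "tie"
    return DdctResult(
        mirna_id=target,
        folds=tuple(float(f) for f in folds),
        fold=fold,
        p_value=float(p),
        direction=direction,
        reference_compartment=reference_compartment,
    )


def ddct_all(
    table: QpcrTable, reference_compartment: str = "venous", paired: bool = True
) -> list[DdctResult]:
    return [
        ddct(table, t, reference_compartment, paired) for t in table.target_mirnas
    ]


def concordance(
    qpcr_results: Sequence[DdctResult], de_results: Sequence[DEResult]
) -> pd.DataFrame:
    """Per-miRNA agreement between qPCR direction and discovery group.

    One row per miRNA present in both result sets, with ``concordant`` true
    iff the qPCR direction equals the discovery group label.
    """
    de_group = {r.mirna_id: r.group for r in de_results}
    rows = []
    for q in qpcr_results:
        if q.mirna_id in de_group:
            rows.append(
                {
                    "mirna": q.mirna_id,
                    "qpcr_direction": q.direction,
                    "de_group": de_group[q.mirna_id],
                    "fold": q.fold,
                    "p_value": q.p_value,
                    "significance": q.stars,
                    "concordant": q.direction == de_group[q.mirna_id],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna", "qpcr_direction", "de_group", "fold",
            "p_value", "significance", "concordant",
        ],
    )
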