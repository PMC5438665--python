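"""Pipeline orchestration: config, full run, and the sample-clustering report.

``run_pipeline`` composes every stage — normalization, paired discovery,
shuffle-null calibration, miRNA- and target-set over-representation with
random-set calibration, tissue correlation, and qPCR confirmation — from a
single config whose defaults are the analysis thresholds this pipeline is
built around (paired-t alpha 0.025, term alpha 0.01, BH 0.05 for gene
terms, 100 shuffles, 1000 random sets, evidence filter at 3 predictions).
Stages whose inputs are not configured are skipped with a logged warning;
one master seed determines every stochastic stage.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import io as pio
from .datatypes import ExpressionMatrix, PairedDesign, ValidationError
from .de import call_de, de_table, profile_correlation, quantile_normalize
from .enrichment import (
    build_target_sets,
    best_per_parent,
    enrichment_table,
    map_orthologs,
    ora,
    random_set_calibration,
)
from .nullcount import null_de_counts
from .qpcr import concordance, ddct_all
from .tissue import (
    correlate_plasma_tissue,
    mean_compartment_profile,
    tissue_correlation_table,
    tissue_enriched_intersection,
)

logger = logging.getLogger("pairmir")


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run."""

    matrix: Optional[str] = None
    matrix_scale: str = "linear"
    design: Optional[str] = None
    mirna_function_gmt: Optional[str] = None
    mirna_disease_gmt: Optional[str] = None
    orthologs: Optional[str] = None
    targets: Optional[str] = None
    gene_function_gmt: Optional[str] = None
    parent_map: Optional[str] = None
    atlas_expression: Optional[str] = None
    atlas_enriched: Optional[str] = None
    qpcr: Optional[str] = None
    spike_in_id: str = "cel-miR-39-3p"
    out_dir: str = "pairmir_results"

    normalize: bool = True
    alpha_de: float = 0.025
    alpha_term: float = 0.01
    alpha_gene_bh: float = 0.05
    n_shuffle: int = 100
    n_random_sets: int = 1000
    min_predictions: int = 3
    collapse_families: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_de", "alpha_term", "alpha_gene_bh"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        for name in ("n_shuffle", "n_random_sets", "min_predictions"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class ClusterReport:
    """Average-linkage sample clustering plus the row-scaled report table."""

    linkage: np.ndarray  # scipy linkage matrix over samples
    sample_ids: list[str]
    scaled: pd.DataFrame  # rows centered to mean 0, variance 1
    distance: pd.DataFrame  # 1 - Pearson sample-sample distance
    dropped_rows: list[str] = field(default_factory=list)

    def leaf_order(self) -> list[str]:
        return [self.sample_ids[i] for i in hierarchy.leaves_list(self.linkage)]


def cluster_samples(
    matrix: ExpressionMatrix, mirna_subset: Optional[Sequence[str]] = None
) -> ClusterReport:
    """Cluster samples by 1 - Pearson correlation with average linkage.

    Rows (miRNAs) constant across samples carry no correlation signal and
    are dropped with a warning; the report table is row-scaled to mean 0
    and unit variance.
    """
    if mirna_subset is not None:
        subset = [m for m in mirna_subset if m in matrix.values.index]
        if not subset:
            raise ValidationError("mirna_subset shares no ids with the matrix")
        values = matrix.values.loc[subset]
    else:
        values = matrix.values
    sd = values.std(axis=1, ddof=0)
    dropped = list(values.index[sd == 0])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant rows from the clustering distance",
            stacklevel=2,
        )
        values = values.loc[sd > 0]
    if values.shape[0] == 0:
        raise ValidationError("no variable rows left for clustering")
    corr = np.corrcoef(values.to_numpy(float).T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    scaled = values.sub(values.mean(axis=1), axis=0).div(
        values.std(axis=1, ddof=0), axis=0
    )
    samples = list(values.columns)
    return ClusterReport(
        linkage=Z,
        sample_ids=samples,
        scaled=scaled,
        distance=pd.DataFrame(dist, index=samples, columns=samples),
        dropped_rows=dropped,
    )


def mutual_nearest_fraction(report: ClusterReport, design: PairedDesign) -> float:
    """Fraction of individuals whose two samples are mutual nearest neighbors."""
    D = report.distance.copy()
    np.fill_diagonal(D.values, np.inf)
    nearest = D.idxmin(axis=1)
    hits = 0
    for pair in design.pairs:
        if nearest[pair.arterial] == pair.venous and nearest[pair.venous] == pair.arterial:
            hits += 1
    return hits / design.n_pairs


def _concat_frames(frames: list[pd.DataFrame]) -> pd.DataFrame:
    non_empty = [f for f in frames if not f.empty]
    if non_empty:
        return pd.concat(non_empty, ignore_index=True)
    return frames[0] if frames else pd.DataFrame()


def _stage_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence(master).generate_state(index + 1)[index] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every configured stage and write all result tables to ``out_dir``.

    Returns the result bundle as a dict of DataFrames.  The discovery stage
    (matrix + design) is mandatory; all other stages are skipped with a
    warning when their inputs are not configured.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"seed\t{config.seed}"]
    bundle: dict[str, pd.DataFrame] = {}

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    if not config.matrix or not config.design:
        raise ValidationError("pipeline stage 'de': matrix and design paths are required")

    try:
        matrix = pio.read_expression_matrix(config.matrix, scale=config.matrix_scale)
        design = pio.read_paired_design(config.design)
        if config.normalize:
            matrix = quantile_normalize(matrix)
        if matrix.scale == "linear":
            matrix = matrix.to_log2()
        log(f"matrix: {matrix.n_mirnas} miRNAs x {matrix.n_samples} samples ({matrix.scale})")

        de_results = call_de(matrix, design, alpha=config.alpha_de)
        table1 = de_table(de_results)
        rho, p = profile_correlation(matrix, design)
        log(
            f"de: {len(de_results)} discoveries at alpha={config.alpha_de} "
            f"({sum(r.group == 'arterial' for r in de_results)} arterial, "
            f"{sum(r.group == 'venous' for r in de_results)} venous); "
            f"profile Spearman rho={rho:.3f} (P={p:.3g})"
        )
        table1.to_csv(out / "differential_expression.tsv", sep="\t", index=False)
        bundle["differential_expression"] = table1
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'de' failed: {exc}") from exc

    try:
        null = null_de_counts(
            matrix, design, alpha=config.alpha_de,
            n_iter=config.n_shuffle, seed=_stage_seed(config.seed, 0),
        )
        null.counts.to_csv(out / "null_counts.tsv", sep="\t", index=False)
        summary = null.summary_frame()
        summary.to_csv(out / "null_summary.tsv", sep="\t", index=False)
        bundle["null_summary"] = summary
        log(
            f"nullcount: observed {null.observed_total} vs null mean "
            f"{null.mean():.2f} +/- {null.se():.2f} over {null.n_iterations} shuffles"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'nullcount' failed: {exc}") from exc

    arterial_ids = {r.mirna_id for r in de_results if r.group == "arterial"}
    venous_ids = {r.mirna_id for r in de_results if r.group == "venous"}

    # miRNA-level term enrichment (per compartment group, per category)
    gmt_specs = [
        ("function", config.mirna_function_gmt),
        ("disease", config.mirna_disease_gmt),
    ]
    if any(path for _, path in gmt_specs):
        try:
            orthologs = (
                pio.read_ortholog_map(config.orthologs) if config.orthologs else None
            )
            frames = []
            for category, path in gmt_specs:
                if not path:
                    continue
                annotation = pio.read_gmt(path, category=category)
                for group, ids in (("arterial", arterial_ids), ("venous", venous_ids)):
                    mapped, unmapped = map_orthologs(ids, orthologs)
                    if unmapped:
                        log(f"enrich-mirna [{category}/{group}]: unmapped ids {unmapped}")
                    hits = ora(
                        mapped, annotation, alpha=config.alpha_term,
                        category=category,
                        collapse_families=config.collapse_families,
                    )
                    hits = random_set_calibration(
                        hits, set_size=max(len(mapped), 1), annotation=annotation,
                        alpha=config.alpha_term, n_sets=config.n_random_sets,
                        seed=_stage_seed(config.seed, 1), category=category,
                    )
                    f = enrichment_table(hits)
                    f.insert(0, "group", group)
                    frames.append(f)
                    log(f"enrich-mirna [{category}/{group}]: {len(hits)} significant terms")
            mirna_enrichment = _concat_frames(frames)
            mirna_enrichment.to_csv(out / "mirna_enrichment.tsv", sep="\t", index=False)
            bundle["mirna_enrichment"] = mirna_enrichment
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'enrich-mirna' failed: {exc}") from exc
    else:
        log("enrich-mirna: skipped (no miRNA annotation configured)")

    # target-set enrichment
    if config.targets and config.gene_function_gmt:
        try:
            targets = pio.read_target_map(config.targets)
            gene_annotation = pio.read_gmt(config.gene_function_gmt, category="gene_function")
            parent_map = (
                pio.read_parent_map(config.parent_map) if config.parent_map else None
            )
            if parent_map:
                gene_annotation.parent_map = parent_map
            sets = build_target_sets(
                arterial_ids, venous_ids, targets, config.min_predictions
            )
            log(
                f"targets: {len(sets.arterial_exclusive)} arterial-exclusive, "
                f"{len(sets.venous_exclusive)} venous-exclusive, {len(sets.shared)} shared"
            )
            pd.DataFrame(
                {
                    "set": ["arterial_exclusive", "venous_exclusive", "shared"],
                    "size": [
                        len(sets.arterial_exclusive),
                        len(sets.venous_exclusive),
                        len(sets.shared),
                    ],
                }
            ).to_csv(out / "target_sets.tsv", sep="\t", index=False)
            frames = []
            for name, gene_set in (
                ("arterial_exclusive", sets.arterial_exclusive),
                ("venous_exclusive", sets.venous_exclusive),
                ("shared", sets.shared),
            ):
                if not gene_set:
                    continue
                hits = ora(
                    gene_set, gene_annotation, alpha=config.alpha_gene_bh,
                    category="gene_function", adjust="bh",
                )
                hits = best_per_parent(hits, parent_map)
                hits = random_set_calibration(
                    hits, set_size=len(gene_set), annotation=gene_annotation,
                    alpha=config.alpha_gene_bh, n_sets=config.n_random_sets,
                    seed=_stage_seed(config.seed, 2), category="gene_function",
                    adjust="bh",
                )
                f = enrichment_table(hits)
                f.insert(0, "target_set", name)
                frames.append(f)
                log(f"enrich-targets [{name}]: {len(hits)} significant terms")
            target_enrichment = _concat_frames(frames)
            target_enrichment.to_csv(out / "target_enrichment.tsv", sep="\t", index=False)
            bundle["target_enrichment"] = target_enrichment
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'enrich-targets' failed: {exc}") from exc
    else:
        log("enrich-targets: skipped (no target map / gene annotation configured)")

    # tissue correlation
    if config.atlas_expression:
        try:
            atlas = pio.read_tissue_atlas(config.atlas_expression, config.atlas_enriched)
            per_compartment = {}
            for compartment in ("arterial", "venous"):
                profile = mean_compartment_profile(matrix, design, compartment)
                per_compartment[compartment] = correlate_plasma_tissue(profile, atlas)
            fig6 = tissue_correlation_table(per_compartment)
            fig6.to_csv(out / "tissue_correlation.tsv", sep="\t", index=False)
            bundle["tissue_correlation"] = fig6
            table2 = tissue_enriched_intersection(de_results, atlas)
            table2.to_csv(out / "tissue_enriched.tsv", sep="\t", index=False)
            bundle["tissue_enriched"] = table2
            top = per_compartment["arterial"][0]
            log(
                f"tissue: top arterial correlation {top.tissue_id} rho={top.rho:.3f}; "
                f"{len(table2)} discoveries in enriched lists"
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'tissue' failed: {exc}") from exc
    else:
        log("tissue: skipped (no atlas configured)")

    # qPCR confirmation
    if config.qpcr:
        try:
            from .qpcr import QpcrTable  # local import to avoid cycle at module load

            df = pio._read_tsv(config.qpcr)
            df["ct"] = df["ct"].astype(float)
            table = QpcrTable(df, spike_in_id=config.spike_in_id)
            q_results = ddct_all(table)
            conc = concordance(q_results, de_results)
            conc.to_csv(out / "qpcr_confirmation.tsv", sep="\t", index=False)
            bundle["qpcr_confirmation"] = conc
            log(
                f"qpcr: {len(q_results)} targets, "
                f"{int(conc['concordant'].sum()) if len(conc) else 0} concordant with discovery"
            )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage 'qpcr' failed: {exc}") from exc
    else:
        log("qpcr: skipped (no qPCR table configured)")

    # clustering report on the discovered miRNAs (all miRNAs when none)
    try:
        subset = sorted(arterial_ids | venous_ids) or None
        report = cluster_samples(matrix, subset)
        report.scaled.to_csv(out / "heatmap_rows.tsv", sep="\t")
        merges = pd.DataFrame(
            report.linkage, columns=["left", "right", "distance", "size"]
        )
        merges.to_csv(out / "sample_linkage.tsv", sep="\t", index=False)
        bundle["sample_linkage"] = merges
        log(f"cluster: leaf order {report.leaf_order()}")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'cluster' failed: {exc}") from exc

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return bundle
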