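"""Readers and writers for the pipeline's file formats.

All tabular files are tab-separated UTF-8 with ``#`` comment lines ignored;
annotation collections use the standard GMT dialect
(``term_id<TAB>description<TAB>member1<TAB>member2...``).  Readers validate
through the domain types and are inverse to the corresponding writers on
valid files.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .datatypes import (
    AnnotationCollection,
    ExpressionMatrix,
    OrthologMap,
    PairedDesign,
    ParseError,
    SamplePair,
    TargetMap,
    Term,
    TissueAtlas,
)

PathLike = Union[str, Path]


def _read_tsv(path: PathLike, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed TSV: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc


# ---------------------------------------------------------------------------
# expression matrix


def read_expression_matrix(path: PathLike, scale: str = "linear") -> ExpressionMatrix:
    """Read a miRNA x sample TSV (first column miRNA ids, header sample ids)."""
    df = _read_tsv(path, index_col=0)
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell: {exc}") from exc
    return ExpressionMatrix(values, scale)


def write_expression_matrix(matrix: ExpressionMatrix, path: PathLike) -> None:
    out = matrix.values.copy()
    out.index.name = "mirna"
    out.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# paired design


def read_paired_design(path: PathLike) -> PairedDesign:
    df = _read_tsv(path)
    required = ["individual", "arterial_sample", "venous_sample"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: design file missing columns {missing}")
    pairs = [
        SamplePair(str(r.individual), str(r.arterial_sample), str(r.venous_sample))
        for r in df.itertuples()
    ]
    return PairedDesign(pairs)


def write_paired_design(design: PairedDesign, path: PathLike) -> None:
    df = pd.DataFrame(
        {
            "individual": design.individuals,
            "arterial_sample": design.arterial_samples,
            "venous_sample": design.venous_samples,
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT annotation


def read_gmt(path: PathLike, category: str = "function") -> AnnotationCollection:
    """Read a GMT file; every line becomes one term of the given category."""
    terms: list[Term] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, got {len(fields)}"
                )
            term_id, name, *members = fields
            members = [m for m in members if m]
            terms.append(Term(term_id, name, category, frozenset(members)))
    return AnnotationCollection(terms)


def write_gmt(annotation: AnnotationCollection, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in annotation.terms:
            fh.write("\t".join([t.term_id, t.name, *sorted(t.members)]) + "\n")


def read_parent_map(path: PathLike) -> dict[str, frozenset[str]]:
    """Read a TSV with columns term, parent (one edge per line)."""
    df = _read_tsv(path)
    missing = [c for c in ("term", "parent") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: parent map missing columns {missing}")
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.term), set()).add(str(r.parent))
    return {k: frozenset(v) for k, v in out.items()}


def write_parent_map(parent_map: dict[str, frozenset[str]], path: PathLike) -> None:
    rows = [(t, p) for t in sorted(parent_map) for p in sorted(parent_map[t])]
    pd.DataFrame(rows, columns=["term", "parent"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# target map


def read_target_map(path: PathLike) -> TargetMap:
    df = _read_tsv(path)
    required = ["mirna", "target", "validated", "n_predictions"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: target map missing columns {missing}")
    try:
        df["validated"] = df["validated"].astype(int).astype(bool)
        df["n_predictions"] = df["n_predictions"].astype(int)
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer evidence field: {exc}") from exc
    return TargetMap(df)


def write_target_map(targets: TargetMap, path: PathLike) -> None:
    out = targets.records.copy()
    out["validated"] = out["validated"].astype(int)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# tissue atlas (expression TSV + enriched-list GMT)


def read_tissue_atlas(
    expression_path: PathLike, enriched_path: Optional[PathLike] = None
) -> TissueAtlas:
    df = _read_tsv(expression_path, index_col=0)
    try:
        expr = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{expression_path}: non-numeric cell: {exc}") from exc
    enriched: dict[str, frozenset[str]] = {}
    if enriched_path is not None:
        gmt = read_gmt(enriched_path, category="function")
        enriched = {t.term_id: t.members for t in gmt.terms}
    return TissueAtlas(expr, enriched)


def write_tissue_atlas(
    atlas: TissueAtlas, expression_path: PathLike, enriched_path: Optional[PathLike] = None
) -> None:
    out = atlas.expression.copy()
    out.index.name = "tissue"
    out.to_csv(expression_path, sep="\t", float_format="%.10g")
    if enriched_path is not None:
        with open(enriched_path, "w", encoding="utf-8") as fh:
            for tissue in atlas.tissue_ids:
                members = atlas.enriched.get(tissue, frozenset())
                if members:
                    fh.write("\t".join([tissue, "enriched", *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# ortholog map


def read_ortholog_map(path: PathLike) -> OrthologMap:
    df = _read_tsv(path)
    missing = [c for c in ("rat", "human") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: ortholog table missing columns {missing}")
    return OrthologMap(dict(zip(df["rat"].astype(str), df["human"].astype(str))))


def write_ortholog_map(orthologs: OrthologMap, path: PathLike) -> None:
    rows = sorted(orthologs.mapping.items())
    pd.DataFrame(rows, columns=["rat", "human"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# id lists


def read_id_list(path: PathLike) -> list[str]:
    """One identifier per line; blank and '#' lines ignored."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_id_list(ids, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i in ids:
            fh.write(f"{i}\n")
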