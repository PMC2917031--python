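"""Readers and writers for every table the pipeline touches.

All formats are plain tab-delimited text with a header row, full-precision
"." decimals, and empty cells for missing values; gene sets use standard
GMT (name, description, symbols...).  Readers never reorder rows or
columns, so ``read(write(x))`` round-trips bit-for-bit at the printed
precision.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    BetaMatrix,
    CentroidSet,
    ExpressionMatrix,
    FeatureMatrix,
    GeneSet,
    RelativeMatrix,
    SampleAnnotation,
    TernaryMatrix,
    annotations_to_frame,
)

logger = logging.getLogger(__name__)

_ANNOTATION_FIELDS = [f.name for f in dataclasses.fields(SampleAnnotation)]


def _read_feature_table(path, gene_column: str) -> tuple[pd.DataFrame, pd.Series]:
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature id(s) in {path}: {dup[:5]}")
    if gene_column not in raw.columns:
        raise ValueError(f"gene annotation column {gene_column!r} not found in {path}")
    genes = raw[gene_column].str.strip()
    data = raw.drop(columns=[gene_column])
    values = data.replace("", np.nan).apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & (data != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell in {path} at row {data.index[r]!r}, "
            f"column {data.columns[c]!r}: {data.iat[r, c]!r}"
        )
    return values, genes


def read_beta_matrix(path, gene_column: str = "gene") -> BetaMatrix:
    """Read a CpG x sample beta-value matrix.

    First column holds CpG ids, ``gene_column`` the gene symbol, remaining
    columns one sample each.  Empty cells become missing; any value outside
    [0, 1] is rejected with its coordinates.
    """
    values, genes = _read_feature_table(path, gene_column)
    return BetaMatrix(values, genes)


def read_ternary_matrix(path, gene_column: str = "gene") -> TernaryMatrix:
    values, genes = _read_feature_table(path, gene_column)
    return TernaryMatrix(values, genes)


def read_relative_matrix(path, gene_column: str = "gene") -> RelativeMatrix:
    values, genes = _read_feature_table(path, gene_column)
    return RelativeMatrix(values, genes)


def read_expression(path, gene_column: str = "gene") -> ExpressionMatrix:
    """Read a probe x sample relative-expression matrix with a probe->gene map."""
    values, genes = _read_feature_table(path, gene_column)
    return ExpressionMatrix(values, genes)


def write_feature_matrix(matrix: FeatureMatrix, path, gene_column: str = "gene") -> None:
    """Write any feature matrix as TSV (feature id, gene symbol, samples...)."""
    out = matrix.values.copy()
    out.insert(0, gene_column, matrix.feature_gene)
    out.to_csv(path, sep="\t", index_label="id", float_format="%.10g")


write_beta_matrix = write_feature_matrix
write_expression = write_feature_matrix


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file: name, description, then symbols."""
    sets: list[GeneSet] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, _description, *symbols = fields
            symbols = [s for s in symbols if s.strip()]
            if len(symbols) != len(set(s.strip().upper() for s in symbols)):
                logger.warning("%s:%d: duplicated symbols in set %r deduplicated",
                               path, lineno, name)
            sets.append(GeneSet.from_symbols(name, symbols))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as handle:
        for gs in sets:
            handle.write("\t".join([gs.name, "na", *sorted(gs.symbols)]) + "\n")


def read_annotation(path) -> list[SampleAnnotation]:
    """Read a sample annotation table; unknown categorical values fold to "unknown"."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in frame.columns:
        frame = frame.rename(columns={frame.columns[0]: "sample_id"})
    if frame["sample_id"].duplicated().any():
        dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample id(s) in {path}: {dup[:5]}")
    annotations = []
    for _, row in frame.iterrows():
        kwargs = {}
        for name in _ANNOTATION_FIELDS:
            if name in row.index and row[name] != "":
                value = row[name]
                if name in ("age", "size_mm"):
                    value = float(value)
                kwargs[name] = value
        annotations.append(SampleAnnotation(**kwargs))
    return annotations


def write_annotation(annotations: list[SampleAnnotation], path) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", float_format="%.10g")


def read_centroids(path) -> CentroidSet:
    """Read a gene x subtype centroid table (first column gene symbols)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return CentroidSet(frame)


def write_centroids(centroids: CentroidSet, path) -> None:
    centroids.centroid_values.to_csv(path, sep="\t", index_label="gene",
                                     float_format="%.10g")


def intersect_samples(*objects):
    """Restrict matrices/annotation lists to their shared samples, in the
    order of the first object; unmatched samples are dropped with a logged
    count (the study itself analyses nested sample subsets)."""
    def ids(obj):
        if isinstance(obj, FeatureMatrix):
            return list(obj.sample_ids)
        return [a.sample_id for a in obj]

    shared = set(ids(objects[0]))
    for obj in objects[1:]:
        shared &= set(ids(obj))
    order = [s for s in ids(objects[0]) if s in shared]
    result = []
    for obj in objects:
        dropped = len(ids(obj)) - len(order)
        if dropped:
            logger.info("dropping %d unmatched sample(s)", dropped)
        if isinstance(obj, FeatureMatrix):
            result.append(obj.subset_samples(order))
        else:
            by_id = {a.sample_id: a for a in obj}
            result.append([by_id[s] for s in order])
    return tuple(result)
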