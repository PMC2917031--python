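"""Nearest-centroid single-sample-predictor (SSP) subtype classification.

Each expression profile is correlated (Pearson) with every subtype
centroid over the genes shared between the expression matrix and the
centroid table; the sample is assigned to the best-correlated subtype,
or left "non-classified" when every correlation falls below the cutoff
(0.2 by convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import _corr_columns
from .containers import CentroidSet, ExpressionMatrix

logger = logging.getLogger(__name__)

NON_CLASSIFIED = "non-classified"


def collapse_probes(expr: ExpressionMatrix, how: str = "mean") -> pd.DataFrame:
    """Collapse probe rows to one row per gene symbol (upper-cased).

    how="mean" averages multi-probe genes; how="first" keeps the first
    probe in matrix order.
    """
    genes = expr.feature_gene.astype(str).str.strip().str.upper()
    if how == "mean":
        return expr.values.groupby(genes).mean()
    if how == "first":
        keep = ~genes.duplicated()
        out = expr.values.loc[keep]
        out.index = genes[keep]
        return out
    raise ValueError(f"unknown collapse rule {how!r}")


@dataclass
class ClassificationResult:
    """Per-sample centroid correlations and the assigned subtype."""

    sample_id: str
    correlations: dict[str, float]
    best_subtype: str
    assigned: str
    cutoff: float


class SSPModel:
    """Nearest-centroid classifier over a fixed centroid table."""

    def __init__(self, expr: ExpressionMatrix, centroids: CentroidSet,
                 collapse: str = "mean"):
        self.expr = expr
        self.centroids = centroids
        self.collapse = collapse

    def fit(self, cutoff: float = 0.2) -> "SSPResults":
        results = classify_ssp(self.expr, self.centroids, cutoff=cutoff,
                               collapse=self.collapse)
        return SSPResults(results, cutoff)


@dataclass
class SSPResults:
    results: list[ClassificationResult]
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {"sample_id": r.sample_id, **{f"r_{k}": v
                                                for k, v in r.correlations.items()},
                   "best_subtype": r.best_subtype, "assigned": r.assigned}
            rows.append(row)
        return pd.DataFrame(rows).set_index("sample_id")

    def summary(self) -> str:
        counts = pd.Series([r.assigned for r in self.results]).value_counts()
        lines = ["SSP nearest-centroid classification",
                 f"  samples:     {len(self.results)}",
                 f"  cutoff:      {self.cutoff}"]
        for label, n in counts.items():
            lines.append(f"  {label:<16} {n}")
        return "\n".join(lines)


def classify_ssp(expr: ExpressionMatrix, centroids: CentroidSet,
                 cutoff: float = 0.2, collapse: str = "mean"
                 ) -> list[ClassificationResult]:
    """Assign each sample to its best-correlated subtype centroid.

    Genes are matched by (upper-cased) symbol; at least 10 shared genes
    are required.  A sample whose correlations to all centroids are below
    ``cutoff`` is "non-classified"; ties at the maximum go to the first
    subtype in centroid column order.
    """
    by_gene = collapse_probes(expr, collapse)
    cent = centroids.centroid_values.copy()
    cent.index = cent.index.astype(str).str.strip().str.upper()
    shared = [g for g in by_gene.index if g in set(cent.index)]
    dropped = len(by_gene) - len(shared)
    if dropped:
        logger.info("dropping %d gene(s) absent from the centroid table", dropped)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} genes shared with the centroid "
                         "table; need >= 10")
    x = by_gene.loc[shared].to_numpy()
    c = cent.loc[shared].to_numpy()
    corr = _corr_columns(x, c)                       # samples x subtypes
    subtypes = list(cent.columns)
    out = []
    for i, sample in enumerate(by_gene.columns):
        r = corr[i]
        best_idx = int(np.argmax(r))
        if (r == r[best_idx]).sum() > 1:
            logger.info("tie at argmax for sample %s; first centroid kept", sample)
        best = subtypes[best_idx]
        assigned = best if r[best_idx] >= cutoff else NON_CLASSIFIED
        out.append(ClassificationResult(
            sample_id=sample,
            correlations=dict(zip(subtypes, map(float, r))),
            best_subtype=best, assigned=assigned, cutoff=cutoff,
        ))
    return out
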