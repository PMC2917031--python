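"""Gene-set scoring of relative methylation and expression.

The average relative methylation of a gene set in one sample is the
unweighted mean of the relative methylation levels of all CpG sites whose
gene belongs to the set (CpG-level averaging, so genes with more CpGs
weigh more); the average relative expression is the mean over matched
genes after probe collapsing.  Subtype contrasts (ANOVA across all five
subtypes, or a t-test between two of them, typically basal-like versus
lumB for polycomb-target sets) delegate to the generic group comparison.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .clustering import group_compare
from .containers import SUBTYPES, GeneSet, annotations_to_frame
from .ssp import collapse_probes

logger = logging.getLogger(__name__)


def _matched_cpgs(rel, geneset: GeneSet) -> pd.Index:
    genes = rel.feature_gene.astype(str).str.strip().str.upper()
    return rel.values.index[genes.isin(geneset.symbols)]


def score_geneset(rel, expr, geneset: GeneSet) -> pd.DataFrame:
    """Per-sample average relative methylation and expression of a gene set.

    Either matrix may be None (score reported as missing).  Raises when
    the set matches nothing on both axes.
    """
    meth_score = expr_score = None
    n_cpgs = n_genes = 0
    index = None
    if rel is not None:
        cpgs = _matched_cpgs(rel, geneset)
        n_cpgs = len(cpgs)
        index = rel.values.columns
        if n_cpgs:
            meth_score = rel.values.loc[cpgs].mean(axis=0, skipna=True)
    if expr is not None:
        by_gene = collapse_probes(expr)
        genes = [g for g in by_gene.index if g in geneset.symbols]
        n_genes = len(genes)
        if index is None:
            index = expr.values.columns
        if n_genes:
            expr_score = by_gene.loc[genes].mean(axis=0, skipna=True)
    if n_cpgs == 0 and n_genes == 0:
        raise ValueError(f"gene set {geneset.name!r} matches no CpGs and no genes")
    out = pd.DataFrame(index=index)
    out["set_name"] = geneset.name
    out["avg_rel_methylation"] = meth_score if meth_score is not None else np.nan
    out["avg_rel_expression"] = (expr_score.reindex(index)
                                 if expr_score is not None else np.nan)
    out["n_cpgs_matched"] = n_cpgs
    out["n_genes_matched"] = n_genes
    return out


def contrast_geneset(scores: pd.DataFrame, annotations,
                     contrast: str = "anova_all_subtypes",
                     value: str = "avg_rel_methylation",
                     subtype_pair: tuple[str, str] = ("basal-like", "lumB")
                     ) -> pd.DataFrame:
    """Compare gene-set scores between molecular subtypes.

    contrast="anova_all_subtypes" runs one-way ANOVA across the five named
    subtypes; contrast="t_two_subtypes" a two-sample t-test between
    ``subtype_pair``.  Samples without a score are excluded (logged).
    """
    frame = annotations_to_frame(annotations)
    shared = [s for s in scores.index if s in frame.index]
    vals = scores.loc[shared, value]
    subtype = frame.loc[shared, "subtype"]
    missing = int(vals.isna().sum())
    if missing:
        logger.info("excluding %d sample(s) without a score", missing)
    keep = vals.notna()
    vals, subtype = vals[keep], subtype[keep]
    if contrast == "anova_all_subtypes":
        levels, test = list(SUBTYPES), "anova"
    elif contrast == "t_two_subtypes":
        levels, test = list(subtype_pair), "t"
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    mask = subtype.isin(levels)
    stat, p = group_compare(vals[mask].to_numpy(), subtype[mask].to_numpy(),
                            test=test)
    rows = [{
        "level": level,
        "mean_score": float(vals[subtype == level].mean()),
        "n": int((subtype == level).sum()),
        "statistic": stat,
        "p_value": p,
    } for level in levels if (subtype == level).any()]
    return pd.DataFrame(rows).set_index("level")


def compare_set_vs_rest(rel, geneset: GeneSet, samples=None
                        ) -> tuple[float, float, float, float]:
    """Are the set's CpGs more methylated than other CpGs in these samples?

    Per-CpG mean relative methylation is computed within the sample subset
    and compared between set-matched and unmatched CpGs with a two-sample
    t-test.  Returns (mean_in_set, mean_other, t, p).
    """
    values = rel.values if samples is None else rel.values[list(samples)]
    in_set = _matched_cpgs(rel, geneset)
    out_set = values.index.difference(in_set)
    if len(in_set) == 0 or len(out_set) == 0:
        raise ValueError("need both set-matched and unmatched CpGs")
    per_cpg = values.mean(axis=1, skipna=True)
    set_vals = per_cpg[in_set].to_numpy()
    other_vals = per_cpg[out_set].to_numpy()
    t, p = group_compare(
        np.concatenate([set_vals, other_vals]),
        np.array(["set"] * len(set_vals) + ["other"] * len(other_vals)),
        test="t")
    return float(np.nanmean(set_vals)), float(np.nanmean(other_vals)), t, p
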