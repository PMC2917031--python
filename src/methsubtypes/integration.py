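"""Methylation-expression integration.

CpG sites are matched to expression probes by shared gene symbol (full
cross product within a gene), each pair's relative methylation is
correlated with expression across the shared tumour samples, and the
global inverse association is assessed with an exact two-sided binomial
test on the number of negative correlation coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONSTANT_FLAG = "constant-methylation"
INSUFFICIENT_FLAG = "insufficient"


def _norm_symbols(series: pd.Series) -> pd.Series:
    return series.astype(str).str.strip().str.upper()


def match_pairs(rel, expr) -> pd.DataFrame:
    """Cross product of CpG sites and expression probes per gene symbol.

    Symbols are upper-cased and whitespace-stripped before matching.
    Returns a DataFrame with columns cpg_id, probe_id, gene_symbol.
    """
    shared = [s for s in rel.sample_ids if s in set(expr.sample_ids)]
    if not shared:
        raise ValueError("methylation and expression matrices share no samples")
    cpg_genes = _norm_symbols(rel.feature_gene)
    probe_genes = _norm_symbols(expr.feature_gene)
    cpg_by_gene = cpg_genes.groupby(cpg_genes).groups
    probe_by_gene = probe_genes.groupby(probe_genes).groups
    rows = []
    for gene in cpg_by_gene:
        if gene not in probe_by_gene:
            continue
        for cpg in cpg_by_gene[gene]:
            for probe in probe_by_gene[gene]:
                rows.append({"cpg_id": cpg, "probe_id": probe,
                             "gene_symbol": gene})
    return pd.DataFrame(rows, columns=["cpg_id", "probe_id", "gene_symbol"])


def pair_correlations(pairs: pd.DataFrame, rel, expr) -> pd.DataFrame:
    """Pearson r per CpG/probe pair over pairwise-complete shared samples.

    Pairs whose relative methylation does not change across the shared
    samples are flagged "constant-methylation" (no r); pairs with fewer
    than 3 complete samples are flagged "insufficient".
    """
    shared = [s for s in rel.sample_ids if s in set(expr.sample_ids)]
    meth = rel.values[shared]
    exprs = expr.values[shared]
    r_values, flags, n_used = [], [], []
    for cpg, probe in zip(pairs["cpg_id"], pairs["probe_id"]):
        m = meth.loc[cpg].to_numpy()
        e = exprs.loc[probe].to_numpy()
        complete = ~(np.isnan(m) | np.isnan(e))
        n = int(complete.sum())
        if n < 3:
            r_values.append(np.nan); flags.append(INSUFFICIENT_FLAG)
        elif np.ptp(m[complete]) == 0:
            r_values.append(np.nan); flags.append(CONSTANT_FLAG)
        else:
            r = np.corrcoef(m[complete], e[complete])[0, 1]
            r_values.append(float(r)); flags.append("")
        n_used.append(n)
    out = pairs.copy()
    out["r"] = r_values
    out["flag"] = flags
    out["n_samples"] = n_used
    return out


def sign_test(pairs: pd.DataFrame) -> tuple[int, int, float, float]:
    """Exact two-sided binomial test for an excess of negative correlations.

    Only pairs with a defined r ("varying" pairs) enter; r == 0 counts as
    non-negative (conservative for the inverse-correlation claim).
    Returns (n_varying, n_negative, fraction_negative, p_binomial).
    """
    varying = pairs[pairs["flag"] == ""]
    n_varying = len(varying)
    if n_varying == 0:
        raise ValueError("no varying pairs to test")
    ties = int((varying["r"] == 0).sum())
    if ties:
        logger.info("%d pair(s) with r exactly 0 counted as non-negative", ties)
    n_negative = int((varying["r"] < 0).sum())
    p = binomial_sign_p(n_negative, n_varying)
    return n_varying, n_negative, n_negative / n_varying, p


def binomial_sign_p(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p (minlike convention, as in R binom.test)."""
    return float(stats.binomtest(k, n, p0).pvalue)


@dataclass
class IntegrationResults:
    """Pair table with correlations plus the global sign test."""

    pairs: pd.DataFrame
    n_pairs: int
    n_constant: int
    n_varying: int
    n_negative: int
    fraction_negative: float
    p_binomial: float

    def summary(self) -> str:
        return "\n".join([
            "Methylation-expression integration",
            f"  CpG/probe pairs:        {self.n_pairs}",
            f"  constant methylation:   {self.n_constant}",
            f"  varying pairs:          {self.n_varying}",
            f"  negative correlations:  {self.n_negative} "
            f"({self.fraction_negative:.0%})",
            f"  binomial P:             {self.p_binomial:.3g}",
        ])


class MethylationExpressionModel:
    """Gene-symbol matching, per-pair correlation and the global sign test,
    bundled as a model over a (RelativeMatrix, ExpressionMatrix) pair."""

    def __init__(self, rel, expr):
        self.rel = rel
        self.expr = expr

    def fit(self) -> IntegrationResults:
        pairs = match_pairs(self.rel, self.expr)
        pairs = pair_correlations(pairs, self.rel, self.expr)
        n_varying, n_negative, fraction, p = sign_test(pairs)
        return IntegrationResults(
            pairs=pairs,
            n_pairs=len(pairs),
            n_constant=int((pairs["flag"] == CONSTANT_FLAG).sum()),
            n_varying=n_varying,
            n_negative=n_negative,
            fraction_negative=fraction,
            p_binomial=p,
        )
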