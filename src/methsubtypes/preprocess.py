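"""Beta-value stratification, methylation frequencies, centring, variance filter.

The pipeline's preprocessing follows the GoldenGate-array convention:
beta-values are trinarized (<=0.3 -> 0, interior -> 0.5, >=0.7 -> 1, the
last interpreted as hypermethylated), per-sample methylation frequency is
the fraction of CpGs at 1, stratified values are mean-centred across the
tumour samples to give relative methylation levels, and only CpGs whose
relative level varies (sample SD >= 0.3) enter the unsupervised analyses.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .containers import BetaMatrix, RelativeMatrix, TernaryMatrix

logger = logging.getLogger(__name__)


def stratify(beta: BetaMatrix, t_low: float = 0.3, t_high: float = 0.7) -> TernaryMatrix:
    """Trinarize beta-values: v <= t_low -> 0; t_low < v < t_high -> 0.5;
    v >= t_high -> 1. Missing values stay missing."""
    if not (0 < t_low < t_high < 1):
        raise ValueError(f"thresholds must satisfy 0 < t_low < t_high < 1, "
                         f"got {t_low}, {t_high}")
    v = beta.values.to_numpy(copy=True)
    out = np.full_like(v, np.nan)
    out[v <= t_low] = 0.0
    out[(v > t_low) & (v < t_high)] = 0.5
    out[v >= t_high] = 1.0
    frame = pd.DataFrame(out, index=beta.values.index, columns=beta.values.columns)
    return TernaryMatrix(frame, beta.feature_gene)


def methylation_frequency(tern: TernaryMatrix, cpg_subset=None) -> pd.DataFrame:
    """Per-sample fraction of (non-missing) CpGs with stratified value 1.

    Returns a DataFrame indexed by sample id with columns
    ``methylation_frequency`` and ``n_informative``.
    """
    values = tern.values
    if cpg_subset is not None:
        cpg_subset = list(cpg_subset)
        if not cpg_subset:
            raise ValueError("cpg_subset is empty")
        missing = set(cpg_subset) - set(values.index)
        if missing:
            raise KeyError(f"cpg_subset ids not in matrix: {sorted(missing)[:5]}")
        values = values.loc[cpg_subset]
    informative = values.notna().sum(axis=0)
    hyper = (values == 1.0).sum(axis=0)
    freq = hyper / informative.replace(0, np.nan)
    return pd.DataFrame({
        "methylation_frequency": freq,
        "n_informative": informative,
    })


def centre(tern: TernaryMatrix, centring_samples) -> RelativeMatrix:
    """Subtract each CpG's mean over ``centring_samples`` from the whole row.

    The centring set is normally the tumour samples; any other columns
    (e.g. normal tissue) are projected using the same tumour-derived mean.
    """
    centring_samples = list(centring_samples)
    if not centring_samples:
        raise ValueError("centring_samples is empty")
    missing = set(centring_samples) - set(tern.values.columns)
    if missing:
        raise KeyError(f"centring samples not in matrix: {sorted(missing)[:5]}")
    means = tern.values[centring_samples].mean(axis=1, skipna=True)
    dead = means.isna()
    if dead.any():
        logger.warning("%d CpG(s) with no informative centring sample become "
                       "all-missing", int(dead.sum()))
    centred = tern.values.sub(means, axis=0)
    return RelativeMatrix(centred, tern.feature_gene)


def filter_variable(rel: RelativeMatrix, sd_min: float = 0.3) -> RelativeMatrix:
    """Keep CpGs whose sample standard deviation (ddof=1, over non-missing
    values) is at least ``sd_min``."""
    sd = rel.values.std(axis=1, ddof=1, skipna=True)
    keep = sd.index[sd >= sd_min]
    return rel.subset_features(keep)


def preprocess_pipeline(beta: BetaMatrix, tumour_samples, t_low: float = 0.3,
                        t_high: float = 0.7, sd_min: float = 0.3):
    """Stratify, centre over the tumour samples, and variance-filter.

    Returns (ternary, relative, filtered_relative, per-sample frequency table).
    """
    tern = stratify(beta, t_low, t_high)
    rel = centre(tern, tumour_samples)
    filtered = filter_variable(rel, sd_min)
    freq = methylation_frequency(tern)
    return tern, rel, filtered, freq
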