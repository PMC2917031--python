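"""Core in-memory containers for the methylation-subtype pipeline.

All matrix-like objects wrap a pandas DataFrame with features (CpG sites or
expression probes) on the rows and samples on the columns; ``NaN`` marks a
missing measurement.  A parallel Series maps each feature to a gene symbol
(many features may share a gene, every feature has exactly one symbol).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUBTYPES = ("basal-like", "lumA", "lumB", "HER2-enriched", "normal-like")
"""The five expression-defined molecular subtypes, in canonical order."""

SUBTYPE_VOCAB = SUBTYPES + ("non-classified", "non-GEX")
ER_VOCAB = ("positive", "negative", "unknown")
FAMILY_VOCAB = ("BRCA1", "BRCA2", "familial", "sporadic", "unknown")
TISSUE_VOCAB = ("tumour", "normal")

TERNARY_LEVELS = (0.0, 0.5, 1.0)


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dup[:5]}")


@dataclass
class FeatureMatrix:
    """Feature x sample numeric grid with a feature -> gene-symbol map."""

    values: pd.DataFrame
    feature_gene: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        self.feature_gene = self.feature_gene.reindex(self.values.index)
        if self.feature_gene.isna().any():
            missing = self.feature_gene.index[self.feature_gene.isna()].tolist()
            raise ValueError(f"features without a gene symbol: {missing[:5]}")
        self._validate()

    def _validate(self) -> None:  # subclasses refine
        pass

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "FeatureMatrix":
        return dataclasses.replace(
            self, values=self.values.loc[:, list(sample_ids)],
            feature_gene=self.feature_gene,
        )

    def subset_features(self, feature_ids) -> "FeatureMatrix":
        keep = list(feature_ids)
        return dataclasses.replace(
            self, values=self.values.loc[keep],
            feature_gene=self.feature_gene.loc[keep],
        )


@dataclass
class BetaMatrix(FeatureMatrix):
    """CpG x sample methylation beta-values in [0, 1].

    A beta-value is the methylated-channel fluorescence over total
    fluorescence for one CpG site in one sample: 0 means fully
    unmethylated, 1 fully methylated.
    """

    def _validate(self) -> None:
        v = self.values.to_numpy()
        bad = (v < 0) | (v > 1)
        if np.any(bad & ~np.isnan(v)):
            r, c = np.argwhere(bad & ~np.isnan(v))[0]
            raise ValueError(
                f"beta-value out of [0,1] at CpG {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}: {v[r, c]}"
            )

    @property
    def cpg_ids(self) -> list[str]:
        return self.feature_ids

    @property
    def cpg_gene(self) -> pd.Series:
        return self.feature_gene


@dataclass
class TernaryMatrix(FeatureMatrix):
    """Stratified beta-values: 0 (unmethylated), 0.5, or 1 (hypermethylated)."""

    def _validate(self) -> None:
        v = self.values.to_numpy()
        ok = np.isnan(v)
        for level in TERNARY_LEVELS:
            ok |= v == level
        if not ok.all():
            r, c = np.argwhere(~ok)[0]
            raise ValueError(
                f"non-ternary value at {self.values.index[r]!r}/"
                f"{self.values.columns[c]!r}: {v[r, c]}"
            )

    cpg_ids = BetaMatrix.cpg_ids
    cpg_gene = BetaMatrix.cpg_gene


@dataclass
class RelativeMatrix(FeatureMatrix):
    """Per-CpG mean-centred ternary values ("relative methylation levels")."""

    cpg_ids = BetaMatrix.cpg_ids
    cpg_gene = BetaMatrix.cpg_gene


@dataclass
class ExpressionMatrix(FeatureMatrix):
    """Probe x sample relative (centred, log-scale) expression levels."""

    @property
    def probe_ids(self) -> list[str]:
        return self.feature_ids

    @property
    def probe_gene(self) -> pd.Series:
        return self.feature_gene


def _fold_vocab(value: object, vocab: tuple[str, ...], default: str) -> str:
    """Map a raw categorical value onto a closed vocabulary, case-insensitively."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return default
    text = str(value).strip()
    lowered = {v.lower(): v for v in vocab}
    return lowered.get(text.lower(), default)


@dataclass
class SampleAnnotation:
    """Clinical and molecular annotation for one sample."""

    sample_id: str
    subtype: str = "non-classified"
    er_status: str = "unknown"
    pgr_status: str = "unknown"
    family_status: str = "unknown"
    grade: str = "unknown"
    node_status: str = "unknown"
    age: float = float("nan")
    size_mm: float = float("nan")
    tissue: str = "tumour"

    def __post_init__(self) -> None:
        self.subtype = _fold_vocab(self.subtype, SUBTYPE_VOCAB, "non-classified")
        self.er_status = _fold_vocab(self.er_status, ER_VOCAB, "unknown")
        self.pgr_status = _fold_vocab(self.pgr_status, ER_VOCAB, "unknown")
        self.family_status = _fold_vocab(self.family_status, FAMILY_VOCAB, "unknown")
        self.tissue = _fold_vocab(self.tissue, TISSUE_VOCAB, "tumour")


def annotations_to_frame(annotations: list[SampleAnnotation]) -> pd.DataFrame:
    """Tabulate annotations, indexed by sample id."""
    frame = pd.DataFrame([dataclasses.asdict(a) for a in annotations])
    return frame.set_index("sample_id")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (e.g. a PRC2 target list)."""

    name: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"gene set {self.name!r} is empty")

    @staticmethod
    def from_symbols(name: str, symbols) -> "GeneSet":
        cleaned = frozenset(str(s).strip().upper() for s in symbols if str(s).strip())
        return GeneSet(name, cleaned)


@dataclass
class CentroidSet:
    """Gene x subtype table of centroid expression values for SSP classification."""

    centroid_values: pd.DataFrame  # genes x subtypes

    def __post_init__(self) -> None:
        self.centroid_values = self.centroid_values.astype(float)
        _check_unique(self.centroid_values.index, "centroid genes")
        if self.centroid_values.isna().all(axis=0).any():
            raise ValueError("centroid set has an all-missing subtype column")

    @property
    def genes(self) -> list[str]:
        return list(self.centroid_values.index)

    @property
    def subtypes(self) -> list[str]:
        return list(self.centroid_values.columns)
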