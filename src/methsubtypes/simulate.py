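"""Synthetic methylation/expression cohorts with known ground truth.

The generator emulates a GoldenGate-style beta-value cohort of breast
tumours split into the five expression subtypes, at the study's sample
sizes (basal-like 43, lumA 46, lumB 35, HER2-enriched 14, normal-like 17,
plus 4 normal-tissue samples).  Each CpG carries a latent methylation
state per subtype (unmethylated / variable / methylated); beta-values are
drawn from state-specific beta-mixture components concentrated below 0.3,
across the interior, and above 0.7, so stratification recovers the state
with high probability.

Subtype-specific baseline methylation probabilities (lumB highest,
basal-like lowest, mirroring the observed frequency gradient) are applied
through a single shared uniform draw per CpG with per-subtype thresholds:
with equal probabilities all subtypes share every state exactly (an exact
null), while unequal probabilities create a correlated
lumB-more-methylated gradient.  On top of this, a configurable number of
differential CpGs get an independent state redraw for one target subtype
with the methylation probability shifted by ``diff_effect``.

A configurable fraction of genes is anti-correlated with expression:
expression = baseline - coupling_strength x (gene-average beta, centred)
+ Gaussian noise.  Centroids are per-subtype mean expression profiles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    SUBTYPES,
    BetaMatrix,
    CentroidSet,
    ExpressionMatrix,
    GeneSet,
    SampleAnnotation,
)

STATE_NAMES = ("unmethylated", "variable", "methylated")

_TABLE_SIZES = {"basal-like": 43, "lumA": 46, "lumB": 35,
                "HER2-enriched": 14, "normal-like": 17}
_TABLE_PROBS = {"basal-like": 0.276, "lumA": 0.311, "lumB": 0.351,
                "HER2-enriched": 0.278, "normal-like": 0.275}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; the defaults are the study
    conditions (Table-1-like subtype sizes, Table-3-like frequency
    gradient)."""

    n_cpgs: int = 500
    n_genes: int = 250
    n_samples: dict = field(default_factory=lambda: dict(_TABLE_SIZES))
    n_normal_tissue: int = 4
    baseline_meth_prob: dict = field(default_factory=lambda: dict(_TABLE_PROBS))
    normal_tissue_meth_prob: float = 0.273
    variable_prob: float = 0.2
    n_differential_cpgs: int = 50
    diff_effect: float = 0.4
    diff_target_subtypes: tuple = ("basal-like", "lumA", "lumB")
    beta_shapes: dict = field(default_factory=lambda: {
        "unmethylated": (5.0, 30.0),
        "variable": (20.0, 20.0),
        "methylated": (30.0, 5.0),
    })
    coupling_fraction: float = 0.6
    coupling_strength: float = 4.0
    expr_noise_sd: float = 0.5
    probes_per_gene_two_fraction: float = 0.1
    geneset_size: int = 64
    seed: int = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.n_differential_cpgs > self.n_cpgs:
            raise ValueError("more differential CpGs than CpGs")
        if self.n_genes > self.n_cpgs:
            raise ValueError("need at least one CpG per gene")
        for name, p in self.baseline_meth_prob.items():
            if not 0 <= p <= 1 or not 0 <= p + self.variable_prob <= 1:
                raise ValueError(f"infeasible state probabilities for {name}")


@dataclass
class SimulationTruth:
    """Ground truth of every planted effect."""

    states: pd.DataFrame                  # CpG x group latent state name
    differential_cpgs: pd.DataFrame       # cpg_id, target_subtype, direction
    coupled_genes: pd.Series              # gene -> bool
    sample_subtype: pd.Series             # sample -> subtype / "normal-tissue"

    @property
    def differential_ids(self) -> list[str]:
        return list(self.differential_cpgs["cpg_id"])


@dataclass
class SimulatedCohort:
    beta: BetaMatrix
    expression: ExpressionMatrix
    annotations: list[SampleAnnotation]
    gene_sets: list[GeneSet]
    centroids: CentroidSet
    truth: SimulationTruth


def simulate(config: SimulationConfig) -> SimulatedCohort:
    """Generate the full fixture bundle; bit-reproducible from the seed."""
    master = np.random.default_rng(config.seed)
    # independent streams so adding CpGs does not perturb expression draws
    rng_states, rng_beta, rng_expr, rng_annot = master.spawn(4)

    cpg_ids = [f"cpg{i:04d}" for i in range(config.n_cpgs)]
    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    # every gene owns >= 1 CpG; extras spread uniformly
    gene_of = list(range(config.n_genes))
    gene_of += list(rng_states.integers(0, config.n_genes,
                                        config.n_cpgs - config.n_genes))
    cpg_gene = pd.Series([gene_ids[g] for g in gene_of], index=cpg_ids)

    groups = list(config.n_samples) + ["normal-tissue"]
    sizes = [config.n_samples[s] for s in config.n_samples] + [config.n_normal_tissue]
    probs = ([config.baseline_meth_prob[s] for s in config.n_samples]
             + [config.normal_tissue_meth_prob])

    # latent states via one shared uniform per CpG and per-group thresholds
    u = rng_states.uniform(size=config.n_cpgs)
    q = config.variable_prob
    state_idx = np.empty((config.n_cpgs, len(groups)), dtype=int)
    for j, p in enumerate(probs):
        state_idx[:, j] = np.where(u < p, 2, np.where(u < p + q, 1, 0))

    sample_ids, sample_group = [], []
    for g, size in zip(groups, sizes):
        tag = "N" if g == "normal-tissue" else g[:4].replace("-", "")
        for i in range(size):
            sample_ids.append(f"{tag}_{i + 1:03d}")
            sample_group.append(g)
    group_of_sample = np.array([groups.index(g) for g in sample_group])
    # per-sample latent states; null CpGs inherit their group's shared state
    states_sample = state_idx[:, group_of_sample]

    # planted differential CpGs: per-sample state draws with the target
    # subtype's methylation probability shifted by +-diff_effect, so each
    # planted CpG carries its intended contrast on the ternary scale
    n_diff = config.n_differential_cpgs
    diff_rows = []
    if n_diff:
        diff_cpgs = rng_states.choice(config.n_cpgs, size=n_diff, replace=False)
        targets = [t for t in config.diff_target_subtypes
                   if t in config.n_samples] or list(config.n_samples)
        for k, ci in enumerate(diff_cpgs):
            target = targets[k % len(targets)]
            direction = "hyper" if k % 2 == 0 else "hypo"
            effect = config.diff_effect
            p_row = np.empty(len(sample_ids))
            q_row = np.full(len(sample_ids), q)
            for j, gi in enumerate(group_of_sample):
                p = probs[gi]
                if groups[gi] != target:
                    p_row[j] = p
                elif direction == "hyper":
                    p_row[j] = min(p + effect, 1.0 - q)
                else:
                    # realise the full -effect on the ternary-mean scale:
                    # first drop P(methylated), then shrink P(variable)
                    p_row[j] = max(p - effect, 0.0)
                    leftover = effect - p
                    if leftover > 0:
                        q_row[j] = max(q - 2.0 * leftover, 0.0)
            u_row = rng_states.uniform(size=len(sample_ids))
            states_sample[ci] = np.where(
                u_row < p_row, 2, np.where(u_row < p_row + q_row, 1, 0))
            diff_rows.append({"cpg_id": cpg_ids[ci], "target_subtype": target,
                              "direction": direction})
    diff_frame = pd.DataFrame(diff_rows,
                              columns=["cpg_id", "target_subtype", "direction"])

    # beta draws from the state components
    shapes = np.array([config.beta_shapes[s] for s in STATE_NAMES])
    beta_values = rng_beta.beta(shapes[states_sample, 0],
                                shapes[states_sample, 1])
    beta = BetaMatrix(
        pd.DataFrame(beta_values, index=cpg_ids, columns=sample_ids),
        cpg_gene.copy(),
    )

    # expression: anti-correlated with gene-average beta for coupled genes
    tumour_cols = [j for j, g in enumerate(sample_group) if g != "normal-tissue"]
    tumour_ids = [sample_ids[j] for j in tumour_cols]
    coupled = pd.Series(
        rng_expr.uniform(size=config.n_genes) < config.coupling_fraction,
        index=gene_ids)
    gene_beta = (pd.DataFrame(beta_values[:, tumour_cols],
                              index=cpg_ids, columns=tumour_ids)
                 .groupby(cpg_gene).mean())
    probe_rows, probe_ids, probe_gene = [], [], []
    n_two = int(round(config.probes_per_gene_two_fraction * config.n_genes))
    two_probe_genes = set(rng_expr.choice(config.n_genes, size=n_two,
                                          replace=False))
    for gi, gene in enumerate(gene_ids):
        signal = np.zeros(len(tumour_ids))
        if coupled[gene] and gene in gene_beta.index:
            b = gene_beta.loc[gene].to_numpy()
            signal = -config.coupling_strength * (b - b.mean())
        n_probes = 2 if gi in two_probe_genes else 1
        for p in range(n_probes):
            probe_ids.append(f"P_{gene}_{p + 1}")
            probe_gene.append(gene)
            probe_rows.append(signal + rng_expr.normal(
                0.0, config.expr_noise_sd, size=len(tumour_ids)))
    expr_values = pd.DataFrame(np.array(probe_rows), index=probe_ids,
                               columns=tumour_ids)
    expr_values = expr_values.sub(expr_values.mean(axis=1), axis=0)  # centred
    expression = ExpressionMatrix(expr_values,
                                  pd.Series(probe_gene, index=probe_ids))

    # annotations: ER/PgR loosely follow subtype, family status marginal
    annotations = []
    for sid, g in zip(sample_ids, sample_group):
        if g == "normal-tissue":
            annotations.append(SampleAnnotation(sid, subtype="non-GEX",
                                                tissue="normal"))
            continue
        er_pos_p = {"basal-like": 0.05, "lumA": 0.96, "lumB": 0.91,
                    "HER2-enriched": 0.36, "normal-like": 0.67}.get(g, 0.5)
        er = "positive" if rng_annot.uniform() < er_pos_p else "negative"
        pgr = er if rng_annot.uniform() < 0.9 else (
            "negative" if er == "positive" else "positive")
        family = rng_annot.choice(["BRCA1", "BRCA2", "familial", "sporadic"],
                                  p=[0.08, 0.07, 0.23, 0.62])
        annotations.append(SampleAnnotation(
            sid, subtype=g, er_status=er, pgr_status=pgr,
            family_status=str(family), tissue="tumour",
            age=float(rng_annot.integers(30, 70))))

    # gene sets: one biased toward lumB-hypermethylated differential genes
    # (a synthetic polycomb-target stand-in), one random null set
    lumb_hyper_genes = [cpg_gene[r.cpg_id] for r in diff_frame.itertuples()
                        if r.target_subtype == "lumB" and r.direction == "hyper"]
    pool = [g for g in gene_ids if g not in set(lumb_hyper_genes)]
    n_filler = min(len(pool), max(0, config.geneset_size
                                  - len(set(lumb_hyper_genes))))
    filler = list(rng_expr.choice(pool, size=n_filler, replace=False))
    prc2_like = GeneSet.from_symbols("SYN_PRC2_TARGETS",
                                     set(lumb_hyper_genes) | set(filler))
    null_set = GeneSet.from_symbols(
        "SYN_NULL_SET", rng_expr.choice(gene_ids, size=min(50, config.n_genes),
                                        replace=False))
    gene_sets = [prc2_like, null_set]

    # centroids: per-subtype mean expression, probe-collapsed
    genes_norm = expression.feature_gene.str.upper()
    by_gene = expr_values.groupby(genes_norm).mean()
    centroid_cols = {}
    for g in config.n_samples:
        cols = [sid for sid, grp in zip(sample_ids, sample_group) if grp == g]
        centroid_cols[g] = by_gene[cols].mean(axis=1)
    centroids = CentroidSet(pd.DataFrame(centroid_cols))

    truth = SimulationTruth(
        states=pd.DataFrame([[STATE_NAMES[s] for s in row] for row in state_idx],
                            index=cpg_ids, columns=groups),
        differential_cpgs=diff_frame,
        coupled_genes=coupled,
        sample_subtype=pd.Series(sample_group, index=sample_ids),
    )
    return SimulatedCohort(beta, expression, annotations, gene_sets,
                           centroids, truth)


def null_config(n_cpgs: int = 500, n_samples: dict | None = None,
                seed: int = 0, **kwargs) -> SimulationConfig:
    """A pure-noise configuration: equal subtype methylation probabilities
    and no planted differential CpGs, so every between-group test is null."""
    if n_samples is None:
        n_samples = dict(_TABLE_SIZES)
    p = dict.fromkeys(list(n_samples), 0.30)
    return SimulationConfig(
        n_cpgs=n_cpgs, n_genes=max(2, n_cpgs // 2), n_samples=n_samples,
        baseline_meth_prob=p, normal_tissue_meth_prob=0.30,
        n_differential_cpgs=0, seed=seed, **kwargs)


def simulate_from_centroids(centroids: CentroidSet, n_per_subtype: int,
                            noise_sd: float, seed: int
                            ) -> tuple[ExpressionMatrix, pd.Series]:
    """Expression profiles drawn as centroid + Gaussian noise.

    Used to exercise the SSP classifier at a controlled sample-centroid
    correlation: r ~= sd(centroid)/sqrt(sd(centroid)^2 + noise_sd^2).
    Returns the matrix and the true generating subtype per sample.
    """
    rng = np.random.default_rng(seed)
    cent = centroids.centroid_values
    cols, labels = {}, {}
    for subtype in cent.columns:
        mu = cent[subtype].to_numpy()
        for i in range(n_per_subtype):
            sid = f"sim_{subtype}_{i + 1:03d}"
            cols[sid] = mu + rng.normal(0.0, noise_sd, size=len(mu))
            labels[sid] = subtype
    values = pd.DataFrame(cols, index=cent.index)
    genes = pd.Series(cent.index, index=cent.index)
    return ExpressionMatrix(values, genes), pd.Series(labels)


def worked_fixture() -> SimulatedCohort:
    """A hand-checkable 8-CpG x 6-sample bundle with literal values.

    Includes one CpG at each stratification boundary (0.30, 0.45, 0.70);
    samples s1-s5 are tumours (s1/s2 lumA, s3/s4 basal-like, s5 lumB) and
    s6 is normal tissue.
    """
    samples = ["s1", "s2", "s3", "s4", "s5", "s6"]
    beta_rows = {
        "c1": [0.30, 0.10, 0.20, 0.05, 0.25, 0.15],   # boundary: 0.30 -> 0
        "c2": [0.45, 0.50, 0.55, 0.40, 0.60, 0.50],   # interior -> 0.5
        "c3": [0.70, 0.90, 0.80, 0.75, 0.95, 0.85],   # boundary: 0.70 -> 1
        "c4": [0.90, 0.85, 0.10, 0.05, 0.95, 0.10],   # hyper in luminal
        "c5": [0.05, 0.10, 0.80, 0.90, 0.15, 0.10],   # hyper in basal
        "c6": [0.50, 0.50, 0.50, 0.50, 0.50, 0.50],   # constant
        "c7": [0.00, 0.20, 0.40, 0.60, 0.80, 1.00],   # spans all strata
        "c8": [0.10, 0.90, 0.10, 0.90, 0.10, 0.90],   # alternating
    }
    genes = {"c1": "GA", "c2": "GA", "c3": "GB", "c4": "GC",
             "c5": "GD", "c6": "GE", "c7": "GF", "c8": "GB"}
    beta = BetaMatrix(
        pd.DataFrame(beta_rows, index=samples).T.astype(float),
        pd.Series(genes),
    )
    expr_rows = {
        "p1": [-0.9, -0.8, 0.8, 0.9, -1.0, 0.7],      # GC: anti c4
        "p2": [0.8, 0.9, -0.9, -0.8, 0.7, 0.9],       # GD: anti c5
        "p3": [0.1, -0.2, 0.3, -0.1, 0.2, -0.3],      # GB: noise
        "p4": [0.0, 0.1, -0.1, 0.2, -0.2, 0.1],       # GF: noise
    }
    probe_gene = {"p1": "GC", "p2": "GD", "p3": "GB", "p4": "GF"}
    expression = ExpressionMatrix(
        pd.DataFrame(expr_rows, index=samples).T.astype(float),
        pd.Series(probe_gene),
    )
    annotations = [
        SampleAnnotation("s1", subtype="lumA", er_status="positive"),
        SampleAnnotation("s2", subtype="lumA", er_status="positive"),
        SampleAnnotation("s3", subtype="basal-like", er_status="negative"),
        SampleAnnotation("s4", subtype="basal-like", er_status="negative"),
        SampleAnnotation("s5", subtype="lumB", er_status="positive"),
        SampleAnnotation("s6", subtype="non-GEX", tissue="normal"),
    ]
    gene_sets = [GeneSet.from_symbols("TOY_SET", {"GC", "GD"})]
    centroids = CentroidSet(pd.DataFrame({
        "lumA": [-0.9, 0.8, 0.0, 0.1],
        "basal-like": [0.85, -0.85, 0.1, 0.0],
        "lumB": [-1.0, 0.7, -0.1, -0.1],
    }, index=["GC", "GD", "GB", "GF"]))
    truth = SimulationTruth(
        states=pd.DataFrame(index=list(beta_rows)),
        differential_cpgs=pd.DataFrame(
            [{"cpg_id": "c4", "target_subtype": "lumA", "direction": "hyper"},
             {"cpg_id": "c5", "target_subtype": "basal-like",
              "direction": "hyper"}]),
        coupled_genes=pd.Series({"GC": True, "GD": True, "GB": False,
                                 "GF": False}),
        sample_subtype=pd.Series({"s1": "lumA", "s2": "lumA",
                                  "s3": "basal-like", "s4": "basal-like",
                                  "s5": "lumB", "s6": "normal-tissue"}),
    )
    return SimulatedCohort(beta, expression, annotations, gene_sets,
                           centroids, truth)
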