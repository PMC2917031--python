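"""Unsupervised structure discovery under Pearson-correlation distance.

Hierarchical clustering is UPGMA (unweighted average linkage) on the
sample-sample correlation-distance matrix ``d = 1 - r``; K-means is a
Lloyd iteration under the same distance with mean centroids and multiple
restarts.  Cluster/annotation association uses two-sided Fisher exact
tests on one-vs-rest 2x2 tables, mirroring how expression-subtype
enrichment of methylation clusters is usually reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SUBTYPES, SampleAnnotation, annotations_to_frame

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# distances

def pearson_distance(x, y) -> float:
    """Correlation distance d = 1 - r over pairwise-complete positions.

    Requires >= 3 complete pairs; a vector that is constant over the
    complete positions has no defined correlation and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 3:
        raise ValueError(f"need >= 3 paired non-missing positions, have {mask.sum()}")
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(1.0 - r)


def sample_distance_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """All pairwise sample correlation distances (pairwise-complete)."""
    corr = values.corr(method="pearson", min_periods=3)
    if corr.isna().any().any():
        bad = corr.columns[corr.isna().any()].tolist()
        raise ValueError(f"correlation undefined for sample(s): {bad[:5]}")
    d = 1.0 - corr
    np.fill_diagonal(d.values, 0.0)
    return d


def _corr_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-by-column Pearson correlation matrix (x cols x y cols);
    nan-free fast path, pairwise-complete fallback."""
    if not (np.isnan(x).any() or np.isnan(y).any()):
        xs = (x - x.mean(axis=0)) / x.std(axis=0)
        ys = (y - y.mean(axis=0)) / y.std(axis=0)
        return xs.T @ ys / x.shape[0]
    out = np.empty((x.shape[1], y.shape[1]))
    for j in range(y.shape[1]):
        yj = y[:, j]
        for i in range(x.shape[1]):
            xi = x[:, i]
            m = ~(np.isnan(xi) | np.isnan(yj))
            out[i, j] = np.corrcoef(xi[m], yj[m])[0, 1]
    return out


# ---------------------------------------------------------------------------
# results container

@dataclass
class ClusterResult:
    """Sample cluster assignments plus, for hierarchical runs, the merge list."""

    assignments: dict[str, int]
    method: str
    k: int
    merge_order: list[tuple[int, int, float]] = field(default_factory=list)
    seed: int | None = None

    def labels(self, sample_ids) -> np.ndarray:
        return np.array([self.assignments[s] for s in sample_ids])

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for label in self.assignments.values():
            sizes[label] = sizes.get(label, 0) + 1
        return sizes


# ---------------------------------------------------------------------------
# hierarchical (UPGMA)

def upgma_merge_list(dist: np.ndarray) -> list[tuple[int, int, float]]:
    """UPGMA merge sequence on a dense distance matrix.

    Leaves are numbered 0..n-1, the i-th merge creates node n+i.  Ties in
    the minimum distance are broken by the lowest (row, column) index pair
    in the current node ordering, so merge lists are reproducible.
    """
    n = dist.shape[0]
    active: list[int] = list(range(n))           # node ids, in creation order
    sizes = {i: 1 for i in range(n)}
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(dist[i, j])

    def get(a: int, b: int) -> float:
        return d[(a, b) if a < b else (b, a)]

    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                dij = get(active[ii], active[jj])
                if best is None or dij < best[0]:
                    best = (dij, ii, jj)
        height, ii, jj = best
        a, b = active[ii], active[jj]
        merges.append((a, b, height))
        new_size = sizes[a] + sizes[b]
        for other in active:
            if other in (a, b):
                continue
            dnew = (sizes[a] * get(a, other) + sizes[b] * get(b, other)) / new_size
            key = (other, next_id) if other < next_id else (next_id, other)
            d[key] = dnew
        sizes[next_id] = new_size
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return merges


def _cut_merges(merges, n: int, cut_k: int) -> np.ndarray:
    """Leaf labels (1..cut_k) after applying the first n - cut_k merges."""
    parent = list(range(n + len(merges)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step, (a, b, _h) in enumerate(merges[: n - cut_k]):
        node = n + step
        parent[find(a)] = node
        parent[find(b)] = node
    roots: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for leaf in range(n):
        root = find(leaf)
        labels[leaf] = roots.setdefault(root, len(roots) + 1)
    return labels


def hierarchical_cluster(rel, cut_k: int) -> ClusterResult:
    """UPGMA on sample correlation distances, cut into ``cut_k`` clusters."""
    if cut_k < 2:
        raise ValueError(f"cut_k must be >= 2, got {cut_k}")
    values = rel.values
    if values.shape[1] < cut_k:
        raise ValueError("fewer samples than requested clusters")
    dist = sample_distance_matrix(values)
    merges = upgma_merge_list(dist.to_numpy())
    labels = _cut_merges(merges, values.shape[1], cut_k)
    assignments = dict(zip(values.columns, (int(l) for l in labels)))
    return ClusterResult(assignments, "hierarchical", cut_k, merge_order=merges)


# ---------------------------------------------------------------------------
# K-means under correlation distance

def kmeans_cluster(rel, k: int, restarts: int = 50, seed: int | None = None,
                   max_iter: int = 100) -> ClusterResult:
    """Lloyd-style K-means with Pearson-correlation distance.

    Samples are assigned to the centroid with the smallest ``1 - r``;
    centroids are per-CpG means of their members; the best of ``restarts``
    random initialisations by total within-cluster distance is returned.
    An emptied cluster is re-seeded from the sample farthest from its
    centroid.
    """
    values = rel.values
    n = values.shape[1]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if seed is None:
        raise ValueError("a seed is required for reproducible K-means")
    x = values.to_numpy()
    rng = np.random.default_rng(seed)
    best_labels, best_objective = None, np.inf
    for _ in range(restarts):
        centroids = x[:, rng.choice(n, size=k, replace=False)].copy()
        labels = np.zeros(n, dtype=int)
        for _it in range(max_iter):
            dist = 1.0 - _corr_columns(x, centroids)       # n x k
            new_labels = dist.argmin(axis=1)
            for c in range(k):
                if not np.any(new_labels == c):            # emptied cluster
                    worst = dist[np.arange(n), new_labels].argmax()
                    new_labels[worst] = c
                    logger.info("re-seeded empty cluster %d from sample %d", c, worst)
            if np.array_equal(new_labels, labels) and _it > 0:
                break
            labels = new_labels
            for c in range(k):
                centroids[:, c] = np.nanmean(x[:, labels == c], axis=1)
        dist = 1.0 - _corr_columns(x, centroids)
        objective = float(dist[np.arange(n), labels].sum())
        if objective < best_objective:
            best_objective, best_labels = objective, labels.copy()
    assignments = dict(zip(values.columns, (int(l) + 1 for l in best_labels)))
    return ClusterResult(assignments, "kmeans", k, seed=seed)


# ---------------------------------------------------------------------------
# association with annotations

def associate_clusters(clusters: ClusterResult,
                       annotations: list[SampleAnnotation],
                       category: str = "subtype",
                       restrict_to=None,
                       levels=None) -> pd.DataFrame:
    """Two-sided Fisher exact tests on one-vs-rest 2x2 tables.

    For each (cluster, category-level) pair the table counts samples
    in/out of the cluster crossed with has/has-not the level, over the
    restricted sample set.  For subtype, samples whose label is not one of
    the five named subtypes are excluded entirely by default (mirroring an
    analysis restricted to expression-classified tumours).
    """
    frame = annotations_to_frame(annotations)
    samples = [s for s in clusters.assignments if s in frame.index]
    if restrict_to is not None:
        restrict_to = set(restrict_to)
        samples = [s for s in samples if s in restrict_to]
    if levels is None:
        levels = list(SUBTYPES) if category == "subtype" else sorted(
            frame.loc[samples, category].unique())
    samples = [s for s in samples if frame.loc[s, category] in levels]
    if not samples:
        raise ValueError("no annotated samples left after restriction")
    values = frame.loc[samples, category]
    labels = clusters.labels(samples)
    rows = []
    for cluster in sorted(set(labels)):
        in_cluster = labels == cluster
        for level in levels:
            is_level = (values == level).to_numpy()
            table = np.array([
                [int((in_cluster & is_level).sum()),
                 int((in_cluster & ~is_level).sum())],
                [int((~in_cluster & is_level).sum()),
                 int((~in_cluster & ~is_level).sum())],
            ])
            if is_level.sum() == 0:
                logger.info("level %r absent from restricted set; skipped", level)
                continue
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            rows.append({
                "cluster": cluster, "level": level,
                "n11": table[0, 0], "n12": table[0, 1],
                "n21": table[1, 0], "n22": table[1, 1],
                "odds_ratio": odds, "p_value": p,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# generic group comparisons

def group_compare(values, groups, test: str = "anova",
                  equal_var: bool = False) -> tuple[float, float]:
    """Two-sided comparison of a numeric vector across groups.

    test="anova": classical one-way F; test="t": two-sample t (Welch by
    default, pooled with ``equal_var=True``); test="wilcoxon": rank-sum
    (exact for small tie-free groups, normal approximation with continuity
    correction otherwise).  Returns (statistic, p_value).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    mask = ~np.isnan(values)
    values, groups = values[mask], groups[mask]
    split = [values[groups == g] for g in pd.unique(groups)]
    if any(len(s) == 0 for s in split) or len(split) < 2:
        raise ValueError("need >= 2 non-empty groups")
    if test == "anova":
        if any(len(s) < 2 for s in split):
            raise ValueError("ANOVA needs >= 2 members per group")
        res = stats.f_oneway(*split)
    elif test == "t":
        if len(split) != 2:
            raise ValueError("t-test needs exactly 2 groups")
        res = stats.ttest_ind(split[0], split[1], equal_var=equal_var)
    elif test == "wilcoxon":
        if len(split) != 2:
            raise ValueError("rank-sum test needs exactly 2 groups")
        exact = (max(len(s) for s in split) <= 25
                 and len(np.unique(values)) == len(values))
        res = stats.mannwhitneyu(split[0], split[1],
                                 alternative="two-sided",
                                 method="exact" if exact else "asymptotic")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
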