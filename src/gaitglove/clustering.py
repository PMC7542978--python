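"""Cluster taxonomy of aligned expression coefficients and sensor salience.

The aligned ECs of the first three components of every run (3N items) are
partitioned by k-means under correlation distance (1 - Pearson r, items and
centroids row-standardized), so patterns are compared by shape rather than
scale.  Clusters are labeled with the component rank they predominantly
contain, resolved to a bijection by maximum-agreement matching, and each
item is flagged correct when its component rank matches its cluster label.
Sensor salience within a cluster is an omnibus Kruskal-Wallis test over the
19 per-sensor coefficient distributions with Dunn-type post-hoc pairwise
rank comparisons under Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .errors import AnalysisError, SizeError

__all__ = [
    "ClusterTaxonomy",
    "SalienceResult",
    "cluster_components",
    "misassignment_table",
    "sensor_salience",
]


def _row_standardize(X: np.ndarray) -> np.ndarray:
    """Center each row and scale to unit norm; zero rows stay zero."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return Xc / norms


def correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Pearson r between two vectors; in [0, 2]."""
    xs = _row_standardize(x[None, :])[0]
    ys = _row_standardize(y[None, :])[0]
    return float(1.0 - xs @ ys)


@dataclass
class ClusterTaxonomy:
    """k-means result over tagged EC items with rank labels and correctness."""

    k: int
    centroids: np.ndarray  # (k, channels), row-standardized
    assignment: np.ndarray  # (items,) cluster ids
    distance: np.ndarray  # (items,) 1 - r to own centroid
    component_rank: np.ndarray  # (items,) 1-based rank tags
    run_ids: list  # per-item run identifiers
    label_map: dict[int, int]  # cluster id -> component rank
    correct: np.ndarray  # (items,) bool
    inertia: float = 0.0
    degenerate: bool = False

    def correct_count(self, rank: int) -> int:
        return int(np.sum(self.correct & (self.component_rank == rank)))


def _kmeans_correlation(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float]:
    """One Lloyd run under correlation distance on row-standardized items."""
    n = X.shape[0]
    for _attempt in range(20):
        centroids = X[rng.choice(n, size=k, replace=False)].copy()
        ok = True
        assign = np.full(n, -1)
        for _ in range(max_iter):
            d = 1.0 - X @ centroids.T  # (n, k)
            new_assign = np.argmin(d, axis=1)
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            counts = np.bincount(assign, minlength=k)
            if np.any(counts == 0):
                ok = False  # empty cluster: re-initialize this replicate
                break
            for c in range(k):
                centroids[c] = _row_standardize(
                    X[assign == c].mean(axis=0, keepdims=True)
                )[0]
        if ok:
            d = 1.0 - X @ centroids.T
            inertia = float(d[np.arange(n), assign].sum())
            return assign, centroids, inertia
    raise AnalysisError(
        "k-means degenerate: could not form k non-empty clusters "
        "(items may be identical)"
    )


def cluster_components(
    items: np.ndarray,
    component_rank: np.ndarray,
    run_ids: list | None = None,
    k: int = 3,
    seed: int = 0,
    replicates: int = 50,
) -> ClusterTaxonomy:
    """Best-of-replicates correlation-distance k-means over tagged EC items.

    ``items`` is (3N, channels); ``component_rank`` carries the 1-based rank
    tag of each item.  Cluster labels are the maximum-agreement bijection
    between clusters and ranks.
    """
    items = np.asarray(items, dtype=float)
    component_rank = np.asarray(component_rank)
    n = items.shape[0]
    if k > n:
        raise SizeError(f"cannot form {k} clusters from {n} items")
    if run_ids is None:
        run_ids = list(range(n))

    X = _row_standardize(items)
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(replicates):
        assign, centroids, inertia = _kmeans_correlation(X, k, rng)
        if best is None or inertia < best[2] - 1e-12:
            best = (assign, centroids, inertia)
    assert best is not None
    assign, centroids, inertia = best

    ranks = np.unique(component_rank)
    agreement = np.zeros((k, len(ranks)))
    for c in range(k):
        for j, r in enumerate(ranks):
            agreement[c, j] = np.sum((assign == c) & (component_rank == r))
    rows, cols = linear_sum_assignment(-agreement)
    label_map = {int(c): int(ranks[j]) for c, j in zip(rows, cols)}

    d = 1.0 - X @ centroids.T
    distance = d[np.arange(n), assign]
    labels = np.array([label_map.get(int(a), -1) for a in assign])
    correct = labels == component_rank
    return ClusterTaxonomy(
        k=k,
        centroids=centroids,
        assignment=assign,
        distance=distance,
        component_rank=component_rank,
        run_ids=list(run_ids),
        label_map=label_map,
        correct=correct,
        inertia=inertia,
    )


def misassignment_table(t: ClusterTaxonomy) -> np.ndarray:
    """Contingency counts of component rank (rows) x assigned cluster label
    (columns), both ordered by rank; row sums equal items per rank."""
    ranks = sorted(t.label_map.values())
    table = np.zeros((len(ranks), len(ranks)), dtype=int)
    labels = np.array([t.label_map[int(a)] for a in t.assignment])
    for i, r in enumerate(ranks):
        for j, c in enumerate(ranks):
            table[i, j] = np.sum((t.component_rank == r) & (labels == c))
    return table


@dataclass
class SalienceResult:
    """Omnibus and post-hoc rank statistics of per-sensor EC distributions."""

    sensors: tuple[str, ...]
    mean_ranks: np.ndarray
    h_statistic: float
    p_value: float
    pairwise_p: np.ndarray  # symmetric, uncorrected two-sided Dunn p-values
    significant_pairs: list[tuple[str, str]] = field(default_factory=list)
    n_comparisons: int = 0
    alpha: float = 0.05


def sensor_salience(
    ecs: np.ndarray,
    sensors: tuple[str, ...] | None = None,
    alpha: float = 0.05,
    n_comparisons: int | None = None,
) -> SalienceResult:
    """Kruskal-Wallis across the per-sensor coefficient distributions.

    ``ecs`` is (items, sensors) for the correctly-assigned members of one
    cluster.  Post-hoc Dunn z-tests on pooled midranks give pairwise
    p-values; pairs are reported significant at ``alpha`` after Bonferroni
    division by ``n_comparisons`` (default: the number of pairs tested).
    """
    ecs = np.asarray(ecs, dtype=float)
    n, p = ecs.shape
    if n < 2:
        raise AnalysisError("sensor salience needs at least 2 items")
    if sensors is None:
        sensors = tuple(f"sensor_{j}" for j in range(p))

    groups = [ecs[:, j] for j in range(p)]
    h, p_omni = stats.kruskal(*groups)

    pooled = ecs.T.ravel()  # group-major
    ranks = stats.rankdata(pooled)
    N = pooled.size
    mean_ranks = ranks.reshape(p, n).mean(axis=1)

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    var_term = N * (N + 1) / 12.0 - tie_term
    se = np.sqrt(var_term * (2.0 / n))
    diff = np.abs(mean_ranks[:, None] - mean_ranks[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / se if se > 0 else np.full_like(diff, np.inf)
    pairwise_p = 2.0 * stats.norm.sf(z)
    np.fill_diagonal(pairwise_p, 1.0)

    n_pairs = p * (p - 1) // 2
    factor = n_pairs if n_comparisons is None else n_comparisons
    sig: list[tuple[str, str]] = []
    for i in range(p):
        for j in range(i + 1, p):
            if pairwise_p[i, j] < alpha / factor:
                sig.append((sensors[i], sensors[j]))
    return SalienceResult(
        sensors=sensors,
        mean_ranks=mean_ranks,
        h_statistic=float(h),
        p_value=float(p_omni),
        pairwise_p=pairwise_p,
        significant_pairs=sig,
        n_comparisons=factor,
        alpha=alpha,
    )
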