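"""Signed weighted correlation networks over the 12 key joint channels.

Per-run 12x12 Pearson matrices (finger MCP/PIP bends, thumb bends, palm arch,
thumb cross) are averaged over correctly-assigned runs into one weighted
undirected graph per hand with 66 edges; negative weights are retained.
Path-based metrics (global efficiency, characteristic path length) use edge
lengths 1/|w| on weight magnitudes; community structure uses signed
modularity with asymmetric treatment of negative weights.  Small-world
statistics are the classical index sigma (clustering over path length,
each relative to a weight-shuffled null ensemble) and the propensity phi
(deviation from lattice and random references built from the same weight
multiset); both conventions are explicit here because the source toolboxes
leave them configurable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from scipy.sparse.csgraph import dijkstra

from .errors import AnalysisError, ValidationError
from .glove_io import SensorRun

__all__ = [
    "JointNetwork",
    "NetworkMetrics",
    "run_correlation",
    "mean_network",
    "threshold_network",
    "global_efficiency",
    "characteristic_path_length",
    "weighted_clustering",
    "null_ensemble",
    "compare_to_null",
    "small_world",
    "louvain_modules",
]


@dataclass
class JointNetwork:
    """Symmetric signed weighted graph over named channels, zero diagonal."""

    nodes: tuple[str, ...]
    weights: np.ndarray
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.shape != (len(self.nodes), len(self.nodes)):
            raise ValidationError("weight matrix shape does not match node count")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValidationError("weight matrix must be symmetric")
        if np.any(np.abs(W) > 1.0 + 1e-10):
            raise ValidationError("weights must lie in [-1, 1]")
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edge_weights(self) -> np.ndarray:
        """Upper-triangle weights as a flat vector (66 entries for 12 nodes)."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu]


@dataclass
class NetworkMetrics:
    """Summary metrics of one joint network."""

    e_glob: float
    swp: float
    swi: float
    modules: dict[str, int]
    q: float
    null_comparison_p: float | None = None
    conventions: dict[str, str] = field(default_factory=dict)


def run_correlation(run: SensorRun) -> np.ndarray:
    """Pearson correlation matrix of a 12-channel run, diagonal zeroed."""
    X = run.data
    sd = X.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [run.layout.labels[i] for i in bad]
        raise AnalysisError(f"zero-variance channel(s) {names}: correlation undefined")
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 0.0)
    return R


def mean_network(
    mats: list[np.ndarray],
    nodes: tuple[str, ...],
    provenance: tuple[str, ...] = (),
) -> JointNetwork:
    """Elementwise mean of per-run correlation matrices; negatives retained."""
    if not mats:
        raise AnalysisError("no matrices to average")
    W = np.mean(np.stack(mats), axis=0)
    np.fill_diagonal(W, 0.0)
    return JointNetwork(nodes=nodes, weights=W, provenance=provenance)


def threshold_network(
    net: JointNetwork, tau: float, sign: str = "positive"
) -> JointNetwork:
    """Keep edges with w >= tau (positive) or w <= -tau (negative); nodes stay."""
    if tau < 0:
        raise ValidationError("tau must be non-negative")
    W = net.weights.copy()
    if sign == "positive":
        W[W < tau] = 0.0
    elif sign == "negative":
        W[W > -tau] = 0.0
    else:
        raise ValidationError("sign must be 'positive' or 'negative'")
    np.fill_diagonal(W, 0.0)
    return JointNetwork(nodes=net.nodes, weights=W, provenance=net.provenance)


def _length_matrix(W: np.ndarray) -> np.ndarray:
    """Edge lengths 1/|w|; absent edges are infinite."""
    A = np.abs(W)
    with np.errstate(divide="ignore"):
        L = np.where(A > 0, 1.0 / A, np.inf)
    np.fill_diagonal(L, 0.0)
    return L


def _shortest_paths(W: np.ndarray) -> np.ndarray:
    L = _length_matrix(W)
    finite = np.where(np.isinf(L), 0.0, L)
    mask = L > 0
    graph = np.where(mask & np.isfinite(L), finite, 0.0)
    return dijkstra(graph, directed=False)


def global_efficiency(net: JointNetwork) -> float:
    """Mean over node pairs of 1/shortest-path-length with lengths 1/|w|.

    Disconnected pairs contribute 0; in [0, 1] for correlation weights.
    """
    n = net.n_nodes
    if n < 2:
        raise AnalysisError("global efficiency needs >= 2 nodes")
    D = _shortest_paths(net.weights)
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D[iu]) & (D[iu] > 0), 1.0 / D[iu], 0.0)
    return float(inv.mean())


def characteristic_path_length(net: JointNetwork) -> float:
    """Mean shortest-path length over pairs; error when disconnected."""
    D = _shortest_paths(net.weights)
    iu = np.triu_indices(net.n_nodes, k=1)
    if np.any(np.isinf(D[iu])):
        raise AnalysisError("network is disconnected: path length undefined")
    return float(D[iu].mean())


def weighted_clustering(net: JointNetwork) -> float:
    """Mean Onnela weighted clustering coefficient on |weights|."""
    A = np.abs(net.weights)
    G = nx.from_numpy_array(A)
    return float(nx.average_clustering(G, weight="weight"))


# ---------------------------------------------------------------------------
# null models and small-world statistics
# ---------------------------------------------------------------------------

def null_ensemble(
    net: JointNetwork,
    n_graphs: int = 100,
    iterations: int = 1000,
    seed: int = 0,
) -> list[JointNetwork]:
    """Weight-shuffled null graphs preserving the edge-weight multiset.

    Each graph starts from the observed edge weights and applies
    ``iterations`` random pairwise swaps of edge weights (topology is the
    complete graph, matching the fully-connected correlation network).
    """
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(net.n_nodes, k=1)
    base = net.weights[iu].copy()
    out = []
    for _ in range(n_graphs):
        w = base.copy()
        m = w.size
        picks = rng.integers(0, m, size=(iterations, 2))
        for a, b in picks:
            w[a], w[b] = w[b], w[a]
        W = np.zeros_like(net.weights)
        W[iu] = w
        W = W + W.T
        out.append(JointNetwork(nodes=net.nodes, weights=W))
    return out


def compare_to_null(
    observed: float | np.ndarray,
    ensemble_values: np.ndarray,
) -> float:
    """Two-sided rank-sum p of observed metric value(s) against the ensemble."""
    obs = np.atleast_1d(np.asarray(observed, dtype=float))
    return float(
        stats.mannwhitneyu(obs, np.asarray(ensemble_values), alternative="two-sided").pvalue
    )


def _lattice_reference(net: JointNetwork) -> JointNetwork:
    """Ring lattice carrying the same weight-magnitude multiset.

    The largest magnitudes are placed on the shortest ring distances, giving
    a maximally clustered arrangement of the observed weights.
    """
    n = net.n_nodes
    iu = np.triu_indices(n, k=1)
    mags = np.sort(np.abs(net.weights[iu]))[::-1]
    ring_dist = np.minimum(np.abs(iu[0] - iu[1]), n - np.abs(iu[0] - iu[1]))
    order = np.argsort(ring_dist, kind="stable")
    w = np.empty_like(mags)
    w[order] = mags
    W = np.zeros((n, n))
    W[iu] = w
    W = W + W.T
    return JointNetwork(nodes=net.nodes, weights=W)


def small_world(
    net: JointNetwork,
    null: list[JointNetwork] | None = None,
    n_null: int = 20,
    seed: int = 0,
) -> tuple[float, float]:
    """(phi, sigma) small-world statistics on weight magnitudes.

    sigma = (C/C_null) / (L/L_null) with the null values being ensemble
    means over weight-shuffled graphs.  phi is the small-world propensity:
    1 - sqrt((dC^2 + dL^2)/2) with dC = (C_latt - C)/(C_latt - C_rand) and
    dL = (L - L_rand)/(L_latt - L_rand), both clamped to [0, 1]; the lattice
    reference is a ring lattice built from the same weight multiset and the
    random reference is the null-ensemble mean.
    """
    if null is None:
        null = null_ensemble(net, n_graphs=n_null, seed=seed)
    C = weighted_clustering(net)
    L = characteristic_path_length(net)
    C_rand = float(np.mean([weighted_clustering(g) for g in null]))
    # sparse graphs can shuffle into disconnected nulls; the path-length
    # reference averages over the connected members only
    null_L = []
    for g in null:
        try:
            null_L.append(characteristic_path_length(g))
        except AnalysisError:
            continue
    if not null_L or C_rand <= 0:
        raise AnalysisError("degenerate null ensemble")
    L_rand = float(np.mean(null_L))
    if L_rand <= 0:
        raise AnalysisError("degenerate null ensemble")
    sigma = (C / C_rand) / (L / L_rand)

    latt = _lattice_reference(net)
    C_latt = weighted_clustering(latt)
    L_latt = characteristic_path_length(latt)
    dC = (C_latt - C) / (C_latt - C_rand) if C_latt != C_rand else 0.0
    dL = (L - L_rand) / (L_latt - L_rand) if L_latt != L_rand else 0.0
    dC = float(np.clip(dC, 0.0, 1.0))
    dL = float(np.clip(dL, 0.0, 1.0))
    phi = 1.0 - np.sqrt((dC**2 + dL**2) / 2.0)
    return float(phi), float(sigma)


# ---------------------------------------------------------------------------
# signed Louvain community detection
# ---------------------------------------------------------------------------

def _signed_modularity_matrix(W: np.ndarray, gamma: float) -> np.ndarray:
    """Signed modularity matrix with asymmetric negative-weight treatment.

    Positive weights carry full modularity weight; negative weights enter
    only through the combined normalization, so positive structure dominates.
    """
    Wp = np.where(W > 0, W, 0.0)
    Wn = np.where(W < 0, -W, 0.0)
    sp, sn = Wp.sum(), Wn.sum()
    B = np.zeros_like(W)
    if sp > 0:
        kp = Wp.sum(axis=1)
        B += (Wp - gamma * np.outer(kp, kp) / sp) / sp
    if sn > 0:
        kn = Wn.sum(axis=1)
        B -= (Wn - gamma * np.outer(kn, kn) / sn) / (sp + sn)
    return 0.5 * (B + B.T)


def _louvain_on_matrix(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Generic Louvain over a (small, dense) modularity matrix."""
    n = B.shape[0]
    comm = np.arange(n)
    members: list[list[int]] = [[i] for i in range(n)]  # meta-node -> base nodes
    M = B.copy()
    while True:
        m = M.shape[0]
        labels = np.arange(m)
        improved_any = False
        while True:
            improved = False
            for i in rng.permutation(m):
                current = labels[i]
                labels[i] = -1
                gains: dict[int, float] = {}
                for c in set(labels[labels >= 0]):
                    mask = labels == c
                    gains[c] = 2.0 * M[i, mask].sum() + M[i, i]
                gains[current] = gains.get(current, M[i, i])
                best_c = max(
                    sorted(gains), key=lambda c: (gains[c], c == current)
                )
                if gains[best_c] <= gains.get(current, -np.inf) + 1e-15:
                    best_c = current
                labels[i] = best_c
                if best_c != current:
                    improved = improved_any = True
            if not improved:
                break
        uniq = np.unique(labels)
        if not improved_any or uniq.size == m:
            # map meta labels back to base nodes
            out = np.empty(n, dtype=int)
            for meta, lab in enumerate(labels):
                for node in members[meta]:
                    out[node] = lab
            # canonical relabel by first occurrence
            seen: dict[int, int] = {}
            for v in out:
                if v not in seen:
                    seen[v] = len(seen)
            return np.array([seen[v] for v in out])
        # aggregate
        new_members: list[list[int]] = []
        M2 = np.zeros((uniq.size, uniq.size))
        for a, ca in enumerate(uniq):
            ma = labels == ca
            new_members.append(
                [node for meta in np.flatnonzero(ma) for node in members[meta]]
            )
            for b, cb in enumerate(uniq):
                M2[a, b] = M[np.ix_(ma, labels == cb)].sum()
        M, members = M2, new_members


def modularity(net: JointNetwork, partition: np.ndarray, gamma: float = 1.0) -> float:
    """Signed modularity of a partition under the asymmetric convention."""
    B = _signed_modularity_matrix(net.weights, gamma)
    same = partition[:, None] == partition[None, :]
    return float(B[same].sum())


def louvain_modules(
    net: JointNetwork,
    gamma: float = 1.0,
    seed: int = 0,
    restarts: int = 100,
) -> tuple[dict[str, int], float]:
    """Consensus signed-Louvain partition over seeded restarts.

    Returns (node -> module id, modularity q).  The most frequent canonical
    partition across restarts wins; ties resolve to the higher-modularity
    partition, then lexicographically.
    """
    W = net.weights
    if np.allclose(W, 0.0):
        return {node: i for i, node in enumerate(net.nodes)}, 0.0
    B = _signed_modularity_matrix(W, gamma)
    rng = np.random.default_rng(seed)
    counts: Counter[tuple[int, ...]] = Counter()
    for _ in range(restarts):
        part = _louvain_on_matrix(B, rng)
        counts[tuple(int(v) for v in part)] += 1
    best = max(
        counts,
        key=lambda p: (
            counts[p],
            modularity(net, np.array(p), gamma),
            tuple(-v for v in p),
        ),
    )
    part = np.array(best)
    return {node: int(part[i]) for i, node in enumerate(net.nodes)}, modularity(
        net, part, gamma
    )
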