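"""Global graph-theory metrics on binary brain networks.

All metrics operate on undirected, unweighted adjacency matrices
(symmetric 0/1, zero diagonal).  Five global attributes are provided:

====================  =========================================================
characteristic path   mean shortest-path hop count over reachable unordered
length (Char)         node pairs
global efficiency     mean of 1/d(i,j) over ordered pairs, with 1/inf = 0 for
(Effi)                unreachable pairs
clustering            mean over nodes of C_i = t_i / (k_i (k_i - 1) / 2),
coefficient (Clus)    C_i = 0 for nodes of degree < 2
transitivity (Tran)   2 * sum_i t_i / sum_i k_i (k_i - 1)
small-worldness (SW)  (Clus / C0) / (Char / L0), with C0 and L0 taken from an
                      ensemble of random graphs of identical size and density
====================  =========================================================

where k_i is the degree of node i and t_i the number of edges among its
neighbours.  Functional brain networks binarized at low sparsity are often
disconnected; Char therefore averages over reachable pairs only and every
result carries a connectedness flag, while efficiency needs no special case.

Metric curves over a sparsity sweep are summarized by the trapezoidal area
under the curve (AUC), which removes the dependence on any single threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "GlobalMetrics",
    "RandomReference",
    "ReferenceCache",
    "MetricCurve",
    "MetricAUC",
    "METRIC_NAMES",
    "characteristic_path_length",
    "global_efficiency",
    "clustering_coefficient",
    "transitivity",
    "random_reference",
    "small_worldness",
    "global_metrics",
    "metric_auc",
]

#: canonical metric order used in all result tables
METRIC_NAMES = ("char_path_length", "efficiency", "clustering", "transitivity", "small_worldness")


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlobalMetrics:
    """The five global attributes of one binary graph."""

    char_path_length: float
    efficiency: float
    clustering: float
    transitivity: float
    small_worldness: float
    connected: bool = True

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class RandomReference:
    """Ensemble means of a matched random-graph reference.

    c0 and l0 are the mean clustering coefficient and mean characteristic
    path length of ``n_random`` uniform random graphs with the same node
    count and edge count as the graph under study.
    """

    c0: float
    l0: float
    n_random: int
    seed: int
    n_nodes: int
    n_edges: int


@dataclass(frozen=True)
class MetricCurve:
    """One metric's values across a sparsity grid."""

    grid: np.ndarray
    values: np.ndarray
    metric_name: str

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.values):
            raise ValueError(
                f"grid has {len(self.grid)} points but values has {len(self.values)}"
            )


@dataclass(frozen=True)
class MetricAUC:
    value: float
    metric_name: str
    s_min: float
    s_max: float


# ---------------------------------------------------------------------------
# adjacency helpers
# ---------------------------------------------------------------------------

def _validate_adjacency(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {adj.shape}")
    return adj


def _hop_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path hop counts (inf for unreachable pairs).

    Uses breadth-first expansion by boolean matrix products: one product
    per hop level, cheap for the network sizes this package handles
    (N <= a few hundred) where per-call overhead dominates, with a
    csgraph fallback for large graphs.
    """
    adj = _validate_adjacency(adj)
    n = adj.shape[0]
    if not adj.any():
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    if n > 256:
        return shortest_path(adj.astype(np.float64), method="D", unweighted=True,
                             directed=False)
    a = adj.astype(bool)
    d = np.where(a, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    reach = a | np.eye(n, dtype=bool)
    hop = 1
    while True:
        new = reach @ a
        newly = new & ~reach
        if not newly.any():
            return d
        hop += 1
        d[newly] = hop
        reach |= newly


def _triangles_and_degrees(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node triangle counts t_i and degrees k_i."""
    a = _validate_adjacency(adj).astype(np.float64)
    k = a.sum(axis=1)
    # t_i = row sum of A * (A @ A), i.e. edges between neighbours of i
    t = (a * (a @ a)).sum(axis=1) / 2.0
    return t, k


# ---------------------------------------------------------------------------
# the five metrics
# ---------------------------------------------------------------------------

def _char_from_distances(d: np.ndarray) -> tuple[float, bool]:
    n = d.shape[0]
    pair_d = d[np.triu_indices(n, k=1)]
    finite = np.isfinite(pair_d)
    if not finite.any():
        raise ValueError("graph has no reachable node pair (empty graph)")
    return float(pair_d[finite].mean()), bool(finite.all())


def _eff_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def _clus_from_tk(t: np.ndarray, k: np.ndarray) -> float:
    denom = k * (k - 1) / 2.0
    c = np.where(denom > 0, t / np.where(denom > 0, denom, 1.0), 0.0)
    return float(c.mean())


def characteristic_path_length(adj: np.ndarray) -> tuple[float, bool]:
    """Mean shortest-path length over reachable unordered pairs.

    Returns
    -------
    (value, connected)
        ``value`` is the pair-restricted mean hop count; ``connected`` is
        False when at least one pair is unreachable (the mean then covers
        the reachable pairs only).

    Raises
    ------
    ValueError
        If the graph has fewer than two nodes or no reachable pair at all.
    """
    adj = _validate_adjacency(adj)
    if adj.shape[0] < 2:
        raise ValueError("characteristic path length needs at least 2 nodes")
    return _char_from_distances(_hop_distances(adj))


def global_efficiency(adj: np.ndarray) -> float:
    """Mean inverse shortest-path length; unreachable pairs contribute 0."""
    adj = _validate_adjacency(adj)
    if adj.shape[0] < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return _eff_from_distances(_hop_distances(adj))


def clustering_coefficient(adj: np.ndarray) -> float:
    """Mean over nodes of the fraction of neighbour pairs that are linked.

    Nodes of degree 0 or 1 have no neighbour pair and contribute C_i = 0.
    """
    adj = _validate_adjacency(adj)
    if adj.shape[0] == 0:
        raise ValueError("clustering coefficient of an empty node set is undefined")
    return _clus_from_tk(*_triangles_and_degrees(adj))


def transitivity(adj: np.ndarray) -> float:
    """Graph-level triangle density 2*sum(t_i) / sum(k_i (k_i - 1)).

    When the graph has no connected triple (denominator zero) the value is
    defined as 0 and a warning is emitted.
    """
    adj = _validate_adjacency(adj)
    t, k = _triangles_and_degrees(adj)
    denom = float((k * (k - 1)).sum())
    if denom == 0.0:
        warnings.warn("transitivity undefined (no connected triples); returning 0", stacklevel=2)
        return 0.0
    return float(2.0 * t.sum() / denom)


# ---------------------------------------------------------------------------
# random reference and small-worldness
# ---------------------------------------------------------------------------

def _random_adjacency(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random graph with exactly k edges on n nodes."""
    m = n * (n - 1) // 2
    chosen = rng.choice(m, size=k, replace=False)
    iu = np.triu_indices(n, k=1)
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[0][chosen], iu[1][chosen]] = 1
    return adj | adj.T


def random_reference(adj: np.ndarray, n_random: int = 100, seed: int = 0) -> RandomReference:
    """Matched random-network reference for small-worldness.

    Generates ``n_random`` graphs drawn uniformly from all graphs with the
    same node count and edge count as ``adj`` (same size and density), and
    returns the ensemble means of clustering (C0) and characteristic path
    length (L0).  Reproducible under ``seed``.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    adj = _validate_adjacency(adj)
    n = adj.shape[0]
    k = int(np.triu(adj, k=1).sum())
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(n, k)))
    cs = np.empty(n_random)
    ls = np.empty(n_random)
    for i in range(n_random):
        r = _random_adjacency(n, k, rng)
        cs[i] = _clus_from_tk(*_triangles_and_degrees(r))
        ls[i] = _char_from_distances(_hop_distances(r))[0] if k > 0 else np.nan
    return RandomReference(
        c0=float(cs.mean()), l0=float(ls.mean()), n_random=n_random,
        seed=seed, n_nodes=n, n_edges=k,
    )


def small_worldness(adj: np.ndarray, ref: RandomReference) -> float:
    """(Clus/C0) / (Char/L0) against a matched random reference.

    Values above 1 indicate small-world organization: more clustered than
    random at comparable path length.
    """
    if ref.c0 <= 0:
        raise ValueError("reference clustering C0 must be positive")
    if ref.l0 <= 0:
        raise ValueError("reference path length L0 must be positive")
    c = clustering_coefficient(adj)
    l, _ = characteristic_path_length(adj)
    if c == 0.0:
        warnings.warn("graph has zero clustering; small-worldness set to 0", stacklevel=2)
        return 0.0
    return (c / ref.c0) / (l / ref.l0)


class ReferenceCache:
    """Cache of :func:`random_reference` results keyed by (n_nodes, n_edges).

    The reference ensemble depends on the graph only through its size and
    density, so one ensemble per (N, k) serves every subject binarized at
    the same sparsity.  Per-key seeds are derived deterministically from
    the base seed, making results independent of call order.
    """

    def __init__(self, n_random: int = 100, seed: int = 0) -> None:
        self.n_random = n_random
        self.seed = seed
        self._store: dict[tuple[int, int], RandomReference] = {}

    def get(self, adj: np.ndarray) -> RandomReference:
        adj = _validate_adjacency(adj)
        n = adj.shape[0]
        k = int(np.triu(adj, k=1).sum())
        key = (n, k)
        if key not in self._store:
            self._store[key] = random_reference(adj, n_random=self.n_random, seed=self.seed)
        return self._store[key]


def global_metrics(adj: np.ndarray, ref: RandomReference | None = None,
                   *, n_random: int = 100, seed: int = 0) -> GlobalMetrics:
    """Compute all five global attributes of one binary graph.

    A matched random reference is generated when ``ref`` is not supplied.
    """
    adj = _validate_adjacency(adj)
    if ref is None:
        ref = random_reference(adj, n_random=n_random, seed=seed)
    d = _hop_distances(adj)
    char, connected = _char_from_distances(d)
    t, k = _triangles_and_degrees(adj)
    clus = _clus_from_tk(t, k)
    tri_denom = float((k * (k - 1)).sum())
    if tri_denom == 0.0:
        warnings.warn("transitivity undefined (no connected triples); returning 0", stacklevel=2)
        tran = 0.0
    else:
        tran = float(2.0 * t.sum() / tri_denom)
    if clus == 0.0:
        warnings.warn("graph has zero clustering; small-worldness set to 0", stacklevel=2)
        sw = 0.0
    elif ref.c0 <= 0 or ref.l0 <= 0:
        # no reference graph had a triangle (tiny, very sparse networks):
        # the normalization is undefined at this density
        warnings.warn("degenerate random reference (C0 or L0 zero); "
                      "small-worldness undefined (NaN)", stacklevel=2)
        sw = float("nan")
    else:
        sw = (clus / ref.c0) / (char / ref.l0)
    return GlobalMetrics(
        char_path_length=char,
        efficiency=_eff_from_distances(d),
        clustering=clus,
        transitivity=tran,
        small_worldness=sw,
        connected=connected,
    )


# ---------------------------------------------------------------------------
# AUC over the sparsity sweep
# ---------------------------------------------------------------------------

def metric_auc(curve: MetricCurve) -> MetricAUC:
    """Trapezoidal area under a metric curve over its sparsity grid."""
    grid = np.asarray(curve.grid, dtype=float)
    values = np.asarray(curve.values, dtype=float)
    if len(grid) < 2:
        raise ValueError("AUC needs a grid of at least 2 points")
    return MetricAUC(
        value=float(np.trapezoid(values, grid)),
        metric_name=curve.metric_name,
        s_min=float(grid[0]),
        s_max=float(grid[-1]),
    )
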