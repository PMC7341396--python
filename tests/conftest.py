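"""Shared fixtures and independent brute-force oracles.

The oracle implementations here deliberately use the dumbest correct
algorithms (Floyd-Warshall distances, exhaustive triple/triangle
enumeration, step-up-by-definition FDR) so the package's vectorized
implementations are checked against an independent computation path.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# brute-force graph-metric oracles
# ---------------------------------------------------------------------------

def bf_distances(adj: np.ndarray) -> np.ndarray:
    """Floyd-Warshall hop distances, inf for unreachable pairs."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def bf_char_path_length(adj: np.ndarray) -> float:
    d = bf_distances(adj)
    vals = [d[i, j] for i in range(len(d)) for j in range(i + 1, len(d))
            if np.isfinite(d[i, j])]
    return float(np.mean(vals))


def bf_global_efficiency(adj: np.ndarray) -> float:
    d = bf_distances(adj)
    n = len(d)
    total = sum(1.0 / d[i, j] for i in range(n) for j in range(n)
                if i != j and np.isfinite(d[i, j]))
    return total / (n * (n - 1))


def bf_node_triangles(adj: np.ndarray, i: int) -> int:
    nbrs = np.flatnonzero(adj[i])
    return sum(int(adj[a, b]) for a, b in itertools.combinations(nbrs, 2))


def bf_clustering(adj: np.ndarray) -> float:
    n = len(adj)
    cs = []
    for i in range(n):
        k = int(adj[i].sum())
        cs.append(bf_node_triangles(adj, i) / (k * (k - 1) / 2) if k >= 2 else 0.0)
    return float(np.mean(cs))


def bf_transitivity(adj: np.ndarray) -> float:
    n = len(adj)
    tri = sum(bf_node_triangles(adj, i) for i in range(n))
    triples = sum(int(adj[i].sum()) * (int(adj[i].sum()) - 1) for i in range(n))
    return 2.0 * tri / triples if triples else 0.0


def bf_bh(p: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-up BH by definition: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, m * p[idx] / rank)
        q_sorted[rank - 1] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= alpha


def random_adjacency(n: int, density: float, rng: np.random.Generator) -> np.ndarray:
    mask = np.triu(np.ones((n, n), dtype=bool), 1)
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[mask] = rng.random(mask.sum()) < density
    return adj | adj.T


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_cohort_config():
    """A scaled-down cohort for fast pipeline tests (structure preserved)."""
    from adgraph import CohortConfig

    return CohortConfig(
        n_rois=30, n_timepoints=60,
        group_sizes={"NC": 5, "EMCI": 5, "LMCI": 5, "AD": 5},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    from adgraph import generate_cohort

    return generate_cohort(small_cohort_config)
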