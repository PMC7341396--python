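"""Functional connectivity matrices and sparsity-threshold binarization.

A subject's functional network starts as the Pearson correlation matrix of
the ROI time series (diagonal zeroed).  The matrix is binarized at a
sparsity S — the fraction of retained edges out of all N(N-1)/2 possible
ones — by keeping the k = round(S * N(N-1)/2) strongest edges.  Because no
single threshold is privileged, analyses sweep S over an arithmetic grid;
the grid bounds are chosen so that (a) the average degree is at least
2*log(N) and (b) the normal-control group's mean small-worldness stays at
or above 1.1, which together limit spurious edges while preserving
small-world topology.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import metrics as _metrics

__all__ = [
    "ConnectivityMatrix",
    "BinaryGraph",
    "SparsityRange",
    "correlation_matrix",
    "edge_count_at_sparsity",
    "binarize_at_sparsity",
    "degree_criterion_lower_bound",
    "select_sparsity_range",
]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix with zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) != 0.0:
            raise ValueError("connectivity matrix diagonal must be zero")
        if v.size and (np.abs(v).max() > 1.0 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    @property
    def roi_count(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected unweighted adjacency at a given sparsity.

    ``empty`` flags the degenerate case where the requested sparsity keeps
    zero edges (possible for very small networks at low S).
    """

    adjacency: np.ndarray
    sparsity: float
    empty: bool = False

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, k=1).sum())


@dataclass(frozen=True)
class SparsityRange:
    """Arithmetic sparsity grid [s_min, s_max] with a fixed step."""

    s_min: float
    s_max: float
    step: float
    grid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not (0 < self.s_min <= self.s_max < 1):
            raise ValueError("need 0 < s_min <= s_max < 1")
        if self.step <= 0:
            raise ValueError("step must be positive")
        n = round((self.s_max - self.s_min) / self.step) + 1
        grid = self.s_min + self.step * np.arange(n)
        if abs(grid[-1] - self.s_max) > 1e-9:
            raise ValueError(
                f"(s_max - s_min) = {self.s_max - self.s_min} is not a multiple of step {self.step}"
            )
        grid[-1] = self.s_max
        object.__setattr__(self, "grid", grid)

    def __len__(self) -> int:
        return len(self.grid)


def correlation_matrix(data: np.ndarray) -> ConnectivityMatrix:
    """Pearson correlation matrix of ROI time series.

    Parameters
    ----------
    data
        T x N array, rows = time points, columns = ROIs.  Needs T >= 3 and
        every column non-constant.

    Returns
    -------
    ConnectivityMatrix
        N x N correlations with the diagonal (self-correlation) zeroed.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("time series must be a 2-D array (time x ROI)")
    t, n = data.shape
    if t < 3:
        raise ValueError(f"need at least 3 time points, got {t}")
    sd = data.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(f"constant time series at ROI index(es) {constant.tolist()}")
    c = np.corrcoef(data, rowvar=False)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 0.0)
    return ConnectivityMatrix(values=c)


def edge_count_at_sparsity(n_nodes: int, sparsity: float) -> int:
    """k = round(S * N(N-1)/2), rounding half up (bit-reproducible)."""
    m = n_nodes * (n_nodes - 1) // 2
    return int(math.floor(sparsity * m + 0.5))


def binarize_at_sparsity(c: ConnectivityMatrix | np.ndarray, sparsity: float,
                         *, rank: str = "signed") -> BinaryGraph:
    """Keep the k strongest edges of a connectivity matrix.

    Edges are ranked by signed correlation value, descending ('signed',
    default) or by absolute value ('absolute').  Ties are broken
    deterministically by ascending (i, j) so the sweep is stable and
    monotone: the edge set at S1 < S2 is a subset of the edge set at S2.

    A sparsity so small that k = 0 returns an edgeless graph flagged
    ``empty`` (with a warning) rather than raising.
    """
    if not (0 < sparsity < 1):
        raise ValueError(f"sparsity must be in (0, 1), got {sparsity}")
    if rank not in ("signed", "absolute"):
        raise ValueError(f"rank must be 'signed' or 'absolute', got {rank!r}")
    values = c.values if isinstance(c, ConnectivityMatrix) else np.asarray(c, dtype=float)
    n = values.shape[0]
    k = edge_count_at_sparsity(n, sparsity)
    ii, jj = np.triu_indices(n, k=1)
    vals = values[ii, jj]
    key = -np.abs(vals) if rank == "absolute" else -vals
    # lexsort: primary key last -> value desc, then i asc, then j asc
    order = np.lexsort((jj, ii, key))[:k]
    adj = np.zeros((n, n), dtype=np.uint8)
    if k == 0:
        warnings.warn(f"sparsity {sparsity} keeps 0 of {len(vals)} edges", stacklevel=2)
        return BinaryGraph(adjacency=adj, sparsity=sparsity, empty=True)
    adj[ii[order], jj[order]] = 1
    adj |= adj.T
    return BinaryGraph(adjacency=adj, sparsity=sparsity, empty=False)


def degree_criterion_lower_bound(n_nodes: int, degree_factor: float = 2.0,
                                 log_base: str = "e") -> float:
    """Smallest sparsity with mean degree >= degree_factor * log(N).

    For a graph binarized at sparsity S the mean degree is exactly
    S * (N - 1), so the bound is degree_factor * log(N) / (N - 1).
    """
    log_n = math.log(n_nodes) if log_base == "e" else math.log10(n_nodes)
    return degree_factor * log_n / (n_nodes - 1)


def select_sparsity_range(nc_matrices: list[ConnectivityMatrix], step: float = 0.01,
                          *, degree_factor: float = 2.0, sw_floor: float = 1.1,
                          log_base: str = "e", rank: str = "signed",
                          n_random: int = 100, seed: int = 0) -> SparsityRange:
    """Select the sparsity sweep from the normal-control group.

    Scans the arithmetic grid {step, 2*step, ...} < 1 and returns the
    maximal contiguous run of sparsities on which

    (a) every NC subject's binarized graph has mean degree at least
        ``degree_factor * log(N)`` (equivalently S*(N-1) >= the bound,
        which is subject-independent), and
    (b) the NC-group mean small-worldness is at least ``sw_floor``.

    Raises ``ValueError``, reporting which criterion fails where, when no
    grid point satisfies both.
    """
    if not nc_matrices:
        raise ValueError("need at least one NC connectivity matrix")
    if step <= 0:
        raise ValueError("step must be positive")
    n = nc_matrices[0].roi_count
    bound = degree_criterion_lower_bound(n, degree_factor, log_base)
    n_points = int(math.ceil((1.0 - 1e-9) / step)) - 1
    grid = step * np.arange(1, n_points + 1)

    cache = _metrics.ReferenceCache(n_random=n_random, seed=seed)
    ok = np.zeros(n_points, dtype=bool)
    degree_ok_any = False
    for idx, s in enumerate(grid):
        # (a) mean degree = 2k/N, identical for every subject at this S
        k = edge_count_at_sparsity(n, s)
        if 2.0 * k / n < degree_factor * (math.log(n) if log_base == "e" else math.log10(n)):
            continue
        degree_ok_any = True
        sws = []
        for c in nc_matrices:
            g = binarize_at_sparsity(c, float(s), rank=rank)
            sws.append(_metrics.small_worldness(g.adjacency, cache.get(g.adjacency)))
        if float(np.mean(sws)) >= sw_floor:
            ok[idx] = True

    if not ok.any():
        if not degree_ok_any:
            raise ValueError(
                f"degree criterion (mean degree >= {degree_factor}*log(N), lower bound "
                f"S >= {bound:.4f}) holds nowhere on the grid"
            )
        raise ValueError(
            f"small-worldness criterion (NC mean >= {sw_floor}) fails at every sparsity "
            f"passing the degree criterion (S >= {bound:.4f})"
        )
    # maximal contiguous run of True
    best_start, best_len, start = 0, 0, None
    for idx, flag in enumerate(np.append(ok, False)):
        if flag and start is None:
            start = idx
        elif not flag and start is not None:
            if idx - start > best_len:
                best_start, best_len = start, idx - start
            start = None
    lo, hi = grid[best_start], grid[best_start + best_len - 1]
    return SparsityRange(s_min=float(lo), s_max=float(hi), step=step)
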