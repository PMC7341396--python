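"""Subnetwork (RSN-level) connectivity and graph metrics.

Given a whole-brain connectivity matrix and a partition of ROIs into
resting-state networks, this module extracts

* the intra-network connectivity submatrix of each network (from which
  subnetwork binary graphs and graph metrics are computed over the same
  sparsity sweep as the whole brain), and
* the inter-network functional connectivity: the mean correlation over
  all region pairs spanning two networks.

Subnetwork binarization spends the SUBNETWORK's own edge budget
(k = round(S * |n|(|n|-1)/2) from its own correlation block) rather than
restricting the globally thresholded graph; the alternative is available
via ``mode='restrict'``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import metrics as _metrics
from .connectivity import BinaryGraph, ConnectivityMatrix, SparsityRange, binarize_at_sparsity
from .metrics import METRIC_NAMES, MetricAUC, MetricCurve, ReferenceCache, metric_auc
from .synthetic import RSNPartition

__all__ = [
    "InterNetworkFC",
    "extract_intra_network",
    "inter_network_fc",
    "all_inter_network_fc",
    "metric_sweep",
    "subnetwork_metric_sweep",
    "SweepResult",
]


@dataclass(frozen=True)
class InterNetworkFC:
    """Mean functional connectivity between two networks."""

    pair: tuple[str, str]
    value: float
    n_pairs: int


@dataclass(frozen=True)
class SweepResult:
    """Curves and AUCs of the five metrics over one sparsity sweep.

    ``valid`` marks grid points where the binarized graph had at least one
    edge and at least one reachable pair; AUC integrates over the maximal
    valid sub-grid only (relevant for very small networks at low S).
    ``connected`` marks grid points where the graph was fully connected.
    """

    grid: np.ndarray
    curves: dict[str, MetricCurve]
    aucs: dict[str, MetricAUC]
    valid: np.ndarray
    connected: np.ndarray


def extract_intra_network(c: ConnectivityMatrix, partition: RSNPartition,
                          network: str) -> ConnectivityMatrix:
    """Principal submatrix of ``c`` over one network's ROIs (order kept)."""
    idx = partition.indices(network)
    if len(idx) < 3:
        raise ValueError(
            f"network {network!r} has {len(idx)} ROIs; graph metrics need at least 3"
        )
    return ConnectivityMatrix(values=c.values[np.ix_(idx, idx)])


def inter_network_fc(c: ConnectivityMatrix, partition: RSNPartition,
                     net_a: str, net_b: str) -> InterNetworkFC:
    """Mean correlation over all (i in a, j in b) region pairs."""
    if net_a == net_b:
        raise ValueError(f"inter-network FC needs two distinct networks, got {net_a!r} twice")
    ia, ib = partition.indices(net_a), partition.indices(net_b)
    block = c.values[np.ix_(ia, ib)]
    return InterNetworkFC(pair=(net_a, net_b), value=float(block.mean()),
                          n_pairs=block.size)


def all_inter_network_fc(c: ConnectivityMatrix, partition: RSNPartition) -> list[InterNetworkFC]:
    """Inter-network FC for every unordered network pair."""
    nets = partition.networks
    return [inter_network_fc(c, partition, a, b)
            for i, a in enumerate(nets) for b in nets[i + 1:]]


def _binary_graphs(c: ConnectivityMatrix, grid: np.ndarray, rank: str) -> list[BinaryGraph]:
    graphs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in grid:
            graphs.append(binarize_at_sparsity(c, float(s), rank=rank))
    return graphs


def _quiet_metrics(adj: np.ndarray, ref) -> _metrics.GlobalMetrics:
    # low-sparsity graphs legitimately hit the zero-triple / zero-clustering
    # warnings; the sweep records the defined values silently
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _metrics.global_metrics(adj, ref)


def _tail_aucs(grid_arr: np.ndarray, values: dict[str, np.ndarray]) -> dict[str, MetricAUC]:
    """Per-metric AUC over the maximal contiguous finite run ending at s_max.

    Grid points where a metric is undefined (empty graph, or degenerate
    small-world reference) are excluded from that metric's integral; a
    metric with fewer than 2 finite points gets a NaN AUC.
    """
    aucs: dict[str, MetricAUC] = {}
    for name in METRIC_NAMES:
        finite = np.isfinite(values[name])
        bad = np.flatnonzero(~finite)
        start = bad.max() + 1 if bad.size else 0
        if len(grid_arr) - start >= 2:
            aucs[name] = metric_auc(MetricCurve(
                grid=grid_arr[start:], values=values[name][start:], metric_name=name))
        else:
            aucs[name] = MetricAUC(value=float("nan"), metric_name=name,
                                   s_min=float(grid_arr[0]), s_max=float(grid_arr[-1]))
    return aucs


def metric_sweep(c: ConnectivityMatrix, grid: SparsityRange | np.ndarray,
                 *, rank: str = "signed",
                 ref_cache: ReferenceCache | None = None) -> SweepResult:
    """All five metric curves and AUCs of one connectivity matrix.

    Binarizes ``c`` at every sparsity on the grid, computes the five
    global metrics per threshold (small-worldness against a matched random
    reference, shared across subjects through ``ref_cache``) and their
    trapezoidal AUCs over the valid portion of the grid.
    """
    grid_arr = grid.grid if isinstance(grid, SparsityRange) else np.asarray(grid, dtype=float)
    if ref_cache is None:
        ref_cache = ReferenceCache()
    values = {name: np.full(len(grid_arr), np.nan) for name in METRIC_NAMES}
    valid = np.zeros(len(grid_arr), dtype=bool)
    connected = np.zeros(len(grid_arr), dtype=bool)
    for i, g in enumerate(_binary_graphs(c, grid_arr, rank)):
        if g.empty:
            continue
        m = _quiet_metrics(g.adjacency, ref_cache.get(g.adjacency))
        for name in METRIC_NAMES:
            values[name][i] = getattr(m, name)
        valid[i] = True
        connected[i] = m.connected
    curves = {name: MetricCurve(grid=grid_arr, values=values[name], metric_name=name)
              for name in METRIC_NAMES}
    return SweepResult(grid=grid_arr, curves=curves, aucs=_tail_aucs(grid_arr, values),
                       valid=valid, connected=connected)


def subnetwork_metric_sweep(c: ConnectivityMatrix, partition: RSNPartition,
                            grid: SparsityRange | np.ndarray, *, rank: str = "signed",
                            mode: str = "own_budget",
                            ref_cache: ReferenceCache | None = None) -> dict[str, SweepResult]:
    """Per-network metric curves and AUCs over the (shared) sparsity grid.

    ``mode='own_budget'`` (default) binarizes each network's own
    correlation block at each sparsity; ``mode='restrict'`` instead
    restricts the whole-brain binary graph to the network's ROIs.
    """
    if mode not in ("own_budget", "restrict"):
        raise ValueError(f"mode must be 'own_budget' or 'restrict', got {mode!r}")
    grid_arr = grid.grid if isinstance(grid, SparsityRange) else np.asarray(grid, dtype=float)
    if ref_cache is None:
        ref_cache = ReferenceCache()
    out: dict[str, SweepResult] = {}
    if mode == "own_budget":
        for net in partition.networks:
            try:
                sub_c = extract_intra_network(c, partition, net)
                out[net] = metric_sweep(sub_c, grid_arr, rank=rank, ref_cache=ref_cache)
            except ValueError as err:
                raise ValueError(f"subnetwork {net!r}: {err}") from err
        return out
    # restrict mode: cut each global binary graph down to the network
    global_graphs = _binary_graphs(c, grid_arr, rank)
    for net in partition.networks:
        idx = partition.indices(net)
        if len(idx) < 3:
            raise ValueError(f"subnetwork {net!r} has fewer than 3 ROIs")
        values = {name: np.full(len(grid_arr), np.nan) for name in METRIC_NAMES}
        valid = np.zeros(len(grid_arr), dtype=bool)
        connected = np.zeros(len(grid_arr), dtype=bool)
        for i, g in enumerate(global_graphs):
            adj = g.adjacency[np.ix_(idx, idx)]
            if not adj.any():
                continue
            m = _quiet_metrics(adj, ref_cache.get(adj))
            for name in METRIC_NAMES:
                values[name][i] = getattr(m, name)
            valid[i] = True
            connected[i] = m.connected
        curves = {name: MetricCurve(grid=grid_arr, values=values[name], metric_name=name)
                  for name in METRIC_NAMES}
        out[net] = SweepResult(grid=grid_arr, curves=curves,
                               aucs=_tail_aucs(grid_arr, values), valid=valid,
                               connected=connected)
    return out
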