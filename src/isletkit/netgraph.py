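"""Functional networks: correlation thresholding, communities, hubs.

Edges connect cell pairs whose Pearson correlation over the sustained
phase exceeds a threshold chosen so that the network's mean degree hits
a target (default 8 connections per cell).  Communities are found by
modularity maximization (Louvain); the most-connected sextile of cells
are hubs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .traces import TraceSet, top_sextile

DEFAULT_K_TARGET = 8.0
DEFAULT_DEGREE_TOL = 0.2


@dataclass
class FunctionalNetwork:
    """Thresholded correlation network.

    ``adjacency`` is boolean, symmetric, zero-diagonal; ``threshold`` is
    the correlation value of the weakest retained edge.
    """

    adjacency: np.ndarray
    threshold: float
    k_avg: float
    degrees: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_cells))
        g.add_edges_from(zip(*np.nonzero(np.triu(self.adjacency, 1))))
        return g


@dataclass
class CommunityPartition:
    labels: np.ndarray
    Q: float
    n_communities: int


@dataclass
class HubLabels:
    hub_flag: np.ndarray


def correlation_matrix(ts: TraceSet, window: tuple[float, float] | None = None
                       ) -> np.ndarray:
    """Pairwise Pearson correlation of traces over ``window``.

    Zero-variance cells get zero rows/columns (excluded from edges) with a
    warning; the diagonal is kept at 1 for well-defined cells.
    """
    v = ts.values
    if window is not None:
        sel = (ts.time_s >= window[0]) & (ts.time_s < window[1])
        if sel.sum() < 2:
            raise ValueError("correlation window contains fewer than 2 frames")
        v = v[sel]
    sd = v.std(axis=0)
    flat = sd <= 1e-12
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance cell(s) excluded from "
                      "correlation edges", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(v, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    np.fill_diagonal(r, np.where(flat, 0.0, 1.0))
    return np.clip(r, -1.0, 1.0)


def threshold_to_degree(r: np.ndarray, k_target: float = DEFAULT_K_TARGET,
                        tol: float = DEFAULT_DEGREE_TOL) -> FunctionalNetwork:
    """Cut the correlation matrix at the rank giving mean degree ``k_target``.

    The round(N * k_target / 2) strongest off-diagonal pairs become edges
    (ties broken deterministically by pair index), so the achieved mean
    degree is exact up to rounding of the edge count; ``tol`` only governs
    the warning emitted when it cannot be met.
    """
    n = r.shape[0]
    if r.shape != (n, n):
        raise ValueError("correlation matrix must be square")
    if k_target >= n - 1:
        raise ValueError(f"k_target must be < N-1 = {n - 1}")
    iu, ju = np.triu_indices(n, k=1)
    vals = r[iu, ju]
    m = int(round(n * k_target / 2.0))
    m = min(m, len(vals))
    order = np.lexsort((ju, iu, -vals))  # strongest first, index tie-break
    keep = order[:m]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[keep], ju[keep]] = True
    adj |= adj.T
    threshold = float(vals[keep[-1]]) if m else float("inf")
    degrees = adj.sum(axis=1)
    k_avg = 2.0 * m / n
    if abs(k_avg - k_target) > tol:
        warnings.warn(f"achieved mean degree {k_avg:.3f} misses target "
                      f"{k_target:g} by more than {tol:g}", stacklevel=2)
    return FunctionalNetwork(adjacency=adj, threshold=threshold,
                             k_avg=k_avg, degrees=degrees)


def modularity(adjacency: np.ndarray, labels: np.ndarray) -> float:
    """Newman-Girvan modularity Q of a partition of an unweighted graph.

    Q = sum_c [ e_c / m - (d_c / 2m)^2 ] with m the edge count, e_c the
    intra-community edge count and d_c the total degree of community c.
    Returns NaN for an empty graph.
    """
    adjacency = np.asarray(adjacency)
    labels = np.asarray(labels)
    if labels.shape[0] != adjacency.shape[0]:
        raise ValueError("labels must cover all nodes")
    deg = adjacency.sum(axis=1)
    two_m = float(deg.sum())
    if two_m == 0:
        return float("nan")
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        e_c = adjacency[np.ix_(idx, idx)].sum() / 2.0
        d_c = deg[idx].sum()
        q += e_c / (two_m / 2.0) - (d_c / two_m) ** 2
    return float(q)


def detect_communities(net: FunctionalNetwork, seed: int = 0,
                       resolution: float = 1.0) -> CommunityPartition:
    """Louvain modularity communities; isolated nodes become singletons.

    Labels are renumbered by ascending smallest member index so the same
    partition always gets the same labeling.
    """
    g = net.to_networkx()
    if net.n_cells == 0:
        raise ValueError("empty network")
    comms = nx.community.louvain_communities(g, seed=seed, resolution=resolution)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    labels = np.empty(net.n_cells, dtype=int)
    for k, c in enumerate(comms):
        labels[list(c)] = k
    q = modularity(net.adjacency, labels)
    if math.isnan(q):
        q = 0.0
    return CommunityPartition(labels=labels, Q=q, n_communities=len(comms))


def identify_hubs(net: FunctionalNetwork) -> HubLabels:
    """Flag the most-connected sextile (ceil(N/6) cells) as hubs.

    Isolated nodes (degree 0) are not hub-eligible.
    """
    if net.n_cells < 6:
        raise ValueError("need at least 6 cells")
    return HubLabels(hub_flag=top_sextile(
        net.degrees.astype(float), eligible=net.degrees > 0))
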