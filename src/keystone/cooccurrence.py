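"""Presence/absence co-occurrence networks and keystone modules.

Candidate keystones often come in groups: sets of taxa with strongly
correlated presence/absence patterns that share large EPI values —
*keystone modules*, plausibly one true keystone plus satellite taxa that
co-occur with it. This module builds the co-occurrence network (nodes =
taxa; edges = taxon pairs in the top quantile of pairwise normalized
mutual information between presence vectors, signed by the Pearson
correlation of those vectors) and tests whether EPI values of network
neighbors are more similar than chance, using a permutation null that
reshuffles EPI values over the nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np

__all__ = [
    "nmi",
    "build_cooccurrence_network",
    "neighbor_epi_correlation",
    "NeighborCorrelationReport",
    "find_modules",
]


def _entropy2(p: np.ndarray) -> float:
    """Shannon entropy (bits) of a discrete distribution; 0 log 0 = 0."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def nmi(x, y, normalization: str = "arithmetic") -> float:
    """Normalized mutual information between two binary vectors.

    Mutual information of the 2x2 joint empirical distribution,
    normalized by the arithmetic mean of the two marginal entropies
    (geometric-mean normalization available via ``normalization``).
    Returns 0 when either vector is constant — a constant presence
    pattern carries no co-occurrence information.
    """
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D binary vectors")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    n = x.size
    joint = np.array([
        [np.sum(~x & ~y), np.sum(~x & y)],
        [np.sum(x & ~y), np.sum(x & y)],
    ]) / n
    hx = _entropy2(joint.sum(axis=1))
    hy = _entropy2(joint.sum(axis=0))
    if hx == 0.0 or hy == 0.0:
        return 0.0
    mi = hx + hy - _entropy2(joint.ravel())
    if normalization == "arithmetic":
        denom = (hx + hy) / 2.0
    elif normalization == "geometric":
        denom = float(np.sqrt(hx * hy))
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return float(min(max(mi / denom, 0.0), 1.0))


def _pairwise_nmi(P: np.ndarray, normalization: str) -> np.ndarray:
    """Vectorized NMI over all row pairs of a binary matrix P (taxa x samples)."""
    P = P.astype(float)
    n = P.shape[1]
    n11 = P @ P.T
    rs = P.sum(axis=1)
    n10 = rs[:, None] - n11
    n01 = rs[None, :] - n11
    n00 = n - n11 - n10 - n01

    def plogp(c):
        p = c / n
        out = np.zeros_like(p)
        nz = p > 0
        out[nz] = p[nz] * np.log2(p[nz])
        return out

    h_joint = -(plogp(n00) + plogp(n01) + plogp(n10) + plogp(n11))
    p1 = rs / n
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(p1 > 0, p1 * np.log2(p1), 0.0)
              + np.where(p1 < 1, (1 - p1) * np.log2(1 - p1), 0.0))
    mi = h[:, None] + h[None, :] - h_joint
    if normalization == "arithmetic":
        denom = (h[:, None] + h[None, :]) / 2.0
    else:
        denom = np.sqrt(np.outer(h, h))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, mi / denom, 0.0)
    return np.clip(out, 0.0, 1.0)


def build_cooccurrence_network(presence: np.ndarray, percentile: float = 0.25,
                               taxon_ids: Optional[list] = None,
                               normalization: str = "arithmetic") -> nx.Graph:
    """Co-occurrence network over taxa from a binary presence matrix.

    NMI is computed for every pair of non-constant taxa; pairs whose NMI
    is at or above the ``1 - percentile`` quantile of all pair values
    are kept as edges (``percentile=0.25`` keeps the top quarter, ties
    admitted). Each edge carries its ``nmi`` value and the ``sign`` of
    the Pearson correlation between the two presence vectors. Constant
    taxa are excluded from pairing (with a warning) but remain isolated
    nodes of the graph.
    """
    presence = np.asarray(presence).astype(bool)
    N, M = presence.shape
    if N < 3:
        raise ValueError("need at least 3 taxa")
    if not 0 < percentile <= 1:
        raise ValueError("percentile must lie in (0, 1]")
    ids = [str(t) for t in (taxon_ids if taxon_ids is not None else range(N))]
    freq = presence.mean(axis=1)
    variable = np.flatnonzero((freq > 0) & (freq < 1))
    if variable.size < N:
        warnings.warn(f"{N - variable.size} constant taxa excluded from pairing")
    G = nx.Graph(percentile=percentile, normalization=normalization)
    G.add_nodes_from(ids)
    if variable.size < 2:
        return G
    sub = presence[variable]
    nmi_mat = _pairwise_nmi(sub, normalization)
    iu = np.triu_indices(variable.size, k=1)
    vals = nmi_mat[iu]
    cutoff = float(np.quantile(vals, 1.0 - percentile))
    G.graph["nmi_cutoff"] = cutoff
    centered = sub.astype(float) - sub.mean(axis=1, keepdims=True)
    for a, b, v in zip(iu[0], iu[1], vals):
        if v >= cutoff:
            cov = float(centered[a] @ centered[b])
            G.add_edge(ids[variable[a]], ids[variable[b]],
                       nmi=float(v), sign=int(np.sign(cov)) if cov != 0 else 0)
    return G


@dataclass
class NeighborCorrelationReport:
    """Observed neighbor-EPI correlation against a node-shuffle null."""

    observed_r: float
    p_value: float
    n_shuffles: int
    null_mean: float
    null_sd: float
    null_q95: float
    n_edges: int


def _edge_pair_correlation(edges: np.ndarray, values: np.ndarray) -> float:
    """Pearson correlation over the symmetrized edge list of endpoint values."""
    x = np.concatenate([values[edges[:, 0]], values[edges[:, 1]]])
    y = np.concatenate([values[edges[:, 1]], values[edges[:, 0]]])
    if np.ptp(x) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def neighbor_epi_correlation(network: nx.Graph, epi_values: dict,
                             n_shuffles: int = 1000, seed: int = 0
                             ) -> NeighborCorrelationReport:
    """Are EPI values of network neighbors more similar than chance?

    The observed statistic is the Pearson correlation of (EPI_i, EPI_j)
    over the symmetrized edge list (each undirected edge contributes
    both orders, making the statistic symmetric in the endpoints). The
    null reshuffles the EPI values over the nodes ``n_shuffles`` times;
    the one-sided permutation p-value is the fraction of null
    correlations at least as large as the observed one (with the +1
    correction).

    ``epi_values`` maps node ids to EPI values; nodes with missing
    (NaN) values are dropped along with their edges.
    """
    nodes = [v for v in network.nodes
             if v in epi_values and np.isfinite(epi_values[v])]
    index = {v: k for k, v in enumerate(nodes)}
    edges = np.array([[index[u], index[v]] for u, v in network.edges
                      if u in index and v in index], dtype=int)
    if edges.shape[0] < 10:
        raise ValueError(f"need at least 10 edges with EPI values on both "
                         f"endpoints, got {edges.shape[0]}")
    values = np.array([epi_values[v] for v in nodes], dtype=float)
    observed = _edge_pair_correlation(edges, values)
    if not np.isfinite(observed):
        warnings.warn("EPI values constant on the network; correlation undefined")
        return NeighborCorrelationReport(float("nan"), float("nan"), n_shuffles,
                                         float("nan"), float("nan"),
                                         float("nan"), edges.shape[0])
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        null[s] = _edge_pair_correlation(edges, rng.permutation(values))
    null = null[np.isfinite(null)]
    p = (1.0 + np.sum(null >= observed)) / (null.size + 1.0)
    return NeighborCorrelationReport(observed, float(p), int(null.size),
                                     float(null.mean()), float(null.std(ddof=1)),
                                     float(np.quantile(null, 0.95)),
                                     int(edges.shape[0]))


def find_modules(network: nx.Graph) -> list:
    """Exploratory keystone-module extraction by greedy modularity.

    Community detection on the co-occurrence network is a convenience
    for browsing candidate modules; systematic module identification
    (and separating keystones from satellite taxa within a module) is an
    open problem and no validated procedure is claimed here.
    """
    positive = nx.Graph()
    positive.add_nodes_from(network.nodes)
    positive.add_edges_from((u, v) for u, v, d in network.edges(data=True)
                            if d.get("sign", 1) >= 0)
    comms = nx.algorithms.community.greedy_modularity_communities(positive)
    return [sorted(c) for c in comms if len(c) > 1]
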