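"""Proximity-based social networks from synchronous GPS positions.

At every grid instant, individuals within the association threshold of one
another (directly or through a chain of intermediates — single-linkage, the
"chain rule" of spatio-temporal grouping) form a grouping event.  Stacking the events of one
midday window gives a group-by-individual (GBI) matrix, from which the
simple ratio association index (SRI) weights a symmetric network: the
proportion of instants a dyad shared a group out of the instants both were
recorded.  Whole-network (density, greedy modularity, CV of edge weights)
and node-level (degree, strength, weighted betweenness) metrics follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "GbiMatrix",
    "SriNetwork",
    "association_threshold",
    "group_fixes",
    "gbi_by_window",
    "sri_network",
    "density",
    "modularity",
    "partition_modularity",
    "cv_edge_weights",
    "node_metrics",
    "to_networkx",
]


@dataclass
class GbiMatrix:
    """Group-by-individual incidence matrix for one set of grid instants.

    ``matrix`` is (n_events, n_individuals) binary; each row is one spatial
    cluster at one instant and ``instant_of_row`` maps rows to instant
    indices.  ``present`` is the (n_individuals, n_instants) availability
    mask the SRI denominator is computed from.
    """

    ids: list[str]
    matrix: np.ndarray
    instant_of_row: np.ndarray
    present: np.ndarray
    #: observed matrices keep one group per individual per instant; swap
    #: permutations move memberships across instants and may not
    validate: bool = True

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[1] != len(self.ids):
            raise ValueError("GBI shape inconsistent with ids")
        if m.shape[0] and not (m.sum(axis=1) >= 1).all():
            raise ValueError("empty grouping event row")
        if not self.validate:
            return
        # an individual may occupy at most one group per instant
        for t in np.unique(self.instant_of_row):
            rows = m[self.instant_of_row == t]
            if (rows.sum(axis=0) > 1).any():
                raise ValueError(f"individual in two groups at instant {t}")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)


@dataclass
class SriNetwork:
    """Symmetric SRI adjacency with its dyadic numerators/denominators."""

    ids: list[str]
    weights: np.ndarray        # SRI in [0, 1], zero diagonal
    together: np.ndarray       # instants the dyad shared a group
    both_recorded: np.ndarray  # instants both individuals were recorded

    def __post_init__(self) -> None:
        w = self.weights
        if not np.allclose(w, w.T) or np.any(np.diag(w) != 0):
            raise ValueError("weights must be symmetric with zero diagonal")
        if np.any((w < 0) | (w > 1)):
            raise ValueError("SRI weights must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)


def association_threshold(body_length: float, unit_accuracy: float) -> float:
    """Spatial association threshold: body length plus twice the per-unit
    GPS accuracy (each of the two collars contributes its own error)."""
    if body_length <= 0 or unit_accuracy < 0:
        raise ValueError("body_length must be > 0 and unit_accuracy >= 0")
    return body_length + 2.0 * unit_accuracy


def _instant_clusters(xy: np.ndarray, threshold: float) -> np.ndarray:
    """Single-linkage cluster labels for points at one instant."""
    n = len(xy)
    if n == 1:
        return np.zeros(1, int)
    adj = squareform(pdist(xy)) <= threshold
    # connected components via simple BFS (n is small: one flock)
    labels = np.full(n, -1, int)
    cur = 0
    for s in range(n):
        if labels[s] >= 0:
            continue
        stack = [s]
        labels[s] = cur
        while stack:
            u = stack.pop()
            nbrs = np.flatnonzero(adj[u] & (labels < 0))
            labels[nbrs] = cur
            stack.extend(nbrs.tolist())
        cur += 1
    return labels


def group_fixes(grid, threshold: float, instant_slice: slice | None = None,
                chain_rule: bool = True) -> GbiMatrix:
    """Build the GBI matrix from a synchronous grid.

    Per instant, present individuals are clustered by single linkage at the
    Euclidean ``threshold`` (two individuals group together if linked by a
    chain of within-threshold neighbours); every cluster, including
    singletons, becomes one GBI row.  With ``chain_rule=False`` clusters
    are instead maximal only in the dyadic sense used verbally in field
    protocols: each individual joins the cluster of its nearest
    within-threshold neighbour (still produces a partition).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    sl = instant_slice if instant_slice is not None else slice(None)
    inst_idx = np.arange(len(grid.instants))[sl]
    present = grid.present[:, sl]
    positions = grid.positions[:, sl]

    rows: list[np.ndarray] = []
    row_instants: list[int] = []
    n_ind = len(grid.ids)
    for j, t in enumerate(inst_idx):
        here = np.flatnonzero(present[:, j])
        if here.size == 0:
            continue
        xy = positions[here, j]
        if chain_rule:
            labels = _instant_clusters(xy, threshold)
        else:
            labels = _nearest_neighbour_clusters(xy, threshold)
        for lab in np.unique(labels):
            row = np.zeros(n_ind, np.uint8)
            row[here[labels == lab]] = 1
            rows.append(row)
            row_instants.append(t)

    matrix = np.vstack(rows) if rows else np.zeros((0, n_ind), np.uint8)
    return GbiMatrix(
        ids=list(grid.ids),
        matrix=matrix,
        instant_of_row=np.asarray(row_instants, int),
        present=present.copy(),
    )


def _nearest_neighbour_clusters(xy: np.ndarray, threshold: float) -> np.ndarray:
    """Strict dyadic variant: link each point only to its nearest
    within-threshold neighbour, then take components of that sparser graph."""
    n = len(xy)
    if n == 1:
        return np.zeros(1, int)
    d = squareform(pdist(xy))
    np.fill_diagonal(d, np.inf)
    adj = np.zeros((n, n), bool)
    for i in range(n):
        j = int(np.argmin(d[i]))
        if d[i, j] <= threshold:
            adj[i, j] = adj[j, i] = True
    labels = np.full(n, -1, int)
    cur = 0
    for s in range(n):
        if labels[s] >= 0:
            continue
        stack = [s]
        labels[s] = cur
        while stack:
            u = stack.pop()
            nbrs = np.flatnonzero(adj[u] & (labels < 0))
            labels[nbrs] = cur
            stack.extend(nbrs.tolist())
        cur += 1
    return labels


def gbi_by_window(grid, threshold: float, windows) -> list[GbiMatrix]:
    """One GBI per daily window, splitting the grid on window membership."""
    instants = grid.instants
    out = []
    for start, end in windows:
        mask = (instants >= start) & (instants < end)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        out.append(group_fixes(grid, threshold,
                               slice(int(idx[0]), int(idx[-1]) + 1)))
    return out


def sri_network(gbi: GbiMatrix) -> SriNetwork:
    """Simple ratio association index network from one GBI matrix.

    together(i, j) = instants i and j share a grouping event; since an
    individual sits in at most one group per instant this is the
    off-diagonal of Bᵀ B.  both_recorded(i, j) counts instants both were
    present per the availability mask — the "recorded" denominator covering
    time alone, with others, or with each other.
    """
    b = gbi.matrix.astype(np.int64)
    together = b.T @ b
    np.fill_diagonal(together, 0)
    p = gbi.present.astype(np.int64)
    both = p @ p.T
    np.fill_diagonal(both, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(both > 0, together / np.maximum(both, 1), 0.0)
    # swap-permuted matrices can double-book an instant for a dyad;
    # the index remains a proportion, so cap at 1
    np.minimum(w, 1.0, out=w)
    np.fill_diagonal(w, 0.0)
    return SriNetwork(list(gbi.ids), w, together, both)


def to_networkx(net: SriNetwork) -> nx.Graph:
    """Weighted graph view; zero-weight dyads are absent edges and edges
    carry ``length`` = 1/weight for shortest-path computations."""
    g = nx.Graph()
    g.add_nodes_from(net.ids)
    n = net.n
    for i in range(n):
        for j in range(i + 1, n):
            w = net.weights[i, j]
            if w > 0:
                g.add_edge(net.ids[i], net.ids[j], weight=float(w),
                           length=1.0 / float(w))
    return g


def density(net: SriNetwork) -> float:
    """Existing edges (weight > 0) over the n(n−1)/2 possible edges."""
    n = net.n
    if n < 2:
        raise ValueError("density needs at least 2 individuals")
    iu = np.triu_indices(n, 1)
    existing = int(np.count_nonzero(net.weights[iu]))
    return existing / (n * (n - 1) / 2)


def partition_modularity(net: SriNetwork, communities) -> float:
    """Weighted modularity Q of a given partition (Newman's formula)."""
    return nx.community.modularity(to_networkx(net), communities,
                                   weight="weight")


def modularity(net: SriNetwork, return_partition: bool = False):
    """Best-found weighted modularity via greedy agglomeration.

    Clauset–Newman–Moore greedy merging on the weighted graph, the same
    fast-greedy algorithm the igraph ecosystem exposes.  Deterministic for
    a given graph.  Raises on an edgeless network, where Q is undefined.
    """
    g = to_networkx(net)
    if g.number_of_edges() == 0:
        raise ValueError("modularity undefined for an edgeless network")
    comms = nx.community.greedy_modularity_communities(g, weight="weight")
    q = nx.community.modularity(g, comms, weight="weight")
    if return_partition:
        return q, [set(c) for c in comms]
    return q


def cv_edge_weights(net: SriNetwork, nonzero_only: bool = False) -> float:
    """Coefficient of variation (sample SD / mean) of dyadic weights.

    By default all n(n−1)/2 dyads enter, zeros included — the social
    differentiation convention; ``nonzero_only`` restricts to existing
    edges.
    """
    iu = np.triu_indices(net.n, 1)
    w = net.weights[iu]
    if nonzero_only:
        w = w[w > 0]
    if w.size == 0 or w.mean() == 0:
        raise ValueError("CV undefined: no (nonzero) dyadic weights")
    sd = w.std(ddof=1) if w.size > 1 else 0.0
    return float(sd / w.mean())


def node_metrics(net: SriNetwork) -> "pd.DataFrame":
    """Degree, strength and weighted betweenness per individual.

    Betweenness counts shortest paths on edge lengths 1/weight (strong
    associations are short), unnormalised, with equal-length paths sharing
    a pair's contribution.  Isolated individuals score zero throughout.
    """
    import pandas as pd

    if net.n < 2:
        raise ValueError("node metrics need at least 2 individuals")
    g = to_networkx(net)
    btw = nx.betweenness_centrality(g, weight="length", normalized=False)
    degree = (net.weights > 0).sum(axis=1)
    strength = net.weights.sum(axis=1)
    return pd.DataFrame(
        {
            "id": net.ids,
            "degree": degree.astype(int),
            "strength": strength,
            "betweenness": [btw[i] for i in net.ids],
        }
    )
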