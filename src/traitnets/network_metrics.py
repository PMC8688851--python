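"""Whole-network and per-trait parameters of a trait network.

Overall parameters
    edge density   ED = Σ_i k_i / (n(n−1))      — weighted-degree density
    diameter       D  = max_{i≠j, connected} d_ij
    average path   AL = mean over trait pairs of the shortest-path length

Node parameters
    degree         k_i = Σ_{j≠i} a_ij           — sum of |r| edge weights
    closeness      C_i = (n−1) / Σ_j d_ij       — reciprocal mean path
    betweenness    B_i = Σ_{{j,k}} σ(j, i, k)   — number of shortest paths
                                                  through i (literal count)

Here d_ij is the shortest-path length over the *significant* edges, with
each traversed edge costing its PCA-space distance by default; the three
cost modes (``pca_distance``, ``inverse_weight``, ``unit``) are recorded
in every output so results are never mode-ambiguous.  Betweenness counts
every co-shortest path as one (integer counts over unordered end pairs,
endpoints excluded); a Brandes-style fractional mode is available.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .network_build import TraitNetwork

LENGTH_MODES = ("pca_distance", "inverse_weight", "unit")
# two shortest-path lengths are tied when equal to this relative tolerance
TIE_RTOL = 1e-9
TIE_ATOL = 1e-12


def _tied(a: float, b: float) -> bool:
    return math.isclose(a, b, rel_tol=TIE_RTOL, abs_tol=TIE_ATOL)


@dataclass
class PathMatrix:
    """All-pairs shortest-path lengths and counts over significant edges.

    ``lengths[i, j]`` is inf for unreachable pairs; ``path_counts[i, j]``
    counts the distinct co-shortest paths (ties resolved with a relative
    tolerance of 1e-9 on path length).  ``through_counts[i]`` is the
    number of shortest paths between unordered pairs {j, k} (j ≠ i ≠ k)
    that pass through node i — the raw ingredient of betweenness.
    """

    lengths: np.ndarray
    path_counts: np.ndarray
    through_counts: np.ndarray
    through_fractions: np.ndarray
    length_mode: str
    trait_names: list[str]

    @property
    def n_nodes(self) -> int:
        return self.lengths.shape[0]

    @property
    def connected(self) -> bool:
        off = ~np.eye(self.n_nodes, dtype=bool)
        return bool(np.isfinite(self.lengths[off]).all()) if self.n_nodes > 1 else True


def edge_lengths(net: TraitNetwork, length_mode: str = "pca_distance") -> np.ndarray:
    """Traversal cost per significant edge; inf where there is no edge."""
    if length_mode not in LENGTH_MODES:
        raise ValueError(f"length_mode must be one of {LENGTH_MODES}")
    has_edge = net.adjacency > 0
    w = np.full_like(net.adjacency, np.inf)
    if length_mode == "pca_distance":
        w[has_edge] = net.distances[has_edge]
    elif length_mode == "inverse_weight":
        w[has_edge] = 1.0 / net.adjacency[has_edge]
    else:
        w[has_edge] = 1.0
    np.fill_diagonal(w, np.inf)  # no self loops
    return w


def shortest_paths(
    net: TraitNetwork, length_mode: str = "pca_distance"
) -> PathMatrix:
    """All-pairs shortest paths over edges with a_ij > 0.

    Lengths come from Dijkstra; the number of distinct shortest paths per
    pair, and the number passing through each node, are counted exactly by
    dynamic programming over the shortest-path DAG of each source, with
    float-equal path lengths tied at relative tolerance 1e-9.
    Disconnected networks are legal: unreachable pairs get inf length and
    zero counts.
    """
    n = net.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    w = edge_lengths(net, length_mode)
    finite = np.isfinite(w)
    graph = csr_matrix((w[finite], np.nonzero(finite)), shape=(n, n))
    lengths = dijkstra(graph, directed=False, indices=None)
    np.fill_diagonal(lengths, 0.0)

    # count shortest paths from every source over the tie-tolerant DAG
    counts = np.zeros((n, n))
    np.fill_diagonal(counts, 1.0)
    neighbors = [np.nonzero(finite[v])[0] for v in range(n)]
    for s in range(n):
        dist = lengths[s]
        order = np.argsort(dist)
        for v in order:
            if v == s or not np.isfinite(dist[v]):
                continue
            total = 0.0
            for u in neighbors[v]:
                if np.isfinite(dist[u]) and _tied(dist[u] + w[u, v], dist[v]):
                    total += counts[s, u]
            counts[s, v] = total

    # through counts: paths s-t via i, summed over unordered pairs {s, t}
    through = np.zeros(n)
    through_frac = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(lengths[s, t]):
                continue
            sigma_st = counts[s, t]
            for i in range(n):
                if i in (s, t):
                    continue
                if np.isfinite(lengths[s, i]) and np.isfinite(lengths[i, t]) \
                        and _tied(lengths[s, i] + lengths[i, t], lengths[s, t]):
                    via = counts[s, i] * counts[i, t]
                    through[i] += via
                    through_frac[i] += via / sigma_st
    return PathMatrix(
        lengths=lengths,
        path_counts=counts,
        through_counts=through,
        through_fractions=through_frac,
        length_mode=length_mode,
        trait_names=list(net.trait_names),
    )


@dataclass
class NetworkSummary:
    """ED, D, AL plus per-trait k, C, B for one network.

    ``diameter`` and ``average_path_length`` are NaN (with
    ``has_paths=False``) for an edgeless network; ``connected`` reports
    whether every trait pair is reachable.
    """

    trait_names: list[str]
    edge_density: float
    diameter: float
    average_path_length: float
    degree: np.ndarray
    closeness: np.ndarray
    betweenness: np.ndarray
    n_nodes: int
    n_edges: int
    connected: bool
    has_paths: bool
    length_mode: str
    betweenness_mode: str
    isolated: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    OVERALL = ("edge_density", "diameter", "average_path_length")
    NODE = ("degree", "closeness", "betweenness")

    def node_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "trait": self.trait_names,
                "degree": self.degree,
                "closeness": self.closeness,
                "betweenness": self.betweenness,
            }
        )

    def to_dict(self) -> dict:
        return {
            "trait_names": list(self.trait_names),
            "edge_density": float(self.edge_density),
            "diameter": None if np.isnan(self.diameter) else float(self.diameter),
            "average_path_length": None
            if np.isnan(self.average_path_length)
            else float(self.average_path_length),
            "degree": [float(v) for v in self.degree],
            "closeness": [float(v) for v in self.closeness],
            "betweenness": [float(v) for v in self.betweenness],
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "connected": self.connected,
            "has_paths": self.has_paths,
            "length_mode": self.length_mode,
            "betweenness_mode": self.betweenness_mode,
            "isolated": [bool(v) for v in self.isolated],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def degree(net: TraitNetwork) -> np.ndarray:
    """Weighted degree k_i = Σ_{j≠i} a_ij (row sums of the adjacency)."""
    return net.adjacency.sum(axis=1)


def edge_density(net: TraitNetwork) -> float:
    """ED = Σ k_i / (n(n−1)); 1 for a complete network of unit weights."""
    n = net.n_nodes
    if n < 2:
        raise ValueError("edge density needs at least 2 nodes")
    return float(degree(net).sum() / (n * (n - 1)))


def _finite_offdiag(paths: PathMatrix) -> np.ndarray:
    off = ~np.eye(paths.n_nodes, dtype=bool)
    vals = paths.lengths[off]
    return vals[np.isfinite(vals)]


def diameter(paths: PathMatrix) -> float:
    """D = max shortest-path length over connected pairs; NaN if none."""
    vals = _finite_offdiag(paths)
    return float(vals.max()) if vals.size else float("nan")


def average_path_length(paths: PathMatrix, denominator: str = "auto") -> float:
    """AL = mean shortest-path length over ordered trait pairs.

    ``denominator``: "auto" (reachable pairs when disconnected, n(n−1)
    when connected — identical for connected networks), "reachable", or
    "all" (always n(n−1); unreachable pairs then deflate the mean).
    NaN when no pair is reachable.
    """
    vals = _finite_offdiag(paths)
    if not vals.size:
        return float("nan")
    n = paths.n_nodes
    if denominator == "all":
        return float(vals.sum() / (n * (n - 1)))
    if denominator in ("auto", "reachable"):
        return float(vals.mean())
    raise ValueError(f"unknown denominator {denominator!r}")


def closeness(paths: PathMatrix) -> np.ndarray:
    """C_i = (n−1) / Σ_j d_ij, restricted to reachable peers.

    For a node with unreachable peers the sum runs over reachable peers
    only and n−1 is replaced by their count; a fully isolated node gets
    C = 0 (flagged via :func:`isolated_nodes`).
    """
    n = paths.n_nodes
    out = np.zeros(n)
    for i in range(n):
        d = np.delete(paths.lengths[i], i)
        reach = np.isfinite(d)
        if reach.any() and d[reach].sum() > 0:
            out[i] = reach.sum() / d[reach].sum()
        elif reach.any():
            out[i] = float("inf")  # zero-length paths to every peer
    return out


def isolated_nodes(paths: PathMatrix) -> np.ndarray:
    """Boolean mask of nodes with no reachable peer (closeness undefined)."""
    n = paths.n_nodes
    off = ~np.eye(n, dtype=bool)
    return ~np.isfinite(np.where(off, paths.lengths, np.inf)).any(axis=1)


def betweenness(paths: PathMatrix, mode: str = "count") -> np.ndarray:
    """B_i = number of shortest paths through i, over unordered pairs.

    ``mode="count"`` (default) counts every co-shortest path as one —
    B_i = Σ_{{j,k}} σ(j, i, k) with endpoints never counted as "through".
    ``mode="fraction"`` divides each pair's contribution by its total
    number of shortest paths (Brandes-style, unnormalised).
    """
    if mode == "count":
        return paths.through_counts.copy()
    if mode == "fraction":
        return paths.through_fractions.copy()
    raise ValueError(f"unknown betweenness mode {mode!r}")


def summarize(
    net: TraitNetwork,
    length_mode: str = "pca_distance",
    betweenness_mode: str = "count",
    al_denominator: str = "auto",
) -> NetworkSummary:
    """Compute all six parameters of one network in one pass."""
    paths = shortest_paths(net, length_mode)
    vals = _finite_offdiag(paths)
    has_paths = bool(vals.size)
    return NetworkSummary(
        trait_names=list(net.trait_names),
        edge_density=edge_density(net),
        diameter=diameter(paths),
        average_path_length=average_path_length(paths, al_denominator),
        degree=degree(net),
        closeness=closeness(paths),
        betweenness=betweenness(paths, betweenness_mode),
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        connected=paths.connected,
        has_paths=has_paths,
        length_mode=length_mode,
        betweenness_mode=betweenness_mode,
        isolated=isolated_nodes(paths),
    )
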