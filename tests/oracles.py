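"""Independent brute-force oracles used by the tests.

These enumerate all simple paths explicitly and never share code with
the package's Dijkstra/DAG-counting implementation, so agreement is a
genuine cross-check.
"""

import math

import numpy as np


def enumerate_shortest_paths(adjacency, cost, rtol=1e-9, atol=1e-12):
    """All-pairs shortest paths by exhaustive simple-path enumeration.

    ``adjacency > 0`` marks traversable edges; ``cost`` gives per-edge
    traversal cost.  Returns (lengths, counts, through) where ``through``
    counts, per node, the shortest paths between unordered pairs of other
    nodes that pass through it (endpoints excluded).
    """
    n = adjacency.shape[0]
    lengths = np.full((n, n), np.inf)
    np.fill_diagonal(lengths, 0.0)
    counts = np.zeros((n, n))
    np.fill_diagonal(counts, 1.0)
    through = np.zeros(n)
    neighbors = [list(np.nonzero(adjacency[v] > 0)[0]) for v in range(n)]

    for s in range(n):
        for t in range(s + 1, n):
            paths = []

            def dfs(v, visited, ln):
                if v == t:
                    paths.append((ln, tuple(visited)))
                    return
                for u in neighbors[v]:
                    if u not in visited:
                        dfs(u, visited + [u], ln + cost[v, u])

            dfs(s, [s], 0.0)
            if not paths:
                continue
            best = min(ln for ln, _ in paths)
            shortest = [
                pth for ln, pth in paths
                if math.isclose(ln, best, rel_tol=rtol, abs_tol=atol)
            ]
            lengths[s, t] = lengths[t, s] = best
            counts[s, t] = counts[t, s] = len(shortest)
            for pth in shortest:
                for v in pth[1:-1]:
                    through[v] += 1
    return lengths, counts, through


def metrics_from_lengths(lengths):
    """Diameter, average path length, and closeness from a length matrix."""
    n = lengths.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = lengths[off][np.isfinite(lengths[off])]
    diam = finite.max() if finite.size else float("nan")
    al = finite.mean() if finite.size else float("nan")
    clo = np.zeros(n)
    for i in range(n):
        d = np.delete(lengths[i], i)
        reach = np.isfinite(d)
        if reach.any() and d[reach].sum() > 0:
            clo[i] = reach.sum() / d[reach].sum()
    return diam, al, clo


def random_geometric_network(rng, n_nodes=None, edge_prob=None):
    """A random test network: metric distances, random |r|-like weights."""
    from traitnets.network_build import TraitNetwork

    n = n_nodes if n_nodes is not None else rng.integers(2, 7)
    pts = rng.random((n, 3))
    dist = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    p = edge_prob if edge_prob is not None else rng.uniform(0.2, 0.9)
    upper = rng.random((n, n)) < p
    weights = rng.uniform(0.05, 1.0, (n, n))
    adj = np.triu(np.where(upper, weights, 0.0), k=1)
    adj = adj + adj.T
    signs = np.sign(rng.standard_normal((n, n)))
    signs = np.triu(signs, 1) + np.triu(signs, 1).T
    return TraitNetwork(
        trait_names=[f"T{i}" for i in range(n)],
        adjacency=adj,
        distances=dist,
        alpha=0.05,
        r_signs=np.where(adj > 0, signs, 0.0),
    )
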