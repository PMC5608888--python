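"""Brute-force reference implementations used only by the tests.

These deliberately share no code with the package: distances come from a
plain Floyd–Warshall sweep, clustering from explicit triangle enumeration,
and the statistics from textbook formulas (or statsmodels/pingouin fits).
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths; np.inf marks unreachable pairs."""
    n = adj.shape[0]
    dist = np.where(adj != 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        dist = np.minimum(dist, dist[:, k : k + 1] + dist[k : k + 1, :])
    return dist


def characteristic_path_length_oracle(adj: np.ndarray) -> float:
    dist = floyd_warshall(adj)
    n = adj.shape[0]
    mask = ~np.eye(n, dtype=bool) & np.isfinite(dist)
    return float(dist[mask].mean())


def global_efficiency_oracle(adj: np.ndarray) -> float:
    dist = floyd_warshall(adj)
    n = adj.shape[0]
    inv = np.zeros_like(dist)
    mask = ~np.eye(n, dtype=bool) & np.isfinite(dist) & (dist > 0)
    inv[mask] = 1.0 / dist[mask]
    return float(inv.sum() / (n * (n - 1)))


def clustering_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b])
        total += 2.0 * links / (k * (k - 1))
    return total / n


def local_efficiency_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        total += global_efficiency_oracle(sub)
    return total / n


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def connected_atlas_graphs(max_nodes: int = 7):
    """All connected simple graphs on 2..max_nodes nodes (networkx atlas)."""
    import networkx as nx

    graphs = []
    for g in nx.graph_atlas_g()[1:]:
        if 2 <= g.number_of_nodes() <= max_nodes and nx.is_connected(g):
            graphs.append(nx.to_numpy_array(g, dtype=np.uint8))
    return graphs
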