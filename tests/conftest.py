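"""Shared fixtures and independent test oracles.

The oracle helpers here deliberately avoid the library code paths they check:
shortest paths via breadth-first search on adjacency lists, clustering via
explicit triangle counting, eigenvector centrality via power iteration, and
deduplication via a direct O(n²) greedy scan.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pandas as pd
import pytest

from cfosnet.connectome import BrainNetwork


def net_from_adjacency(adj: np.ndarray, weights: np.ndarray | None = None) -> BrainNetwork:
    adj = np.asarray(adj, dtype=bool)
    w = adj.astype(float) if weights is None else np.where(adj, weights, 0.0)
    ids = tuple(f"n{i}" for i in range(adj.shape[0]))
    return BrainNetwork(region_ids=ids, weights=w, nominal_density=0.0)


def random_adjacency(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    upper = np.triu(rng.random((n, n)) < p, k=1)
    return upper | upper.T


# ---------------------------------------------------------------------------
# independent graph oracles (BFS / enumeration / power iteration)
# ---------------------------------------------------------------------------

def bfs_distances(adj: np.ndarray, source: int) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in range(n):
            if adj[u, v] and np.isinf(dist[v]):
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def oracle_global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        d = bfs_distances(adj, i)
        for j in range(n):
            if j != i and np.isfinite(d[j]) and d[j] > 0:
                total += 1.0 / d[j]
    return total / (n * (n - 1))


def oracle_local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        if len(nb) < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        out[i] = oracle_global_efficiency(sub)
    return out


def oracle_avg_shortest_path(adj: np.ndarray) -> float:
    n = adj.shape[0]
    lengths = []
    for i in range(n):
        d = bfs_distances(adj, i)
        lengths.extend(d[j] for j in range(n) if j != i and np.isfinite(d[j]))
    return float(np.mean(lengths))


def oracle_clustering(adj: np.ndarray) -> float:
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        k = len(nb)
        if k < 2:
            continue
        links = sum(adj[u, v] for a, u in enumerate(nb) for v in nb[a + 1 :])
        vals.append(links / (k * (k - 1) / 2))
    return float(np.mean(vals))


def oracle_power_iteration(adj: np.ndarray, n_iter: int = 20000, tol: float = 1e-14) -> np.ndarray:
    a = adj.astype(float)
    v = np.ones(a.shape[0])
    for _ in range(n_iter):
        nxt = a @ v
        norm = np.linalg.norm(nxt)
        if norm == 0:
            raise ValueError("edgeless graph")
        nxt = nxt / norm
        if np.linalg.norm(nxt - v) < tol:
            v = nxt
            break
        v = nxt
    v = np.abs(v)
    return v / v.max()


def oracle_greedy_dedup(
    points: np.ndarray, order: np.ndarray, min_dist: float
) -> np.ndarray:
    """O(n²) greedy minimum-separation retention; returns kept boolean mask."""
    kept: list[int] = []
    mask = np.zeros(len(points), dtype=bool)
    for i in order:
        if kept:
            d2 = np.sum((points[kept] - points[i]) ** 2, axis=1)
            if d2.min() < min_dist**2:
                continue
        kept.append(i)
        mask[i] = True
    return mask


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_region_table():
    return pd.DataFrame(
        {
            "label": [0, 1, 2, 3, 4],
            "abbreviation": ["clear", "Vv", "PPa", "Hc", "Wm"],
            "name": [
                "outside brain",
                "ventral nucleus of ventral telencephalon",
                "anterior parvocellular preoptic nucleus",
                "caudal hypothalamus",
                "white matter tract",
            ],
            "tissue_class": ["clear", "gray", "gray", "gray", "white"],
            "volume_mm3": [5.0, 0.5, 1.0, 0.5, 0.3],
        }
    )
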