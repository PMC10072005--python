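"""Independent brute-force graph-metric oracles used by the test suite.

Everything here is written for clarity at tiny n, deliberately avoiding the
vectorized implementations under test: clustering by explicit neighbour-pair
enumeration, distances by Floyd–Warshall, transitivity by naive triangle /
triple counting.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

INF = float("inf")


def brute_clustering(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if adj[a, b])
        total += 2.0 * links / (len(nbrs) * (len(nbrs) - 1))
    return total / n


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    d[adj > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_path_length(adj: np.ndarray) -> float:
    d = floyd_warshall(adj)
    vals = [
        d[i, j]
        for i in range(adj.shape[0])
        for j in range(adj.shape[0])
        if i != j and d[i, j] < INF
    ]
    return float(np.mean(vals)) if vals else float("nan")


def brute_global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall(adj)
    total = sum(
        1.0 / d[i, j] for i in range(n) for j in range(n) if i != j and d[i, j] < INF
    )
    return total / (n * (n - 1))


def brute_local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        total += brute_global_efficiency(adj[np.ix_(nbrs, nbrs)])
    return total / n


def brute_transitivity(adj: np.ndarray) -> float:
    n = adj.shape[0]
    triangles = sum(
        1
        for i, j, k in combinations(range(n), 3)
        if adj[i, j] and adj[j, k] and adj[i, k]
    )
    triples = sum(
        1
        for i in range(n)
        for j, k in combinations([m for m in range(n) if adj[i, m]], 2)
    )
    return 3.0 * triangles / triples if triples else 0.0


def is_connected(adj: np.ndarray) -> bool:
    n = adj.shape[0]
    seen = {0}
    stack = [0]
    while stack:
        i = stack.pop()
        for j in range(n):
            if adj[i, j] and j not in seen:
                seen.add(j)
                stack.append(j)
    return len(seen) == n


def all_graphs(n: int):
    """Yield every labeled simple graph on n nodes as an adjacency matrix."""
    pairs = list(combinations(range(n), 2))
    for code in range(2 ** len(pairs)):
        adj = np.zeros((n, n), dtype=np.uint8)
        for b, (i, j) in enumerate(pairs):
            if code >> b & 1:
                adj[i, j] = adj[j, i] = 1
        yield adj


def random_graph(n: int, p: float, rng) -> np.ndarray:
    adj = np.zeros((n, n), dtype=np.uint8)
    for i, j in combinations(range(n), 2):
        if rng.random() < p:
            adj[i, j] = adj[j, i] = 1
    return adj
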