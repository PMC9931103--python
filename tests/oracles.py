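"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's own code paths: ranking is done by
sorting, shortest paths by exhaustive simple-path enumeration, and
regression by the normal equations.
"""

from __future__ import annotations

import numpy as np


def average_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks computed by explicit sorting and tie grouping."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=float)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Rank both vectors (average ranks for ties), then Pearson on ranks."""
    rx, ry = average_ranks(x), average_ranks(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    denom = np.sqrt((dx @ dx) * (dy @ dy))
    if denom == 0:
        return 0.0
    return float((dx @ dy) / denom)


def _edge_cost(weights: np.ndarray, alpha: float) -> np.ndarray:
    w = np.abs(weights)
    cost = np.full_like(w, np.inf)
    m = w > 0
    cost[m] = (1.0 / w[m]) ** alpha
    return cost


def enumerate_shortest_paths(
    weights: np.ndarray,
    alpha: float = 1.0,
    rtol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exhaustive all-pairs shortest paths on a small weighted graph.

    Returns (distances, path_counts, through_counts) where
    through_counts[i, j, k] is the number of minimal j-k paths having i
    as an intermediate node.  Enumerates every simple path, so only
    usable for <= ~8 nodes.
    """
    n = weights.shape[0]
    cost = _edge_cost(weights, alpha)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    counts = np.zeros((n, n))
    np.fill_diagonal(counts, 1.0)
    through = np.zeros((n, n, n))

    def all_paths(src: int, dst: int):
        paths = []

        def dfs(node: int, visited: set[int], length: float, inner: list[int]):
            if node == dst:
                paths.append((length, list(inner)))
                return
            for nxt in range(n):
                if np.isfinite(cost[node, nxt]) and nxt not in visited:
                    dfs(nxt, visited | {nxt}, length + cost[node, nxt],
                        inner + ([node] if node != src else []))

        dfs(src, {src}, 0.0, [])
        return paths

    for j in range(n):
        for k in range(j + 1, n):
            paths = all_paths(j, k)
            if not paths:
                continue
            best = min(p[0] for p in paths)
            tol = rtol * max(1.0, best)
            minimal = [p for p in paths if p[0] <= best + tol]
            dist[j, k] = dist[k, j] = best
            counts[j, k] = counts[k, j] = len(minimal)
            for _, inner in minimal:
                for i in inner:
                    through[i, j, k] += 1
                    through[i, k, j] += 1
    return dist, counts, through


def betweenness_oracle(weights: np.ndarray, alpha: float = 1.0,
                       rtol: float = 1e-9) -> np.ndarray:
    """Freeman betweenness by exhaustive path enumeration."""
    n = weights.shape[0]
    _, counts, through = enumerate_shortest_paths(weights, alpha, rtol)
    cb = np.zeros(n)
    for i in range(n):
        for j in range(n):
            for k in range(j + 1, n):
                if i in (j, k) or counts[j, k] == 0:
                    continue
                cb[i] += through[i, j, k] / counts[j, k]
    return cb


def closeness_oracle(weights: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """1 / (sum of brute-force distances to reachable nodes)."""
    dist, _, _ = enumerate_shortest_paths(weights, alpha)
    n = weights.shape[0]
    out = np.zeros(n)
    for i in range(n):
        dj = np.array([dist[i, j] for j in range(n)
                       if j != i and np.isfinite(dist[i, j])])
        if dj.size:
            out[i] = 1.0 / dj.sum()
    return out


def ols_r2_oracle(y: np.ndarray, X: np.ndarray) -> float:
    """1 - SSE/SST from the normal equations, floored at 0."""
    n = y.size
    A = np.column_stack([np.ones(n), X])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return 0.0
    return max(0.0, 1.0 - float(resid @ resid) / sst)


def random_weighted_graph(rng: np.random.Generator, n: int,
                          p_edge: float = 0.5) -> np.ndarray:
    """Random symmetric signed weight matrix with zero diagonal."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                mag = rng.uniform(0.2, 1.0)
                w[i, j] = w[j, i] = mag * rng.choice([-1.0, 1.0])
    return w
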