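"""Independent brute-force oracles for graph efficiency metrics.

Shortest paths are found by exhaustive depth-first enumeration of all
simple paths (feasible for N <= 8), entirely independent of the package's
Dijkstra-based implementation.  Metric formulas are re-derived here with
naive loops.
"""

from __future__ import annotations

import numpy as np


def bf_shortest_paths(w: np.ndarray) -> np.ndarray:
    """All-pairs weighted shortest paths by enumerating every simple path.

    Edge length is 1/weight; unreachable pairs get inf.
    """
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)

    def dfs(node: int, target: int, visited: set, length: float) -> float:
        if node == target:
            return length
        best = np.inf
        for nxt in range(n):
            if w[node, nxt] > 0 and nxt not in visited:
                best = min(
                    best,
                    dfs(nxt, target, visited | {nxt}, length + 1.0 / w[node, nxt]),
                )
        return best

    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dfs(i, j, {i}, 0.0)
    return d


def bf_nodal_global_efficiency(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    d = bf_shortest_paths(w)
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(
            1.0 / d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])
        ) / (n - 1)
    return out


def bf_global_efficiency(w: np.ndarray) -> float:
    n = w.shape[0]
    if n < 2:
        return 0.0
    d = bf_shortest_paths(w)
    total = sum(
        1.0 / d[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and np.isfinite(d[i, j])
    )
    return total / (n * (n - 1))


def bf_nodal_local_efficiency(w: np.ndarray) -> np.ndarray:
    """Cube-root weighted nodal local efficiency on the neighbor subgraph."""
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        dsub = bf_shortest_paths(sub)
        total = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and np.isfinite(dsub[a, b]) and dsub[a, b] > 0:
                    total += (
                        (1.0 / dsub[a, b]) * w[i, nbrs[a]] * w[i, nbrs[b]]
                    ) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def bf_local_efficiency(w: np.ndarray) -> float:
    """Mean over nodes of neighbor-subgraph global efficiency."""
    n = w.shape[0]
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        sub = w[np.ix_(nbrs, nbrs)]
        vals.append(bf_global_efficiency(sub) if len(nbrs) >= 2 else 0.0)
    return float(np.mean(vals)) if vals else 0.0


def bf_clustering(w: np.ndarray) -> float:
    n = w.shape[0]
    c = np.zeros(n)
    deg = (w > 0).sum(axis=1)
    for i in range(n):
        if deg[i] < 2:
            continue
        tri = 0.0
        for j in range(n):
            for h in range(n):
                tri += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        c[i] = tri / (deg[i] * (deg[i] - 1))
    return float(c.mean())


def bf_path_length(w: np.ndarray) -> float:
    """Harmonic-mean characteristic path length."""
    n = w.shape[0]
    d = bf_shortest_paths(w)
    total = sum(
        1.0 / d[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and np.isfinite(d[i, j])
    )
    mean_inv = total / (n * (n - 1))
    return 1.0 / mean_inv if mean_inv > 0 else np.inf


def random_weighted_graph(rng: np.random.Generator, n: int, p: float = 0.5) -> np.ndarray:
    """Random symmetric nonnegative weight matrix with edge density ~p."""
    mask = rng.random((n, n)) < p
    wts = rng.uniform(0.05, 1.0, size=(n, n))
    w = np.where(mask, wts, 0.0)
    w = np.triu(w, 1)
    return w + w.T
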