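"""Weighted graph efficiency metrics and degree-preserving null models.

Implements, for weighted undirected graphs with nonnegative weights:

* global efficiency  E_glob = mean over ordered pairs of 1/d_ij,
* nodal global efficiency  E_glob^nodal(i) = (1/(N-1)) Σ_j 1/d_ij,
* local efficiency  E_loc = mean over nodes of the neighbor-subgraph
  global efficiency,
* nodal local efficiency with the cube-root weighted form
  (1/(k_i(k_i-1))) Σ_{j≠k∈G_i} (w_ij w_ik / d_jk)^{1/3},
* weighted clustering  C_w with (W_ij W_ih W_jh)^{1/3} triangle terms,
* harmonic characteristic path length  L_w = 1 / mean(1/d_ij),

where d_ij is the weighted shortest path with edge length 1/w (stronger
connections are shorter; ``length="literal"`` uses length = w for audit).
Small-world normalization (γ, λ, σ) uses Maslov–Sneppen double-edge-swap
nulls that preserve the degree sequence exactly and permute the weight
multiset over the rewired edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .connectome import WeightedGraph


@dataclass(frozen=True)
class GlobalMetrics:
    """Whole-network metrics at one sparsity level."""

    e_glob: float
    e_loc: float
    c_w: float
    l_w: float


@dataclass(frozen=True)
class SmallWorldMetrics:
    """Null-normalized clustering and path length (γ, λ) and their ratio σ."""

    gamma: float
    lam: float
    sigma: float
    c_w_rand: np.ndarray
    l_w_rand: np.ndarray
    degenerate: bool = False


@dataclass
class NodalMetricSet:
    """Per-node efficiency curves over a sparsity grid, with integrals."""

    levels: np.ndarray  # (S,)
    e_glob_nodal: np.ndarray  # (N, S)
    e_loc_nodal: np.ndarray  # (N, S)


def _length_matrix(w: np.ndarray, length: str) -> np.ndarray:
    if length == "inverse":
        with np.errstate(divide="ignore"):
            ell = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    elif length == "literal":
        ell = w.copy()
    else:
        raise ValueError("length must be 'inverse' or 'literal'")
    return ell


def shortest_weighted_paths(
    g: WeightedGraph | np.ndarray, length: str = "inverse"
) -> np.ndarray:
    """All-pairs weighted shortest path lengths (∞ between components)."""
    w = g.weights if isinstance(g, WeightedGraph) else np.asarray(g, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    ell = _length_matrix(w, length)
    d = shortest_path(csr_array(ell), method="D", directed=False)
    np.fill_diagonal(d, 0.0)
    return d


def _pair_efficiency_sum(d: np.ndarray) -> np.ndarray:
    """Row sums of 1/d over off-diagonal finite entries."""
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return inv.sum(axis=1)


def nodal_efficiencies(
    g: WeightedGraph, length: str = "inverse"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-node global and local efficiency of a weighted graph.

    Nodal global efficiency averages 1/d from the node to all others
    (disconnected pairs contribute 0).  Nodal local efficiency applies the
    cube-root weighted form on the subgraph of the node's neighbors, with
    inter-neighbor paths computed within that subgraph; nodes of degree < 2
    score 0.
    """
    w = g.weights
    n = w.shape[0]
    if n < 2:
        return np.zeros(n), np.zeros(n)
    d = shortest_weighted_paths(g, length=length)
    e_glob_nodal = _pair_efficiency_sum(d) / (n - 1)

    e_loc_nodal = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        k = len(nbrs)
        if k < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        dsub = shortest_weighted_paths(sub, length=length)
        with np.errstate(divide="ignore"):
            inv_d = np.where(np.isfinite(dsub) & (dsub > 0), 1.0 / dsub, 0.0)
        wi = w[i, nbrs]
        terms = np.cbrt(np.outer(wi, wi) * inv_d)
        np.fill_diagonal(terms, 0.0)
        e_loc_nodal[i] = terms.sum() / (k * (k - 1))
    return e_glob_nodal, e_loc_nodal


def _subgraph_global_efficiency(sub_w: np.ndarray, length: str) -> float:
    k = sub_w.shape[0]
    if k < 2:
        return 0.0
    d = shortest_weighted_paths(sub_w, length=length)
    return float(_pair_efficiency_sum(d).sum() / (k * (k - 1)))


def clustering_coefficient(w: np.ndarray) -> float:
    """Mean weighted clustering with cube-root triangle intensities."""
    a = np.cbrt(w)
    tri = np.einsum("ij,jh,hi->i", a, a, a)
    deg = (w > 0).sum(axis=1)
    c = np.zeros(w.shape[0])
    ok = deg >= 2
    c[ok] = tri[ok] / (deg[ok] * (deg[ok] - 1.0))
    return float(c.mean()) if len(c) else 0.0


def characteristic_path_length(d: np.ndarray) -> float:
    """Harmonic-form path length: reciprocal of the mean of 1/d_ij."""
    n = d.shape[0]
    if n < 2:
        return np.inf
    mean_inv = _pair_efficiency_sum(d).sum() / (n * (n - 1))
    return float(1.0 / mean_inv) if mean_inv > 0 else np.inf


def global_metrics(g: WeightedGraph, length: str = "inverse") -> GlobalMetrics:
    """Whole-network efficiency, clustering, and path length."""
    w = g.weights
    n = w.shape[0]
    d = shortest_weighted_paths(g, length=length)
    pair_sum = _pair_efficiency_sum(d).sum()
    e_glob = float(pair_sum / (n * (n - 1))) if n > 1 else 0.0
    e_loc_terms = []
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        e_loc_terms.append(
            _subgraph_global_efficiency(w[np.ix_(nbrs, nbrs)], length)
        )
    e_loc = float(np.mean(e_loc_terms)) if e_loc_terms else 0.0
    return GlobalMetrics(
        e_glob=e_glob,
        e_loc=e_loc,
        c_w=clustering_coefficient(w),
        l_w=characteristic_path_length(d),
    )


@njit(cache=True)
def _double_edge_swap(ei, ej, adj, n_swaps, max_trials, seed):  # pragma: no cover
    """In-place Maslov–Sneppen rewiring; returns the number of successes."""
    np.random.seed(seed)
    m = ei.shape[0]
    successes = 0
    trials = 0
    while successes < n_swaps and trials < max_trials:
        trials += 1
        e1 = np.random.randint(m)
        e2 = np.random.randint(m)
        if e1 == e2:
            continue
        a, b = ei[e1], ej[e1]
        c, d = ei[e2], ej[e2]
        if np.random.randint(2) == 1:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        ej[e1] = d
        ei[e2] = c
        ej[e2] = b
        successes += 1
    return successes


def rewired_null(
    g: WeightedGraph,
    rng: np.random.Generator,
    swaps_per_edge: int = 10,
) -> tuple[np.ndarray, bool]:
    """One degree-preserving null: rewired topology, permuted weights.

    Returns the null weight matrix and a flag that is True when the graph
    was too sparse to rewire (the original is returned unchanged).
    """
    w = g.weights
    iu, ju = np.nonzero(np.triu(w, 1))
    m = len(iu)
    if m < 2:
        return w.copy(), True
    ei = iu.astype(np.int64).copy()
    ej = ju.astype(np.int64).copy()
    adj = w > 0
    n_swaps = swaps_per_edge * m
    seed = int(rng.integers(0, 2**31))
    done = _double_edge_swap(ei, ej, adj.copy(), n_swaps, 100 * n_swaps, seed)
    if done == 0:
        return w.copy(), True
    weights = w[iu, ju]
    perm = rng.permutation(m)
    null = np.zeros_like(w)
    null[ei, ej] = weights[perm]
    null = null + null.T
    return null, False


def null_model_metrics(
    g: WeightedGraph,
    n_rand: int = 100,
    seed: int = 0,
    length: str = "inverse",
    swaps_per_edge: int = 10,
) -> SmallWorldMetrics:
    """γ, λ, σ from Maslov–Sneppen matched random networks.

    Each null keeps the node count, edge count, and exact degree sequence
    of the real graph and reassigns the real weight multiset at random to
    the rewired edges.  γ = C_w / mean C_w^rand, λ = L_w / mean L_w^rand,
    σ = γ/λ.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    rng = np.random.default_rng(seed)
    c_real = clustering_coefficient(g.weights)
    l_real = characteristic_path_length(shortest_weighted_paths(g, length=length))
    c_rand = np.empty(n_rand)
    l_rand = np.empty(n_rand)
    degenerate = False
    for k in range(n_rand):
        null, flag = rewired_null(g, rng, swaps_per_edge=swaps_per_edge)
        degenerate = degenerate or flag
        c_rand[k] = clustering_coefficient(null)
        l_rand[k] = characteristic_path_length(
            shortest_weighted_paths(null, length=length)
        )
    if degenerate:
        warnings.warn(
            "graph too sparse to rewire; null(s) equal the original graph",
            stacklevel=2,
        )
    gamma = c_real / c_rand.mean() if c_rand.mean() > 0 else np.nan
    lam = l_real / l_rand.mean() if np.isfinite(l_rand.mean()) else np.nan
    return SmallWorldMetrics(
        gamma=float(gamma),
        lam=float(lam),
        sigma=float(gamma / lam) if lam and np.isfinite(lam) else np.nan,
        c_w_rand=c_rand,
        l_w_rand=l_rand,
        degenerate=degenerate,
    )


def nodal_curves(
    graphs: list[WeightedGraph], length: str = "inverse"
) -> NodalMetricSet:
    """Nodal efficiency curves across a thresholded graph series."""
    levels = np.array([g.sparsity for g in graphs])
    n = graphs[0].n_nodes
    e_glob = np.empty((n, len(graphs)))
    e_loc = np.empty((n, len(graphs)))
    for k, g in enumerate(graphs):
        e_glob[:, k], e_loc[:, k] = nodal_efficiencies(g, length=length)
    return NodalMetricSet(levels=levels, e_glob_nodal=e_glob, e_loc_nodal=e_loc)


def integrate_curves(
    curves: np.ndarray, levels: np.ndarray, method: str = "trapezoid"
) -> np.ndarray:
    """Area under per-node metric curves over the sparsity grid.

    With a single level the integral is the value itself.  ``method`` is
    ``"trapezoid"`` (default) or ``"riemann"`` (left sum).
    """
    curves = np.atleast_2d(curves)
    levels = np.asarray(levels, dtype=float)
    if levels.size < 1:
        raise ValueError("need at least one sparsity level")
    if levels.size == 1:
        return curves[:, 0].copy()
    if method == "trapezoid":
        return np.trapezoid(curves, x=levels, axis=1)
    if method == "riemann":
        return (curves[:, :-1] * np.diff(levels)).sum(axis=1)
    raise ValueError("method must be 'trapezoid' or 'riemann'")


def normalize_within_subject(integrated: np.ndarray) -> np.ndarray:
    """Divide nodal integrals by their mean over nodes (subject mean -> 1)."""
    mean = integrated.mean()
    if mean == 0:
        raise ValueError("subject mean of integrated metrics is zero")
    return integrated / mean


def integrate_and_normalize(
    metric_set: NodalMetricSet, method: str = "trapezoid"
) -> dict[str, np.ndarray]:
    """Integrated and subject-normalized nodal metrics for one subject."""
    out: dict[str, np.ndarray] = {}
    for name, curves in (
        ("e_glob", metric_set.e_glob_nodal),
        ("e_loc", metric_set.e_loc_nodal),
    ):
        integ = integrate_curves(curves, metric_set.levels, method=method)
        out[f"{name}_integrated"] = integ
        out[f"{name}_normalized"] = normalize_within_subject(integ)
    return out
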