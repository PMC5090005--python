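"""Validation controls for the selected-region regression.

Two controls probe whether an observed brain–behavior fit could arise by
chance: (1) shuffling the IE scores across subjects and refitting the
regression on the originally selected metrics; (2) refitting against the
true IE using randomly drawn sets of non-selected ("uncorrelated") nodes
of the same size as the selected set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ShuffleSummary:
    """Permutation-null summary for one fitted model."""

    observed_F: float
    null_F: np.ndarray
    frac_significant: float
    #: fraction of permuted F values below the observed F
    observed_percentile: float
    df1: int
    df2: int


@dataclass
class ControlSummary:
    """Random uncorrelated-region control summary."""

    F: np.ndarray
    r2: np.ndarray
    p: np.ndarray
    frac_significant: float
    k: int


def _fast_f_stats(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Overall F for regressing each column of Y on X (with intercept).

    Uses an orthonormal basis of the centered design so thousands of
    permuted responses are fitted in one matrix product.
    """
    n, k = X.shape
    Xc = X - X.mean(axis=0)
    q, r = np.linalg.qr(Xc)
    rank = int((np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())).sum())
    q = q[:, :rank]
    df1, df2 = rank, n - rank - 1
    if df2 < 1:
        raise ValueError("insufficient residual df")
    Yc = Y - Y.mean(axis=0)
    ss_tot = (Yc**2).sum(axis=0)
    proj = q.T @ Yc
    ss_mod = (proj**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, ss_mod / ss_tot, 0.0)
        F = (r2 / df1) / ((1 - r2) / df2)
    return F, df1, df2


def shuffle_validation(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ShuffleSummary:
    """Refit the regression on label-shuffled IE and summarize the null.

    ``n_perm = 1`` reproduces a single-shuffle sanity check; larger values
    give a calibrated permutation null for the observed overall F.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    obs, df1, df2 = _fast_f_stats(X, y[:, None])
    perms = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    null_F, *_ = _fast_f_stats(X, perms)
    f_crit = stats.f.ppf(1 - alpha, df1, df2)
    return ShuffleSummary(
        observed_F=float(obs[0]),
        null_F=null_F,
        frac_significant=float((null_F > f_crit).mean()),
        observed_percentile=float((null_F < obs[0]).mean()),
        df1=df1,
        df2=df2,
    )


def random_region_control(
    all_metrics: np.ndarray,
    excluded: set[int],
    k: int,
    y: np.ndarray,
    n_draws: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ControlSummary:
    """Fit IE on random k-subsets of non-selected nodes.

    ``excluded`` is the selected node set; draws come from its complement.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    all_metrics = np.asarray(all_metrics, dtype=float)
    y = np.asarray(y, dtype=float)
    pool = np.array(
        [j for j in range(all_metrics.shape[1]) if j not in excluded]
    )
    if len(pool) < k:
        raise ValueError(f"only {len(pool)} non-selected nodes for k={k}")
    rng = np.random.default_rng(seed)
    F = np.empty(n_draws)
    r2 = np.empty(n_draws)
    p = np.empty(n_draws)
    for d in range(n_draws):
        cols = rng.choice(pool, size=k, replace=False)
        f, df1, df2 = _fast_f_stats(all_metrics[:, cols], y[:, None])
        F[d] = f[0]
        r2[d] = df1 * f[0] / (df1 * f[0] + df2)
        p[d] = stats.f.sf(f[0], df1, df2)
    return ControlSummary(
        F=F,
        r2=r2,
        p=p,
        frac_significant=float((p < alpha).mean()),
        k=k,
    )
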