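"""Weighted functional connectome construction.

ROI averaging, Pearson correlation, Fisher z transform, and
positive-weight sparsity thresholding across the small-world regime.
Sparsity is the fraction of the N(N-1)/2 possible edges retained; at each
level the strongest positive edges are kept, so graphs at increasing
sparsity are nested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import SubjectTimeSeries

#: cap applied to |r| before atanh so duplicated signals stay finite
Z_CAP_R = 1.0 - 1e-7


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Pearson correlation matrix with its Fisher z transform."""

    r: np.ndarray
    z: np.ndarray
    n_timepoints: int


@dataclass(frozen=True)
class SparsityGrid:
    """Arithmetic grid of sparsity levels (fractions of possible edges).

    The default 0.03–0.51 in steps of 0.02 spans the small-world regime
    of sparse functional brain networks (25 levels).
    """

    s_min: float = 0.03
    s_max: float = 0.51
    step: float = 0.02

    def __post_init__(self) -> None:
        if not (0 < self.s_min <= self.s_max < 1):
            raise ValueError("need 0 < s_min <= s_max < 1")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def levels(self) -> np.ndarray:
        n = int(round((self.s_max - self.s_min) / self.step)) + 1
        return np.round(self.s_min + self.step * np.arange(n), 10)


@dataclass(frozen=True)
class WeightedGraph:
    """Symmetric nonnegative weight matrix at one sparsity level."""

    weights: np.ndarray
    sparsity: float
    #: achieved sparsity; differs from requested when positive edges run out
    achieved_sparsity: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    @property
    def degree(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=1)


def roi_timeseries(voxel_ts: SubjectTimeSeries) -> SubjectTimeSeries:
    """Average voxel columns within each ROI label into one ROI column."""
    if voxel_ts.voxel_labels is None:
        return voxel_ts
    labels = np.asarray(voxel_ts.voxel_labels)
    rois = np.unique(labels)
    out = np.empty((voxel_ts.data.shape[0], len(rois)))
    for k, roi in enumerate(rois):
        members = labels == roi
        if not members.any():
            raise ValueError(f"ROI {roi} has no voxels")
        out[:, k] = voxel_ts.data[:, members].mean(axis=1)
    return SubjectTimeSeries(voxel_ts.subject_id, out, tr=voxel_ts.tr)


def correlation_matrix(roi_ts: SubjectTimeSeries) -> ConnectivityMatrix:
    """Pearson correlations among ROI series, with capped Fisher z.

    Zero-variance columns are reported and their correlations set to 0.
    """
    data = np.asarray(roi_ts.data, dtype=float)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 timepoints")
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        warnings.warn(
            f"zero-variance node column(s) {dead.tolist()}: correlations set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data, rowvar=False)
    if dead.size:
        r[dead, :] = 0.0
        r[:, dead] = 0.0
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    z = np.arctanh(np.clip(r, -Z_CAP_R, Z_CAP_R))
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(r=r, z=z, n_timepoints=data.shape[0])


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def threshold_series(
    cm: ConnectivityMatrix,
    grid: SparsityGrid,
    weights: str = "z",
) -> list[WeightedGraph]:
    """Threshold a connectivity matrix at every sparsity level of the grid.

    At level S, the round(S·N(N-1)/2) largest positive edges are retained
    (ranked by Fisher z; ties broken by ascending (i, j) index).  Retained
    edge weight is the Fisher z value (``weights="r"`` keeps raw r, which
    ranks identically since atanh is monotone).  When fewer positive edges
    exist than requested, all positive edges are kept and the achievable
    sparsity is reported on the graph.
    """
    if weights not in ("z", "r"):
        raise ValueError("weights must be 'z' or 'r'")
    n = cm.z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    zvals = cm.z[iu, ju]
    wvals = zvals if weights == "z" else cm.r[iu, ju]
    pos = zvals > 0
    # sort positive edges by descending z, ties by ascending (i, j)
    order = np.lexsort((ju[pos], iu[pos], -zvals[pos]))
    pi, pj, pw = iu[pos][order], ju[pos][order], wvals[pos][order]
    n_possible = n * (n - 1) // 2
    graphs: list[WeightedGraph] = []
    for s in grid.levels:
        k = _round_half_up(float(s) * n_possible)
        if k > len(pi):
            warnings.warn(
                f"sparsity {s}: only {len(pi)} positive edges available "
                f"({len(pi) / n_possible:.4f} achievable), keeping all",
                stacklevel=2,
            )
            k = len(pi)
        w = np.zeros((n, n))
        w[pi[:k], pj[:k]] = pw[:k]
        w = w + w.T
        graphs.append(
            WeightedGraph(
                weights=w,
                sparsity=float(s),
                achieved_sparsity=k / n_possible,
            )
        )
    return graphs


def min_sparsity(n_nodes: int) -> float:
    """Lower sparsity bound giving mean degree 2·log10(N).

    Used to validate (not force) a grid's lower end together with the
    small-worldness > 1.1 check.
    """
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    return 2.0 * np.log10(n_nodes) / (n_nodes - 1)
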