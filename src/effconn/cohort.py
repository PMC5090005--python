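"""Synthetic resting-state cohort generator with a planted brain–behavior link.

The generator emulates the statistical structure of a small resting-state
fMRI study: a modular group connectome perturbed per subject, ROI (or voxel)
BOLD-like time series whose correlation structure approximates each subject's
weight matrix, slow nuisance confounds, and behavioral inverse-efficiency
(IE) scores linearly coupled to planted nodal efficiencies.  Everything is
reproducible from a single seed, and the planted coupling gives every
downstream stage an exact ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SubjectTimeSeries:
    """One subject's time × signal matrix (ROI-level or voxel-level)."""

    subject_id: str
    data: np.ndarray  # shape (T, P)
    tr: float = 2.0
    #: ROI label per column when columns are voxels; None for ROI-level data.
    voxel_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.isnan(self.data).any():
            raise ValueError(f"{self.subject_id}: time series contains NaN")
        if self.voxel_labels is not None and len(self.voxel_labels) != self.data.shape[1]:
            raise ValueError("voxel_labels length must match column count")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class NuisanceSet:
    """Per-subject nuisance signals: 6 motion parameters, WM and CSF means."""

    motion6: np.ndarray  # (T, 6)
    wm: np.ndarray  # (T,)
    csf: np.ndarray  # (T,)

    def __post_init__(self) -> None:
        t = self.motion6.shape[0]
        if self.motion6.shape[1] != 6:
            raise ValueError("motion6 must have exactly 6 columns")
        if len(self.wm) != t or len(self.csf) != t:
            raise ValueError("nuisance series lengths disagree")


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a synthetic cohort.

    Defaults mirror a typical small resting-state study: 24 subjects,
    160 nodes in 6 modules, 240 volumes at TR = 2 s (235 retained after the
    conditioning stage drops the first 5), 30 trials per behavioral block.
    """

    n_subjects: int = 24
    n_nodes: int = 160
    #: node index -> module label; None derives modules from an atlas-style
    #: equal partition into ``n_modules`` blocks.
    module_assignment: np.ndarray | None = None
    n_modules: int = 6
    within_weight_mean: float = 0.35
    between_weight_mean: float = 0.10
    weight_sd: float = 0.05
    subject_noise_sd: float = 0.03
    #: default: two default-mode nodes with equal negative effects (better —
    #: lower — IE with higher DMN local efficiency)
    planted_nodes: tuple[int, ...] = (5, 12)
    planted_betas: tuple[float, ...] = (-300.0, -300.0)
    behavior_noise_sd: float | None = None
    #: population R² of the planted linear model; used to calibrate the
    #: behavioral noise when ``behavior_noise_sd`` is None.
    target_r2: float = 0.7
    behavior_mean: float = 530.0  # ms, typical direction-task IE scale
    n_timepoints: int = 240
    tr: float = 2.0
    n_trials: int = 30
    nuisance_amplitude: float = 0.4
    voxels_per_roi: int = 1
    voxel_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints <= 0:
            raise ValueError("n_timepoints must be positive")
        if self.within_weight_mean < 0 or self.between_weight_mean < 0:
            raise ValueError("weight means must be nonnegative")
        if any(k < 0 or k >= self.n_nodes for k in self.planted_nodes):
            raise ValueError("planted_nodes must be valid node ids")
        if self.planted_betas and len(self.planted_betas) != len(self.planted_nodes):
            raise ValueError("planted_betas must match planted_nodes")

    def modules(self) -> np.ndarray:
        if self.module_assignment is not None:
            return np.asarray(self.module_assignment)
        return np.arange(self.n_nodes) * self.n_modules // self.n_nodes


@dataclass
class Cohort:
    """Output bundle of :func:`simulate_cohort`."""

    spec: CohortSpec
    series: list[SubjectTimeSeries]
    nuisance: list[NuisanceSet]
    #: per-subject ground-truth weight matrices (the targets of estimation)
    true_weights: list[np.ndarray]
    modules: np.ndarray
    #: count of subjects whose target correlation needed eigenvalue repair
    n_repaired: int = 0


def nearest_positive_definite(corr: np.ndarray, floor: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Repair a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues below ``floor`` are clipped up, then the matrix is rescaled
    to unit diagonal.  Returns the repaired matrix and a flag saying whether
    any clipping occurred.
    """
    sym = (corr + corr.T) / 2
    vals, vecs = np.linalg.eigh(sym)
    repaired = bool(vals.min() < floor)
    if repaired:
        vals = np.clip(vals, floor, None)
        sym = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(sym))
        sym = sym / np.outer(d, d)
        np.fill_diagonal(sym, 1.0)
    return sym, repaired


def _group_backbone(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Modular group-mean weight matrix, clipped to nonnegative."""
    mods = spec.modules()
    same = mods[:, None] == mods[None, :]
    mean = np.where(same, spec.within_weight_mean, spec.between_weight_mean)
    noise = rng.normal(0.0, spec.weight_sd, size=(spec.n_nodes, spec.n_nodes))
    noise = (noise + noise.T) / np.sqrt(2)
    w = np.clip(mean + noise, 0.0, 0.95)
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w


def _smooth_walk(rng: np.random.Generator, t: int, scale: float) -> np.ndarray:
    """Slow random walk: cumulative sum of small increments, de-meaned."""
    walk = np.cumsum(rng.normal(0.0, scale, size=t))
    return walk - walk.mean()


def _low_freq_confound(rng: np.random.Generator, t: int, tr: float) -> np.ndarray:
    """Sum of slow sinusoids (< 0.01 Hz) plus a drift, unit-variance."""
    time = np.arange(t) * tr
    sig = np.zeros(t)
    for _ in range(3):
        f = rng.uniform(0.001, 0.009)
        sig += rng.normal(0, 1) * np.sin(2 * np.pi * f * time + rng.uniform(0, 2 * np.pi))
    sig += rng.normal(0, 0.3) * np.linspace(-1, 1, t)
    sd = sig.std()
    return sig / sd if sd > 0 else sig


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a cohort of subject time series with known connectivity.

    Per subject, the group modular backbone is perturbed by Gaussian weight
    noise (clipped to nonnegative), used as the off-diagonal of a target
    correlation matrix (repaired to positive definite by eigenvalue clipping
    when needed), and ROI series are drawn from the corresponding zero-mean
    multivariate normal.  Optional voxel expansion replicates each ROI signal
    into ``voxels_per_roi`` noisy voxel columns.  Motion/WM/CSF nuisance
    signals are generated and mixed into the data with
    ``nuisance_amplitude``.
    """
    rng = np.random.default_rng(spec.seed)
    backbone = _group_backbone(spec, rng)
    mods = spec.modules()
    series: list[SubjectTimeSeries] = []
    nuisance: list[NuisanceSet] = []
    true_weights: list[np.ndarray] = []
    n_repaired = 0
    t, n = spec.n_timepoints, spec.n_nodes

    for s in range(spec.n_subjects):
        srng = np.random.default_rng(rng.integers(0, 2**31))
        if spec.subject_noise_sd > 0:
            pert = srng.normal(0.0, spec.subject_noise_sd, size=(n, n))
            w = np.clip(backbone + (pert + pert.T) / 2, 0.0, 0.95)
            np.fill_diagonal(w, 0.0)
        else:
            w = backbone.copy()
        true_weights.append(w)

        target = w.copy()
        np.fill_diagonal(target, 1.0)
        target, repaired = nearest_positive_definite(target)
        n_repaired += repaired

        chol = np.linalg.cholesky(target)
        roi = srng.standard_normal(size=(t, n)) @ chol.T

        motion = np.column_stack(
            [_smooth_walk(srng, t, 0.02) for _ in range(3)]
            + [_smooth_walk(srng, t, 0.005) for _ in range(3)]
        )
        wm = _low_freq_confound(srng, t, spec.tr)
        csf = _low_freq_confound(srng, t, spec.tr)
        nuis = NuisanceSet(motion6=motion, wm=wm, csf=csf)
        nuisance.append(nuis)

        if spec.nuisance_amplitude > 0:
            load_wm = srng.normal(0, 1, size=n)
            load_csf = srng.normal(0, 1, size=n)
            roi = roi + spec.nuisance_amplitude * (
                np.outer(wm, load_wm) + np.outer(csf, load_csf)
            )

        sid = f"sub-{s:02d}"
        if spec.voxels_per_roi > 1:
            v = spec.voxels_per_roi
            labels = np.repeat(np.arange(n), v)
            vox = np.repeat(roi, v, axis=1) + srng.normal(
                0.0, spec.voxel_noise_sd, size=(t, n * v)
            )
            series.append(
                SubjectTimeSeries(sid, vox, tr=spec.tr, voxel_labels=labels)
            )
        else:
            series.append(SubjectTimeSeries(sid, roi, tr=spec.tr))

    if n_repaired:
        warnings.warn(
            f"{n_repaired} subject target correlation(s) repaired to "
            "positive definite by eigenvalue clipping",
            stacklevel=2,
        )
    return Cohort(
        spec=spec,
        series=series,
        nuisance=nuisance,
        true_weights=true_weights,
        modules=mods,
        n_repaired=n_repaired,
    )


@dataclass(frozen=True)
class PlantedBehavior:
    """IE targets produced by :func:`plant_behavior` with realized model facts."""

    ie: np.ndarray  # per-subject target IE, ms
    planted_nodes: tuple[int, ...]
    betas: np.ndarray
    noise_sd: float
    #: population R² of the planted linear model given the realized metric
    #: variance: var(signal) / (var(signal) + noise_sd²)
    population_r2: float


def plant_behavior(
    normalized_metrics: np.ndarray,
    spec: CohortSpec,
    seed: int | None = None,
) -> PlantedBehavior:
    """Plant a linear IE–efficiency association on computed nodal metrics.

    ``IE_s = μ + Σ_k β_k · m_{s,k} + ε_s`` with ``ε ~ N(0, σ²)``.  When the
    spec gives no explicit ``behavior_noise_sd``, σ is calibrated so the
    population R² of the planted model equals ``spec.target_r2``.

    Parameters
    ----------
    normalized_metrics
        Subject × node matrix of integrated, subject-normalized nodal
        metrics (typically local efficiency).
    spec
        Cohort spec carrying planted nodes, betas and noise level.
    seed
        Seed for the behavioral noise; defaults to ``spec.seed + 1``.
    """
    if not spec.planted_nodes:
        raise ValueError("spec.planted_nodes is empty")
    cols = np.asarray(spec.planted_nodes)
    m = normalized_metrics[:, cols]
    if np.any(m.std(axis=0) == 0):
        bad = cols[m.std(axis=0) == 0].tolist()
        raise ValueError(f"planted metric columns have zero variance: {bad}")
    betas = np.asarray(
        spec.planted_betas if spec.planted_betas else [-300.0] * len(cols),
        dtype=float,
    )
    signal = m @ betas
    # center the planted effect so the intercept (behavior_mean) sets the IE
    # scale; the linear form is unchanged up to that intercept
    signal = signal - signal.mean()
    sig_var = float(signal.var(ddof=1))
    if spec.behavior_noise_sd is not None:
        noise_sd = float(spec.behavior_noise_sd)
    else:
        r2 = spec.target_r2
        if not 0 < r2 <= 1:
            raise ValueError("target_r2 must lie in (0, 1]")
        noise_sd = float(np.sqrt(sig_var * (1 - r2) / r2)) if r2 < 1 else 0.0
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    eps = rng.normal(0.0, noise_sd, size=m.shape[0]) if noise_sd > 0 else 0.0
    ie = spec.behavior_mean + signal + eps
    pop_r2 = sig_var / (sig_var + noise_sd**2) if sig_var + noise_sd**2 > 0 else 0.0
    return PlantedBehavior(
        ie=ie,
        planted_nodes=tuple(int(c) for c in cols),
        betas=betas,
        noise_sd=noise_sd,
        population_r2=float(pop_r2),
    )


def simulate_trials(
    target_ie: float,
    n_trials: int,
    accuracy: float,
    seed: int,
    rt_sigma_log: float = 0.2,
) -> pd.DataFrame:
    """Generate a per-trial (rt_ms, correct) table realizing a target IE.

    Correctness is Bernoulli(accuracy); correct-trial response times are
    lognormal with mean ``accuracy · target_ie`` so that the expected
    inverse efficiency (mean correct RT / accuracy) equals ``target_ie``.
    """
    if not 0 < accuracy <= 1:
        raise ValueError("accuracy must lie in (0, 1]")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if target_ie <= 0:
        raise ValueError("target_ie must be positive (ms)")
    rng = np.random.default_rng(seed)
    correct = rng.random(n_trials) < accuracy
    mean_rt = accuracy * target_ie
    mu_log = np.log(mean_rt) - rt_sigma_log**2 / 2
    rt = rng.lognormal(mean=mu_log, sigma=rt_sigma_log, size=n_trials)
    return pd.DataFrame({"rt_ms": rt, "correct": correct.astype(int)})


def noise_sd_for_target_r2(signal: np.ndarray, target_r2: float) -> float:
    """Behavioral noise SD giving population R² = target_r2 for a signal."""
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must lie in (0, 1)")
    return float(np.sqrt(signal.var(ddof=1) * (1 - target_r2) / target_r2))


def with_planted(spec: CohortSpec, nodes: tuple[int, ...], betas: tuple[float, ...]) -> CohortSpec:
    """Convenience: copy a spec with new planted nodes/betas."""
    return replace(spec, planted_nodes=nodes, planted_betas=betas)
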