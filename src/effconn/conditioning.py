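"""Temporal preprocessing of ROI/voxel BOLD-like series.

Stages, in order: drop initial volumes, zero-phase band-pass filter,
linear detrend, and nuisance regression against an intercept, the
Friston 24-parameter motion expansion, and mean WM/CSF signals.
Spatial preprocessing (realignment, normalization, smoothing) is out of
scope — it requires real images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .cohort import NuisanceSet, SubjectTimeSeries


@dataclass(frozen=True)
class ConditioningConfig:
    """Temporal preprocessing options.

    ``band`` is (low, high) in Hz and must satisfy 0 <= low < high < Nyquist;
    ``band=None`` skips filtering.  ``detrend_first`` swaps the
    band-pass/detrend order (contested practice; the default filters first).
    """

    n_drop: int = 5
    band: tuple[float, float] | None = (0.01, 0.08)
    detrend: bool = True
    use_friston24: bool = True
    use_wm_csf: bool = True
    detrend_first: bool = False
    filter_order: int = 2

    def validate(self, tr: float) -> None:
        if self.n_drop < 0:
            raise ValueError("n_drop must be >= 0")
        if self.band is None:
            return
        low, high = self.band
        nyq = 1.0 / (2.0 * tr)
        if not (0 <= low < high < nyq):
            raise ValueError(
                f"band {self.band} invalid for TR={tr} (Nyquist {nyq:.3f} Hz)"
            )


def friston24(motion6: np.ndarray) -> np.ndarray:
    """Expand 6 motion parameters into the 24-parameter regressor set.

    Per parameter m: [m(t), m(t-1), m(t)^2, m(t-1)^2], with the lagged row 0
    zero-filled.  Column order is blockwise: the 6 current params, then the
    6 lagged, then the 6 squared, then the 6 lagged-squared.
    """
    m = np.asarray(motion6, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"expected time x 6 motion matrix, got {m.shape}")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 timepoints")
    lag = np.vstack([np.zeros((1, 6)), m[:-1]])
    return np.hstack([m, lag, m**2, lag**2])


def _bandpass(data: np.ndarray, band: tuple[float, float], tr: float, order: int) -> np.ndarray:
    nyq = 1.0 / (2.0 * tr)
    low, high = band
    if low <= 0:
        sos = sps.butter(order, high / nyq, btype="lowpass", output="sos")
    else:
        sos = sps.butter(order, [low / nyq, high / nyq], btype="bandpass", output="sos")
    return sps.sosfiltfilt(sos, data, axis=0)


def residualize(data: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residuals of each data column on the design (rank-safe).

    Rank deficiency is reported and handled by least-squares projection onto
    the design's column space, which drops the collinear directions.
    """
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            f"nuisance design rank-deficient ({rank}/{design.shape[1]}); "
            "collinear columns contribute nothing",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    return data - design @ beta


def condition_series(
    ts: SubjectTimeSeries,
    nuis: NuisanceSet | None,
    cfg: ConditioningConfig,
) -> SubjectTimeSeries:
    """Apply the full temporal conditioning pipeline to one subject.

    Order: drop ``n_drop`` volumes -> zero-phase Butterworth band-pass ->
    linear detrend -> OLS residualization on [intercept, Friston-24, WM, CSF]
    (nuisance rows are dropped in step one alongside the data).  Output
    columns are mean-zero.
    """
    cfg.validate(ts.tr)
    data = np.asarray(ts.data, dtype=float)[cfg.n_drop :]
    if nuis is not None and nuis.motion6.shape[0] != ts.data.shape[0]:
        raise ValueError("nuisance length must match raw series length")
    min_len = 3 * (cfg.filter_order * 2 + 1)
    if data.shape[0] < min_len:
        raise ValueError(
            f"series too short after dropping {cfg.n_drop} volumes "
            f"({data.shape[0]} < {min_len} filter warm-up)"
        )

    def _detrend(x: np.ndarray) -> np.ndarray:
        return sps.detrend(x, axis=0, type="linear") if cfg.detrend else x

    def _filter(x: np.ndarray) -> np.ndarray:
        if cfg.band is None:
            return x
        return _bandpass(x, cfg.band, ts.tr, cfg.filter_order)

    if cfg.detrend_first:
        data = _filter(_detrend(data))
    else:
        data = _detrend(_filter(data))

    cols: list[np.ndarray] = [np.ones((data.shape[0], 1))]
    if nuis is not None:
        if cfg.use_friston24:
            cols.append(friston24(nuis.motion6[cfg.n_drop :]))
        if cfg.use_wm_csf:
            cols.append(nuis.wm[cfg.n_drop :, None])
            cols.append(nuis.csf[cfg.n_drop :, None])
    design = np.hstack(cols)
    data = residualize(data, design)
    data = data - data.mean(axis=0)
    return SubjectTimeSeries(
        subject_id=ts.subject_id,
        data=data,
        tr=ts.tr,
        voxel_labels=ts.voxel_labels,
    )
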