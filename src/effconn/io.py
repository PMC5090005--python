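"""Plain-text I/O: TSV tables and JSON reports, all auditable formats.

Writers and readers round-trip to numerical equality (tolerance 1e-12 is
guaranteed by full-precision formatting).  Readers validate structure and
report offending rows/columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .atlas import ATLAS_COLUMNS, validate_atlas
from .cohort import NuisanceSet, SubjectTimeSeries


def write_atlas(atlas: pd.DataFrame, path: str | Path) -> None:
    validate_atlas(atlas)
    atlas.to_csv(path, sep="\t", index=False)


def read_atlas(path: str | Path) -> pd.DataFrame:
    atlas = pd.read_csv(path, sep="\t")
    try:
        validate_atlas(atlas)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err
    return atlas


def write_matrix(m: np.ndarray, path: str | Path, node_ids=None) -> None:
    """Square matrix as TSV with node_id header and index."""
    n = m.shape[0]
    ids = np.arange(n) if node_ids is None else node_ids
    df = pd.DataFrame(m, index=ids, columns=ids)
    df.to_csv(path, sep="\t", index_label="node_id", float_format="%.17g")


def read_matrix(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col="node_id")
    m = df.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: matrix is {m.shape}, expected square")
    return m


def write_series(ts: SubjectTimeSeries, path: str | Path) -> None:
    """Time × ROI (or voxel) series; header is node_id or voxel label."""
    cols = (
        [str(c) for c in ts.voxel_labels]
        if ts.voxel_labels is not None
        else [str(c) for c in range(ts.data.shape[1])]
    )
    pd.DataFrame(ts.data, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_series(
    path: str | Path,
    subject_id: str | None = None,
    tr: float = 2.0,
    voxel_level: bool = False,
) -> SubjectTimeSeries:
    df = pd.read_csv(path, sep="\t")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"{path}: missing values in column(s) {bad}")
    sid = subject_id or Path(path).stem
    labels = df.columns.astype(int).to_numpy() if voxel_level else None
    return SubjectTimeSeries(
        sid, df.to_numpy(dtype=float), tr=tr, voxel_labels=labels
    )


def write_nuisance(nuis: NuisanceSet, path: str | Path) -> None:
    cols = {f"motion{k}": nuis.motion6[:, k] for k in range(6)}
    cols["wm"] = nuis.wm
    cols["csf"] = nuis.csf
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_nuisance(path: str | Path) -> NuisanceSet:
    df = pd.read_csv(path, sep="\t")
    need = [f"motion{k}" for k in range(6)] + ["wm", "csf"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing nuisance column(s) {missing}")
    return NuisanceSet(
        motion6=df[[f"motion{k}" for k in range(6)]].to_numpy(float),
        wm=df["wm"].to_numpy(float),
        csf=df["csf"].to_numpy(float),
    )


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = ["subject_id", "condition", "rt_ms", "correct"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    neg = df.index[df["rt_ms"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative rt_ms at row(s) {neg.tolist()}")
    bad = df.index[~df["correct"].isin([0, 1, True, False])]
    if len(bad):
        raise ValueError(f"{path}: non-binary correct at row(s) {bad.tolist()}")
    return df


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj: Any) -> Any:
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.bool_):
            return bool(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
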