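"""Node parcellation tables (atlases) for network construction.

An atlas is a :class:`pandas.DataFrame` with one row per network node and
columns ``node_id, name, x, y, z, subnetwork, hemisphere``.  Coordinates are
fabricated placeholders in MNI-like millimetres — they label nodes for
reporting and never enter any computation.  Two synthetic fixtures are
provided: a 160-node / 6-subnetwork table shaped like meta-analytic
functional parcellations, and a 90-node anatomical-style table.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

ATLAS_COLUMNS = ["node_id", "name", "x", "y", "z", "subnetwork", "hemisphere"]

#: Subnetwork sizes of the synthetic 160-node functional atlas.
D160_SUBNETWORKS: dict[str, int] = {
    "default": 34,
    "fronto-parietal": 21,
    "cingulo-opercular": 32,
    "sensorimotor": 33,
    "occipital": 22,
    "cerebellum": 18,
}


def make_atlas(
    n_nodes: int,
    subnetwork_sizes: Mapping[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Fabricate a deterministic atlas table.

    Parameters
    ----------
    n_nodes
        Total number of nodes; the subnetwork sizes must sum to this.
    subnetwork_sizes
        Mapping from subnetwork label to node count.
    seed
        Seed for the fabricated coordinates and hemisphere assignment.

    Returns
    -------
    pandas.DataFrame
        Table with columns ``node_id, name, x, y, z, subnetwork, hemisphere``
        and ``node_id`` contiguous from 0.
    """
    total = sum(subnetwork_sizes.values())
    if total != n_nodes:
        raise ValueError(
            f"subnetwork sizes sum to {total}, expected n_nodes={n_nodes}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    node_id = 0
    for label, count in subnetwork_sizes.items():
        for k in range(count):
            x = float(np.round(rng.uniform(-70, 70), 1))
            y = float(np.round(rng.uniform(-100, 70), 1))
            z = float(np.round(rng.uniform(-45, 75), 1))
            hemi = "L" if x < -2 else ("R" if x > 2 else "M")
            rows.append(
                (node_id, f"{label}_{k:02d}_{hemi}", x, y, z, label, hemi)
            )
            node_id += 1
    atlas = pd.DataFrame(rows, columns=ATLAS_COLUMNS)
    validate_atlas(atlas)
    return atlas


def validate_atlas(atlas: pd.DataFrame) -> None:
    """Check atlas invariants: columns, unique contiguous node ids."""
    missing = [c for c in ATLAS_COLUMNS if c not in atlas.columns]
    if missing:
        raise ValueError(f"atlas missing columns: {missing}")
    ids = atlas["node_id"].to_numpy()
    if len(set(ids.tolist())) != len(ids):
        raise ValueError("atlas node_id values are not unique")
    if not np.array_equal(np.sort(ids), np.arange(len(ids))):
        raise ValueError("atlas node_id values must be contiguous from 0")


def dosenbach160_like(seed: int = 160) -> pd.DataFrame:
    """Synthetic 160-node atlas with the six canonical functional subnetworks."""
    return make_atlas(160, D160_SUBNETWORKS, seed=seed)


def aal90_like(seed: int = 90) -> pd.DataFrame:
    """Synthetic 90-node anatomical-style atlas (single 'cerebrum' label)."""
    return make_atlas(90, {"cerebrum": 90}, seed=seed)
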