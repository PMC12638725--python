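"""Allostatic-interoceptive network (AIN) region atlas.

The default atlas covers 24 regions — 12 anatomical families
(insula, anterior/mid/posterior cingulate, four orbitofrontal subdivisions,
amygdala, hippocampus, parahippocampal gyrus, thalamus) in each hemisphere —
labelled with AAL-2-style names. MNI centroids are approximate region
centers-of-mass and are used only as spatial features for network clustering.
"""

from __future__ import annotations

import itertools
from importlib import resources

import numpy as np
import pandas as pd

ATLAS_COLUMNS = ["label", "hemisphere", "family", "x", "y", "z"]


def load_atlas(path=None) -> pd.DataFrame:
    """Load an atlas definition (CSV: label, hemisphere, family, x, y, z).

    With no ``path`` the shipped 24-region AIN atlas is returned.
    """
    if path is None:
        with resources.files("cardioain.data").joinpath("ain_atlas.csv").open() as fh:
            atlas = pd.read_csv(fh)
    else:
        atlas = pd.read_csv(path)
    missing = set(ATLAS_COLUMNS) - set(atlas.columns)
    if missing:
        raise ValueError(f"atlas file lacks columns: {sorted(missing)}")
    if atlas["label"].duplicated().any():
        dupes = atlas.loc[atlas["label"].duplicated(), "label"].tolist()
        raise ValueError(f"duplicate atlas labels: {dupes}")
    if not set(atlas["hemisphere"]) <= {"L", "R"}:
        raise ValueError("hemisphere must be L or R")
    return atlas.reset_index(drop=True)


def connection_pairs(atlas: pd.DataFrame) -> list[tuple[str, str]]:
    """Strict-upper-triangle connection enumeration in atlas row order.

    For the default 24-region atlas this yields 24*23/2 = 276 pairs; every
    connection-level result table has exactly one row per pair, in this order.
    """
    labels = atlas["label"].tolist()
    return list(itertools.combinations(labels, 2))


def centroid_distances(atlas: pd.DataFrame) -> np.ndarray:
    """Pairwise Euclidean distances between MNI centroids (mm), ROI x ROI."""
    xyz = atlas[["x", "y", "z"]].to_numpy(dtype=float)
    diff = xyz[:, None, :] - xyz[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))
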