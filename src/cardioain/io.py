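"""Readers and writers for the pipeline's plain-text artifacts.

All tabular IO is UTF-8 CSV/TSV with explicit schemas. Result tables carry a
header comment line with the package version, seed, and configuration hash
so every output is traceable to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import GROUPS

PHENOTYPE_COLUMNS = ["id", "group", "age", "sex", "education", "mmse", "cdr_sob",
                     "scanner", "tiv", "sbp", "bmi", "diabetes", "htn_treated", "smoker"]
_BOOL_COLS = ["diabetes", "htn_treated", "smoker"]


def load_phenotype(path) -> pd.DataFrame:
    """Load and validate a phenotype CSV into a typed cohort table.

    Raises ``ValueError`` with row numbers for duplicate ids, unknown group
    labels, or out-of-range MMSE. Attaches a per-column missingness report
    under ``df.attrs['missingness']``.
    """
    df = pd.read_csv(path, comment="#")
    missing_cols = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"phenotype file lacks columns: {sorted(missing_cols)}")
    dup = df["id"].duplicated(keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()     # +2: header + 1-based
        raise ValueError(f"duplicate ids {sorted(set(df.loc[dup, 'id']))} at rows {rows}")
    bad_group = ~df["group"].isin(GROUPS)
    if bad_group.any():
        rows = (df.index[bad_group] + 2).tolist()
        raise ValueError(f"unknown group labels at rows {rows}: "
                         f"{sorted(set(df.loc[bad_group, 'group']))}")
    mmse = df["mmse"].astype(float)
    bad_mmse = mmse.notna() & ((mmse < 0) | (mmse > 30))
    if bad_mmse.any():
        rows = (df.index[bad_mmse] + 2).tolist()
        raise ValueError(f"MMSE outside [0, 30] at rows {rows}")
    for col in _BOOL_COLS:
        obs = df[col].notna()
        df[col] = df[col].astype(object)
        df.loc[obs, col] = df.loc[obs, col].astype(bool)
    df.attrs["missingness"] = {c: float(df[c].isna().mean()) for c in PHENOTYPE_COLUMNS}
    return df


def save_phenotype(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def load_volumes(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "id" not in df.columns:
        raise ValueError("volume table needs an 'id' column")
    rois = [c for c in df.columns if c != "id"]
    if df[rois].isna().any().any():
        raise ValueError("volume table has missing cells")
    if (df[rois].to_numpy(dtype=float) <= 0).any():
        raise ValueError("volumes must be positive")
    return df


def save_volumes(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def save_timeseries(ts_by_id: dict[str, pd.DataFrame], directory) -> None:
    """One TSV per participant (rows = timepoints, columns = ROI labels)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for pid, ts in ts_by_id.items():
        ts.to_csv(directory / f"{pid}.tsv", sep="\t", index=False)


def load_timeseries(directory, ids=None) -> dict[str, pd.DataFrame]:
    directory = Path(directory)
    paths = sorted(directory.glob("*.tsv"))
    if ids is not None:
        wanted = set(ids)
        paths = [p for p in paths if p.stem in wanted]
        found = {p.stem for p in paths}
        if wanted - found:
            raise ValueError(f"missing time-series for: {sorted(wanted - found)[:5]}")
    return {p.stem: pd.read_csv(p, sep="\t") for p in paths}


def save_connectivity(conn: pd.DataFrame, path) -> None:
    """Condensed per-participant connectivity (rows = participants, cols = pairs)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    conn.to_csv(path, index_label="id")


def load_connectivity(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col="id")


def config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, seed=None, config=None, sep="\t") -> None:
    """Write a result table with a provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (f"# cardioain {__version__} | seed={seed} | "
              f"config={config_hash(config) if config is not None else 'none'}")
    for key, val in df.attrs.items():
        header += f" | {key}={val}"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, sep=sep, index=False)


def read_table(path, sep="\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    Path(path).write_text(json.dumps(obj, indent=2, default=_default, sort_keys=True))
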