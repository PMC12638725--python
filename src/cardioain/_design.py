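"""Design-matrix construction shared by the structural and functional GLMs."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import drop_aliased_columns


def encode_term(cohort: pd.DataFrame, term: str):
    """Encode one model term as (columns, names).

    ``sex`` is an indicator with M=1; ``group``/``scanner``/``diagnosis`` are
    drop-first indicator contrasts over the levels present (reference level =
    'CN' for group when present, else first sorted level); numeric columns
    pass through.
    """
    if term == "sex":
        return [(cohort["sex"] == "M").to_numpy(dtype=float)], ["sex[M]"]
    if term in ("group", "scanner", "diagnosis"):
        col = "group" if term == "diagnosis" else term
        levels = sorted(cohort[col].unique())
        if term in ("group", "diagnosis") and "CN" in levels:
            levels = ["CN"] + [l for l in levels if l != "CN"]
        cols, names = [], []
        for level in levels[1:]:
            cols.append((cohort[col] == level).to_numpy(dtype=float))
            names.append(f"{term}[{level}]")
        return cols, names
    return [cohort[term].to_numpy(dtype=float)], [term]


def build_design(cohort: pd.DataFrame, covariates, frs: bool = True):
    """Intercept + (optionally) FRS + encoded covariates, aliased columns dropped.

    Returns ``(X, names, dropped)``. The intercept and the FRS column are
    protected: if either is aliased the design is rejected outright.
    """
    cols = [np.ones(len(cohort))]
    names = ["intercept"]
    keep = 1
    if frs:
        cols.append(cohort["frs_points"].to_numpy(dtype=float))
        names.append("frs")
        keep = 2
    for term in covariates:
        tcols, tnames = encode_term(cohort, term)
        cols.extend(tcols)
        names.extend(tnames)
    X = np.column_stack(cols)
    return drop_aliased_columns(X, names, keep=keep)
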