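"""Chained-equations imputation (MICE-style) for cardiovascular risk factors.

Continuous variables are imputed by predictive-mean matching (PMM) against a
linear model on the other risk factors plus the always-complete predictors;
binary variables by a logistic-model probability draw. Variables are visited
in order of increasing missingness for a fixed number of full cycles. The
procedure is deterministic for a fixed seed and never alters observed cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import LogisticRegression


def _encode(col: pd.Series) -> np.ndarray:
    if col.dtype == object or str(col.dtype) == "category":
        try:
            return col.astype(float).to_numpy()
        except (ValueError, TypeError):
            return col.map({"M": 1.0, "F": 0.0}).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


class ChainedImputer(BaseEstimator, TransformerMixin):
    """Single-completion chained-equations imputer.

    Parameters
    ----------
    continuous, binary : list of str
        Columns to impute, by type. Binary columns hold {0, 1}/bool values.
    predictors : list of str
        Always-complete columns (e.g. age, sex) entered in every model.
    n_cycles : int, default 10
        Full passes over the incomplete variables.
    donor_k : int, default 5
        PMM donor pool size for continuous variables.
    seed : int
        Drives donor draws and Bernoulli draws; fixed seed => fixed output.
    """

    def __init__(self, continuous=(), binary=(), predictors=(), n_cycles=10,
                 donor_k=5, seed=0):
        self.continuous = list(continuous)
        self.binary = list(binary)
        self.predictors = list(predictors)
        self.n_cycles = n_cycles
        self.donor_k = donor_k
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        targets = self.continuous + self.binary
        for col in targets:
            frac = X[col].isna().mean()
            if frac == 1.0:
                raise ValueError(f"column {col!r} is entirely missing")
            if frac > 0.5:
                raise ValueError(
                    f"column {col!r} is {frac:.0%} missing; imputation model unidentifiable"
                )
        for col in self.predictors:
            if X[col].isna().any():
                raise ValueError(f"predictor column {col!r} must be complete")
        self.columns_ = targets
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        rng = np.random.default_rng(self.seed)
        out = X.copy()
        mask = {c: out[c].isna().to_numpy() for c in self.columns_}
        incomplete = [c for c in self.columns_ if mask[c].any()]
        # visit order: increasing missingness, stable for ties
        incomplete.sort(key=lambda c: (mask[c].mean(), self.columns_.index(c)))
        if not incomplete:
            return out

        work = {}
        for c in self.columns_ + self.predictors:
            work[c] = _encode(out[c])
        # initial fill: mean (continuous) / mode (binary) of observed values
        for c in incomplete:
            obs = work[c][~mask[c]]
            fill = obs.mean() if c in self.continuous else float(np.round(obs.mean()))
            work[c][mask[c]] = fill

        for _ in range(self.n_cycles):
            for c in incomplete:
                others = [o for o in self.columns_ if o != c] + self.predictors
                design = np.column_stack([np.ones(len(out))] + [work[o] for o in others])
                obs, mis = ~mask[c], mask[c]
                y_obs = work[c][obs]
                if c in self.continuous:
                    beta, *_ = np.linalg.lstsq(design[obs], y_obs, rcond=None)
                    yhat_obs = design[obs] @ beta
                    yhat_mis = design[mis] @ beta
                    work[c][mis] = self._pmm_draw(yhat_obs, y_obs, yhat_mis, rng)
                else:
                    classes = np.unique(y_obs)
                    if classes.size == 1:
                        p_mis = np.full(mis.sum(), float(classes[0]))
                    else:
                        model = LogisticRegression(max_iter=500)
                        model.fit(design[obs][:, 1:], y_obs)
                        p_mis = model.predict_proba(design[mis][:, 1:])[:, 1]
                    work[c][mis] = (rng.random(mis.sum()) < p_mis).astype(float)

        for c in incomplete:
            # restore observed cells bit-for-bit, keep imputed draws elsewhere
            final = work[c].copy()
            final[~mask[c]] = _encode(X[c])[~mask[c]]
            observed = X[c].dropna()
            if c in self.binary and (observed.map(lambda v: isinstance(v, (bool, np.bool_)))
                                     .all()):
                out[c] = final.astype(bool)
            else:
                out[c] = final
        return out

    def _pmm_draw(self, yhat_obs, y_obs, yhat_mis, rng):
        """Predictive-mean matching: draw one of the donor_k nearest observed values."""
        k = min(self.donor_k, y_obs.size)
        imputed = np.empty(yhat_mis.size)
        for i, yh in enumerate(yhat_mis):
            dist = np.abs(yhat_obs - yh)
            donors = np.argpartition(dist, k - 1)[:k]
            imputed[i] = y_obs[donors[rng.integers(k)]]
        return imputed


def impute_missing(records: pd.DataFrame, n_cycles: int = 10, seed: int = 0) -> pd.DataFrame:
    """Functional wrapper: complete the risk-factor columns of a phenotype table."""
    from .framingham import BINARY_FIELDS

    imputer = ChainedImputer(
        continuous=["sbp", "bmi"],
        binary=BINARY_FIELDS,
        predictors=["age", "sex"],
        n_cycles=n_cycles,
        seed=seed,
    )
    return imputer.fit_transform(records)
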