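"""ROI-level grey-matter analyses against composite cardiovascular risk.

Four stages, mirroring a region-wise reading of a voxel-based morphometry
design: (1) TIV correction of regional volumes; (2) Pearson correlation of
corrected volume with the risk score per region; (3) covariate-adjusted OLS
per region within a matched tandem (volume ~ risk + group + scanner + TIV);
(4) normative w-scores — each participant's volume expressed as a
standardized deviation from the value a reference-sample regression predicts
— and the risk x diagnosis interaction contrast between the two patient
groups on those w-scores. All region-wise families are Benjamini-Hochberg
FDR corrected across the atlas.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from ._design import build_design, encode_term
from ._stats import bh_fdr, ols


def _roi_columns(volumes: pd.DataFrame) -> list[str]:
    return [c for c in volumes.columns if c != "id"]


def _aligned(volumes: pd.DataFrame, cohort: pd.DataFrame):
    """Volumes re-indexed to the cohort's participant order."""
    missing = set(cohort["id"]) - set(volumes["id"])
    if missing:
        raise ValueError(f"volume table lacks participants: {sorted(missing)[:5]}")
    vol = volumes.set_index("id").loc[cohort["id"]]
    return vol[_roi_columns(volumes)]


class TIVCorrector(BaseEstimator, TransformerMixin):
    """Remove head-size (TIV) dependence from regional volumes.

    ``method='residual'`` regresses each region's volume on TIV across the
    analysis sample and returns residual + grand mean; ``'proportional'``
    rescales by mean(TIV)/TIV. ``'auto'`` falls back to proportional when TIV
    is constant (residualization unidentifiable).
    """

    def __init__(self, method: str = "residual"):
        self.method = method

    def fit(self, volumes: pd.DataFrame, y=None, *, tiv: np.ndarray):
        tiv = np.asarray(tiv, dtype=float)
        if np.any(tiv <= 0):
            raise ValueError("tiv must be positive")
        method = self.method
        if method == "auto":
            method = "proportional" if np.ptp(tiv) == 0 else "residual"
        if method == "residual" and np.ptp(tiv) == 0:
            raise ValueError("constant TIV: residualization unidentifiable; "
                             "use method='proportional'")
        self.method_ = method
        self.tiv_ = tiv
        rois = _roi_columns(volumes)
        V = volumes[rois].to_numpy(dtype=float)
        if method == "residual":
            X = np.column_stack([np.ones_like(tiv), tiv])
            fit = ols(X, V)
            self.coef_ = fit.beta
            self.mean_ = V.mean(axis=0)
        else:
            self.mean_tiv_ = tiv.mean()
        self.rois_ = rois
        return self

    def transform(self, volumes: pd.DataFrame) -> pd.DataFrame:
        out = volumes.copy()
        V = volumes[self.rois_].to_numpy(dtype=float)
        if self.method_ == "residual":
            X = np.column_stack([np.ones_like(self.tiv_), self.tiv_])
            out[self.rois_] = V - X @ self.coef_ + self.mean_
        else:
            out[self.rois_] = V * (self.mean_tiv_ / self.tiv_)[:, None]
        return out


def tiv_correct(volumes: pd.DataFrame, tiv: np.ndarray, method: str = "residual") -> pd.DataFrame:
    """Functional wrapper over :class:`TIVCorrector` (fit and transform in place)."""
    return TIVCorrector(method=method).fit(volumes, tiv=tiv).transform(volumes)


def roi_frs_correlation(volumes: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of (TIV-corrected) regional volume with the risk score.

    Returns one row per region (r, p, q) with BH-FDR across regions — the
    statistic shown in region-wise spider plots.
    """
    if len(cohort) < 4:
        raise ValueError("need at least 4 participants for a correlation")
    frs = cohort["frs_points"].to_numpy(dtype=float)
    if np.ptp(frs) == 0:
        raise ValueError("frs_points has zero variance")
    V = _aligned(volumes, cohort)
    n = len(cohort)
    fc = frs - frs.mean()
    Vc = V.to_numpy() - V.to_numpy().mean(axis=0)
    denom = np.sqrt((fc**2).sum() * (Vc**2).sum(axis=0))
    r = np.where(denom > 0, (Vc * fc[:, None]).sum(axis=0) / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p = np.where(np.isnan(p), np.where(np.abs(r) == 1.0, 0.0, np.nan), p)
    return pd.DataFrame({"unit": V.columns, "r": r, "p": p, "q": bh_fdr(p), "n": n})


def roi_frs_regression(volumes: pd.DataFrame, cohort: pd.DataFrame,
                       covariates=("group", "scanner", "tiv")) -> pd.DataFrame:
    """Per-region OLS: volume ~ 1 + FRS + group + scanner contrasts + TIV.

    The FRS coefficient row is reported per region with BH-FDR across the
    atlas. Aliased covariate columns (e.g. scanner confounded with group)
    are dropped with a warning.
    """
    V = _aligned(volumes, cohort)
    X, names, dropped = build_design(cohort, covariates, frs=True)
    if dropped:
        warnings.warn(f"dropped aliased design columns: {dropped}")
    fit = ols(X, V.to_numpy())
    k = names.index("frs")
    p = fit.p[k]
    return pd.DataFrame({"unit": V.columns, "beta": fit.beta[k], "se": fit.se[k],
                         "t": fit.t[k], "p": p, "q": bh_fdr(p), "n": len(cohort),
                         "df": fit.df})


class WScoreTransformer(BaseEstimator, TransformerMixin):
    """Normative w-scores for regional volumes.

    Per region, an OLS of volume on the covariates is fitted on a reference
    sample (by default the matched controls); every participant's w-score is
    the regression residual divided by the reference residual SD (ddof=1).
    Within the reference sample this construction gives per-region mean 0 and
    SD 1 exactly (up to floating-point error).

    Parameters
    ----------
    covariates : sequence of str
        Terms of the normative model (default age, sex, tiv, scanner).
        Add ``'diagnosis'`` to honor a pooled normative fit over patients and
        controls with diagnosis indicators.
    global_covariate : bool
        If True, each participant's global mean volume across the atlas is
        entered as an additional covariate.
    """

    def __init__(self, covariates=("age", "sex", "tiv", "scanner"),
                 global_covariate: bool = False):
        self.covariates = tuple(covariates)
        self.global_covariate = global_covariate

    _CATEGORICAL = ("scanner", "group", "diagnosis")

    def _design(self, cohort: pd.DataFrame, volumes_mat: np.ndarray,
                levels: dict | None = None):
        """Build the normative design; categorical contrasts use the fit-time
        level sets (``levels``) so transform-time subsets stay aligned."""
        cols = [np.ones(len(cohort))]
        names = ["intercept"]
        for term in self.covariates:
            if term == "sex":
                cols.append((cohort["sex"] == "M").to_numpy(dtype=float))
                names.append("sex[M]")
            elif term in self._CATEGORICAL:
                src = "group" if term == "diagnosis" else term
                lv = (levels or {}).get(term) or sorted(cohort[src].unique())
                for level in lv[1:]:
                    cols.append((cohort[src] == level).to_numpy(dtype=float))
                    names.append(f"{term}[{level}]")
            else:
                cols.append(cohort[term].to_numpy(dtype=float))
                names.append(term)
        if self.global_covariate:
            cols.append(volumes_mat.mean(axis=1))
            names.append("global_volume")
        return np.column_stack(cols), names

    def fit(self, volumes: pd.DataFrame, y=None, *, cohort: pd.DataFrame,
            reference_ids=None):
        self.levels_ = {}
        for term in self.covariates:
            if term in self._CATEGORICAL:
                src = "group" if term == "diagnosis" else term
                lv = sorted(cohort[src].unique())
                if term in ("group", "diagnosis") and "CN" in lv:
                    lv = ["CN"] + [l for l in lv if l != "CN"]
                self.levels_[term] = lv
        if reference_ids is None:
            reference_ids = cohort.loc[cohort["group"] == "CN", "id"]
        ref_mask = cohort["id"].isin(set(reference_ids)).to_numpy()
        V = _aligned(volumes, cohort).to_numpy()
        X, names = self._design(cohort, V, self.levels_)
        n_ref, p = int(ref_mask.sum()), X.shape[1]
        if n_ref < p + 2:
            raise ValueError(f"reference sample ({n_ref}) smaller than "
                             f"covariate count + 2 ({p + 2})")
        if n_ref < 10 * p:
            warnings.warn(f"reference sample ({n_ref}) below 10x covariate count ({p})")
        fit = ols(X[ref_mask], V[ref_mask])
        self.names_ = names
        self.coef_ = fit.beta
        self.resid_sd_ = np.std(fit.resid, axis=0, ddof=1)
        if np.any(self.resid_sd_ == 0):
            raise ValueError("zero residual variance in the reference sample")
        self.rois_ = _roi_columns(volumes)
        return self

    def transform(self, volumes: pd.DataFrame, *, cohort: pd.DataFrame) -> pd.DataFrame:
        V = _aligned(volumes, cohort).to_numpy()
        X, _ = self._design(cohort, V, self.levels_)
        w = (V - X @ self.coef_) / self.resid_sd_
        out = pd.DataFrame(w, columns=self.rois_)
        out.insert(0, "id", cohort["id"].to_numpy())
        return out


def compute_wscores(volumes: pd.DataFrame, cohort: pd.DataFrame, reference_ids=None,
                    covariates=("age", "sex", "tiv", "scanner"),
                    global_covariate: bool = False) -> pd.DataFrame:
    """Fit the normative model on the reference sample and score everyone."""
    tf = WScoreTransformer(covariates=covariates, global_covariate=global_covariate)
    tf.fit(volumes, cohort=cohort, reference_ids=reference_ids)
    return tf.transform(volumes, cohort=cohort)


def interaction_contrast(wscores: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Risk x diagnosis interaction on w-scores between the two patient groups.

    Model per region: w ~ 1 + FRS + diagnosis + FRS x diagnosis, with the
    diagnosis indicator = 1 for AD. The reported interaction coefficient is
    therefore FRS-slope(AD) - FRS-slope(FTLD): positive means the risk
    association is more negative in FTLD than in AD. Swapping the diagnosis
    labels negates the coefficient exactly.
    """
    sub = cohort[cohort["group"].isin(["FTLD", "AD"])].reset_index(drop=True)
    present = set(sub["group"])
    if present != {"FTLD", "AD"}:
        raise ValueError(f"both diagnoses required, found {sorted(present)}")
    W = _aligned(wscores, sub).to_numpy()
    frs = sub["frs_points"].to_numpy(dtype=float)
    dx = (sub["group"] == "AD").to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(sub)), frs, dx, frs * dx])
    fit = ols(X, W)
    p = fit.p[3]
    return pd.DataFrame({"unit": _roi_columns(wscores), "beta": fit.beta[3],
                         "se": fit.se[3], "t": fit.t[3], "p": p, "q": bh_fdr(p),
                         "n": len(sub), "df": fit.df})
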