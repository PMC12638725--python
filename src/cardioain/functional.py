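"""ROI-to-ROI functional connectivity GLMs with two-level FDR inference.

Connectivity is estimated per participant as the Fisher z-transform of the
pairwise Pearson correlation between ROI time-series (optionally after a
zero-phase band-pass). Each of the 276 unique connections gets its own OLS
(z ~ risk score + group + scanner) with BH-FDR across connections. For
cluster-level ("functional network connectivity") inference, ROIs are
grouped by complete-linkage hierarchical clustering on a blend of
connectivity-profile similarity and anatomical proximity; each within/
between network pair aggregates its member connections' squared t-values,
with a Satterthwaite-style parametric p (or a seeded permutation engine),
and a connection is declared significant only when both its own q and its
network pair's q fall below the threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal as spsig
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score

from ._design import build_design
from ._stats import bh_fdr, ols
from .atlas import centroid_distances, connection_pairs

R_CLIP = 1.0 - 1e-7


def pair_label(a: str, b: str) -> str:
    return f"{a}__{b}"


def estimate_connectivity(ts: pd.DataFrame, band: tuple[float, float] | None = None,
                          tr: float = 2.0) -> pd.DataFrame:
    """Fisher-z connectivity matrix from one participant's ROI time-series.

    Optional band-pass: 4th-order Butterworth applied forward-backward
    (zero phase), band in Hz against the sampling rate 1/tr. Correlations are
    clipped to |r| <= 1 - 1e-7 before the atanh transform; the diagonal is
    NaN (undefined), and a constant ROI column yields NaN for its row/column
    with a warning.
    """
    if len(ts) < 50:
        raise ValueError("need at least 50 timepoints")
    X = ts.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("time-series contains non-finite values")
    if band is not None:
        low, high = band
        nyq = 0.5 / tr
        if not 0 <= low < high < nyq:
            raise ValueError(f"band must satisfy 0 <= low < high < Nyquist ({nyq} Hz)")
        sos = spsig.butter(4, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")
        X = spsig.sosfiltfilt(sos, X, axis=0)
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"constant ROI columns set to undefined: "
                      f"{list(ts.columns[constant])}")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    np.fill_diagonal(z, np.nan)
    return pd.DataFrame(z, index=ts.columns, columns=ts.columns)


def condense(conn: pd.DataFrame, atlas: pd.DataFrame) -> pd.Series:
    """Upper-triangle vectorization of a ROI x ROI matrix in atlas order."""
    labels = atlas["label"].tolist()
    mat = conn.loc[labels, labels].to_numpy()
    iu = np.triu_indices(len(labels), k=1)
    return pd.Series(mat[iu], index=[pair_label(a, b) for a, b in connection_pairs(atlas)])


def connectivity_table(conn_by_id: dict[str, pd.DataFrame], atlas: pd.DataFrame) -> pd.DataFrame:
    """Stack per-participant matrices into a (participants x connections) table."""
    rows = {pid: condense(mat, atlas) for pid, mat in conn_by_id.items()}
    return pd.DataFrame.from_dict(rows, orient="index")


def connection_glm(conn: pd.DataFrame, cohort: pd.DataFrame,
                   covariates=("group", "scanner")) -> pd.DataFrame:
    """Per-connection OLS of Fisher-z on the risk score, adjusted for covariates.

    ``conn`` is a (participants x connections) table indexed by participant
    id. The FRS coefficient row is reported per connection; BH-FDR across the
    full connection family.
    """
    missing = set(cohort["id"]) - set(conn.index)
    if missing:
        raise ValueError(f"connectivity missing for ids: {sorted(missing)[:5]}")
    Z = conn.loc[cohort["id"]].to_numpy(dtype=float)
    X, names, dropped = build_design(cohort, covariates, frs=True)
    if dropped:
        warnings.warn(f"dropped aliased design columns: {dropped}")
    fit = ols(X, Z)
    k = names.index("frs")
    p = fit.p[k]
    return pd.DataFrame({"unit": conn.columns, "beta": fit.beta[k], "se": fit.se[k],
                         "t": fit.t[k], "p": p, "q": bh_fdr(p), "n": len(cohort),
                         "df": fit.df})


def _profile_dissimilarity(mean_z: np.ndarray) -> np.ndarray:
    """1 - correlation between connectivity profiles, excluding self-entries."""
    n = mean_z.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = np.ones(n, dtype=bool)
            mask[[i, j]] = False
            a, b = mean_z[i, mask], mean_z[j, mask]
            if a.std() == 0 or b.std() == 0:
                d = 1.0
            else:
                d = 1.0 - np.corrcoef(a, b)[0, 1]
            D[i, j] = D[j, i] = d
    return D


class ROIClusterer(BaseEstimator, ClusterMixin):
    """Complete-linkage ROI clustering on functional similarity + anatomy.

    Dissimilarity: ``alpha * (1 - profile correlation) + (1 - alpha) *
    (centroid distance / max centroid distance)``. With ``n_clusters=None``
    the cluster count maximizes the silhouette over ``k_range``.
    """

    def __init__(self, alpha: float = 0.5, n_clusters: int | None = None,
                 k_range=(2, 8)):
        self.alpha = alpha
        self.n_clusters = n_clusters
        self.k_range = k_range

    def fit(self, mean_conn: pd.DataFrame, y=None, *, atlas: pd.DataFrame):
        labels = atlas["label"].tolist()
        mat = mean_conn.loc[labels, labels].to_numpy(dtype=float).copy()
        np.fill_diagonal(mat, 0.0)
        if not np.all(np.isfinite(mat)):
            raise ValueError("group-mean connectivity must be finite off-diagonal")
        n = len(labels)
        if self.n_clusters is not None and self.n_clusters > n:
            raise ValueError(f"n_clusters={self.n_clusters} exceeds ROI count {n}")
        D_fun = _profile_dissimilarity(mat)
        D_anat = centroid_distances(atlas)
        if D_anat.max() > 0:
            D_anat = D_anat / D_anat.max()
        D = self.alpha * D_fun + (1.0 - self.alpha) * D_anat
        np.fill_diagonal(D, 0.0)
        D = 0.5 * (D + D.T)
        Z = linkage(squareform(D, checks=False), method="complete")
        if self.n_clusters is not None:
            k = self.n_clusters
        else:
            best, k = -np.inf, self.k_range[0]
            for kk in range(self.k_range[0], min(self.k_range[1], n - 1) + 1):
                lab = fcluster(Z, kk, criterion="maxclust")
                if len(np.unique(lab)) < 2:
                    continue
                s = silhouette_score(D, lab, metric="precomputed")
                if s > best + 1e-12:
                    best, k = s, kk
        assign = fcluster(Z, k, criterion="maxclust")
        self.linkage_ = Z
        self.labels_ = assign
        self.assignment_ = dict(zip(labels, (int(a) for a in assign)))
        return self

    def fit_predict(self, mean_conn, y=None, **kwargs):
        return self.fit(mean_conn, **kwargs).labels_


def cluster_rois(mean_conn: pd.DataFrame, atlas: pd.DataFrame,
                 k: int | None = None, alpha: float = 0.5) -> dict[str, int]:
    """Functional wrapper over :class:`ROIClusterer`; returns label -> network id."""
    return ROIClusterer(alpha=alpha, n_clusters=k).fit(mean_conn, atlas=atlas).assignment_


def _satterthwaite_p(stat: float, m: int, df: int) -> float:
    """P-value for a mean of m squared t_df values via moment matching.

    Each squared t_df is F(1, df); the sum is approximated by a scaled
    chi-square with matched mean and variance.
    """
    if df <= 4:
        raise ValueError("parametric cluster p needs residual df > 4")
    mu = df / (df - 2.0)
    var = 2.0 * df**2 * (df - 1.0) / ((df - 2.0) ** 2 * (df - 4.0))
    S, M, V = m * stat, m * mu, m * var
    c = V / (2.0 * M)
    nu = 2.0 * M**2 / V
    return float(sps.chi2.sf(S / c, nu))


def _network_pairs(connections, assignment):
    """Map each connection label 'A__B' to its (sorted) network pair."""
    out = {}
    for c in connections:
        a, b = c.split("__")
        na, nb = assignment[a], assignment[b]
        out[c] = (min(na, nb), max(na, nb))
    return out


def _fwl_tvalues(conn, cohort, covariates, perm_frs=None):
    """Connection t-values via Frisch-Waugh-Lovell residualization.

    Residualize FRS and every connection on the nuisance design; the FRS
    t-value equals the correlation t of the residuals with df = n - p. With
    ``perm_frs`` a (n_perm, n) matrix of permuted FRS vectors, returns a
    (n_perm, n_connections) t matrix in one pass.
    """
    Z = conn.loc[cohort["id"]].to_numpy(dtype=float)
    X, names, _ = build_design(cohort, covariates, frs=False)
    n, p_nuis = X.shape
    Q, _ = np.linalg.qr(X)
    Ry = Z - Q @ (Q.T @ Z)
    frs = cohort["frs_points"].to_numpy(dtype=float)
    if perm_frs is None:
        F = (frs - 0)[None, :]
    else:
        F = perm_frs
    RF = F.T - Q @ (Q.T @ F.T)          # (n, n_perm)
    df = n - p_nuis - 1
    ry_norm = np.sqrt((Ry**2).sum(axis=0))
    rf_norm = np.sqrt((RF**2).sum(axis=0))
    r = (RF.T @ Ry) / np.outer(rf_norm, np.where(ry_norm > 0, ry_norm, np.inf))
    r = np.clip(r, -R_CLIP, R_CLIP)
    t = r * np.sqrt(df / (1.0 - r**2))
    return t if perm_frs is not None else t[0], df


def cluster_inference(results: pd.DataFrame, assignment: dict[str, int],
                      alpha: float = 0.05, method: str = "parametric",
                      conn: pd.DataFrame | None = None,
                      cohort: pd.DataFrame | None = None,
                      covariates=("group", "scanner"),
                      n_permutations: int = 5000, seed: int = 0):
    """Network-pair ("functional network connectivity") inference.

    Per network pair the aggregate statistic is the mean squared t of its
    member connections. ``method='parametric'`` uses a Satterthwaite-style
    chi-square approximation to the null mean of squared t values;
    ``'permutation'`` permutes the risk score across participants (seeded)
    and recomputes the aggregate. Network pairs are BH-FDR corrected, and
    ``significant_connections`` applies the dual threshold: connection q <
    alpha AND its network pair's q < alpha.
    """
    netpair = _network_pairs(results["unit"], assignment)
    groups: dict[tuple, list[int]] = {}
    for i, c in enumerate(results["unit"]):
        groups.setdefault(netpair[c], []).append(i)

    t_obs = results["t"].to_numpy(dtype=float)
    df = int(results["df"].iloc[0]) if "df" in results else None
    rows = []
    perm_stats = None
    if method == "permutation":
        if conn is None or cohort is None:
            raise ValueError("permutation method needs conn and cohort")
        rng = np.random.default_rng(seed)
        n = len(cohort)
        frs = cohort["frs_points"].to_numpy(dtype=float)
        perms = np.stack([frs[rng.permutation(n)] for _ in range(n_permutations)])
        t_perm, _ = _fwl_tvalues(conn, cohort, covariates, perm_frs=perms)
        perm_stats = t_perm**2

    for pair, idx in sorted(groups.items()):
        m = len(idx)
        stat = float((t_obs[idx] ** 2).mean())
        if method == "parametric":
            p = _satterthwaite_p(stat, m, df)
        else:
            null = perm_stats[:, idx].mean(axis=1)
            p = float((1 + (null >= stat).sum()) / (1 + n_permutations))
        rows.append({"network_a": pair[0], "network_b": pair[1], "n_connections": m,
                     "stat": stat, "p": p})
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p"].to_numpy())

    pair_q = {(r.network_a, r.network_b): r.q for r in table.itertuples()}
    sig = [c for c, qc in zip(results["unit"], results["q"])
           if qc < alpha and pair_q[netpair[c]] < alpha]
    return {"table": table, "assignment": dict(assignment),
            "significant_connections": sig, "alpha": alpha, "method": method}
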