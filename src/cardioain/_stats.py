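"""Shared statistical primitives: vectorized OLS, FDR, summary-statistic tests.

Every regression in the package funnels through :func:`ols` so that the
numerical path (QR with classical standard errors) is identical across the
structural, functional, and subsampling analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class OLSFit:
    """Coefficients and classical inference for ``Y ~ X`` (possibly multi-response).

    Attributes
    ----------
    beta, se, t, p : ndarray, shape (p_params, n_responses)
    df : int
        Residual degrees of freedom ``n - rank``.
    """

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    resid: np.ndarray


def ols(X: np.ndarray, Y: np.ndarray) -> OLSFit:
    """Ordinary least squares with classical (homoskedastic) standard errors.

    Parameters
    ----------
    X : (n, p) design matrix, full column rank.
    Y : (n,) or (n, m) response(s). All responses share the design.

    Notes
    -----
    Solved by QR decomposition; singular designs raise ``LinAlgError`` so the
    caller can drop aliased columns explicitly rather than silently pinning
    coefficients.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    n, p = X.shape
    if n <= p:
        raise np.linalg.LinAlgError(f"{n} observations for {p} parameters")
    Q, R = np.linalg.qr(X)
    rdiag = np.abs(np.diag(R))
    if rdiag.min() < 1e-10 * max(rdiag.max(), 1.0):
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta = np.linalg.solve(R, Q.T @ Y)
    resid = Y - X @ beta
    df = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    Rinv = np.linalg.solve(R, np.eye(p))
    xtx_inv_diag = np.einsum("ij,ij->i", Rinv, Rinv)
    se = np.sqrt(np.outer(xtx_inv_diag, sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * sps.t.sf(np.abs(t), df)
    if squeeze:
        beta, se, t, pvals, resid = (a[..., 0] for a in (beta, se, t, pvals, resid))
    return OLSFit(beta=beta, se=se, t=t, p=pvals, df=df, resid=resid)


def drop_aliased_columns(X: np.ndarray, names: list[str], keep: int = 1):
    """Greedily drop trailing columns that are linear combinations of earlier ones.

    The first ``keep`` columns (intercept + terms of interest) are never dropped.
    Returns the reduced matrix, surviving names, and the dropped names.
    """
    X = np.asarray(X, dtype=float)
    cols = [X[:, i] for i in range(X.shape[1])]
    kept_idx: list[int] = []
    dropped: list[str] = []
    for i in range(X.shape[1]):
        cand = np.column_stack([cols[j] for j in kept_idx] + [cols[i]])
        if np.linalg.matrix_rank(cand, tol=1e-8 * max(1.0, np.abs(cand).max())) == cand.shape[1]:
            kept_idx.append(i)
        elif i < keep:
            raise np.linalg.LinAlgError(f"required column {names[i]!r} is aliased")
        else:
            dropped.append(names[i])
    return X[:, kept_idx], [names[i] for i in kept_idx], dropped


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j, clipped to [0, 1]. Delegates to
    statsmodels' implementation; the identity above is enforced by a
    brute-force oracle in the test suite.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def pooled_t_from_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Two-sample pooled-variance (Student) t from summary statistics.

    Returns ``(t, df, p)`` with a two-sided p-value. This is the test used for
    demographic comparisons between matched groups, and it reproduces a
    published table's statistics directly from its printed mean ± SD rows.
    """
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    if se == 0:
        if mean1 == mean2:
            return 0.0, df, 1.0
        return np.nan, df, np.nan
    t = (mean1 - mean2) / se
    return float(t), df, float(2.0 * sps.t.sf(abs(t), df))


def welch_t_from_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Welch (unequal-variance) two-sample t from summary statistics."""
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se = np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    t = (mean1 - mean2) / se
    return float(t), float(df), float(2.0 * sps.t.sf(abs(t), df))


def chi_square_2x2(counts: np.ndarray):
    """Pearson chi-square on a 2x2 count table, no continuity correction.

    Identical margins give chi-square exactly 0. Returns ``(chi2, p)``.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 count table")
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if np.any(expected == 0):
        raise ValueError("zero expected count; chi-square undefined")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return chi2, float(sps.chi2.sf(chi2, df=1))
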