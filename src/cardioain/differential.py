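"""Subsampling framework comparing risk-connectivity associations between diagnoses.

For every connection significant in either diagnosis, each diagnosis cohort
is repeatedly subsampled without replacement (stratified, default by sex and
scanner), an OLS of connectivity on the risk score (adjusting for age, sex,
scanner) is refitted per draw, and the risk coefficient's t-value is stored.
The two resulting empirical t distributions are compared by an independent
two-sample t-test, giving a per-connection direction and magnitude of the
differential association.

Caveat printed in all outputs: subsamples of one cohort overlap, so the
between-distribution t-test treats correlated draws as independent; the
statistic is a descriptive separation measure, anti-conservative as a
hypothesis test. The procedure is reproduced as specified rather than
"corrected".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._design import build_design
from ._stats import ols, pooled_t_from_summary

OVERLAP_CAVEAT = ("subsample draws overlap within a group; the between-group t "
                  "treats them as independent and is anti-conservative as a test")


@dataclass
class SubsamplingConfig:
    """Subsampling settings; the fraction is mandatory in reports because it
    controls the spread of the t distributions."""

    n_iterations: int = 1000
    subsample_fraction: float = 0.8
    stratify_by: tuple = ("sex", "scanner")
    covariates: tuple = ("age", "sex", "scanner")
    seed: int = 0

    def validate(self):
        if self.n_iterations < 2:
            raise ValueError("n_iterations must be >= 2")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must be in (0, 1]")


@dataclass
class SubsamplingDistribution:
    """Empirical t-value distribution for one (connection, diagnosis)."""

    connection: str
    group: str
    t_values: np.ndarray
    config: SubsamplingConfig

    @property
    def mean(self) -> float:
        return float(self.t_values.mean())

    @property
    def sd(self) -> float:
        return float(self.t_values.std(ddof=1))


def select_connections(results_a: pd.DataFrame, results_b: pd.DataFrame,
                       alpha: float = 0.05,
                       restrict_a=None, restrict_b=None) -> list[str]:
    """Union of connections with q < alpha in either diagnosis, in atlas order.

    ``restrict_a``/``restrict_b`` optionally gate each side to a precomputed
    significant set (e.g. the dual connection+cluster threshold survivors).
    """
    if list(results_a["unit"]) != list(results_b["unit"]):
        raise ValueError("result sets cover different connection universes")
    sig_a = set(results_a.loc[results_a["q"] < alpha, "unit"])
    sig_b = set(results_b.loc[results_b["q"] < alpha, "unit"])
    if restrict_a is not None:
        sig_a &= set(restrict_a)
    if restrict_b is not None:
        sig_b &= set(restrict_b)
    union = sig_a | sig_b
    return [c for c in results_a["unit"] if c in union]


def _stratum_labels(cohort: pd.DataFrame, stratify_by) -> np.ndarray:
    if not stratify_by:
        return np.zeros(len(cohort), dtype=int)
    key = cohort[list(stratify_by)].astype(str).agg("|".join, axis=1)
    strata, labels = {}, np.empty(len(cohort), dtype=int)
    for i, k in enumerate(key):
        labels[i] = strata.setdefault(k, len(strata))
    return labels


def _merge_small_strata(labels: np.ndarray, min_size: int = 2):
    """Merge singleton strata into the largest stratum, with a warning note."""
    merged = labels.copy()
    notes = []
    counts = np.bincount(merged)
    if (counts[counts > 0] < min_size).any():
        biggest = int(np.argmax(counts))
        for s in np.flatnonzero((counts > 0) & (counts < min_size)):
            notes.append(f"stratum {s} (n={counts[s]}) merged into stratum {biggest}")
            merged[merged == s] = biggest
    return merged, notes


def subsample_tvalues(conn: pd.DataFrame, cohort: pd.DataFrame, connection: str,
                      config: SubsamplingConfig) -> SubsamplingDistribution:
    """Empirical t distribution of the risk coefficient over stratified subsamples.

    Each iteration draws ``subsample_fraction`` of the participants within
    every stratum without replacement (round half up, at least one per
    non-empty stratum), sorts the draw into cohort order, and refits
    z ~ 1 + FRS + age + sex + scanner. Iteration i uses the seeded generator
    ``default_rng(config.seed + i)``, so runs are reproducible and, at
    fraction 1.0, every iteration reproduces the full-sample fit exactly.
    """
    config.validate()
    groups = set(cohort["group"])
    if len(groups) != 1:
        raise ValueError(f"cohort must hold a single diagnosis, found {sorted(groups)}")
    if connection not in conn.columns:
        raise ValueError(f"connection {connection!r} not present")
    y_all = conn.loc[cohort["id"], connection].to_numpy(dtype=float)
    labels, notes = _merge_small_strata(_stratum_labels(cohort, config.stratify_by))
    strata = [np.flatnonzero(labels == s) for s in np.unique(labels)]
    take = [max(1, math.floor(len(idx) * config.subsample_fraction + 0.5))
            for idx in strata]

    X_full, names, _ = build_design(cohort, config.covariates, frs=True)
    k = names.index("frs")
    tvals = np.empty(config.n_iterations)
    for i in range(config.n_iterations):
        rng = np.random.default_rng(config.seed + i)
        for attempt in range(10):
            pick = np.sort(np.concatenate([
                idx[rng.choice(len(idx), size=m, replace=False)]
                for idx, m in zip(strata, take)
            ]))
            try:
                fit = ols(X_full[pick], y_all[pick])
            except np.linalg.LinAlgError:
                continue
            tvals[i] = fit.t[k]
            break
        else:
            raise RuntimeError(f"iteration {i}: singular fit after 10 redraws")
    dist = SubsamplingDistribution(connection=connection, group=next(iter(groups)),
                                   t_values=tvals, config=config)
    dist.notes = notes
    return dist


@dataclass
class DifferentialResult:
    connection: str
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    p: float
    df: int
    direction: str = ""
    caveat: str = OVERLAP_CAVEAT


def compare_groups(dist_a: SubsamplingDistribution,
                   dist_b: SubsamplingDistribution) -> DifferentialResult:
    """Pooled-variance independent t-test between two t-value distributions.

    Negative t means group A's association is more negative (stronger
    negative risk effect) than group B's; the sign flips exactly when the
    inputs are swapped. df = 2 * n_iterations - 2.
    """
    if len(dist_a.t_values) != len(dist_b.t_values):
        raise ValueError("distributions must have equal n_iterations")
    n = len(dist_a.t_values)
    t, df, p = pooled_t_from_summary(dist_a.mean, dist_a.sd, n, dist_b.mean, dist_b.sd, n)
    if np.isnan(t):   # zero variance in both with differing means
        t, p = np.inf * np.sign(dist_a.mean - dist_b.mean), 0.0
    if t < 0:
        direction = f"{dist_a.group} stronger"
    elif t > 0:
        direction = f"{dist_b.group} stronger"
    else:
        direction = "equal"
    return DifferentialResult(connection=dist_a.connection, group_a=dist_a.group,
                              group_b=dist_b.group, mean_a=dist_a.mean, sd_a=dist_a.sd,
                              mean_b=dist_b.mean, sd_b=dist_b.sd, t=float(t), p=float(p),
                              df=int(df), direction=direction)


def run_differential(conn_a: pd.DataFrame, cohort_a: pd.DataFrame,
                     conn_b: pd.DataFrame, cohort_b: pd.DataFrame,
                     connections: list[str],
                     config: SubsamplingConfig) -> pd.DataFrame:
    """Per-connection subsampling comparison between two diagnosis cohorts.

    ``cohort_a``/``cohort_b`` are single-diagnosis (patients-only) samples.
    Output rows are sorted by t ascending (most negative — group A most
    strongly affected — first). Each connection's subsample sequence derives
    deterministically from the base seed and the connection's position.
    """
    rows = []
    for j, c in enumerate(connections):
        base = config.seed + 7919 * j
        cfg_a = SubsamplingConfig(config.n_iterations, config.subsample_fraction,
                                  config.stratify_by, config.covariates, base)
        cfg_b = SubsamplingConfig(config.n_iterations, config.subsample_fraction,
                                  config.stratify_by, config.covariates,
                                  base + 500009)
        da = subsample_tvalues(conn_a, cohort_a, c, cfg_a)
        db = subsample_tvalues(conn_b, cohort_b, c, cfg_b)
        res = compare_groups(da, db)
        rows.append({"connection": c,
                     "a_group": res.group_a, "a_mean": res.mean_a, "a_sd": res.sd_a,
                     "b_group": res.group_b, "b_mean": res.mean_b, "b_sd": res.sd_b,
                     "t": res.t, "p": res.p, "df": res.df, "direction": res.direction})
    cols = ["connection", "a_group", "a_mean", "a_sd", "b_group", "b_mean", "b_sd",
            "t", "p", "df", "direction"]
    table = pd.DataFrame(rows, columns=cols)
    if len(table):
        table = table.sort_values("t", kind="stable").reset_index(drop=True)
    table.attrs["subsample_fraction"] = config.subsample_fraction
    table.attrs["n_iterations"] = config.n_iterations
    table.attrs["caveat"] = OVERLAP_CAVEAT
    return table
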