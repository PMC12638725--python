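"""Inclusion filters, age/sex-matched case-control tandems, demographics table.

A "tandem" is one patient group (FTLD or AD) paired 1:1 with controls matched
exactly on sex and greedily on nearest age (hardest — oldest — patients
matched first), without replacement within the tandem. The demographic table
compares the matched groups with pooled-variance t-tests (continuous
variables) and a Pearson chi-square without continuity correction (sex), so
identical margins give chi-square exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import chi_square_2x2, pooled_t_from_summary, welch_t_from_summary

GROUPS = ("CN", "FTLD", "AD")


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    if cohort["id"].duplicated().any():
        dup = cohort.loc[cohort["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate participant ids: {dup}")
    bad = set(cohort["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    mmse = cohort["mmse"].dropna()
    if ((mmse < 0) | (mmse > 30)).any():
        raise ValueError("mmse outside [0, 30]")
    return cohort


def apply_inclusion_filters(cohort: pd.DataFrame, max_age: float = 85.0,
                            cn_mmse_min: float = 24.0):
    """Drop controls with MMSE <= cn_mmse_min and patients older than max_age.

    Controls must score strictly above the MMSE floor (a score equal to the
    floor is excluded). Returns ``(filtered_cohort, removal_log)`` where the
    log has one (id, reason) row per removal.
    """
    validate_cohort(cohort)
    removals = []
    keep = np.ones(len(cohort), dtype=bool)
    is_cn = (cohort["group"] == "CN").to_numpy()
    mmse_fail = is_cn & (cohort["mmse"].to_numpy(dtype=float) <= cn_mmse_min)
    age_fail = ~is_cn & (cohort["age"].to_numpy(dtype=float) > max_age)
    for idx in np.flatnonzero(mmse_fail):
        removals.append({"id": cohort["id"].iloc[idx], "reason": f"CN mmse <= {cn_mmse_min}"})
    for idx in np.flatnonzero(age_fail):
        removals.append({"id": cohort["id"].iloc[idx], "reason": f"patient age > {max_age}"})
    keep &= ~(mmse_fail | age_fail)
    log = pd.DataFrame(removals, columns=["id", "reason"])
    return cohort.loc[keep].reset_index(drop=True), log


@dataclass
class Tandem:
    """A matched patient-control sample analyzed as one cohort with a group term."""

    patient_group: str
    pairs: pd.DataFrame                      # columns: patient_id, control_id, age_diff
    matched: pd.DataFrame                    # pooled phenotype rows (patients + controls)
    balance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def _std_mean_diff(a: np.ndarray, b: np.ndarray) -> float:
    pooled_sd = np.sqrt(0.5 * (a.var(ddof=1) + b.var(ddof=1)))
    if pooled_sd == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled_sd)


def match_tandem(patients: pd.DataFrame, controls: pd.DataFrame, seed: int = 0) -> Tandem:
    """1:1 nearest-neighbor matching without replacement, exact on sex.

    Patients are matched in order of descending age (ties broken by a seeded
    uniform draw); each takes the unused same-sex control with the smallest
    absolute age difference. If a sex stratum runs out of controls, remaining
    patients of that sex are left unmatched with a warning.
    """
    if len(patients) == 0 or len(controls) == 0:
        raise ValueError("patients and controls must be non-empty")
    patient_group = patients["group"].iloc[0]
    rng = np.random.default_rng(seed)
    warnings: list[str] = []

    order = patients.assign(_tie=rng.random(len(patients)))
    order = order.sort_values(["age", "_tie"], ascending=[False, True])

    available: dict[str, dict] = {}
    for sex in ("M", "F"):
        sub = controls[controls["sex"] == sex]
        available[sex] = {"ids": sub["id"].to_numpy().copy(),
                          "ages": sub["age"].to_numpy(dtype=float).copy(),
                          "used": np.zeros(len(sub), dtype=bool)}
    pairs = []
    for _, pat in order.iterrows():
        pool = available[pat["sex"]]
        free = ~pool["used"]
        if not free.any():
            warnings.append(f"no unused {pat['sex']} control for patient {pat['id']}")
            continue
        dist = np.abs(pool["ages"] - float(pat["age"]))
        dist[~free] = np.inf
        best = np.flatnonzero(dist == dist.min())
        choice = best[rng.integers(len(best))] if len(best) > 1 else best[0]
        pool["used"][choice] = True
        pairs.append({"patient_id": pat["id"], "control_id": pool["ids"][choice],
                      "age_diff": float(pat["age"]) - pool["ages"][choice]})
    pairs_df = pd.DataFrame(pairs, columns=["patient_id", "control_id", "age_diff"])
    matched_patients = patients[patients["id"].isin(pairs_df["patient_id"])]
    matched_controls = controls[controls["id"].isin(pairs_df["control_id"])]
    matched = pd.concat([matched_patients, matched_controls], ignore_index=True)

    pa = matched_patients["age"].to_numpy(dtype=float)
    ca = matched_controls["age"].to_numpy(dtype=float)
    balance = {
        "n_matched": int(len(pairs_df)),
        "n_patients": int(len(patients)),
        "age_smd": _std_mean_diff(pa, ca) if len(pairs_df) > 1 else 0.0,
        "patient_male_fraction": float((matched_patients["sex"] == "M").mean()),
        "control_male_fraction": float((matched_controls["sex"] == "M").mean()),
        "mean_abs_age_diff": float(pairs_df["age_diff"].abs().mean()) if len(pairs_df) else 0.0,
    }
    return Tandem(patient_group=patient_group, pairs=pairs_df, matched=matched,
                  balance=balance, warnings=warnings)


_TABLE_VARS = [("age", "Age"), ("education", "Education"), ("mmse", "MMSE"),
               ("cdr_sob", "CDR-SoB"), ("frs_points", "FRS")]


def demographic_table(tandem: Tandem, welch: bool = False) -> pd.DataFrame:
    """Group mean +/- SD comparison table for a matched tandem.

    Continuous variables use a two-sided two-sample t-test (pooled-variance
    Student by default, Welch with ``welch=True``); sex uses Pearson
    chi-square on the 2x2 count table. CDR-SoB is summarized for patients
    only (controls are by construction unimpaired) and carries no test.
    """
    cn = tandem.matched[tandem.matched["group"] == "CN"]
    pat = tandem.matched[tandem.matched["group"] == tandem.patient_group]
    rows = []
    for col, name in _TABLE_VARS:
        if col not in tandem.matched.columns:
            continue
        a = cn[col].to_numpy(dtype=float)
        b = pat[col].to_numpy(dtype=float)
        if col == "cdr_sob":
            rows.append({"variable": name, "cn": "-",
                         "patient": f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
                         "statistic": np.nan, "p": np.nan})
            continue
        test = welch_t_from_summary if welch else pooled_t_from_summary
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() != b.mean():
            t, p = np.nan, np.nan   # zero variance in both groups: t undefined
        else:
            t, _, p = test(a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b))
        rows.append({"variable": name,
                     "cn": f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
                     "patient": f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
                     "statistic": t, "p": p})
    counts = np.array([[(cn["sex"] == "M").sum(), (cn["sex"] == "F").sum()],
                       [(pat["sex"] == "M").sum(), (pat["sex"] == "F").sum()]])
    chi2, p = chi_square_2x2(counts)
    rows.insert(1, {"variable": "Sex (M:F)",
                    "cn": f"{counts[0, 0]}:{counts[0, 1]}",
                    "patient": f"{counts[1, 0]}:{counts[1, 1]}",
                    "statistic": chi2, "p": p})
    return pd.DataFrame(rows)
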