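"""Non-laboratory (office-based) Framingham general cardiovascular risk score.

The score is a sex-stratified points model over age band, body-mass index
band, systolic blood pressure band (with separate bands under
anti-hypertensive treatment), current smoking, and diabetes; the point total
maps through a sex-specific lookup to a 10-year general-CVD risk fraction.
BMI substitutes for the laboratory lipid panel, which makes the score
computable from office measurements alone. Higher points mean higher risk.

The point and risk tables ship as TSV resources (``data/frs_points.tsv``,
``data/frs_risk.tsv``) transcribed from the published office-based model, so
the scoring is auditable and versioned with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .impute import ChainedImputer

RISK_FACTOR_FIELDS = ["age", "sex", "sbp", "bmi", "diabetes", "htn_treated", "smoker"]
IMPUTABLE_FIELDS = ["sbp", "bmi", "diabetes", "htn_treated", "smoker"]
BINARY_FIELDS = ["diabetes", "htn_treated", "smoker"]

_RANGES = {"age": (30.0, 110.0), "sbp": (70.0, 250.0), "bmi": (10.0, 70.0)}

_POINTS_CACHE: pd.DataFrame | None = None
_RISK_CACHE: pd.DataFrame | None = None


def load_point_table() -> pd.DataFrame:
    """The sex-specific point bands (sex, variable, lower, upper, points)."""
    global _POINTS_CACHE
    if _POINTS_CACHE is None:
        with resources.files("cardioain.data").joinpath("frs_points.tsv").open() as fh:
            _POINTS_CACHE = pd.read_csv(fh, sep="\t")
    return _POINTS_CACHE.copy()


def load_risk_table() -> pd.DataFrame:
    """The sex-specific points -> 10-year risk lookup."""
    global _RISK_CACHE
    if _RISK_CACHE is None:
        with resources.files("cardioain.data").joinpath("frs_risk.tsv").open() as fh:
            _RISK_CACHE = pd.read_csv(fh, sep="\t")
    return _RISK_CACHE.copy()


@dataclass(frozen=True)
class FRSResult:
    """Sex-specific point total and its mapped 10-year CVD risk."""

    frs_points: int
    ten_year_risk: float
    imputed_flags: dict = field(default_factory=dict)


def _band_points(table: pd.DataFrame, sex: str, variable: str, value: float) -> int:
    rows = table[(table["sex"] == sex) & (table["variable"] == variable)]
    for _, row in rows.iterrows():
        lower, upper = float(row["lower"]), float(row["upper"])
        if lower <= value < upper:
            return int(row["points"])
    raise ValueError(f"{variable}={value} outside the scored bands for sex={sex}")


def validate_record(record) -> dict:
    """Validate one participant's risk-factor record; missing allowed except age/sex."""
    rec = {k: record[k] for k in RISK_FACTOR_FIELDS}
    if pd.isna(rec["age"]) or pd.isna(rec["sex"]):
        raise ValueError("age and sex may not be missing")
    if rec["sex"] not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {rec['sex']!r}")
    for name, (lo, hi) in _RANGES.items():
        val = rec[name]
        if val is not None and not pd.isna(val) and not (lo <= float(val) <= hi):
            raise ValueError(f"{name}={val} outside physiological range [{lo}, {hi}]")
    return rec


def compute_frs(record) -> FRSResult:
    """Score one complete risk-factor record.

    Pure function: the same inputs always give the same ``FRSResult``. Raises
    ``ValueError`` naming the offending field on out-of-range or missing input.
    """
    rec = validate_record(record)
    for name in RISK_FACTOR_FIELDS:
        if rec[name] is None or pd.isna(rec[name]):
            raise ValueError(f"cannot score incomplete record: {name} is missing")
    table = load_point_table()
    sex = rec["sex"]
    pts = _band_points(table, sex, "age", float(rec["age"]))
    pts += _band_points(table, sex, "bmi", float(rec["bmi"]))
    sbp_var = "sbp_treated" if bool(rec["htn_treated"]) else "sbp_untreated"
    pts += _band_points(table, sex, sbp_var, float(rec["sbp"]))
    if bool(rec["smoker"]):
        pts += _band_points(table, sex, "smoker", 1.0)
    if bool(rec["diabetes"]):
        pts += _band_points(table, sex, "diabetes", 1.0)
    return FRSResult(frs_points=pts, ten_year_risk=ten_year_risk(sex, pts))


def ten_year_risk(sex: str, points: int) -> float:
    """Sex-specific 10-year risk for a point total (clamped to the table range)."""
    risk = load_risk_table()
    rows = risk[risk["sex"] == sex].sort_values("points")
    clamped = int(np.clip(points, rows["points"].min(), rows["points"].max()))
    return float(rows.loc[rows["points"] == clamped, "risk"].iloc[0])


def score_cohort(
    cohort: pd.DataFrame,
    seed: int,
    n_cycles: int = 10,
    n_imputations: int = 1,
) -> pd.DataFrame:
    """Add ``frs_points``, ``ten_year_risk`` and imputation flags to a phenotype table.

    Missing risk factors are completed by chained-equations imputation first
    (:class:`~cardioain.impute.ChainedImputer`). With ``n_imputations > 1``
    the score is averaged over independent completions (sensitivity mode);
    the default carries a single completed dataset downstream. Row order is
    preserved and observed cells are never altered.
    """
    out = cohort.copy()
    if len(out) == 0:
        out["frs_points"] = pd.Series(dtype=float)
        out["ten_year_risk"] = pd.Series(dtype=float)
        for f in IMPUTABLE_FIELDS:
            out[f"{f}_imputed"] = pd.Series(dtype=bool)
        return out
    risk_cols = out[RISK_FACTOR_FIELDS].copy()
    observed_mask = risk_cols.notna()
    for f in IMPUTABLE_FIELDS:
        out[f"{f}_imputed"] = ~observed_mask[f]

    points = np.zeros((n_imputations, len(out)))
    risks = np.zeros_like(points)
    completed_first = None
    for m in range(n_imputations):
        if observed_mask.all().all():
            completed = risk_cols
        else:
            imputer = ChainedImputer(
                continuous=["sbp", "bmi"],
                binary=BINARY_FIELDS,
                predictors=["age", "sex"],
                n_cycles=n_cycles,
                seed=seed + m,
            )
            completed = imputer.fit_transform(risk_cols)
        if completed_first is None:
            completed_first = completed
        for i, (_, rec) in enumerate(completed.iterrows()):
            try:
                res = compute_frs(rec)
            except ValueError as err:
                pid = out["id"].iloc[i] if "id" in out.columns else i
                raise ValueError(f"participant {pid}: {err}") from err
            points[m, i] = res.frs_points
            risks[m, i] = res.ten_year_risk

    out[IMPUTABLE_FIELDS] = completed_first[IMPUTABLE_FIELDS].to_numpy()
    out["frs_points"] = points.mean(axis=0)
    out["ten_year_risk"] = risks.mean(axis=0)
    if n_imputations == 1:
        out["frs_points"] = out["frs_points"].astype(int)
    return out
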