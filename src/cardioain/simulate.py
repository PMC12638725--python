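"""Synthetic multi-group, multi-scanner cohorts with planted risk effects.

The generator emulates the statistical structure the downstream analyses
assume: two dementia groups (FTLD, AD) plus healthy controls (CN) recruited
across several scanners, office-measured cardiovascular risk factors with a
small evenly-distributed missing fraction, regional grey-matter volumes that
depend linearly on age, sex, head size (TIV), scanner, and — with planted
group-specific slopes — on the composite risk score, and ROI time-series
whose pairwise Fisher-z connectivity likewise carries planted linear risk
effects. Ground truth (true scores, planted slopes, per-subject target z) is
returned alongside, so every analysis stage can be tested for recovery.

Signals are stationary Gaussian; no hemodynamics or voxel-level imaging is
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .atlas import connection_pairs, load_atlas
from .framingham import compute_frs


class NotPositiveDefiniteError(ValueError):
    """Raised when a supplied base correlation matrix is not positive definite."""


def nearest_correlation(matrix: np.ndarray, tol: float = 1e-8, max_iter: int = 100) -> np.ndarray:
    """Project a symmetric matrix to the nearest correlation matrix.

    Higham-style alternating projections (PSD cone <-> unit diagonal) with a
    Dykstra correction, followed by an eigenvalue floor and diagonal rescale
    so the result is strictly positive definite with an exact unit diagonal.
    """
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("input must be symmetric")
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 1.0)

    Y = A.copy()
    dS = np.zeros_like(A)
    for _ in range(max_iter):
        R = Y - dS
        w, V = np.linalg.eigh(R)
        X = (V * np.clip(w, 0.0, None)) @ V.T
        dS = X - R
        Y_prev = Y
        Y = X.copy()
        np.fill_diagonal(Y, 1.0)
        if np.linalg.norm(Y - Y_prev, "fro") <= tol * max(1.0, np.linalg.norm(Y, "fro")):
            break
    # enforce strict positive definiteness and exact unit diagonal
    w, V = np.linalg.eigh(0.5 * (Y + Y.T))
    if w.min() < 1e-10:
        w = np.clip(w, 1e-10, None)
        Y = (V * w) @ V.T
        d = 1.0 / np.sqrt(np.diag(Y))
        Y = Y * np.outer(d, d)
    Y = 0.5 * (Y + Y.T)
    np.fill_diagonal(Y, 1.0)
    return Y


def default_base_correlation(atlas: pd.DataFrame) -> np.ndarray:
    """Structured resting-state-like base correlation over the atlas.

    Homotopic (same-family, opposite-hemisphere) pairs correlate at 0.5,
    regions in the same anatomical system at 0.3, everything else at 0.1;
    projected to the nearest correlation matrix for safety.
    """
    systems = {
        "insula": "salience", "ACC": "cingulate", "MCC": "cingulate", "PCC": "cingulate",
        "OFCmed": "orbitofrontal", "OFCsup": "orbitofrontal", "OFCmid": "orbitofrontal",
        "OFCinf": "orbitofrontal", "amygdala": "mtl", "hippocampus": "mtl",
        "parahippocampal": "mtl", "thalamus": "thalamus",
    }
    fam = atlas["family"].to_numpy()
    n = len(atlas)
    C = np.full((n, n), 0.1)
    for i in range(n):
        for j in range(n):
            if systems.get(fam[i]) == systems.get(fam[j]):
                C[i, j] = 0.3
            if fam[i] == fam[j]:
                C[i, j] = 0.5
    np.fill_diagonal(C, 1.0)
    return nearest_correlation(C)


# planted effects mirroring the pattern of group-specific vulnerability:
# fronto-insular/thalamic volumes and OFC-medial-temporal & midline
# connections in FTLD; medial-temporal volumes and a smaller OFC-MTL
# connection set in AD
_FTLD_VOLUME_ROIS = ["Insula_L", "Insula_R", "Cingulum_Ant_L", "Cingulum_Ant_R",
                     "Thalamus_L", "Thalamus_R"]
_AD_VOLUME_ROIS = ["Hippocampus_L", "Hippocampus_R", "Amygdala_L", "Amygdala_R",
                   "ParaHippocampal_L", "ParaHippocampal_R"]
_FTLD_CONNECTIONS = [
    ("Frontal_Med_Orb_R", "Hippocampus_L"), ("Frontal_Med_Orb_L", "Hippocampus_L"),
    ("Cingulum_Mid_L", "Cingulum_Post_L"), ("Thalamus_L", "Thalamus_R"),
    ("Frontal_Med_Orb_R", "ParaHippocampal_L"), ("Frontal_Sup_Orb_R", "ParaHippocampal_L"),
    ("Cingulum_Mid_L", "Cingulum_Post_R"), ("Frontal_Med_Orb_L", "ParaHippocampal_L"),
    ("Insula_L", "Insula_R"), ("Frontal_Med_Orb_L", "Hippocampus_R"),
]
_AD_CONNECTIONS = [
    ("Frontal_Med_Orb_R", "Hippocampus_R"), ("Frontal_Sup_Orb_R", "ParaHippocampal_R"),
    ("Frontal_Inf_Orb_R", "ParaHippocampal_L"), ("Frontal_Mid_Orb_R", "ParaHippocampal_L"),
    ("Frontal_Med_Orb_R", "ParaHippocampal_R"),
]


def default_volume_slopes() -> dict:
    slopes = {("FTLD", r): -1.5 for r in _FTLD_VOLUME_ROIS}
    slopes.update({("AD", r): -1.5 for r in _AD_VOLUME_ROIS})
    return slopes


def default_connectivity_slopes() -> dict:
    slopes = {("FTLD", c): -0.010 for c in _FTLD_CONNECTIONS}
    slopes.update({("AD", c): -0.008 for c in _AD_CONNECTIONS})
    return slopes


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the target cohort design: group sizes 685/304/512
    (CN/FTLD/AD), five scanners, controls a few years younger than patients
    (the demographic difference matching must remove), <10% evenly
    distributed missingness in the risk factors, a risk-score distribution
    centred near 13.7 +/- 3.9 points, and planted negative risk slopes on
    group-specific volumes and connections.
    """

    seed: int = 0
    n_per_group: dict = field(default_factory=lambda: {"CN": 685, "FTLD": 304, "AD": 512})
    scanner_count: int = 5
    age_mean: dict = field(default_factory=lambda: {"CN": 62.0, "FTLD": 65.4, "AD": 69.0})
    age_sd: dict = field(default_factory=lambda: {"CN": 9.0, "FTLD": 7.9, "AD": 8.0})
    sex_balance: dict = field(default_factory=lambda: {"CN": 0.47, "FTLD": 0.55, "AD": 0.45})
    missing_rate: float = 0.08
    volume_slopes: dict = field(default_factory=default_volume_slopes)
    connectivity_slopes: dict = field(default_factory=default_connectivity_slopes)
    scanner_effect_sd: float = 0.02          # additive on Fisher-z values
    scanner_effect_sd_volume: float = 3.0    # additive on ROI volumes (volume units)
    noise_sd_volume: float = 8.0
    noise_sd_z: float = 0.08                 # subject-level connectivity noise
    timepoints: int = 200
    base_correlation: np.ndarray | None = None

    def validate(self, atlas: pd.DataFrame) -> np.ndarray:
        if any(n < 2 for n in self.n_per_group.values()):
            raise ValueError("each group needs at least 2 participants")
        if not 0.0 <= self.missing_rate <= 0.10:
            raise ValueError("missing_rate must be in [0, 0.10]")
        if self.scanner_count < 1:
            raise ValueError("scanner_count must be >= 1")
        if self.timepoints < 50:
            raise ValueError("timepoints must be >= 50")
        if self.base_correlation is None:
            C = default_base_correlation(atlas)
        else:
            C = np.asarray(self.base_correlation, dtype=float)
            if C.shape != (len(atlas), len(atlas)):
                raise ValueError("base_correlation shape must match the atlas")
            if not np.allclose(C, C.T, atol=1e-10):
                raise NotPositiveDefiniteError("base_correlation must be symmetric")
            if np.linalg.eigvalsh(C).min() <= 0:
                raise NotPositiveDefiniteError("base_correlation must be positive definite")
        return C


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests.

    ``linear_z`` holds each subject's noise-free connection z values
    (base + slope * FRS + scanner); ``target_z`` the realized subject-level z
    after connectivity noise and projection to a valid correlation matrix —
    the value the time-series connectivity estimator converges to.
    """

    frs_true: pd.Series
    volume_slopes: dict
    connectivity_slopes: dict
    linear_z: pd.DataFrame
    target_z: pd.DataFrame
    scanner_offsets_z: dict
    scanner_offsets_volume: dict


def _truncated_normal(rng, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: SimulationConfig, atlas: pd.DataFrame | None = None,
                    include_timeseries: bool = True):
    """Generate (phenotype table, ROI volume table, time-series dict, ground truth).

    Deterministic for a fixed config/seed. With ``include_timeseries=False``
    the expensive per-subject signal sampling is skipped and the time-series
    dict is empty; ``GroundTruth.target_z`` still carries the subject-level
    connectivity, which downstream analyses accept directly.
    """
    if atlas is None:
        atlas = load_atlas()
    base_corr = config.validate(atlas)
    rng = np.random.default_rng(config.seed)
    labels = atlas["label"].tolist()
    pairs = connection_pairs(atlas)
    pair_cols = [f"{a}__{b}" for a, b in pairs]
    iu = np.triu_indices(len(labels), k=1)

    scanners = [f"scanner{k:02d}" for k in range(config.scanner_count)]
    off_z = {s: rng.normal(0.0, config.scanner_effect_sd) for s in scanners}
    off_vol = {s: rng.normal(0.0, config.scanner_effect_sd_volume) for s in scanners}

    rows = []
    for group, n in config.n_per_group.items():
        age = np.round(np.clip(rng.normal(config.age_mean[group], config.age_sd[group], n),
                               35.0, 95.0), 1)
        sex = np.where(rng.random(n) < config.sex_balance[group], "M", "F")
        scanner = rng.choice(scanners, size=n)
        tiv = np.clip(rng.normal(1450.0, 110.0, n) + np.where(sex == "M", 100.0, 0.0),
                      1000.0, 2100.0)
        bmi = np.round(np.clip(rng.normal(27.0, 4.5, n), 16.0, 55.0), 1)
        sbp = np.round(np.clip(85.0 + 0.9 * bmi + 0.35 * age + rng.normal(0, 12.0, n),
                               90.0, 230.0), 0)
        htn = rng.random(n) < 0.6 / (1.0 + np.exp(-(sbp - 140.0) / 12.0))
        diabetes = rng.random(n) < (0.12 + 0.10 * (bmi > 30.0))
        smoker = rng.random(n) < 0.22
        education = np.round(np.clip(rng.normal(14.0, 5.0, n), 0.0, 26.0), 0)
        if group == "CN":
            mmse = np.round(_truncated_normal(rng, 28.1, 2.0, 25.0, 30.49, n), 0)
            cdr = np.zeros(n)
        else:
            mmse = np.round(_truncated_normal(rng, 21.5, 6.4, 0.0, 30.49, n), 0)
            cdr = np.round(np.clip(rng.normal(8.6, 4.0, n), 0.5, 18.0), 1)
        for i in range(n):
            rows.append(dict(group=group, age=age[i], sex=sex[i], education=education[i],
                             mmse=mmse[i], cdr_sob=cdr[i], scanner=scanner[i], tiv=tiv[i],
                             sbp=sbp[i], bmi=bmi[i], diabetes=bool(diabetes[i]),
                             htn_treated=bool(htn[i]), smoker=bool(smoker[i])))
    cohort = pd.DataFrame(rows)
    cohort.insert(0, "id", [f"sub-{i:04d}" for i in range(len(cohort))])

    frs_true = np.array([
        compute_frs(rec).frs_points
        for rec in cohort[["age", "sex", "sbp", "bmi", "diabetes", "htn_treated", "smoker"]]
        .to_dict("records")
    ], dtype=float)

    # regional volumes: mu_r + age + sex + planted FRS slope + TIV + scanner + noise
    n_roi = len(labels)
    mu = 80.0 + 4.0 * np.arange(n_roi)
    slope_mat = np.zeros((len(cohort), n_roi))
    for (group, roi), b in config.volume_slopes.items():
        if roi not in labels:
            raise ValueError(f"volume slope for unknown ROI {roi!r}")
        slope_mat[(cohort["group"] == group).to_numpy(), labels.index(roi)] = b
    male = (cohort["sex"] == "M").to_numpy(dtype=float)
    vol = (mu[None, :]
           - 0.35 * cohort["age"].to_numpy()[:, None]
           + 4.0 * male[:, None]
           + slope_mat * frs_true[:, None]
           + 0.03 * cohort["tiv"].to_numpy()[:, None]
           + np.array([off_vol[s] for s in cohort["scanner"]])[:, None]
           + rng.normal(0.0, config.noise_sd_volume, (len(cohort), n_roi)))
    volumes = pd.DataFrame(vol, columns=labels)
    volumes.insert(0, "id", cohort["id"].to_numpy())

    # subject-level connectivity: z = base + slope*FRS + scanner + noise, projected
    base_z = np.arctanh(np.clip(base_corr[iu], -1 + 1e-7, 1 - 1e-7))
    slope_z = np.zeros((len(cohort), len(pairs)))
    pair_index = {p: k for k, p in enumerate(pairs)}
    for (group, conn), b in config.connectivity_slopes.items():
        key = tuple(conn)
        if key not in pair_index:
            key = (key[1], key[0])
        if key not in pair_index:
            raise ValueError(f"connectivity slope for unknown connection {conn!r}")
        slope_z[(cohort["group"] == group).to_numpy(), pair_index[key]] = b
    scan_z = np.array([off_z[s] for s in cohort["scanner"]])
    linear_z = base_z[None, :] + slope_z * frs_true[:, None] + scan_z[:, None]
    target_z = linear_z + rng.normal(0.0, config.noise_sd_z, linear_z.shape)

    timeseries: dict[str, pd.DataFrame] = {}
    adjusted = np.empty_like(target_z)
    for i, pid in enumerate(cohort["id"]):
        C = np.eye(n_roi)
        C[iu] = np.tanh(target_z[i])
        C = C + np.triu(C, 1).T
        if np.linalg.eigvalsh(C).min() < 1e-8:
            C = nearest_correlation(C)
        adjusted[i] = np.arctanh(np.clip(C[iu], -1 + 1e-7, 1 - 1e-7))
        if include_timeseries:
            L = np.linalg.cholesky(C)
            sig = rng.standard_normal((config.timepoints, n_roi)) @ L.T
            timeseries[pid] = pd.DataFrame(sig, columns=labels)
    target_z = adjusted

    truth = GroundTruth(
        frs_true=pd.Series(frs_true, index=cohort["id"], name="frs_true"),
        volume_slopes=dict(config.volume_slopes),
        connectivity_slopes=dict(config.connectivity_slopes),
        linear_z=pd.DataFrame(linear_z, index=cohort["id"], columns=pair_cols),
        target_z=pd.DataFrame(target_z, index=cohort["id"], columns=pair_cols),
        scanner_offsets_z=off_z,
        scanner_offsets_volume=off_vol,
    )

    # evenly-distributed missingness in the imputable risk factors
    if config.missing_rate > 0:
        for col in ["sbp", "bmi", "diabetes", "htn_treated", "smoker"]:
            mask = rng.random(len(cohort)) < config.missing_rate
            cohort[col] = cohort[col].astype(object)
            cohort.loc[mask, col] = np.nan

    return cohort, volumes, timeseries, truth
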