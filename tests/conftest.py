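import numpy as np
import pandas as pd
import pytest

from cardioain import SimulationConfig, generate_cohort, load_atlas


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


@pytest.fixture(scope="session")
def small_sim(atlas):
    """Small cohort with time-series, shared across tests (read-only)."""
    cfg = SimulationConfig(seed=7, n_per_group={"CN": 120, "FTLD": 80, "AD": 80},
                           timepoints=80)
    return cfg, generate_cohort(cfg, atlas)


@pytest.fixture(scope="session")
def medium_sim(atlas):
    """Medium cohort without time-series, for recovery/regression tests."""
    cfg = SimulationConfig(seed=11, n_per_group={"CN": 300, "FTLD": 300, "AD": 300})
    cohort, vols, _, truth = generate_cohort(cfg, atlas, include_timeseries=False)
    scored = cohort.copy()
    scored["frs_points"] = truth.frs_true.to_numpy()
    return cfg, scored, vols, truth


def make_single_group_sample(rng, n, group="FTLD", n_scanners=4,
                             frs_mean=13.7, frs_sd=3.9):
    """Lean single-diagnosis phenotype frame for focused connectivity sims."""
    return pd.DataFrame({
        "id": [f"{group.lower()}-{i:04d}" for i in range(n)],
        "group": group,
        "age": np.round(rng.normal(66.0, 8.0, n), 1),
        "sex": np.where(rng.random(n) < 0.5, "M", "F"),
        "scanner": rng.integers(n_scanners, size=n).astype(str),
        "frs_points": np.round(rng.normal(frs_mean, frs_sd, n)),
    })


def make_connectivity(rng, cohort, slopes: dict, noise_sd=0.08, n_connections=6,
                      base_z=0.3):
    """Subject x connection Fisher-z table with planted linear FRS slopes."""
    frs = cohort["frs_points"].to_numpy(dtype=float)
    cols = [f"roiA{i}__roiB{i}" for i in range(n_connections)]
    slope_vec = np.array([slopes.get(c, 0.0) for c in cols])
    Z = base_z + np.outer(frs, slope_vec) + rng.normal(0, noise_sd, (len(cohort), len(cols)))
    return pd.DataFrame(Z, index=cohort["id"], columns=cols)
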