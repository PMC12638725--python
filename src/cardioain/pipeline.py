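"""End-to-end orchestration: simulate/load -> score -> filter -> match ->
structural -> functional -> differential comparison, with a run manifest.

Every stage writes its artifacts under the output directory; re-running with
the same configuration and seeds reproduces all numeric outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .atlas import load_atlas
from .cohort import apply_inclusion_filters, demographic_table, match_tandem
from .differential import SubsamplingConfig, run_differential, select_connections
from .framingham import score_cohort
from .functional import (cluster_inference, cluster_rois, connection_glm,
                         connectivity_table, estimate_connectivity, pair_label)
from .simulate import SimulationConfig, generate_cohort
from .structural import (compute_wscores, interaction_contrast,
                         roi_frs_correlation, roi_frs_regression, tiv_correct)


@dataclass
class PipelineConfig:
    """All stage-level options of a full run; YAML round-trippable."""

    out_dir: str = "cardioain_out"
    seed: int = 0
    # inputs: either simulate=True or paths to phenotype/volumes/time-series
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    phenotype_path: str | None = None
    volumes_path: str | None = None
    timeseries_dir: str | None = None
    atlas_path: str | None = None
    # stage options
    impute_cycles: int = 10
    max_age: float = 85.0
    cn_mmse_min: float = 24.0
    tiv_method: str = "residual"
    wscore_fit: str = "cn_only"          # or "pooled" (adds diagnosis covariate)
    wscore_global_covariate: bool = False
    band: tuple | None = None
    fdr_alpha: float = 0.05
    cluster_method: str = "parametric"   # or "permutation"
    cluster_k: int | None = None
    n_permutations: int = 5000
    selection: str = "dual"              # or "connection" (connection-level q only)
    n_iterations: int = 1000
    subsample_fraction: float = 0.8
    use_planted_connectivity: bool = False   # simulate-mode shortcut: skip time-series

    @classmethod
    def from_yaml(cls, path):
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self):
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if not self.simulate:
            for name in ("phenotype_path", "volumes_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{name} must point to an existing file")
            if self.timeseries_dir is None or not Path(self.timeseries_dir).exists():
                raise ValueError("timeseries_dir must point to an existing directory")


def _analyze_tandem(tag, tandem, volumes, conn, atlas, cfg, outdir, manifest):
    alpha = cfg.fdr_alpha
    t1 = demographic_table(tandem)
    io.write_table(t1, outdir / f"tandem_{tag}" / "table1.tsv", seed=cfg.seed)
    tandem.pairs.to_csv(outdir / f"tandem_{tag}" / "pairs.csv", index=False)
    io.save_phenotype(tandem.matched, outdir / f"tandem_{tag}" / "matched.csv")
    io.write_json(tandem.balance, outdir / f"tandem_{tag}" / "balance.json")

    sub = tandem.matched
    vol_sub = volumes[volumes["id"].isin(set(sub["id"]))].reset_index(drop=True)
    vol_sub = vol_sub.set_index("id").loc[sub["id"]].reset_index()
    corrected = tiv_correct(vol_sub, sub["tiv"].to_numpy(dtype=float),
                            method=cfg.tiv_method)
    sdir = outdir / f"structural_{tag}"
    corr = roi_frs_correlation(corrected, sub)
    io.write_table(corr, sdir / "roi_correlations.tsv", seed=cfg.seed)
    reg = roi_frs_regression(vol_sub, sub)
    io.write_table(reg, sdir / "roi_regressions.tsv", seed=cfg.seed)

    fdir = outdir / f"functional_{tag}"
    conn_sub = conn.loc[sub["id"]]
    glm = connection_glm(conn_sub, sub)
    io.write_table(glm, fdir / "connection_glm.tsv", seed=cfg.seed)
    labels = atlas["label"].tolist()
    mean_mat = pd.DataFrame(np.zeros((len(labels), len(labels))),
                            index=labels, columns=labels)
    iu = np.triu_indices(len(labels), k=1)
    mean_vals = conn_sub.mean(axis=0).to_numpy()
    m = mean_mat.to_numpy()
    m[iu] = mean_vals
    mean_mat.iloc[:, :] = m + m.T
    networks = cluster_rois(mean_mat, atlas, k=cfg.cluster_k)
    ci = cluster_inference(glm, networks, alpha=alpha, method=cfg.cluster_method,
                           conn=conn_sub, cohort=sub,
                           n_permutations=cfg.n_permutations, seed=cfg.seed)
    io.write_table(ci["table"], fdir / "cluster_inference.tsv", seed=cfg.seed)
    io.write_json({"assignment": networks,
                   "significant_connections": ci["significant_connections"]},
                  fdir / "networks.json")
    manifest["stages"][f"tandem_{tag}"] = {"n_matched": int(tandem.balance["n_matched"]),
                                           "warnings": tandem.warnings}
    return glm, ci


def run_pipeline(config: PipelineConfig):
    """Execute the full analysis; returns the run manifest dict."""
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    atlas = load_atlas(config.atlas_path)
    manifest = {"config": dataclasses.asdict(config), "seed": config.seed,
                "stages": {}, "warnings": []}
    stage = "simulate/load"
    try:
        if config.simulate:
            sim = SimulationConfig(seed=config.seed, **config.sim_overrides)
            cohort, volumes, ts, truth = generate_cohort(
                sim, atlas, include_timeseries=not config.use_planted_connectivity)
            if config.use_planted_connectivity:
                conn_all = truth.target_z
            else:
                conn_all = connectivity_table(
                    {pid: estimate_connectivity(df, band=config.band)
                     for pid, df in ts.items()}, atlas)
        else:
            cohort = io.load_phenotype(config.phenotype_path)
            volumes = io.load_volumes(config.volumes_path)
            ts = io.load_timeseries(config.timeseries_dir, ids=cohort["id"])
            conn_all = connectivity_table(
                {pid: estimate_connectivity(df, band=config.band)
                 for pid, df in ts.items()}, atlas)
        io.save_connectivity(conn_all, outdir / "connectivity.csv")

        stage = "score"
        scored = score_cohort(cohort, seed=config.seed, n_cycles=config.impute_cycles)
        io.save_phenotype(scored, outdir / "phenotype_scored.csv")

        stage = "filter"
        filtered, removal_log = apply_inclusion_filters(
            scored, max_age=config.max_age, cn_mmse_min=config.cn_mmse_min)
        removal_log.to_csv(outdir / "removal_log.csv", index=False)
        manifest["stages"]["filter"] = {"n_removed": int(len(removal_log))}

        stage = "match"
        controls = filtered[filtered["group"] == "CN"]
        results = {}
        tandems = {}
        for tag in ("FTLD", "AD"):
            patients = filtered[filtered["group"] == tag]
            if len(patients) == 0:
                continue
            tandems[tag] = match_tandem(patients, controls, seed=config.seed)
        stage = "analysis"
        for tag, tandem in tandems.items():
            glm, ci = _analyze_tandem(tag, tandem, volumes, conn_all, atlas,
                                      config, outdir, manifest)
            # w-scores + interaction need the pooled tandem w-relative frame
            sub = tandem.matched
            vols = volumes[volumes["id"].isin(set(sub["id"]))]
            covs = ["age", "sex", "tiv", "scanner"]
            if config.wscore_fit == "pooled":
                covs.append("diagnosis")
                ref = sub["id"]
            else:
                ref = sub.loc[sub["group"] == "CN", "id"]
            w = compute_wscores(vols, sub, reference_ids=ref, covariates=covs,
                                global_covariate=config.wscore_global_covariate)
            w.to_csv(outdir / f"structural_{tag}" / "wscores.csv", index=False)
            results[tag] = {"glm": glm, "ci": ci, "tandem": tandem, "wscores": w}

        if set(results) == {"FTLD", "AD"}:
            stage = "interaction"
            pooled_ids = pd.concat([results["FTLD"]["tandem"].matched,
                                    results["AD"]["tandem"].matched])
            patients = pooled_ids[pooled_ids["group"].isin(["FTLD", "AD"])]
            patients = patients.drop_duplicates("id").reset_index(drop=True)
            vols = volumes[volumes["id"].isin(set(patients["id"]))]
            w_pool = compute_wscores(vols, patients, reference_ids=patients["id"],
                                     covariates=["age", "sex", "tiv", "scanner"])
            inter = interaction_contrast(w_pool, patients)
            io.write_table(inter, outdir / "structural_interaction.tsv", seed=config.seed)

            stage = "differential"
            restrict = {}
            for tag in ("FTLD", "AD"):
                restrict[tag] = (results[tag]["ci"]["significant_connections"]
                                 if config.selection == "dual" else None)
            selected = select_connections(results["FTLD"]["glm"], results["AD"]["glm"],
                                          alpha=config.fdr_alpha,
                                          restrict_a=restrict["FTLD"],
                                          restrict_b=restrict["AD"])
            sub_cfg = SubsamplingConfig(n_iterations=config.n_iterations,
                                        subsample_fraction=config.subsample_fraction,
                                        seed=config.seed)
            pa = results["FTLD"]["tandem"].matched
            pa = pa[pa["group"] == "FTLD"].reset_index(drop=True)
            pb = results["AD"]["tandem"].matched
            pb = pb[pb["group"] == "AD"].reset_index(drop=True)
            table2 = run_differential(conn_all, pa, conn_all, pb, selected, sub_cfg)
            io.write_table(table2, outdir / "table2.tsv", seed=config.seed)
            manifest["stages"]["differential"] = {"n_selected": len(selected)}
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        io.write_json(manifest, outdir / "manifest.json")
        raise
    manifest["checksums"] = {
        str(p.relative_to(outdir)): io.file_checksum(p)
        for p in sorted(outdir.rglob("*")) if p.is_file() and p.name != "manifest.json"
    }
    io.write_json(manifest, outdir / "manifest.json")
    return manifest
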