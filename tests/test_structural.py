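"""Structural stage: TIV correction, correlations, adjusted GLMs, w-scores."""

import numpy as np
import pandas as pd
import pytest

from cardioain import (bh_fdr, compute_wscores, interaction_contrast,
                       roi_frs_correlation, roi_frs_regression, tiv_correct)
from cardioain._stats import ols
from cardioain.structural import WScoreTransformer


def make_sample(n=120, seed=0, n_scanners=3):
    rng = np.random.default_rng(seed)
    cohort = pd.DataFrame({
        "id": [f"s{i}" for i in range(n)],
        "group": np.where(rng.random(n) < 0.5, "FTLD", "CN"),
        "age": rng.normal(65, 8, n).round(1),
        "sex": np.where(rng.random(n) < 0.5, "M", "F"),
        "scanner": rng.integers(n_scanners, size=n).astype(str),
        "tiv": rng.normal(1450, 100, n),
        "frs_points": np.round(rng.normal(13.7, 3.9, n)),
    })
    return rng, cohort


class TestTIVCorrect:
    def test_constant_tiv_proportional_mode_is_identity(self):
        _, cohort = make_sample(30)
        vols = pd.DataFrame({"id": cohort["id"], "roi1": np.arange(30) + 50.0})
        tiv = np.full(30, 1500.0)
        with pytest.raises(ValueError, match="constant TIV"):
            tiv_correct(vols, tiv, method="residual")
        out = tiv_correct(vols, tiv, method="proportional")
        assert np.allclose(out["roi1"], vols["roi1"])
        auto = tiv_correct(vols, tiv, method="auto")
        assert np.allclose(auto["roi1"], vols["roi1"])

    def test_perfect_collinearity_residualizes_to_constant(self):
        _, cohort = make_sample(40)
        tiv = cohort["tiv"].to_numpy()
        vols = pd.DataFrame({"id": cohort["id"], "roi1": 0.01 * tiv})
        out = tiv_correct(vols, tiv)
        assert np.ptp(out["roi1"].to_numpy()) < 1e-10

    def test_planted_tiv_slope_removed(self):
        rng, cohort = make_sample(200, seed=1)
        tiv = cohort["tiv"].to_numpy()
        vols = pd.DataFrame({"id": cohort["id"],
                             "roi1": 30.0 + 0.02 * tiv + rng.normal(0, 2, 200)})
        out = tiv_correct(vols, tiv)
        assert abs(np.corrcoef(out["roi1"], tiv)[0, 1]) < 1e-8


class TestCorrelation:
    def test_exact_linear_negative_gives_minus_one(self):
        _, cohort = make_sample(50)
        vols = pd.DataFrame({"id": cohort["id"],
                             "roi1": 100.0 - 2.0 * cohort["frs_points"]})
        res = roi_frs_correlation(vols, cohort)
        assert res["r"].iloc[0] == pytest.approx(-1.0, abs=1e-12)
        assert res["p"].iloc[0] == 0.0

    def test_constant_frs_rejected(self):
        _, cohort = make_sample(50)
        cohort["frs_points"] = 13.0
        vols = pd.DataFrame({"id": cohort["id"], "roi1": np.arange(50.0)})
        with pytest.raises(ValueError, match="variance"):
            roi_frs_correlation(vols, cohort)

    def test_planted_negative_slope_gives_negative_r(self):
        """Monte-Carlo: slope -2 vs noise sd 8 yields r<0 in >=95% of reps."""
        neg = 0
        for rep in range(200):
            rng = np.random.default_rng(1000 + rep)
            frs = np.round(rng.normal(13.7, 3.9, 120))
            cohort = pd.DataFrame({"id": [f"s{i}" for i in range(120)],
                                   "frs_points": frs})
            vols = pd.DataFrame({"id": cohort["id"],
                                 "roi1": 100 - 2.0 * frs + rng.normal(0, 8, 120)})
            neg += roi_frs_correlation(vols, cohort)["r"].iloc[0] < 0
        assert neg / 200 >= 0.95


class TestRegression:
    def test_matches_normal_equations_oracle(self):
        for rep in range(50):
            rng, cohort = make_sample(n=60, seed=rep)
            vols = pd.DataFrame({"id": cohort["id"],
                                 "roiA": rng.normal(100, 10, 60),
                                 "roiB": rng.normal(80, 10, 60)})
            res = roi_frs_regression(vols, cohort)
            # oracle: explicit (X'X)^-1 X'y with classical SEs
            X = np.column_stack([
                np.ones(60), cohort["frs_points"],
                (cohort["group"] == "FTLD").astype(float),
                (cohort["scanner"] == "1").astype(float),
                (cohort["scanner"] == "2").astype(float),
                cohort["tiv"]])
            for roi in ("roiA", "roiB"):
                y = vols[roi].to_numpy()
                xtx_inv = np.linalg.inv(X.T @ X)
                beta = xtx_inv @ X.T @ y
                sig2 = np.sum((y - X @ beta) ** 2) / (60 - X.shape[1])
                t_frs = beta[1] / np.sqrt(xtx_inv[1, 1] * sig2)
                assert res.loc[res["unit"] == roi, "t"].iloc[0] == pytest.approx(
                    t_frs, abs=1e-8)

    def test_single_scanner_equals_model_without_scanner(self):
        rng, cohort = make_sample(80, seed=3, n_scanners=1)
        vols = pd.DataFrame({"id": cohort["id"], "roi1": rng.normal(100, 10, 80)})
        with_scanner = roi_frs_regression(vols, cohort)
        without = roi_frs_regression(vols, cohort, covariates=("group", "tiv"))
        assert with_scanner["t"].iloc[0] == pytest.approx(without["t"].iloc[0], abs=1e-12)

    def test_null_fdr_calibration(self):
        """No planted effect, 200 reps x 24 ROIs: any-q<0.05 fraction <= 0.06."""
        hits = 0
        n, m = 200, 24
        for rep in range(200):
            rng, cohort = make_sample(n=n, seed=5000 + rep)
            Y = rng.normal(100, 8, (n, m))
            vols = pd.DataFrame(Y, columns=[f"roi{j}" for j in range(m)])
            vols.insert(0, "id", cohort["id"])
            res = roi_frs_regression(vols, cohort)
            hits += (res["q"] < 0.05).any()
        assert hits / 200 <= 0.06


class TestWScores:
    def test_reference_mean_zero_sd_one(self):
        rng, cohort = make_sample(150, seed=4)
        vols = pd.DataFrame(rng.normal(100, 9, (150, 5)),
                            columns=[f"roi{j}" for j in range(5)])
        vols.insert(0, "id", cohort["id"])
        w = compute_wscores(vols, cohort, reference_ids=cohort["id"])
        W = w.drop(columns="id").to_numpy()
        assert np.abs(W.mean(axis=0)).max() < 1e-10
        assert np.abs(W.std(axis=0, ddof=1) - 1.0).max() < 1e-10

    def test_w_units_are_reference_residual_sds(self):
        """A participant sitting exactly at the normative prediction scores 0;
        one residual SD above scores +1."""
        rng, cohort = make_sample(100, seed=6)
        vols = pd.DataFrame({"id": cohort["id"], "roi1": rng.normal(100, 9, 100)})
        tf = WScoreTransformer(covariates=("age", "sex", "tiv", "scanner"))
        tf.fit(vols, cohort=cohort, reference_ids=cohort["id"])
        probe = cohort.iloc[[0, 0]].copy()
        probe["id"] = ["at_pred", "plus_one_sd"]
        Xrow = tf._design(probe, np.zeros((2, 1)), tf.levels_)[0]
        pred = (Xrow @ tf.coef_)[:, 0]
        pvols = pd.DataFrame({"id": probe["id"],
                              "roi1": [pred[0], pred[1] + tf.resid_sd_[0]]})
        w = tf.transform(pvols, cohort=probe)
        assert w["roi1"].tolist() == pytest.approx([0.0, 1.0], abs=1e-12)

    def test_invariant_to_affine_covariate_rescaling(self):
        rng, cohort = make_sample(120, seed=7)
        vols = pd.DataFrame({"id": cohort["id"], "roi1": rng.normal(100, 9, 120)})
        w1 = compute_wscores(vols, cohort, reference_ids=cohort["id"])
        rescaled = cohort.copy()
        rescaled["age"] = 10.0 * rescaled["age"] - 200.0
        rescaled["tiv"] = rescaled["tiv"] / 1000.0 + 3.0
        w2 = compute_wscores(vols, rescaled, reference_ids=cohort["id"])
        assert np.allclose(w1["roi1"], w2["roi1"], atol=1e-8)

    def test_tiny_reference_rejected(self):
        rng, cohort = make_sample(20, seed=8)
        vols = pd.DataFrame({"id": cohort["id"], "roi1": rng.normal(100, 9, 20)})
        with pytest.raises(ValueError, match="reference"):
            compute_wscores(vols, cohort, reference_ids=cohort["id"].iloc[:5])


class TestInteraction:
    def _patients(self, seed, b_ftld, b_ad, n=300, noise=1.0):
        rng = np.random.default_rng(seed)
        groups = np.repeat(["FTLD", "AD"], n)
        frs = np.round(rng.normal(13.7, 3.9, 2 * n))
        slope = np.where(groups == "FTLD", b_ftld, b_ad)
        cohort = pd.DataFrame({"id": [f"p{i}" for i in range(2 * n)],
                               "group": groups, "frs_points": frs})
        w = pd.DataFrame({"id": cohort["id"],
                          "roi1": slope * frs + rng.normal(0, noise, 2 * n)})
        return cohort, w

    def test_label_swap_flips_sign_exactly(self):
        cohort, w = self._patients(0, -1.0, 0.5, n=80)
        res = interaction_contrast(w, cohort)
        swapped = cohort.copy()
        swapped["group"] = swapped["group"].map({"FTLD": "AD", "AD": "FTLD"})
        res_swap = interaction_contrast(w, swapped)
        assert res_swap["beta"].iloc[0] == pytest.approx(-res["beta"].iloc[0], abs=1e-12)

    def test_single_diagnosis_rejected(self):
        cohort, w = self._patients(1, 0.0, 0.0, n=40)
        with pytest.raises(ValueError, match="both"):
            interaction_contrast(w, cohort[cohort["group"] == "AD"])

    def test_differential_slope_detected_with_power(self):
        """b_FTLD=-3, b_AD=0, n=300/group, unit noise: q<0.05 in >=90% of reps."""
        hits = 0
        for rep in range(100):
            cohort, w = self._patients(2000 + rep, -3.0, 0.0)
            res = interaction_contrast(w, cohort)
            hits += res["q"].iloc[0] < 0.05
            assert res["beta"].iloc[0] > 0  # positive = more negative slope in FTLD
        assert hits / 100 >= 0.90

    def test_null_interaction_calibration(self):
        """Equal slopes in both groups: q<0.05 rate at the nominal 5% level
        (<= 0.06 over 1000 replicates)."""
        hits = 0
        reps = 1000
        for rep in range(reps):
            cohort, w = self._patients(3000 + rep, -1.0, -1.0, n=100)
            res = interaction_contrast(w, cohort)
            hits += res["q"].iloc[0] < 0.05
        assert hits / reps <= 0.06


def test_unadjusted_standardized_regression_matches_correlation_t():
    rng, cohort = make_sample(90, seed=9)
    vols = pd.DataFrame({"id": cohort["id"], "roi1": rng.normal(100, 9, 90)})
    corr = roi_frs_correlation(vols, cohort)
    r = corr["r"].iloc[0]
    t_corr = r * np.sqrt((90 - 2) / (1 - r**2))
    X = np.column_stack([np.ones(90), cohort["frs_points"].to_numpy(dtype=float)])
    fit = ols(X, vols["roi1"].to_numpy())
    assert fit.t[1] == pytest.approx(t_corr, abs=1e-8)
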