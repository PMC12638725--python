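"""Connectivity estimation, per-connection GLMs, clustering, network inference."""

import numpy as np
import pandas as pd
import pytest

from cardioain import (cluster_inference, cluster_rois, connection_glm,
                       connection_pairs, estimate_connectivity)
from cardioain.functional import R_CLIP, _fwl_tvalues, condense
from conftest import make_connectivity, make_single_group_sample


class TestEstimateConnectivity:
    def test_identical_columns_clipped(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        ts = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=100)})
        z = estimate_connectivity(ts)
        assert z.loc["a", "b"] == pytest.approx(np.arctanh(R_CLIP))
        assert np.isnan(z.loc["a", "a"])

    def test_white_noise_null_distribution(self):
        """Independent columns, T=2000: |r| < 0.08 for 95% of pairs (sd ~ 1/sqrt(T))."""
        rng = np.random.default_rng(1)
        ts = pd.DataFrame(rng.standard_normal((2000, 20)),
                          columns=[f"r{i}" for i in range(20)])
        z = estimate_connectivity(ts)
        r = np.tanh(z.to_numpy()[np.triu_indices(20, k=1)])
        assert (np.abs(r) < 0.08).mean() >= 0.95

    def test_known_correlation_recovered(self):
        rng = np.random.default_rng(2)
        # draw (x, y) with true r = 0.5 via cholesky
        L = np.linalg.cholesky(np.array([[1.0, 0.5], [0.5, 1.0]]))
        X = rng.standard_normal((5000, 2)) @ L.T
        z = estimate_connectivity(pd.DataFrame(X, columns=["a", "b"]))
        assert z.loc["a", "b"] == pytest.approx(np.arctanh(0.5), abs=0.05)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        ts = pd.DataFrame(rng.standard_normal((200, 4)), columns=list("abcd"))
        z1 = estimate_connectivity(ts)
        ts2 = ts.copy()
        ts2["a"] = 7.0 * ts2["a"] - 100.0
        z2 = estimate_connectivity(ts2)
        assert np.allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12, equal_nan=True)

    def test_constant_column_undefined_with_warning(self):
        rng = np.random.default_rng(4)
        ts = pd.DataFrame({"a": np.ones(100), "b": rng.normal(size=100),
                           "c": rng.normal(size=100)})
        with pytest.warns(UserWarning, match="constant"):
            z = estimate_connectivity(ts)
        assert np.isnan(z.loc["a", "b"]) and np.isnan(z.loc["c", "a"])
        assert np.isfinite(z.loc["b", "c"])

    def test_bad_band_rejected(self):
        ts = pd.DataFrame(np.random.default_rng(5).standard_normal((100, 3)))
        with pytest.raises(ValueError, match="band"):
            estimate_connectivity(ts, band=(0.2, 0.1), tr=2.0)
        with pytest.raises(ValueError, match="band"):
            estimate_connectivity(ts, band=(0.01, 0.3), tr=2.0)  # high >= Nyquist

    def test_bandpass_removes_slow_drift(self):
        rng = np.random.default_rng(6)
        t = np.arange(400)
        drift = np.sin(2 * np.pi * 0.001 * t * 2.0)
        ts = pd.DataFrame({"a": drift + 0.3 * rng.standard_normal(400),
                           "b": drift + 0.3 * rng.standard_normal(400),
                           "c": rng.standard_normal(400)})
        raw = estimate_connectivity(ts)
        filt = estimate_connectivity(ts, band=(0.008, 0.09), tr=2.0)
        assert filt.loc["a", "b"] < raw.loc["a", "b"]


def test_connection_enumeration_is_full_upper_triangle(atlas):
    pairs = connection_pairs(atlas)
    assert len(pairs) == 24 * 23 // 2 == 276
    assert len(set(pairs)) == 276
    labels = atlas["label"].tolist()
    assert all(labels.index(a) < labels.index(b) for a, b in pairs)


class TestConnectionGLM:
    def test_oracle_equivalence(self):
        rng = np.random.default_rng(0)
        cohort = make_single_group_sample(rng, 80)
        cohort.loc[:39, "group"] = "CN"
        conn = make_connectivity(rng, cohort, {}, n_connections=5)
        res = connection_glm(conn, cohort)
        X = np.column_stack([
            np.ones(80), cohort["frs_points"],
            (cohort["group"] == "FTLD").astype(float)]
            + [(cohort["scanner"] == s).astype(float)
               for s in sorted(cohort["scanner"].unique())[1:]])
        xtx_inv = np.linalg.inv(X.T @ X)
        for j, c in enumerate(conn.columns):
            y = conn[c].to_numpy()
            beta = xtx_inv @ X.T @ y
            sig2 = np.sum((y - X @ beta) ** 2) / (80 - X.shape[1])
            t = beta[1] / np.sqrt(xtx_inv[1, 1] * sig2)
            assert res["t"].iloc[j] == pytest.approx(t, abs=1e-8)

    def test_mismatched_ids_rejected(self):
        rng = np.random.default_rng(1)
        cohort = make_single_group_sample(rng, 30)
        conn = make_connectivity(rng, cohort.iloc[:20], {})
        with pytest.raises(ValueError, match="missing"):
            connection_glm(conn, cohort)

    def test_planted_connections_rank_in_top_decile(self):
        """Planted slope -0.01 on 6 of 60 connections, n=600, noise 0.08:
        planted |t| in the top decile in >=90% of reps."""
        hits = 0
        reps = 50
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            cohort = make_single_group_sample(rng, 600)
            slopes = {f"roiA{i}__roiB{i}": -0.01 for i in range(6)}
            conn = make_connectivity(rng, cohort, slopes, n_connections=60)
            res = connection_glm(conn, cohort, covariates=("scanner",))
            cutoff = np.quantile(np.abs(res["t"]), 0.9)
            planted = res[res["unit"].isin(slopes)]
            hits += (np.abs(planted["t"]) >= cutoff).all()
        assert hits / reps >= 0.90

    def test_fwl_tvalues_equal_full_model(self):
        rng = np.random.default_rng(2)
        cohort = make_single_group_sample(rng, 100)
        conn = make_connectivity(rng, cohort, {}, n_connections=8)
        res = connection_glm(conn, cohort, covariates=("scanner",))
        t_fwl, df = _fwl_tvalues(conn, cohort, ("scanner",))
        assert np.allclose(t_fwl, res["t"].to_numpy(), atol=1e-8)
        assert df == res["df"].iloc[0]


class TestClusterROIs:
    def _block_matrix(self, labels, block_a, within=0.8, between=0.0):
        n = len(labels)
        M = np.full((n, n), between)
        for i in range(n):
            for j in range(n):
                if (labels[i] in block_a) == (labels[j] in block_a):
                    M[i, j] = within
        np.fill_diagonal(M, 0.0)
        return pd.DataFrame(M, index=labels, columns=labels)

    def test_separated_blocks_recovered_with_alpha_one(self, atlas):
        labels = atlas["label"].tolist()
        block_a = set(labels[:12])
        M = self._block_matrix(labels, block_a)
        assign = cluster_rois(M, atlas, k=2, alpha=1.0)
        ids_a = {assign[l] for l in labels if l in block_a}
        ids_b = {assign[l] for l in labels if l not in block_a}
        assert len(ids_a) == 1 and len(ids_b) == 1 and ids_a != ids_b

    def test_alpha_zero_clusters_by_anatomy(self, atlas):
        """With alpha=0 only centroids matter: hemispheres' frontal vs posterior
        clumps dominate; check left/right OFC regions cluster apart from
        posterior medial-temporal regions."""
        rng = np.random.default_rng(0)
        labels = atlas["label"].tolist()
        M = rng.normal(0, 0.05, (24, 24))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        assign = cluster_rois(pd.DataFrame(M, index=labels, columns=labels),
                              atlas, k=2, alpha=0.0)
        ofc = [l for l in labels if l.startswith("Frontal")]
        mtl = [l for l in labels if "Hippocamp" in l or "ParaHippocampal" in l]
        assert len({assign[l] for l in ofc}) == 1
        assert len({assign[l] for l in mtl}) == 1
        assert assign[ofc[0]] != assign[mtl[0]]

    def test_assignment_invariant_to_roi_order(self, atlas):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            labels = atlas["label"].tolist()
            M = rng.normal(0, 0.3, (24, 24))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0.0)
            dfM = pd.DataFrame(M, index=labels, columns=labels)
            a1 = cluster_rois(dfM, atlas, k=3)
            perm = rng.permutation(24)
            shuffled = dfM.iloc[perm, perm]
            a2 = cluster_rois(shuffled, atlas, k=3)
            # same partition up to cluster relabeling
            groups1 = {}
            groups2 = {}
            for l in labels:
                groups1.setdefault(a1[l], set()).add(l)
                groups2.setdefault(a2[l], set()).add(l)
            assert {frozenset(g) for g in groups1.values()} == \
                   {frozenset(g) for g in groups2.values()}

    def test_k_exceeding_roi_count_rejected(self, atlas):
        M = pd.DataFrame(np.zeros((24, 24)), index=atlas["label"], columns=atlas["label"])
        with pytest.raises(ValueError):
            cluster_rois(M, atlas, k=30)


class TestClusterInference:
    def _results(self, tvals, df=100):
        units = [f"n{i}__m{i}" for i in range(len(tvals))]
        p = np.ones(len(tvals))
        return pd.DataFrame({"unit": units, "t": tvals, "p": p,
                             "q": p, "df": df})

    def test_zero_t_gives_zero_statistics(self):
        res = self._results(np.zeros(6))
        assignment = {}
        for i in range(6):
            assignment[f"n{i}"] = 1 + (i % 2)
            assignment[f"m{i}"] = 1 + (i % 2)
        out = cluster_inference(res, assignment)
        assert (out["table"]["stat"] == 0.0).all()
        assert out["significant_connections"] == []

    def test_planted_network_pair_has_max_statistic(self):
        """Effects confined to one network pair put it on top in >=95% of reps."""
        hits = 0
        reps = 100
        for rep in range(reps):
            rng = np.random.default_rng(200 + rep)
            tvals = rng.standard_normal(40)
            tvals[:8] += 4.0      # planted block
            assignment = {}
            for i in range(40):
                net = 1 if i < 8 else (2 if i < 24 else 3)
                assignment[f"n{i}"] = net
                assignment[f"m{i}"] = net
            out = cluster_inference(self._results(tvals), assignment)
            table = out["table"]
            best = table.loc[table["stat"].idxmax()]
            hits += (best["network_a"], best["network_b"]) == (1, 1)
        assert hits / reps >= 0.95

    def test_permutation_null_calibration(self):
        """No planted effect: any cluster-level q<0.05 in <= 6% of 200 reps."""
        hits = 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(300 + rep)
            cohort = make_single_group_sample(rng, 150)
            conn = make_connectivity(rng, cohort, {}, n_connections=12)
            res = connection_glm(conn, cohort, covariates=("scanner",))
            assignment = {}
            for i in range(12):
                net = 1 + (i % 3)
                assignment[f"roiA{i}"] = net
                assignment[f"roiB{i}"] = net
            out = cluster_inference(res, assignment, method="permutation",
                                    conn=conn, cohort=cohort,
                                    covariates=("scanner",),
                                    n_permutations=199, seed=rep)
            hits += (out["table"]["q"] < 0.05).any()
        assert hits / reps <= 0.06

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        cohort = make_single_group_sample(rng, 100)
        conn = make_connectivity(rng, cohort, {"roiA0__roiB0": -0.02}, n_connections=6)
        res = connection_glm(conn, cohort, covariates=("scanner",))
        assignment = {f"roiA{i}": 1 + i % 2 for i in range(6)}
        assignment.update({f"roiB{i}": 1 + i % 2 for i in range(6)})
        out1 = cluster_inference(res, assignment, method="permutation", conn=conn,
                                 cohort=cohort, covariates=("scanner",),
                                 n_permutations=99, seed=5)
        out2 = cluster_inference(res, assignment, method="permutation", conn=conn,
                                 cohort=cohort, covariates=("scanner",),
                                 n_permutations=99, seed=5)
        pd.testing.assert_frame_equal(out1["table"], out2["table"])
        assert out1["significant_connections"] == out2["significant_connections"]


def test_condense_roundtrip(atlas, small_sim):
    _, (cohort, _, ts, _) = small_sim
    pid = cohort["id"].iloc[0]
    z = estimate_connectivity(ts[pid])
    vec = condense(z, atlas)
    assert len(vec) == 276
    assert vec["Insula_L__Insula_R"] == z.loc["Insula_L", "Insula_R"]
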