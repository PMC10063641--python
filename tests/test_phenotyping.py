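"""Consensus clustering, group PCA, tumor clustering, SigClust, labeling,
and frozen-model validation assignment."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from deltarad.phenotyping import (PhenotypeModel, build_phenotype_model,
                                  cluster_features, cluster_index,
                                  cluster_tumors, consensus_cluster,
                                  label_phenotypes, null_eigenvalues,
                                  sigclust_test, summarize_groups_pca,
                                  two_means_labels)


class TestConsensus:
    def test_point_masses_perfect_consensus(self):
        x = np.vstack([np.zeros((30, 3)), np.full((30, 3), 5.0)])
        res = consensus_cluster(x, resamples=100, seed=0)
        assert res.chosen_k == 2
        m = res.consensus[2]
        within = m[:30, :30]
        across = m[:30, 30:]
        assert np.all(within == 1.0)
        assert np.all(across == 0.0)

    def test_planted_blobs_recovered(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 1, (30, 3)),
                       rng.normal(10, 1, (30, 3))])
        res = consensus_cluster(x, resamples=200, seed=1)
        assert res.chosen_k == 2
        from scipy.cluster import hierarchy
        labels = hierarchy.fcluster(hierarchy.linkage(x, "ward"), 2,
                                    criterion="maxclust")
        assert adjusted_rand_score([0] * 30 + [1] * 30, labels) == 1.0

    def test_matrix_construction_invariants(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(25, 4))
        res = consensus_cluster(x, k_range=(2, 3, 4), resamples=100, seed=2)
        for k, m in res.consensus.items():
            assert np.allclose(m, m.T)
            assert np.all(np.diag(m) == 1.0)
            assert m.min() >= 0.0 and m.max() <= 1.0
        ks = sorted(res.areas)
        areas = [res.areas[k] for k in ks]
        assert all(b >= a - 1e-9 for a, b in zip(areas, areas[1:]))

    def test_bad_parameters_rejected(self):
        x = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError, match="k_range"):
            consensus_cluster(x, k_range=(2, 10))
        with pytest.raises(ValueError, match="subsample_fraction"):
            consensus_cluster(x, subsample_fraction=1.5)


class TestClusterFeatures:
    def _paired_features(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(n, 3))
        cols = {}
        for i in range(3):
            cols[f"f{2 * i}"] = base[:, i]
            cols[f"f{2 * i + 1}"] = base[:, i] + \
                rng.normal(0, 0.1, n)  # r ~ 0.99 within pair
        return pd.DataFrame(cols)

    def test_planted_correlation_blocks(self):
        df = self._paired_features()
        groups, res = cluster_features(df, k_range=(2, 3, 4, 5),
                                       resamples=150, seed=1)
        assert res.chosen_k == 3
        for i in range(3):
            assert groups[f"f{2 * i}"] == groups[f"f{2 * i + 1}"]

    def test_duplicate_columns_same_group(self):
        df = self._paired_features()
        df["dup"] = df["f0"]
        groups, _ = cluster_features(df, resamples=100, seed=2)
        assert groups["dup"] == groups["f0"]

    def test_column_order_invariance(self):
        df = self._paired_features()
        g1, _ = cluster_features(df, resamples=100, seed=3)
        g2, _ = cluster_features(df[list(df.columns)[::-1]],
                                 resamples=100, seed=3)
        # same partition up to group-id relabeling
        cols = list(df.columns)
        part1 = {frozenset(c for c in cols if g1[c] == g)
                 for g in set(g1.values())}
        part2 = {frozenset(c for c in cols if g2[c] == g)
                 for g in set(g2.values())}
        assert part1 == part2

    def test_constant_column_rejected(self):
        df = self._paired_features()
        df["const"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cluster_features(df, resamples=50, seed=0)


class TestGroupPca:
    def test_rank_one_group_single_pc(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=300)
        df = pd.DataFrame({"a": a, "b": 2 * a})
        pcs, models = summarize_groups_pca(df, {"a": 1, "b": 1})
        assert list(pcs.columns) == ["C1-PC1"]
        assert models[1].n_retained == 1

    def test_isotropic_group_keeps_both_pcs(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(500, 2)), columns=["a", "b"])
        pcs, models = summarize_groups_pca(df, {"a": 1, "b": 1})
        assert models[1].n_retained == 2
        assert set(pcs.columns) == {"C1-PC1", "C1-PC2"}

    def test_orientation_sum_nonnegative_and_sign_flip(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(200, 3)),
                          columns=["a", "b", "c"])
        pcs1, m1 = summarize_groups_pca(df, {c: 1 for c in df})
        assert all(load.sum() >= 0 for load in m1[1].loadings)
        pcs2, m2 = summarize_groups_pca(-df, {c: 1 for c in df})
        np.testing.assert_allclose(np.abs(pcs1.to_numpy()),
                                   np.abs(pcs2.to_numpy()), atol=1e-9)

    def test_single_feature_group_passthrough(self):
        df = pd.DataFrame({"solo": [1.0, 2.0, 3.0], "x": [0, 1, 0.5],
                           "y": [0.1, 0.9, 0.4]})
        pcs, models = summarize_groups_pca(df, {"solo": 1, "x": 2, "y": 2})
        np.testing.assert_allclose(pcs["C1-PC1"],
                                   df["solo"] - df["solo"].mean())
        assert models[1].loadings.tolist() == [[1.0]]

    def test_full_reconstruction(self):
        """All components back-project to the centered data exactly."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(50, 4))
        xc = x - x.mean(axis=0)
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        recon = (xc @ vt.T) @ vt
        np.testing.assert_allclose(recon, xc, atol=1e-9)


class TestClusterTumors:
    def test_planted_partition_recovery(self):
        rng = np.random.default_rng(4)
        x = np.vstack([rng.normal(0, 1, (25, 6)),
                       rng.normal(8, 1, (25, 6))])
        pc = pd.DataFrame(x, index=[f"s{i}" for i in range(50)])
        _, assign, res = cluster_tumors(pc, resamples=150, seed=5)
        assert res.chosen_k == 2
        assert adjusted_rand_score([0] * 25 + [1] * 25, assign) == 1.0

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(5)
        x = np.vstack([rng.normal(0, 1, (15, 3)),
                       rng.normal(6, 1, (15, 3))])
        pc = pd.DataFrame(x, index=[f"s{i}" for i in range(30)])
        _, a1, _ = cluster_tumors(pc, resamples=100, seed=6)
        perm = rng.permutation(30)
        _, a2, _ = cluster_tumors(pc.iloc[perm], resamples=100, seed=6)
        merged = pd.concat([a1.rename("a"), a2.rename("b")], axis=1)
        assert adjusted_rand_score(merged["a"], merged["b"]) == 1.0

    def test_too_few_subjects_rejected(self):
        pc = pd.DataFrame(np.eye(4))
        with pytest.raises(ValueError, match="at least 8"):
            cluster_tumors(pc)


class TestSigClust:
    def test_point_masses_zero_ci(self):
        x = np.vstack([np.zeros((20, 3)), np.full((20, 3), 4.0)])
        labels = np.array([0] * 20 + [1] * 20)
        assert cluster_index(x, labels) == 0.0
        ci, p, _ = sigclust_test(pd.DataFrame(x), labels, n_sim=200, seed=0)
        assert ci == 0.0
        assert p < 0.05

    def test_strong_separation_significant(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(0, 1, (25, 6)),
                       rng.normal(10, 1, (25, 6))])
        labels = two_means_labels(x)
        ci, p, _ = sigclust_test(pd.DataFrame(x), labels, n_sim=500, seed=2)
        assert p < 0.01

    def test_ci_bounded_and_monotone_in_separation(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, (30, 4))
        cis = []
        for sep in (2.0, 5.0, 10.0):
            x = np.vstack([base, rng.normal(0, 1, (30, 4)) + sep])
            labels = np.array([0] * 30 + [1] * 30)
            ci = cluster_index(x, labels)
            assert 0.0 <= ci <= 1.0
            cis.append(ci)
        assert cis[0] >= cis[1] >= cis[2]

    def test_assignment_validation(self):
        x = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(ValueError, match="two"):
            sigclust_test(pd.DataFrame(x), np.zeros(20), n_sim=100)

    def test_null_eigenvalues_floor(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, 5))
        lam = null_eigenvalues(x)
        assert (lam > 0).all()
        assert lam.shape == (5,)


class TestLabeling:
    def _pc_and_assignment(self):
        pc = pd.DataFrame({"C1-PC1": [-1.0] * 5 + [1.0] * 5},
                          index=[f"s{i}" for i in range(10)])
        assign = pd.Series([7] * 5 + [3] * 5, index=pc.index)
        return pc, assign

    def test_low_mean_is_phenotype_one(self):
        pc, assign = self._pc_and_assignment()
        phen, desc = label_phenotypes(pc, assign)
        assert (phen[:5] == 1).all() and (phen[5:] == 2).all()
        assert "decreasing" in desc[1] and "increasing" in desc[2]

    def test_invariant_to_cluster_id_permutation(self):
        pc, assign = self._pc_and_assignment()
        phen1, _ = label_phenotypes(pc, assign)
        remap = assign.map({7: 1, 3: 2})
        phen2, _ = label_phenotypes(pc, remap)
        pd.testing.assert_series_equal(phen1, phen2)

    def test_tie_broken_by_size(self):
        pc = pd.DataFrame({"C1-PC1": [0.0] * 9},
                          index=[f"s{i}" for i in range(9)])
        assign = pd.Series([1] * 6 + [2] * 3, index=pc.index)
        phen, _ = label_phenotypes(pc, assign)
        assert (phen[assign == 1] == 1).all()  # larger cluster labeled 1


class TestValidationAssignment:
    def _toy_model(self):
        stats = pd.DataFrame({"mean": [0.0, 0.0], "sd": [1.0, 1.0]},
                             index=["fa", "fb"])
        from deltarad.phenotyping import GroupPca
        gp = GroupPca(features=["fa", "fb"], mean=np.zeros(2),
                      loadings=np.array([[np.sqrt(0.5), np.sqrt(0.5)]]),
                      explained_variance_ratio=[1.0], n_retained=1)
        return PhenotypeModel(
            zscore_stats=stats, feature_groups={"fa": 1, "fb": 1},
            group_pca={1: gp}, pc_columns=["C1-PC1"],
            centroids={1: np.array([-1.0]), 2: np.array([1.0])},
            labels={1: "Phenotype 1", 2: "Phenotype 2"})

    def test_exact_centroid_assigned(self):
        model = self._toy_model()
        s = np.sqrt(0.5)
        deltas = pd.DataFrame({"fa": [1 / (2 * s)], "fb": [1 / (2 * s)]},
                              index=["v1"])
        assert model.assign(deltas).loc["v1"] == 2

    def test_equidistant_tie_goes_low(self):
        model = self._toy_model()
        deltas = pd.DataFrame({"fa": [0.0], "fb": [0.0]}, index=["v1"])
        assert model.assign(deltas).loc["v1"] == 1

    def test_missing_feature_rejected(self):
        model = self._toy_model()
        with pytest.raises(KeyError, match="fb"):
            model.assign(pd.DataFrame({"fa": [0.0]}))

    def test_json_round_trip(self, tmp_path):
        model = self._toy_model()
        path = tmp_path / "model.json"
        model.save(path)
        loaded = PhenotypeModel.load(path)
        deltas = pd.DataFrame({"fa": [0.3, -0.4], "fb": [0.1, -0.8]},
                              index=["a", "b"])
        pd.testing.assert_series_equal(model.assign(deltas),
                                       loaded.assign(deltas))

    def test_newer_schema_refused(self, tmp_path):
        model = self._toy_model()
        obj = model.to_json()
        obj["schema_version"] = 99
        with pytest.raises(ValueError, match="schema version"):
            PhenotypeModel.from_json(obj)


def test_discovery_self_assignment(discovery_run):
    """Discovery subjects re-assigned through their own frozen model keep
    their labels whenever strictly closer to their own centroid."""
    model = discovery_run["model"]
    deltas = discovery_run["deltas"][list(model.feature_groups)]
    reassigned = model.assign(deltas)
    pcs = model.project(deltas)
    phen = discovery_run["phenotypes"]
    cents = model.centroids
    strict = 0
    for sid in pcs.index:
        own = np.linalg.norm(pcs.loc[sid].to_numpy() - cents[phen[sid]])
        other = min(np.linalg.norm(pcs.loc[sid].to_numpy() - cents[p])
                    for p in cents if p != phen[sid])
        if own < other:
            strict += 1
            assert reassigned[sid] == phen[sid]
    assert strict > 0
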