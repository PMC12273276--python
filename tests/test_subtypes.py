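import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from methclass import subtypes as sub

import oracles


def block_beta(n_per_block=6, n_sites=40, seed=0):
    """Two perfectly separated sample blocks with opposite site profiles."""
    rng = np.random.default_rng(seed)
    profile = rng.uniform(0.1, 0.9, n_sites)
    a = np.clip(profile[:, None] + rng.normal(0, 0.01, (n_sites, n_per_block)), 0, 1)
    b = np.clip((1 - profile)[:, None] + rng.normal(0, 0.01, (n_sites, n_per_block)), 0, 1)
    cols = [f"A{i}" for i in range(n_per_block)] + [f"B{i}" for i in range(n_per_block)]
    return pd.DataFrame(np.hstack([a, b]),
                        index=[f"chr1:{i}" for i in range(n_sites)], columns=cols)


class TestPanelSelection:
    def test_top_variance_sites_match_bruteforce(self, toy_beta):
        var = toy_beta.var(axis=1, ddof=1)
        expected = list(var.sort_values(ascending=False).index[:3])
        panel = sub.select_variable_cpgs(toy_beta, fraction=0.3)
        assert panel.site_ids == expected
        assert len(panel) == 3

    def test_constant_matrix_deterministic_tiebreak(self):
        df = pd.DataFrame(0.5, index=[f"chr1:{i}" for i in (3, 1, 2)],
                          columns=list("ab"))
        panel = sub.select_variable_cpgs(df, fraction=1.0)
        assert panel.site_ids == sorted(df.index)

    def test_missingness_filter_excludes_sites_before_ranking(self):
        df = pd.DataFrame(np.random.default_rng(0).uniform(0, 1, (4, 4)),
                          index=[f"chr1:{i}" for i in range(4)],
                          columns=list("abcd"))
        df.iloc[0, :3] = np.nan  # 75% missing
        panel = sub.select_variable_cpgs(df, fraction=1.0, max_missing_frac=0.5)
        assert "chr1:0" not in panel.site_ids
        assert panel.n_evaluable == 3

    def test_all_missing_errors(self):
        df = pd.DataFrame(np.nan, index=["chr1:1"], columns=list("ab"))
        with pytest.raises(ValueError):
            sub.select_variable_cpgs(df, fraction=1.0, max_missing_frac=0.1)


class TestConsensus:
    def test_two_blocks_give_binary_consensus(self):
        df = block_beta()
        res = sub.consensus_cluster(df, k_range=[2], n_resamples=60,
                                    subsample_frac=0.8, seed=0)
        c = res.consensus[2]
        n = 6
        within = np.concatenate([c[:n, :n][np.triu_indices(n, 1)],
                                 c[n:, n:][np.triu_indices(n, 1)]])
        between = c[:n, n:].ravel()
        assert np.allclose(within, 1.0)
        assert np.allclose(between, 0.0)

    def test_matrix_invariants(self):
        df = block_beta(n_per_block=7, seed=3)
        res = sub.consensus_cluster(df, k_range=[2, 3, 4], n_resamples=50, seed=1)
        for k, c in res.consensus.items():
            assert np.allclose(c, c.T)
            assert np.allclose(np.diag(c), 1.0)
            assert c.min() >= 0 and c.max() <= 1
            assert res.delta_areas[k] >= 0

    def test_consensus_equals_bruteforce_replay(self):
        """Co-clustering fractions must match an independent recomputation
        driven by the same resample stream."""
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.uniform(0, 1, (30, 12)),
                          index=[f"chr1:{i}" for i in range(30)],
                          columns=[f"s{i}" for i in range(12)])
        res = sub.consensus_cluster(df, k_range=[3], n_resamples=50,
                                    subsample_frac=0.8, seed=11)
        D = sub.pearson_distance_matrix(df)
        expected = oracles.consensus_bruteforce(D, k=3, n_resamples=50,
                                                subsample_frac=0.8, seed=11)
        assert np.allclose(res.consensus[3], expected, atol=1e-12)

    def test_never_cosampled_pairs_raise(self):
        df = block_beta(n_per_block=2, n_sites=10)
        # subsample of 1 sample: no pair can ever be co-sampled
        with pytest.raises(ValueError, match="co-sampled"):
            sub.consensus_cluster(df, k_range=[2], n_resamples=20,
                                  subsample_frac=0.2, seed=0)


class TestChooseK:
    def test_two_block_toy_chooses_two(self):
        # exchangeable block members (exact replicates): no sub-structure
        rng = np.random.default_rng(1)
        profile = rng.uniform(0.1, 0.9, 40)
        a = np.tile(profile, (6, 1)).T
        b = np.tile(1 - profile, (6, 1)).T
        df = pd.DataFrame(np.hstack([a, b]),
                          index=[f"chr1:{i}" for i in range(40)],
                          columns=[f"s{i}" for i in range(12)])
        res = sub.consensus_cluster(df, k_range=[2, 3, 4], n_resamples=60, seed=0)
        assert sub.choose_k(res) == 2
        assert not res.weak_structure

    def test_featureless_noise_flags_weak_structure(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.uniform(0, 1, (50, 24)),
                          index=[f"chr1:{i}" for i in range(50)],
                          columns=[f"s{i}" for i in range(24)])
        res = sub.consensus_cluster(df, k_range=[2, 3, 4], n_resamples=60, seed=0)
        k = sub.choose_k(res)
        assert k == 2
        assert res.weak_structure


class TestLabelAssignment:
    @staticmethod
    def _beta_for_means(means, n_per=3, n_sites=50):
        cols, vals, labs = [], [], []
        for ci, m in enumerate(means):
            for j in range(n_per):
                cols.append(f"c{ci}_{j}")
                vals.append(np.full(n_sites, m))
                labs.append(ci + 1)
        df = pd.DataFrame(np.array(vals).T,
                          index=[f"chr1:{i}" for i in range(n_sites)], columns=cols)
        return df, np.array(labs)

    def test_ascending_means_map_to_class_names(self):
        df, labs = self._beta_for_means([0.2, 0.4, 0.6, 0.8])
        named = sub.assign_class_labels(labs, df)
        for ci, expected in enumerate(sub.CLASS_ORDER):
            assert (named[labs == ci + 1] == expected).all()

    def test_cluster_index_permutation_invariance(self):
        df, labs = self._beta_for_means([0.8, 0.2, 0.6, 0.4])
        named = sub.assign_class_labels(labs, df)
        perm = np.array([3, 1, 4, 2])[labs - 1]  # relabel cluster ids
        named_perm = sub.assign_class_labels(perm, df)
        assert (named == named_perm).all()

    def test_non_four_k_gets_generic_ordered_names(self):
        df, labs = self._beta_for_means([0.2, 0.5, 0.8])
        named = sub.assign_class_labels(labs, df)
        assert set(named) == {"C1", "C2", "C3"}
        assert (named[labs == 1] == "C1").all() and (named[labs == 3] == "C3").all()

    def test_merge_mapping(self):
        assert sub.merge_label("DEM") == "DEM+LOW"
        assert sub.merge_label("LOW") == "DEM+LOW"
        assert sub.merge_label("INT") == "INT+CIMP"
        assert sub.merge_label("CIMP") == "INT+CIMP"


class TestCentroidClassifier:
    @staticmethod
    def _train(seed=0):
        rng = np.random.default_rng(seed)
        sites = [f"chr1:{i}" for i in range(60)]
        profiles = {c: np.clip(rng.uniform(0.05 + 0.2 * i, 0.15 + 0.2 * i, 60)
                               + rng.normal(0, 0.05, 60), 0, 1)
                    for i, c in enumerate(sub.CLASS_ORDER)}
        cols, vals, labs = [], [], []
        for c in sub.CLASS_ORDER:
            for j in range(4):
                cols.append(f"{c}{j}")
                vals.append(np.clip(profiles[c] + rng.normal(0, 0.02, 60), 0, 1))
                labs.append(c)
        df = pd.DataFrame(np.array(vals).T, index=sites, columns=cols)
        labels = pd.Series(labs, index=cols)
        return df, labels

    def test_self_consistency_and_centroid_identity(self):
        df, labels = self._train()
        model = sub.train_centroid_classifier(df, labels)
        calls = sub.classify_samples(model, df, min_shared_sites=10)
        assert (calls["label"] == labels).all()
        # a sample exactly equal to a centroid lands on it with distance 0
        probe = model.centroids[["INT"]].rename(columns={"INT": "probe"})
        call = sub.classify_samples(model, probe, min_shared_sites=10)
        assert call.loc["probe", "label"] == "INT"

    def test_small_class_rejected(self):
        df, labels = self._train()
        labels = labels.copy()
        labels[labels == "DEM"] = "LOW"
        labels.iloc[0] = "DEM"  # lone member
        with pytest.raises(ValueError, match="<2"):
            sub.train_centroid_classifier(df, labels)

    def test_serialization_round_trip(self, tmp_path):
        df, labels = self._train(seed=2)
        model = sub.train_centroid_classifier(df, labels, training_tag="toy")
        path = tmp_path / "model.json"
        model.to_json(path)
        back = sub.CentroidModel.from_json(path)
        pd.testing.assert_frame_equal(back.centroids, model.centroids)
        c1 = sub.classify_samples(model, df, min_shared_sites=10)
        c2 = sub.classify_samples(back, df, min_shared_sites=10)
        pd.testing.assert_frame_equal(c1, c2)

    def test_all_missing_sample_unclassifiable(self):
        df, labels = self._train()
        model = sub.train_centroid_classifier(df, labels)
        new = pd.DataFrame(np.nan, index=df.index, columns=["empty"])
        call = sub.classify_samples(model, new)
        assert call.loc["empty", "status"] == "unclassifiable"
        assert call.loc["empty", "label"] is None

    def test_exact_tie_resolves_to_lower_beta_class(self):
        sites = [f"chr1:{i}" for i in range(10)]
        base = np.linspace(0.1, 0.9, 10)
        cent = pd.DataFrame({"DEM": base - 0.05, "LOW": base - 0.02,
                             "INT": base + 0.02, "CIMP": base + 0.05}, index=sites)
        model = sub.CentroidModel(class_order=sub.CLASS_ORDER, centroids=cent)
        # equidistant (equal correlation) probe: the shared shape itself
        probe = pd.DataFrame({"p": base}, index=sites)
        call = sub.classify_samples(model, probe, min_shared_sites=5)
        assert call.loc["p", "status"] == "tie"
        assert call.loc["p", "label"] == "DEM"

    def test_centroid_order_invariant_enforced(self):
        sites = [f"chr1:{i}" for i in range(5)]
        cent = pd.DataFrame({"DEM": [0.9] * 5, "LOW": [0.1] * 5,
                             "INT": [0.5] * 5, "CIMP": [0.6] * 5}, index=sites)
        with pytest.raises(ValueError, match="increase"):
            sub.CentroidModel(class_order=sub.CLASS_ORDER, centroids=cent)


class TestModelResults:
    def test_fit_recovers_planted_classes(self, default_cohort, fitted):
        truth = default_cohort["truth"]
        assert fitted.k == 4
        ari = adjusted_rand_score(truth.classes.loc[fitted.labels.index],
                                  fitted.labels)
        assert ari >= 0.9
        means = fitted.class_mean_beta()
        assert list(means.index) == sub.CLASS_ORDER
        assert means.is_monotonic_increasing

    def test_training_samples_reclassified_consistently(self, fitted):
        calls = fitted.predict(fitted.panel_beta)
        agree = (calls["label"] == fitted.labels.loc[calls.index]).mean()
        assert agree >= 0.99

    def test_summary_mentions_classes_and_k(self, fitted):
        text = fitted.summary()
        assert "chosen k: 4" in text
        for c in sub.CLASS_ORDER:
            assert c in text
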