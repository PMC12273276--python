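import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methclass import signatures as sig
from methclass.io import SignedGeneSet

import oracles


class TestZScore:
    def test_simple_values(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        z = sig.zscore_normalize(df)
        assert np.allclose(z.loc["g"], [-1, 0, 1])

    def test_idempotent_on_z_scale(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(20, 10)))
        z1 = sig.zscore_normalize(df)
        z2 = sig.zscore_normalize(z1)
        assert np.allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)

    def test_moments_recomputed(self):
        rng = np.random.default_rng(1)
        z = sig.zscore_normalize(pd.DataFrame(rng.uniform(size=(50, 8))))
        assert np.abs(z.mean(axis=1)).max() < 1e-10
        assert np.abs(z.std(axis=1, ddof=1) - 1).max() < 1e-10

    def test_constant_gene_missing_with_warning(self, caplog):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]],
                          index=["flat", "ok"], columns=list("abc"))
        z = sig.zscore_normalize(df)
        assert z.loc["flat"].isna().all()
        assert "constant" in caplog.text


class TestSignatureScore:
    @staticmethod
    def _z():
        return pd.DataFrame({"s1": [0.1, 0.5, 0.9], "s2": [1.0, -1.0, 0.0]},
                            index=["A", "B", "C"])

    def test_median_of_three(self):
        res = sig.signature_score(self._z(), ["A", "B", "C"])
        assert res.scores["s1"] == pytest.approx(0.5)
        assert res.scores["s2"] == pytest.approx(0.0)

    def test_single_gene_set(self):
        res = sig.signature_score(self._z(), ["B"], min_genes=1)
        assert res.scores["s1"] == pytest.approx(0.5)
        assert res.scores["s2"] == pytest.approx(-1.0)

    def test_insufficient_genes_skipped_with_status(self):
        res = sig.signature_score(self._z(), ["A", "ZZZ", "YYY"])
        assert res.status == "skipped"
        assert res.scores is None
        assert res.genes_missing == ["ZZZ", "YYY"]

    def test_absent_genes_only_reported_not_scored(self):
        res = sig.signature_score(self._z(), ["A", "B", "C", "Q"], min_genes=3)
        assert res.status == "ok"
        assert res.genes_missing == ["Q"]

    def test_planted_immune_signature_high_in_low(self, default_cohort, fitted):
        truth = default_cohort["truth"]
        z = sig.zscore_normalize(default_cohort["expr"].values)
        res = sig.signature_score(z, truth.immune_genes, name="immune")
        by_class = res.scores.groupby(fitted.labels).mean()
        assert by_class["LOW"] > by_class["CIMP"]
        assert by_class["LOW"] == by_class.max()


class TestDichotomy:
    def test_ties_at_median_go_low(self):
        s = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd"))
        d = sig.dichotomize(s)
        assert (d[["b", "c"]] == "LO").all()
        assert d["d"] == "HI"

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=-5, max_value=5, allow_nan=False),
                    min_size=2, max_size=30))
    def test_group_balance_up_to_median_ties(self, vals):
        s = pd.Series(vals, index=[f"s{i}" for i in range(len(vals))])
        d = sig.dichotomize(s)
        n_hi = (d == "HI").sum()
        n_lo = (d == "LO").sum()
        ties = (s == s.median()).sum()
        # median ties all land in LO: LO is never the smaller side, HI never
        # exceeds half the cohort, and without ties an even split is exact
        assert n_lo >= n_hi
        assert n_hi <= len(vals) // 2
        if ties == 0 and len(vals) % 2 == 0:
            assert n_hi == n_lo


class TestClassAssociation:
    def test_balanced_table_gives_zero(self):
        d = pd.Series(["HI", "LO"] * 10, index=[f"s{i}" for i in range(20)])
        lab = pd.Series(["A"] * 10 + ["B"] * 10, index=d.index)
        chi2, dof, p, _ = sig.class_association(d, lab)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_formula(self):
        # 2x2 table (30, 10; 10, 30)
        idx = [f"s{i}" for i in range(80)]
        lab = pd.Series(["A"] * 40 + ["B"] * 40, index=idx)
        d = pd.Series(["HI"] * 30 + ["LO"] * 10 + ["HI"] * 10 + ["LO"] * 30,
                      index=idx)
        chi2, dof, p, table = sig.class_association(d, lab)
        expected, df_exp = oracles.chi2_hand(table.to_numpy())
        assert chi2 == pytest.approx(expected, abs=1e-10)
        assert dof == df_exp == 1

    def test_planted_immune_association_significant(self, default_cohort, fitted):
        truth = default_cohort["truth"]
        z = sig.zscore_normalize(default_cohort["expr"].values)
        scores = sig.signature_score(z, truth.immune_genes, name="immune").scores
        chi2, dof, p, _ = sig.class_association(sig.dichotomize(scores),
                                                fitted.labels)
        assert dof == 3
        assert p < 0.01


class TestPrerankedGsea:
    @staticmethod
    def _ranked(n=10, seed=0):
        rng = np.random.default_rng(seed)
        vals = np.sort(rng.normal(size=n))[::-1]
        return pd.Series(vals, index=[f"g{i}" for i in range(n)])

    def test_top_two_weight_zero_matches_bruteforce(self):
        ranked = self._ranked()
        res = sig.preranked_gsea(ranked, ["g0", "g1"], weight=0.0, n_perm=50, seed=1)
        expected = oracles.gsea_es_bruteforce(ranked.to_dict(), ["g0", "g1"], 0.0)
        assert res.es == pytest.approx(expected, abs=1e-12)
        assert res.es == pytest.approx(1.0 - 0 / 8)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("weight", [0.0, 1.0])
    def test_es_matches_bruteforce_on_random_instances(self, seed, weight):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        ranked = pd.Series(rng.normal(size=n),
                           index=[f"g{i}" for i in range(n)])
        genes = list(rng.choice(ranked.index, size=int(rng.integers(2, n // 2)),
                                replace=False))
        res = sig.preranked_gsea(ranked, genes, weight=weight, n_perm=50, seed=0)
        expected = oracles.gsea_es_bruteforce(ranked.to_dict(), genes, weight)
        assert res.es == pytest.approx(expected, abs=1e-12)
        assert abs(res.es) <= 1.0 + 1e-12
        assert np.sign(res.nes) == np.sign(res.es) or res.nes == 0

    def test_all_genes_hit_gives_nonnegative_es(self):
        ranked = self._ranked(8)
        res = sig.preranked_gsea(ranked, list(ranked.index), weight=1.0,
                                 n_perm=30, seed=0)
        assert res.es >= 0
        expected = oracles.gsea_es_bruteforce(ranked.to_dict(),
                                              list(ranked.index), 1.0)
        assert res.es == pytest.approx(expected, abs=1e-12)

    def test_exhaustive_permutation_p_is_exact(self):
        ranked = pd.Series([3.0, 2.0, 1.0, -1.0, -2.0, -3.0],
                           index=[f"g{i}" for i in range(6)])
        res = sig.preranked_gsea(ranked, ["g0", "g1"], weight=1.0,
                                 n_perm=15, seed=0)
        assert res.n_perm == 15  # all C(6,2) subsets enumerated
        from itertools import combinations
        null = [oracles.gsea_es_bruteforce(ranked.to_dict(), list(pair), 1.0)
                for pair in combinations(ranked.index, 2)]
        expected_p = np.mean([abs(e) >= abs(res.es) - 1e-12 for e in null])
        assert res.p == pytest.approx(expected_p, abs=1e-12)

    def test_unknown_set_rejected(self):
        with pytest.raises(ValueError):
            sig.preranked_gsea(self._ranked(), ["nope"], n_perm=20)


class TestUrActivation:
    @staticmethod
    def _regulon(n_pos, n_neg=0):
        d = {f"t{i}": 1 for i in range(n_pos)}
        d.update({f"n{i}": -1 for i in range(n_neg)})
        return SignedGeneSet(name="REG", directions=d)

    def test_all_consistent(self):
        effects = {f"t{i}": 2.0 for i in range(4)}
        r = sig.ur_activation_z(effects, self._regulon(4))
        assert r.z == pytest.approx(2.0)

    def test_perfect_split_is_zero(self):
        effects = {"t0": 1.0, "t1": 1.0, "t2": -1.0, "t3": -1.0}
        r = sig.ur_activation_z(effects, self._regulon(4))
        assert r.z == pytest.approx(0.0)

    def test_nine_one_closed_form(self):
        effects = {f"t{i}": 1.0 for i in range(9)}
        effects["t9"] = -1.0
        r = sig.ur_activation_z(effects, self._regulon(10))
        assert r.z == pytest.approx(8 / np.sqrt(10))

    def test_expected_inhibition_counts_as_consistent(self):
        effects = {"n0": -1.0, "n1": -2.0, "n2": -0.5, "n3": -3.0}
        r = sig.ur_activation_z(effects, self._regulon(0, 4))
        assert r.z == pytest.approx(2.0)

    def test_too_few_targets_not_scored(self):
        effects = {"t0": 1.0, "t1": 1.0}
        r = sig.ur_activation_z(effects, self._regulon(4))
        assert r.status == "not scored"
        assert np.isnan(r.z)

    @settings(deadline=None, max_examples=40)
    @given(signs=st.lists(st.sampled_from([1.0, -1.0]), min_size=4, max_size=25))
    def test_z_bounded_by_sqrt_n(self, signs):
        effects = {f"t{i}": s for i, s in enumerate(signs)}
        r = sig.ur_activation_z(effects, self._regulon(len(signs)))
        assert abs(r.z) <= np.sqrt(len(signs)) + 1e-12
        if all(s == 1.0 for s in signs):
            assert r.z == pytest.approx(np.sqrt(len(signs)))


class TestDerivedSignature:
    @staticmethod
    def _cohort(genes, n=60, seed=0, driver_sd=1.0, noise=0.3):
        rng = np.random.default_rng(seed)
        driver = rng.normal(0, driver_sd, n)
        rows = {g: driver + rng.normal(0, noise, n) for g in genes}
        return pd.DataFrame(rows).T

    def test_colinear_candidates_all_retained(self):
        genes = [f"g{i}" for i in range(5)]
        a = self._cohort(genes, seed=1, noise=1e-6)
        b = self._cohort(genes, seed=2, noise=1e-6)
        retained, _ = sig.derive_correlated_signature(a, b, genes)
        assert retained == genes

    def test_planted_anticorrelated_gene_dropped(self):
        genes = [f"g{i}" for i in range(9)]
        a = self._cohort(genes, seed=3)
        b = self._cohort(genes, seed=4)
        a.loc["g8"] *= -1
        b.loc["g8"] *= -1
        retained, audit = sig.derive_correlated_signature(a, b, genes)
        assert "g8" not in retained
        assert set(retained) == set(genes[:8])
        assert audit["a"]["gene_mean_rho"]["g8"] < 0

    def test_destroyed_cohort_b_retains_nothing(self):
        genes = [f"g{i}" for i in range(8)]
        a = self._cohort(genes, seed=5)
        rng = np.random.default_rng(6)
        b = self._cohort(genes, seed=7, driver_sd=0.0, noise=1.0)
        b.loc[:] = rng.permutation(b.to_numpy().ravel()).reshape(b.shape)
        retained, _ = sig.derive_correlated_signature(a, b, genes)
        assert retained == []

    def test_too_few_candidates_rejected(self):
        genes = ["g0", "g1"]
        a = self._cohort(genes)
        with pytest.raises(ValueError):
            sig.derive_correlated_signature(a, a, genes)
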