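"""Compositional statistics: filtering, CLR, diversity, ordination, testing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cihpheno as cp
from cihpheno.microbiome import _pseudo_f_terms


def table_from_matrix(mat, groups=None):
    mat = np.asarray(mat)
    counts = pd.DataFrame(
        mat,
        index=[f"f{i}" for i in range(mat.shape[0])],
        columns=[f"s{j}" for j in range(mat.shape[1])],
    )
    g = pd.Series(groups, index=counts.columns) if groups is not None else None
    return cp.CountTable(counts, g)


class TestFiltering:
    def test_low_prevalence_feature_removed(self):
        mat = np.ones((2, 48), dtype=int) * 10
        mat[1] = 0
        mat[1, 0] = 5  # present in 1/48 samples ~ 2%
        filtered, _ = cp.filter_features(table_from_matrix(mat))
        assert list(filtered.counts.index) == ["f0"]

    def test_low_abundance_feature_kept_but_not_da_eligible(self):
        # f1 peaks at 0.4% relative abundance: retained, not eligible
        mat = np.array([[996, 1000], [4, 2]])
        filtered, da = cp.filter_features(table_from_matrix(mat))
        assert "f1" in filtered.counts.index
        assert not da["f1"]
        assert da["f0"]

    def test_all_zero_feature_removed(self):
        mat = np.array([[5, 5], [0, 0]])
        filtered, _ = cp.filter_features(table_from_matrix(mat))
        assert list(filtered.counts.index) == ["f0"]

    def test_everything_removed_raises(self):
        # identity: every feature in exactly 1/48 samples (~2% prevalence)
        mat = np.eye(48, dtype=int)
        with pytest.raises(ValueError, match="every feature"):
            cp.filter_features(table_from_matrix(mat))


class TestCLR:
    def test_equal_counts_map_to_zero(self):
        clr = cp.clr_transform(table_from_matrix(np.full((4, 3), 7)))
        assert np.allclose(clr.to_numpy(), 0.0)

    def test_geometric_mean_arithmetic(self):
        # proportions 1:10:100 (no zeros): clr = (-ln10, 0, ln10)
        clr = cp.clr_transform(table_from_matrix([[10], [100], [1000]]), pseudocount=1e-12)
        expected = np.array([-np.log(10.0), 0.0, np.log(10.0)])
        assert np.allclose(clr.to_numpy().ravel(), expected, atol=1e-9)

    def test_rows_sum_to_zero_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        mat = rng.integers(1, 500, size=(30, 8))
        t1 = table_from_matrix(mat)
        t2 = table_from_matrix(mat * 13)
        c1 = cp.clr_transform(t1, pseudocount=1e-9)
        c2 = cp.clr_transform(t2, pseudocount=1e-9)
        assert np.abs(c1.sum(axis=0).to_numpy()).max() < 1e-9
        assert np.allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-6)

    def test_matches_scikit_bio(self):
        from skbio.stats.composition import clr as skbio_clr

        rng = np.random.default_rng(1)
        mat = rng.integers(0, 200, size=(12, 5))
        ours = cp.clr_transform(table_from_matrix(mat), pseudocount=0.5)
        theirs = skbio_clr((mat + 0.5).T).T
        assert np.allclose(ours.to_numpy(), theirs, atol=1e-10)


class TestAlphaDiversity:
    def test_uniform_four_taxa_closed_forms(self):
        div = cp.alpha_diversity(table_from_matrix([[25], [25], [25], [25]]))
        assert div["shannon"].iloc[0] == pytest.approx(np.log(4.0), abs=1e-12)
        assert div["simpson"].iloc[0] == pytest.approx(0.75, abs=1e-12)

    def test_chao1_formula_arithmetic(self):
        # counts (5,3,1,1,2): S=5, f1=2, f2=1 -> 5 + 2*1/(2*2) = 5.5
        div = cp.alpha_diversity(table_from_matrix([[5], [3], [1], [1], [2]]))
        assert div["chao1"].iloc[0] == pytest.approx(5.5)

    def test_single_taxon_sample(self):
        div = cp.alpha_diversity(table_from_matrix([[40]]))
        assert div.iloc[0].tolist() == [1.0, 0.0, 0.0]

    def test_matches_scikit_bio(self):
        from skbio.diversity.alpha import chao1, shannon, simpson

        rng = np.random.default_rng(2)
        mat = rng.integers(0, 50, size=(40, 6)) * rng.integers(0, 2, size=(40, 6))
        mat[0] += 1  # no empty samples
        div = cp.alpha_diversity(table_from_matrix(mat))
        for j, s in enumerate(div.index):
            counts = mat[:, j]
            assert div.loc[s, "chao1"] == pytest.approx(chao1(counts, bias_corrected=True))
            assert div.loc[s, "shannon"] == pytest.approx(shannon(counts, base=np.e))
            assert div.loc[s, "simpson"] == pytest.approx(simpson(counts))


class TestPCA:
    def test_planted_clusters_separate_on_pc1(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, size=(20, 10))
        b = rng.normal(0, 1, size=(20, 10))
        b[:3] += 6.0  # shift 3 features in the second cluster
        clr_like = pd.DataFrame(
            np.hstack([a, b]), columns=[f"s{i}" for i in range(20)]
        )
        clr_like -= clr_like.mean(axis=0)
        scores, _, evr = cp.pca_clr(clr_like)
        labels = [0] * 10 + [1] * 10
        assert silhouette_score(scores[["PC1"]], labels) > 0.5
        assert evr[0] >= evr[1]

    def test_duplicated_samples_get_identical_scores(self):
        rng = np.random.default_rng(4)
        mat = rng.normal(size=(8, 5))
        mat[:, 4] = mat[:, 0]
        clr_like = pd.DataFrame(mat - mat.mean(axis=0), columns=list("abcde"))
        scores, _, _ = cp.pca_clr(clr_like)
        assert np.allclose(scores.loc["a"], scores.loc["e"], atol=1e-9)

    def test_rank_deficient_raises(self):
        flat = pd.DataFrame(np.zeros((5, 4)), columns=list("abcd"))
        with pytest.raises(ValueError, match="rank"):
            cp.pca_clr(flat)


class TestPermanova:
    @staticmethod
    def brute_force_p(X, labels):
        """ANOVA-identity pseudo-F enumerated over all label permutations."""

        def f_stat(lab):
            grand = X.mean(axis=0)
            ssb = ssw = 0.0
            for g in set(lab):
                sub = X[np.asarray(lab) == g]
                ssb += len(sub) * np.sum((sub.mean(axis=0) - grand) ** 2)
                ssw += np.sum((sub - sub.mean(axis=0)) ** 2)
            g_n = len(set(lab))
            return (ssb / (g_n - 1)) / (ssw / (len(lab) - g_n))

        f_obs = f_stat(labels)
        hits = total = 0
        for perm in itertools.permutations(labels):
            hits += f_stat(list(perm)) >= f_obs - 1e-12
            total += 1
        return f_obs, hits / total

    def test_exhaustive_p_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 4))
        X[3:] += 1.0
        labels = ["a", "a", "a", "b", "b", "b"]
        clr_like = pd.DataFrame(X.T, columns=[f"s{i}" for i in range(6)])
        res = cp.permanova(clr_like, pd.Series(labels, index=clr_like.columns), method="exact")
        f_oracle, p_oracle = self.brute_force_p(X, labels)
        assert res["pseudo_F"].iloc[0] == pytest.approx(f_oracle, rel=1e-9)
        assert res["p"].iloc[0] == pytest.approx(p_oracle, abs=1e-12)

    def test_statistic_matches_scikit_bio(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 6))
        labels = ["a"] * 6 + ["b"] * 6
        clr_like = pd.DataFrame(X.T, columns=[f"s{i}" for i in range(12)])
        res = cp.permanova(clr_like, pd.Series(labels, index=clr_like.columns), n_perm=99, seed=0)
        d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        sk = skbio_permanova(DistanceMatrix(d, ids=clr_like.columns), grouping=labels, permutations=0)
        assert res["pseudo_F"].iloc[0] == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_planted_shift_detected_with_small_p(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 8))
        X[10:] += 3.0
        labels = ["a"] * 10 + ["b"] * 10
        clr_like = pd.DataFrame(X.T, columns=[f"s{i}" for i in range(20)])
        res = cp.permanova(clr_like, pd.Series(labels, index=clr_like.columns), n_perm=999, seed=1)
        assert res["p"].iloc[0] <= 0.005

    def test_small_group_skipped_with_warning(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(8, 4))
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 2
        clr_like = pd.DataFrame(X.T, columns=[f"s{i}" for i in range(8)])
        with pytest.warns(UserWarning, match="skipped"):
            res = cp.permanova(clr_like, pd.Series(labels, index=clr_like.columns), n_perm=49, seed=2)
        assert set(res["comparison"]) == {"a vs b"}


class TestDifferentialAbundance:
    def test_null_data_rarely_rejects(self):
        total = 0
        for seed in range(5):
            table, _ = cp.simulate_count_table(
                cp.CountSimSpec(n_taxa=50, n_samples_per_group=12, groups=("A", "B"), seed=seed)
            )
            clr = cp.clr_transform(table)
            res = cp.differential_abundance(clr, table.groups)
            total += int(res["reject"].sum())
        assert total <= 3  # expected ~0 under the null at FDR 10%

    def test_planted_effect_recovered_with_sign(self):
        spec = cp.CountSimSpec(
            n_taxa=50, n_samples_per_group=16, groups=("A", "B"),
            planted_effects=((4, "B", 2.0),), dispersion=0.01, seed=9,
        )
        table, _ = cp.simulate_count_table(spec)
        clr = cp.clr_transform(table)
        res = cp.differential_abundance(clr, table.groups)
        row = res.loc["taxon_0004"]
        assert row["reject"]
        assert row["mean_1"] < row["mean_2"]  # increased in group B

    def test_q_never_below_p(self):
        table, _ = cp.simulate_count_table(
            cp.CountSimSpec(n_taxa=30, n_samples_per_group=6, groups=("A", "B"), seed=10)
        )
        clr = cp.clr_transform(table)
        res = cp.differential_abundance(clr, table.groups)
        assert (res["q"] >= res["p"] - 1e-12).all()


class TestModules:
    def make_table(self, kos, values):
        counts = pd.DataFrame(
            np.array(values)[:, None] * np.ones((1, 2)), index=kos, columns=["s1", "s2"]
        ).astype(int)
        return cp.CountTable(counts + (counts.sum(axis=0) == 0).astype(int))

    def test_median_of_steps_rule(self):
        d = cp.ModuleDefinition("M1", "demo", (frozenset({"K00001"}), frozenset({"K00002", "K00003"})))
        counts = pd.DataFrame(
            {"s1": [4, 7, 3]}, index=["K00001", "K00002", "K00003"]
        )
        abund, cover = cp.aggregate_modules(counts, [d])
        assert abund.loc["M1", "s1"] == 7.0  # median of step sums 4 and 10
        assert cover.loc["M1", "s1"] == 1.0

    def test_absent_module_scores_zero(self):
        d = cp.ModuleDefinition("M2", "absent", (frozenset({"K09999"}),))
        counts = pd.DataFrame({"s1": [5]}, index=["K00001"])
        abund, cover = cp.aggregate_modules(counts, [d])
        assert abund.loc["M2", "s1"] == 0.0
        assert cover.loc["M2", "s1"] == 0.0

    def test_two_thirds_coverage_passes(self):
        d = cp.ModuleDefinition(
            "M3", "partial",
            (frozenset({"K00001"}), frozenset({"K00002"}), frozenset({"K00003"})),
        )
        counts = pd.DataFrame({"s1": [6, 2, 0]}, index=["K00001", "K00002", "K00003"])
        abund, cover = cp.aggregate_modules(counts, [d])
        assert cover.loc["M3", "s1"] == pytest.approx(2 / 3)
        assert abund.loc["M3", "s1"] == 2.0  # median of (6, 2, 0)

    def test_invalid_ko_id_rejected(self):
        with pytest.raises(ValueError, match="invalid KO"):
            cp.ModuleDefinition("M4", "bad", (frozenset({"X123"}),))


class TestCountTableValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            table_from_matrix([[-1, 2]])

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            table_from_matrix([[1, 0], [2, 0]])
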