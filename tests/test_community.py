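import numpy as np
import pandas as pd
import pytest
import skbio
from scipy.spatial.distance import pdist, squareform

import microbiodx as m
from microbiodx.errors import ValidationError
from microbiodx.simulate import _random_bifurcating_newick


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

class TestAlphaDiversity:
    def test_chao1_formula_oracle(self):
        # S_obs=5, F1=2, F2=1 -> chao1 = 5 + 2*1/(2*2) = 5.5
        t = m.FeatureTable([f"f{i}" for i in range(5)], ["s"],
                           np.array([[5], [3], [1], [1], [2]], float))
        res = m.alpha_diversity(t)
        assert res.loc["s", "observed_features"] == 5
        assert res.loc["s", "chao1"] == pytest.approx(5.5)

    def test_uniform_sample_shannon_simpson(self):
        t = m.FeatureTable([f"f{i}" for i in range(4)], ["s"],
                           np.full((4, 1), 10.0))
        res = m.alpha_diversity(t)
        assert res.loc["s", "shannon"] == pytest.approx(np.log(4))
        assert res.loc["s", "simpson"] == pytest.approx(0.75)

    def test_single_feature_degenerate(self):
        t = m.FeatureTable(["f"], ["s"], np.array([[7.0]]))
        res = m.alpha_diversity(t)
        assert res.loc["s", "shannon"] == 0.0
        assert res.loc["s", "simpson"] == 0.0
        assert res.loc["s", "chao1"] == 1.0

    def test_estimator_lower_bounds(self, planted_cohort):
        table, *_ = planted_cohort
        res = m.alpha_diversity(table)
        assert (res["chao1"] >= res["observed_features"] - 1e-9).all()
        assert (res["ace"] >= res["observed_features"] - 1e-9).all()
        assert res["simpson"].between(0, 1).all()

    def test_non_integer_counts_rejected_for_richness(self, tiny_table):
        rel = tiny_table.relative_abundance()
        with pytest.raises(ValidationError):
            m.alpha_diversity(rel)
        res = m.alpha_diversity(rel, richness_estimators=False)
        assert "shannon" in res.columns and "chao1" not in res.columns

    def test_all_zero_sample_rejected(self):
        t = m.FeatureTable(["f"], ["s1", "s2"], np.array([[3.0, 0.0]]))
        with pytest.raises(ValidationError):
            m.alpha_diversity(t)


# ---------------------------------------------------------------------------
# UniFrac with brute-force branch enumeration oracle
# ---------------------------------------------------------------------------

def brute_force_unifrac(tree: skbio.TreeNode, table: m.FeatureTable,
                        i: int, j: int, weighted: bool) -> float:
    """Independent per-branch enumeration of the UniFrac definitions."""
    count = {f: (table.counts[k, i], table.counts[k, j])
             for k, f in enumerate(table.feature_ids)}
    tot_a = sum(v[0] for v in count.values())
    tot_b = sum(v[1] for v in count.values())
    num = den = 0.0
    for node in tree.traverse(include_self=False):
        length = node.length or 0.0
        leaves = [t.name for t in node.tips()] or [node.name]
        a = sum(count.get(n, (0, 0))[0] for n in leaves)
        b = sum(count.get(n, (0, 0))[1] for n in leaves)
        if weighted:
            num += length * abs(a / tot_a - b / tot_b)
        else:
            pa, pb = a > 0, b > 0
            num += length * (pa != pb)
            den += length * (pa or pb)
    if weighted:
        for tip in tree.tips():
            depth = tip.accumulate_to_ancestor(tree)
            a, b = count.get(tip.name, (0, 0))
            den += depth * (a / tot_a + b / tot_b)
    return num / den if den > 0 else 0.0


class TestUnifrac:
    def test_identical_samples_zero(self):
        t = m.FeatureTable(["A", "B"], ["s1", "s2"],
                           np.array([[3.0, 3.0], [5.0, 5.0]]))
        tree = m.read_tree_string("(A:1,B:1);")
        for weighted in (False, True):
            dm = m.unifrac(t, tree, weighted=weighted)
            assert dm.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_on_star_tree(self):
        t = m.FeatureTable(["A", "B"], ["s1", "s2"],
                           np.array([[4.0, 0.0], [0.0, 6.0]]))
        tree = m.read_tree_string("(A:1,B:1);")
        dm = m.unifrac(t, tree, weighted=False)
        assert dm.data[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_brute_force_on_random_instances(self, weighted):
        rng = np.random.default_rng(42)
        for _ in range(20):
            names = [f"L{k}" for k in range(8)]
            tree = m.read_tree_string(_random_bifurcating_newick(names, rng))
            counts = rng.integers(0, 6, size=(8, 3)).astype(float)
            counts[:, counts.sum(axis=0) == 0] += 1
            table = m.FeatureTable(names, ["a", "b", "c"], counts)
            dm = m.unifrac(table, tree, weighted=weighted)
            for i in range(3):
                for j in range(i + 1, 3):
                    expect = brute_force_unifrac(tree.tree, table, i, j, weighted)
                    assert dm.data[i, j] == pytest.approx(expect, abs=1e-12)

    def test_missing_feature_rejected(self, tiny_table):
        tree = m.read_tree_string("(OTU1:1,OTU2:1);")
        with pytest.raises(ValidationError):
            m.unifrac(tiny_table, tree)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

class TestPcoa:
    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 2))
        dm = m.DistanceMatrix([f"s{i}" for i in range(10)],
                              squareform(pdist(pts)))
        ordn = m.pcoa(dm, k=2)
        from scipy.spatial import procrustes
        _, _, disparity = procrustes(pts, ordn.coordinates.to_numpy())
        assert disparity < 1e-8

    def test_identical_samples_zero_eigenvalues(self):
        dm = m.DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        ordn = m.pcoa(dm, k=2)
        np.testing.assert_allclose(ordn.eigenvalues, 0.0, atol=1e-10)

    def test_distance_roundtrip_full_rank(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(7, 6))
        d = squareform(pdist(pts))
        dm = m.DistanceMatrix([f"s{i}" for i in range(7)], d)
        ordn = m.pcoa(dm, k=6)
        back = squareform(pdist(ordn.coordinates.to_numpy()))
        np.testing.assert_allclose(back, d, atol=1e-8)

    def test_too_many_axes_rejected(self):
        dm = m.DistanceMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValidationError):
            m.pcoa(dm, k=5)


class TestPlsda:
    def _table_with_separating_feature(self, seed=0, signal=True):
        rng = np.random.default_rng(seed)
        n = 20
        counts = rng.uniform(1, 10, size=(15, n))
        if signal:
            counts[0, n // 2:] += 50
        return m.FeatureTable([f"f{i}" for i in range(15)],
                              [f"s{i}" for i in range(n)], counts)

    def test_separates_groups_on_component_one(self):
        t = self._table_with_separating_feature()
        labels = pd.Series(["A"] * 10 + ["B"] * 10, index=t.sample_ids)
        ordn = m.plsda(t, labels, k=2)
        s = ordn.coordinates["PLS1"]
        a, b = s[labels == "A"], s[labels == "B"]
        assert a.max() < b.min() or b.max() < a.min()

    def test_shuffled_labels_no_true_group_alignment(self):
        t = self._table_with_separating_feature()
        true = np.array([0] * 10 + [1] * 10)
        rng = np.random.default_rng(3)
        seps = []
        for _ in range(20):
            lab = pd.Series(rng.permutation(["A"] * 10 + ["B"] * 10),
                            index=t.sample_ids)
            s = m.plsda(t, lab, k=1).coordinates["PLS1"].to_numpy()
            seps.append(s[true == 1].mean() - s[true == 0].mean())
        seps = np.array(seps)
        se = seps.std(ddof=1) / np.sqrt(len(seps))
        assert abs(seps.mean()) < 4 * se + 1e-12

    def test_k_zero_rejected(self):
        t = self._table_with_separating_feature()
        labels = pd.Series(["A"] * 10 + ["B"] * 10, index=t.sample_ids)
        with pytest.raises(ValidationError):
            m.plsda(t, labels, k=0)

    def test_singleton_group_rejected(self):
        t = self._table_with_separating_feature()
        labels = pd.Series(["A"] * 19 + ["B"], index=t.sample_ids)
        with pytest.raises(ValidationError):
            m.plsda(t, labels, k=1)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

class TestAnosim:
    def _toy(self):
        # two tight clusters far apart: all between > all within
        pts = np.array([[0, 0], [0.1, 0], [0, 0.1],
                        [10, 10], [10.1, 10], [10, 10.1]])
        ids = [f"s{i}" for i in range(6)]
        labels = pd.Series(["A", "A", "A", "B", "B", "B"], index=ids)
        return m.DistanceMatrix(ids, squareform(pdist(pts))), labels

    def test_perfect_separation_r_one(self):
        dm, labels = self._toy()
        res = m.anosim(dm, labels, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value >= 1 / 100

    def test_duplicated_groups_r_nonpositive(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [0, 0], [1, 0], [0, 1]], float)
        ids = [f"s{i}" for i in range(6)]
        d = squareform(pdist(pts))
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=ids)
        res = m.anosim(m.DistanceMatrix(ids, d), labels, 99, seed=1)
        assert res.r <= 0

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 3))
        ids = [f"s{i}" for i in range(12)]
        d = squareform(pdist(pts))
        labels = pd.Series(["A"] * 6 + ["B"] * 6, index=ids)
        ours = m.anosim(m.DistanceMatrix(ids, d), labels, 9, seed=0).r
        ref = skbio.stats.distance.anosim(skbio.DistanceMatrix(d, ids),
                                          labels.to_numpy(), permutations=9)
        assert ours == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_singleton_group_rejected(self):
        dm, _ = self._toy()
        labels = pd.Series(["A"] * 5 + ["B"], index=dm.sample_ids)
        with pytest.raises(ValidationError):
            m.anosim(dm, labels, 99, seed=0)


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

class TestDiffAbundance:
    def test_exact_wilcoxon_p(self):
        t = m.FeatureTable(["f"], [f"s{i}" for i in range(6)],
                           np.array([[1, 2, 3, 4, 5, 6]], float))
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=t.sample_ids)
        res = m.diff_abundance(t, labels, relative=False)
        assert res.loc["f", "p"] == pytest.approx(0.1)
        assert res.loc["f", "test"] == "wilcoxon"

    def test_constant_feature_degenerate(self):
        t = m.FeatureTable(["f", "g"], [f"s{i}" for i in range(6)],
                           np.array([[2.0] * 6, [1, 2, 3, 4, 5, 6]]))
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=t.sample_ids)
        res = m.diff_abundance(t, labels, relative=False)
        assert res.loc["f", "p"] == 1.0 and res.loc["f", "degenerate"]

    def test_three_groups_use_kruskal(self):
        rng = np.random.default_rng(0)
        t = m.FeatureTable(["f"], [f"s{i}" for i in range(9)],
                           rng.uniform(size=(1, 9)))
        labels = pd.Series(["A"] * 3 + ["B"] * 3 + ["C"] * 3, index=t.sample_ids)
        res = m.diff_abundance(t, labels, relative=False)
        assert res.loc["f", "test"] == "kruskal_wallis"

    def test_q_at_least_p(self, planted_cohort):
        table, meta, _, _ = planted_cohort
        res = m.diff_abundance(table, meta.group)
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_order_invariance(self, planted_cohort):
        table, meta, _, _ = planted_cohort
        res1 = m.diff_abundance(table, meta.group)
        perm = np.random.default_rng(1).permutation(len(table.sample_ids))
        shuffled = table.select_samples([table.sample_ids[i] for i in perm])
        res2 = m.diff_abundance(shuffled, meta.group)
        pd.testing.assert_series_equal(res1["p"], res2["p"])


# ---------------------------------------------------------------------------
# LDA effect sizes
# ---------------------------------------------------------------------------

class TestLdaEffectSize:
    def test_identical_feature_excluded_at_screen(self):
        rng = np.random.default_rng(0)
        counts = rng.uniform(1, 5, size=(10, 20))
        counts[0] = 3.0  # constant across everyone
        t = m.FeatureTable([f"f{i}" for i in range(10)],
                           [f"s{i}" for i in range(20)], counts)
        labels = pd.Series(["A"] * 10 + ["B"] * 10, index=t.sample_ids)
        res = m.lda_effect_size(t, labels, seed=0)
        assert "f0" not in res.index

    def test_planted_strong_marker_scores_above_cutoff(self):
        hits = 0
        for seed in range(5):
            table, meta, _, truth = m.simulate_cohort(
                {"HC": 30, "IgAN": 30}, n_features=60, n_planted=1,
                effect_size=10.0, depth=10000, seed=seed)
            res = m.lda_effect_size(table, meta.group, seed=seed)
            marker = truth.planted_marker_ids[0]
            hits += marker in res.index and res.loc[marker, "lda_score"] >= 3.0
        assert hits >= 4

    def test_reported_subset_of_survivors(self, planted_cohort):
        table, meta, _, _ = planted_cohort
        screen = m.diff_abundance(table, meta.group)
        survivors = set(screen.index[screen["p"] < 0.05])
        res = m.lda_effect_size(table, meta.group, seed=2)
        assert set(res.index) <= survivors


# ---------------------------------------------------------------------------
# Venn partition
# ---------------------------------------------------------------------------

class TestSharedFeatures:
    def test_identical_presence_all_central(self, planted_cohort):
        table, meta, _, _ = planted_cohort
        # table is dense enough that all features occur in both groups
        regions = m.shared_features(table, meta.group)
        assert regions[("HC", "IgAN")] == len(table.feature_ids)

    def test_disjoint_sets(self):
        counts = np.array([[1.0, 0.0], [0.0, 1.0]])
        t = m.FeatureTable(["f1", "f2"], ["a", "b"], counts)
        labels = pd.Series(["HC", "IgAN"], index=["a", "b"])
        regions = m.shared_features(t, labels)
        assert regions[("HC", "IgAN")] == 0
        assert regions[("HC",)] == 1 and regions[("IgAN",)] == 1

    def test_matches_set_algebra_oracle_three_groups(self):
        rng = np.random.default_rng(9)
        counts = (rng.uniform(size=(30, 9)) < 0.4).astype(float)
        counts[:, counts.sum(axis=0) == 0] += 1
        ids = [f"s{i}" for i in range(9)]
        t = m.FeatureTable([f"f{i}" for i in range(30)], ids, counts)
        labels = pd.Series(["HC"] * 3 + ["IgAN"] * 3 + ["n_IgAN"] * 3, index=ids)
        regions = m.shared_features(t, labels)
        sets = {g: {f for k, f in enumerate(t.feature_ids)
                    if counts[k][(labels == g).to_numpy()].any()}
                for g in ("HC", "IgAN", "n_IgAN")}
        expect_central = sets["HC"] & sets["IgAN"] & sets["n_IgAN"]
        assert regions[("HC", "IgAN", "n_IgAN")] == len(expect_central)
        union = sets["HC"] | sets["IgAN"] | sets["n_IgAN"]
        assert sum(regions.values()) == len(union)
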