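"""Alpha/beta diversity, ordination and nonparametric group tests.

UniFrac is cross-checked against an exhaustive branch-enumeration oracle on
small random trees; the Wilcoxon exact path against full enumeration of
rank assignments.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import skbio

from gradientscope import FeatureTable, SampleMetadata
from gradientscope.diversity import (
    alpha,
    alpha_frame,
    alpha_group_tests,
    bray_curtis,
    kruskal_wallis,
    pcoa,
    permanova,
    significance_stars,
    unifrac,
    wilcoxon_rank_sum,
)
from gradientscope.synthetic import generate_tree
from gradientscope.core_data import Phylogeny


def _table(counts, features=None, samples=None) -> FeatureTable:
    counts = np.asarray(counts)
    features = features or [f"F{i}" for i in range(counts.shape[0])]
    samples = samples or [f"S{j}" for j in range(counts.shape[1])]
    return FeatureTable(pd.DataFrame(counts, index=features, columns=samples))


class TestAlpha:
    def test_uniform_closed_forms(self):
        t = _table([[25], [25], [25], [25]])
        assert alpha(t, "shannon")["S0"] == pytest.approx(2.0)  # log2(4) bits
        assert alpha(t, "simpson")["S0"] == pytest.approx(0.75)  # 1 - 4/16
        assert alpha(t, "observed")["S0"] == 4

    def test_chao1_no_singletons_equals_observed(self):
        t = _table([[5], [5], [5]])
        assert alpha(t, "chao1")["S0"] == pytest.approx(3.0)

    def test_chao1_classic_formula(self):
        # F1=2 singletons, F2=1 doubleton: 3 + 2^2/(2*1) = 5
        t = _table([[1], [1], [2]])
        assert alpha(t, "chao1")["S0"] == pytest.approx(5.0)

    def test_chao1_at_least_observed_and_shannon_maximal_at_uniform(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(30, 5))
        counts[0] += 1  # no empty samples
        t = _table(counts)
        af = alpha_frame(t)
        assert (af["chao1"] >= af["observed"] - 1e-9).all()
        assert ((af["simpson"] >= 0) & (af["simpson"] <= 1)).all()
        k = 30
        uniform = alpha(_table(np.full((k, 1), 10)), "shannon")["S0"]
        assert (af["shannon"] <= uniform + 1e-9).all()

    def test_simpson_invariant_to_feature_order(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 50, size=20)
        t1 = _table(col[:, None])
        t2 = _table(col[::-1][:, None])
        assert alpha(t1, "simpson")["S0"] == pytest.approx(alpha(t2, "simpson")["S0"])


class TestAlphaGroupTests:
    def test_identical_groups_give_f_zero_p_one(self, four_group_metadata):
        values = pd.Series(
            [1.0, 2.0, 3.0, 4.0] * 4, index=four_group_metadata.sample_ids
        )
        res = alpha_group_tests(values, four_group_metadata)
        assert res.anova_f == pytest.approx(0.0)
        assert res.anova_p == pytest.approx(1.0)
        t_cw = res.pairwise.query("group1 == 'captive' and group2 == 'wild'")["t"]
        assert float(t_cw.iloc[0]) == pytest.approx(0.0)

    def test_power_on_three_sd_gap(self):
        rng = np.random.default_rng(11)
        hits = 0
        meta = SampleMetadata(pd.DataFrame(
            {"individual_id": [f"i{k}" for k in range(40)],
             "lifestyle": ["captive"] * 20 + ["wild"] * 20},
            index=[f"s{k}" for k in range(40)]))
        for _ in range(100):
            a = rng.normal(0, 1, 20)
            b = rng.normal(3, 1, 20)
            values = pd.Series(np.concatenate([a, b]), index=meta.sample_ids)
            res = alpha_group_tests(values, meta)
            p = float(res.pairwise["p"].iloc[0])
            hits += p < 0.001
        assert hits >= 95

    def test_singleton_group_excluded_with_note(self):
        meta = SampleMetadata(pd.DataFrame(
            {"individual_id": ["a", "b", "c", "d", "e"],
             "lifestyle": ["captive", "captive", "wild", "wild", "semi-wild"]},
            index=list("vwxyz")))
        values = pd.Series([1.0, 2.0, 5.0, 6.0, 3.0], index=list("vwxyz"))
        res = alpha_group_tests(values, meta)
        assert res.excluded_groups == ["semi-wild"]
        assert set(res.pairwise["group1"]) | set(res.pairwise["group2"]) == {
            "captive", "wild"}

    def test_star_bins(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == "ns"


class TestBrayCurtis:
    def test_identity_disjoint_and_hand_value(self):
        t = _table([[2, 4, 2], [2, 0, 2]])
        dm = bray_curtis(t)
        assert dm["S0", "S2"] == pytest.approx(0.0)
        assert dm["S0", "S1"] == pytest.approx(0.5)  # (|2-4|+|2-0|)/8
        disjoint = _table([[3, 0], [0, 7]])
        assert bray_curtis(disjoint)["S0", "S1"] == pytest.approx(1.0)


def _unifrac_oracle(tree: Phylogeny, counts: dict, s1: str, s2: str,
                    weighted: bool, normalized: bool = False) -> float:
    """Exhaustive branch enumeration over every edge of the tree."""
    total1 = sum(counts[s1].values())
    total2 = sum(counts[s2].values())
    shared = unique = 0.0
    w_num = w_den = 0.0
    for node in tree.tree.traverse(include_self=False):
        length = node.length or 0.0
        leaves = {t.name for t in node.tips()} or {node.name}
        a_count = sum(counts[s1].get(l, 0) for l in leaves)
        b_count = sum(counts[s2].get(l, 0) for l in leaves)
        a, b = a_count / total1, b_count / total2
        if a_count > 0 and b_count > 0:
            shared += length
        elif a_count > 0 or b_count > 0:
            unique += length
        w_num += length * abs(a - b)
        w_den += length * (a + b)
    if weighted:
        return w_num / w_den if normalized else w_num
    return unique / (unique + shared) if unique + shared > 0 else 0.0


class TestUniFrac:
    def _tree(self, newick: str) -> Phylogeny:
        import io

        return Phylogeny(skbio.TreeNode.read(io.StringIO(newick)))

    def test_identical_presence_gives_zero(self):
        tree = self._tree("((A:1,B:1):1,(C:1,D:1):1):0;")
        t = _table([[1, 2], [1, 1], [0, 0], [0, 0]], features=list("ABCD"))
        dm = unifrac(t, tree, weighted=False)
        assert dm["S0", "S1"] == pytest.approx(0.0)

    def test_disjoint_clades_give_one(self):
        tree = self._tree("((A:1,B:1):1,(C:1,D:1):1):0;")
        t = _table([[1, 0], [1, 0], [0, 1], [0, 1]], features=list("ABCD"))
        assert unifrac(t, tree, weighted=False)["S0", "S1"] == pytest.approx(1.0)

    def test_partial_overlap_hand_value(self):
        # samples {A,B} vs {A,C}: unique branches B:1, C:1 and the two
        # internal edges (observed 5 edges of length 1 + shared A) -> 3/5
        tree = self._tree("((A:1,B:1):1,(C:1,D:1):1):0;")
        t = _table([[1, 1], [1, 0], [0, 1], [0, 0]], features=list("ABCD"))
        assert unifrac(t, tree, weighted=False)["S0", "S1"] == pytest.approx(0.6)

    @pytest.mark.parametrize("weighted,normalized", [
        (False, False), (True, False), (True, True)])
    def test_matches_exhaustive_enumeration_on_random_trees(self, weighted, normalized):
        rng = np.random.default_rng(12)
        for case in range(40):
            n_leaves = int(rng.integers(3, 7))
            ids = [f"L{i}" for i in range(n_leaves)]
            tree = generate_tree(ids, seed=1000 + case)
            counts = rng.integers(0, 6, size=(n_leaves, 2))
            counts[rng.integers(0, n_leaves), :] += 1  # non-empty samples
            t = _table(counts, features=ids)
            dm = unifrac(t, tree, weighted=weighted, normalized=normalized)
            cdict = {s: dict(zip(ids, t.data[s])) for s in t.sample_ids}
            expected = _unifrac_oracle(tree, cdict, "S0", "S1", weighted, normalized)
            assert dm["S0", "S1"] == pytest.approx(expected, abs=1e-12)

    def test_missing_feature_named_in_error(self):
        tree = self._tree("((A:1,B:1):1,(C:1,D:1):1):0;")
        t = _table([[1, 1], [1, 1]], features=["A", "MISSING"])
        with pytest.raises(ValueError, match="MISSING"):
            unifrac(t, tree)


class TestPCoA:
    def test_collinear_points_embed_exactly(self):
        pos = np.array([0.0, 1.0, 3.0])
        d = np.abs(pos[:, None] - pos[None])
        dm = skbio.DistanceMatrix(d, ids=list("abc"))
        res = pcoa(dm, n_axes=1)
        axis1 = res.samples.iloc[:, 0].to_numpy()
        recon = np.abs(axis1[:, None] - axis1[None])
        np.testing.assert_allclose(recon, d, atol=1e-9)

    def test_duplicated_sample_gets_identical_coordinates(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 0], [0, 2]])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(skbio.DistanceMatrix(d, ids=list("abcd")), n_axes=2)
        np.testing.assert_allclose(res.samples.loc["b"], res.samples.loc["c"],
                                   atol=1e-9)

    def test_gower_identity_for_euclidean_input(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(skbio.DistanceMatrix(d, ids=[f"s{i}" for i in range(8)]))
        centered = pts - pts.mean(axis=0)
        total_mass = (centered**2).sum()
        assert res.eigvals[res.eigvals > 0].sum() == pytest.approx(total_mass, rel=1e-9)


class TestPermanova:
    def _meta(self, labels):
        return SampleMetadata(pd.DataFrame(
            {"individual_id": [f"i{k}" for k in range(len(labels))],
             "lifestyle": labels},
            index=[f"s{k}" for k in range(len(labels))]))

    def test_minimum_p_is_one_over_nperm_plus_one(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal(0, 0.05, (10, 2)), rng.normal(5, 0.05, (10, 2))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = skbio.DistanceMatrix(d, ids=[f"s{k}" for k in range(20)])
        meta = self._meta(["captive"] * 10 + ["wild"] * 10)
        res = permanova(dm, meta, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_group_of_size_one_rejected(self):
        d = np.ones((3, 3)) - np.eye(3)
        dm = skbio.DistanceMatrix(d, ids=["s0", "s1", "s2"])
        meta = self._meta(["captive", "captive", "wild"])
        with pytest.raises(ValueError, match="size 1"):
            permanova(dm, meta, n_perm=99, seed=0)

    def test_invariant_to_joint_row_and_label_permutation(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = ["captive"] * 6 + ["wild"] * 6
        ids = [f"s{k}" for k in range(12)]
        dm = skbio.DistanceMatrix(d, ids=ids)
        res1 = permanova(dm, self._meta(labels), n_perm=99, seed=7)
        perm = rng.permutation(12)
        dm2 = skbio.DistanceMatrix(d[np.ix_(perm, perm)],
                                   ids=[ids[i] for i in perm])
        meta2 = SampleMetadata(pd.DataFrame(
            {"individual_id": [f"i{k}" for k in perm],
             "lifestyle": [labels[i] for i in perm]},
            index=[ids[i] for i in perm]))
        res2 = permanova(dm2, meta2, n_perm=99, seed=7)
        assert res1.pseudo_f == pytest.approx(res2.pseudo_f)


class TestRankTests:
    def test_kruskal_hand_value(self):
        # ranks 1..6 in three groups of two: H = 32/7
        h, p, tied = kruskal_wallis([1, 2, 3, 4, 5, 6],
                                    ["a", "a", "b", "b", "c", "c"])
        assert h == pytest.approx(32 / 7)
        assert not tied

    def test_kruskal_all_identical_flagged(self):
        h, p, tied = kruskal_wallis([2, 2, 2, 2], ["a", "a", "b", "b"])
        assert tied and p == 1.0

    def test_wilcoxon_exact_hand_value(self):
        # most extreme split of 6 ranks: two-sided p = 2 / C(6,3) = 0.1
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == pytest.approx(6.0)
        assert p == pytest.approx(0.1)

    def test_same_multiset_not_significant(self):
        _, p = wilcoxon_rank_sum([1.5, 2.5, 3.5], [1.5, 2.5, 3.5])
        assert p >= 0.9

    def test_exact_path_matches_full_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n1, n2 = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            pool = rng.permutation(np.arange(1, n1 + n2 + 1)).astype(float)
            x, y = pool[:n1], pool[n1:]
            _, p = wilcoxon_rank_sum(x, y)
            # enumerate all assignments of ranks to the first sample
            ranks = np.arange(1, n1 + n2 + 1)
            obs = sum(np.searchsorted(np.sort(np.concatenate([x, y])), x) + 1)
            stats = [sum(c) for c in itertools.combinations(ranks, n1)]
            mean = n1 * (n1 + n2 + 1) / 2
            extreme = sum(abs(s - mean) >= abs(obs - mean) - 1e-9 for s in stats)
            assert p == pytest.approx(extreme / len(stats), abs=1e-12)
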