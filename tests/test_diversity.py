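import numpy as np
import pytest
import skbio

from gutdiet import diversity, preprocess
from gutdiet.preprocess import DegenerateInputError

from conftest import make_table, random_tree


# --- explicit per-branch enumeration oracles (independent of BranchMatrix) --

def branch_table(tree):
    return [
        (frozenset(t.name for t in node.tips(include_self=True)), node.length)
        for node in tree.postorder(include_self=False)
    ]


def brute_faith(tree, observed: set) -> float:
    return sum(l for leaves, l in branch_table(tree) if leaves & observed)


def brute_unweighted(tree, set_a: set, set_b: set) -> float:
    unique = either = 0.0
    for leaves, l in branch_table(tree):
        in_a, in_b = bool(leaves & set_a), bool(leaves & set_b)
        if in_a or in_b:
            either += l
        if in_a != in_b:
            unique += l
    return unique / either if either else 0.0


def brute_weighted(tree, prop_a: dict, prop_b: dict) -> float:
    total = 0.0
    for leaves, l in branch_table(tree):
        pa = sum(prop_a.get(x, 0.0) for x in leaves)
        pb = sum(prop_b.get(x, 0.0) for x in leaves)
        total += l * abs(pa - pb)
    return total


class TestChao1:
    @pytest.mark.parametrize(
        "counts,expected",
        [([2, 2, 2], 3.0), ([1, 1, 2, 4], 4.5), ([5, 3, 1, 1], 5.0)],
    )
    def test_hand_cases(self, counts, expected):
        assert diversity.chao1(np.array(counts)) == pytest.approx(expected)

    def test_at_least_observed_richness(self, rng):
        counts = rng.integers(0, 10, size=50)
        counts[0] = 1
        assert diversity.chao1(counts) >= (counts > 0).sum()

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            diversity.chao1(np.zeros(3, dtype=int))


class TestShannon:
    def test_single_taxon_zero(self):
        assert diversity.shannon(np.array([0, 7, 0])) == 0.0

    @pytest.mark.parametrize("s", [2, 4, 16, 64])
    def test_uniform_closed_form(self, s):
        assert diversity.shannon(np.ones(s)) == pytest.approx(np.log(s), abs=1e-12)

    def test_hand_case(self):
        expected = -(0.25 * np.log(0.25) * 2 + 0.5 * np.log(0.5))
        assert diversity.shannon(np.array([1, 1, 2])) == pytest.approx(expected)

    def test_base_flag(self):
        assert diversity.shannon(np.ones(8), base=2) == pytest.approx(3.0)


class TestFaithPD:
    def test_star_tree(self):
        tree = skbio.TreeNode.read(["(A:1,B:1,C:1);"])
        assert diversity.faith_pd([1, 1, 1], tree, ["A", "B", "C"]) == pytest.approx(3.0)
        assert diversity.faith_pd([1, 0, 0], tree, ["A", "B", "C"]) == pytest.approx(1.0)

    def test_caterpillar_union_of_paths(self):
        tree = skbio.TreeNode.read(["((A:1,B:1):1,C:2):0;"])
        assert diversity.faith_pd([1, 0, 1], tree, ["A", "B", "C"]) == pytest.approx(4.0)

    def test_matches_brute_force_on_random_trees(self, rng):
        for n in (4, 6, 9):
            tree = random_tree([f"L{i}" for i in range(n)], rng)
            counts = rng.integers(0, 3, size=n)
            counts[0] = 1
            observed = {f"L{i}" for i in range(n) if counts[i] > 0}
            assert diversity.faith_pd(counts, tree, [f"L{i}" for i in range(n)]) == (
                pytest.approx(brute_faith(tree, observed), abs=1e-10))

    def test_missing_taxon_named(self, rng):
        tree = random_tree(["A", "B"], rng)
        with pytest.raises(ValueError, match="ghost"):
            diversity.faith_pd([1, 1, 1], tree, ["A", "B", "ghost"])


class TestBrayCurtis:
    def test_hand_cases(self):
        cm = preprocess.to_proportions(make_table([[3, 1], [1, 3], [4, 0], [0, 2]]))
        d = diversity.bray_curtis(cm)
        assert d["S0", "S0"] == 0.0
        assert d["S2", "S3"] == pytest.approx(1.0)  # disjoint supports
        assert d["S0", "S1"] == pytest.approx(0.5)  # (0.75,0.25) vs (0.25,0.75)

    def test_range_and_symmetry(self, rng):
        cm = preprocess.to_proportions(make_table(rng.integers(0, 20, (10, 6)) + 1))
        d = diversity.bray_curtis(cm).data
        assert ((d >= 0) & (d <= 1)).all()
        np.testing.assert_allclose(d, d.T)


class TestUniFrac:
    def test_identical_presence_zero(self, rng):
        tree = random_tree(["A", "B", "C"], rng)
        table = make_table([[1, 2, 0], [5, 1, 0]], taxon_ids=["A", "B", "C"])
        d = diversity.unweighted_unifrac(table, tree)
        assert d["S0", "S1"] == pytest.approx(0.0)

    def test_disjoint_root_clades_distance_one(self):
        tree = skbio.TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"])
        table = make_table([[1, 1, 0, 0], [0, 0, 1, 1]], taxon_ids=list("ABCD"))
        d = diversity.unweighted_unifrac(table, tree)
        assert d["S0", "S1"] == pytest.approx(1.0)

    def test_identical_compositions_weighted_zero(self, rng):
        tree = random_tree(["A", "B", "C"], rng)
        table = make_table([[2, 4, 6], [1, 2, 3]], taxon_ids=["A", "B", "C"])
        d = diversity.weighted_unifrac(table, tree)
        assert d["S0", "S1"] == pytest.approx(0.0, abs=1e-12)

    def test_weighted_three_leaf_hand_sum(self):
        tree = skbio.TreeNode.read(["((A:1,B:1):1,C:1);"])
        table = make_table([[1, 0, 0], [0, 1, 0]], taxon_ids=["A", "B", "C"])
        d = diversity.weighted_unifrac(table, tree)
        # branches: A (|1-0|=1), B (|0-1|=1), AB-stem (|1-1|=0), C (0) -> 2
        assert d["S0", "S1"] == pytest.approx(2.0)

    @pytest.mark.parametrize("n_leaves", [2, 3, 4, 5, 6])
    def test_both_variants_match_brute_force(self, n_leaves, rng):
        leaf_names = [f"L{i}" for i in range(n_leaves)]
        for rep in range(5):
            tree = random_tree(leaf_names, rng)
            counts = rng.integers(0, 6, size=(3, n_leaves))
            counts[:, 0] += 1
            table = make_table(counts, taxon_ids=leaf_names)
            uu = diversity.unweighted_unifrac(table, tree)
            wu = diversity.weighted_unifrac(table, tree)
            props = counts / counts.sum(axis=1, keepdims=True)
            for i in range(3):
                for j in range(i + 1, 3):
                    set_i = {leaf_names[k] for k in range(n_leaves) if counts[i, k]}
                    set_j = {leaf_names[k] for k in range(n_leaves) if counts[j, k]}
                    assert uu.data[i, j] == pytest.approx(
                        brute_unweighted(tree, set_i, set_j), abs=1e-10)
                    assert wu.data[i, j] == pytest.approx(
                        brute_weighted(tree, dict(zip(leaf_names, props[i])),
                                       dict(zip(leaf_names, props[j]))), abs=1e-10)

    def test_matches_skbio_reference(self, rng):
        # independent library cross-check on a larger random instance
        leaf_names = [f"L{i}" for i in range(12)]
        tree = random_tree(leaf_names, rng)
        counts = rng.integers(0, 8, size=(5, 12))
        counts[:, 0] += 1
        table = make_table(counts, taxon_ids=leaf_names)
        ref_u = skbio.diversity.beta_diversity(
            "unweighted_unifrac", counts, ids=table.sample_ids,
            tree=tree, taxa=leaf_names)
        ref_w = skbio.diversity.beta_diversity(
            "weighted_unifrac", counts, ids=table.sample_ids,
            tree=tree, taxa=leaf_names)
        np.testing.assert_allclose(
            diversity.unweighted_unifrac(table, tree).data, ref_u.data, atol=1e-10)
        np.testing.assert_allclose(
            diversity.weighted_unifrac(table, tree).data, ref_w.data, atol=1e-10)

    def test_normalized_weighted_bounded(self, rng):
        leaf_names = [f"L{i}" for i in range(8)]
        tree = random_tree(leaf_names, rng)
        counts = rng.integers(0, 9, size=(6, 8))
        counts[:, 0] += 1
        table = make_table(counts, taxon_ids=leaf_names)
        d = diversity.weighted_unifrac(table, tree, normalized=True).data
        assert ((d >= 0) & (d <= 1 + 1e-12)).all()


class TestDistanceProperties:
    def test_metric_axioms_and_triangle_inequality(self, rng):
        leaf_names = [f"L{i}" for i in range(10)]
        tree = random_tree(leaf_names, rng)
        counts = rng.integers(0, 10, size=(12, 10))
        counts[:, 0] += 1
        table = make_table(counts, taxon_ids=leaf_names)
        mats = [
            diversity.bray_curtis(preprocess.to_proportions(table)).data,
            diversity.unweighted_unifrac(table, tree).data,
        ]
        triples = rng.integers(0, 12, size=(120, 3))
        for d in mats:
            assert (np.diag(d) == 0).all()
            assert (d >= 0).all()
            np.testing.assert_allclose(d, d.T, atol=1e-12)
            for i, j, k in triples:
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-10

    def test_taxon_order_permutation_invariance(self, rng):
        leaf_names = [f"L{i}" for i in range(7)]
        tree = random_tree(leaf_names, rng)
        counts = rng.integers(0, 10, size=(4, 7))
        counts[:, 0] += 1
        table = make_table(counts, taxon_ids=leaf_names)
        perm = rng.permutation(7)
        table_p = make_table(counts[:, perm], taxon_ids=[leaf_names[p] for p in perm])
        for fn in (diversity.unweighted_unifrac, diversity.weighted_unifrac):
            np.testing.assert_allclose(
                fn(table, tree).data, fn(table_p, tree).data, atol=1e-12)
        a1 = diversity.alpha_diversity(table, tree)
        a2 = diversity.alpha_diversity(table_p, tree)
        np.testing.assert_allclose(a1.to_numpy(), a2.to_numpy(), atol=1e-12)

    def test_phylum_aggregation_commutes_with_shannon(self, rng):
        lineages = {
            f"T{j}": {"phylum": f"p{j % 3}", "genus": f"g{j}"} for j in range(9)
        }
        table = make_table(rng.integers(0, 30, (5, 9)) + 1, lineages=lineages)
        agg = preprocess.aggregate(table, "phylum")
        direct = np.stack([
            table.counts.T.groupby(table.lineages["phylum"].to_numpy()).sum().T.loc[s]
            for s in table.sample_ids
        ])
        for i, s in enumerate(agg.sample_ids):
            assert diversity.shannon(agg.counts.loc[s].to_numpy()) == pytest.approx(
                diversity.shannon(direct[i]), abs=1e-12)
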