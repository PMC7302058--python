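import itertools

import numpy as np
import pytest

from partcong.trees import Tree, RootedTree, popcount
from partcong.treemath import (
    tree_splits, rf_distance, matching_distance, mean_nnd,
    majority_rule_consensus, tree_shape_stats,
)
from partcong.synthetic_data import simulate_tree_pair

TAXA5 = list("ABCDE")


def T(newick, taxa=TAXA5):
    return Tree.from_newick(newick, taxa=taxa)


def random_tree(n, seed):
    return simulate_tree_pair(n, 0, np.random.default_rng(seed)).tree1


class TestSplits:
    def test_read_off_edges(self):
        t = T("((A,B),C,(D,E));")
        assert tree_splits(t) == frozenset({0b11000, 0b11100})

    def test_binary_tree_has_n_minus_3(self):
        t = random_tree(6, 0)
        assert len(tree_splits(t)) == 3

    def test_star_has_none(self):
        assert tree_splits(Tree(TAXA5, [])) == frozenset()

    def test_newick_roundtrip(self):
        t = random_tree(8, 3)
        assert Tree.from_newick(t.to_newick(), taxa=t.taxa) == t

    def test_rooted_newick_kept_as_written(self):
        rt = RootedTree.from_newick("((A,B),(C,D));")
        kids = sorted(popcount(c.clade) for c in rt.root.children)
        assert kids == [2, 2]


class TestRF:
    def test_identical_zero(self):
        t = random_tree(7, 1)
        assert rf_distance(t, t) == 0

    def test_one_split_swap(self):
        a = T("((A,B),C,(D,E));")
        b = T("((A,C),B,(D,E));")
        assert rf_distance(a, b) == 2

    def test_no_shared_splits_maximal(self):
        a = T("((A,B),C,(D,E));")
        b = T("((A,D),C,(B,E));")
        assert not (a.splits & b.splits)
        assert rf_distance(a, b) == 4

    def test_leafset_mismatch_raises(self):
        a = random_tree(6, 0)
        b = random_tree(7, 0)
        with pytest.raises(ValueError):
            rf_distance(a, b)


def brute_matching(t1, t2):
    n = t1.n_taxa
    a = sorted(t1.splits)
    b = sorted(t2.splits)
    size = max(len(a), len(b))
    A = a + ["dummy"] * (size - len(a))
    B = b + ["dummy"] * (size - len(b))

    def cost(x, y):
        if x == "dummy" and y == "dummy":
            return 0
        if x == "dummy":
            p = popcount(y)
            return min(p, n - p)
        if y == "dummy":
            p = popcount(x)
            return min(p, n - p)
        p = popcount(x ^ y)
        return min(p, n - p)

    return min(
        sum(cost(A[i], B[perm[i]]) for i in range(size))
        for perm in itertools.permutations(range(size))
    )


class TestMatchingDistance:
    def test_identical_zero(self):
        t = random_tree(8, 2)
        assert matching_distance(t, t) == 0

    def test_hand_example(self):
        a = T("((A,B),C,(D,E));")
        b = T("((A,C),B,(D,E));")
        # DE pairs with DE at 0; AB vs AC differ by {B,C}: cost 2
        assert matching_distance(a, b) == 2

    def test_matches_brute_force(self):
        for seed in range(10):
            pair = simulate_tree_pair(7, 3, np.random.default_rng(seed))
            assert matching_distance(pair.tree1, pair.tree2) == brute_matching(
                pair.tree1, pair.tree2)

    def test_unequal_split_counts_use_dummy_padding(self):
        full = T("((A,B),C,(D,E));")
        poly = Tree(TAXA5, [0b11000])        # DE only
        assert matching_distance(full, poly) == brute_matching(full, poly)
        assert matching_distance(full, poly) == matching_distance(poly, full)

    def test_zero_iff_rf_zero(self):
        for seed in range(8):
            pair = simulate_tree_pair(8, seed % 3, np.random.default_rng(seed))
            md = matching_distance(pair.tree1, pair.tree2)
            rf = rf_distance(pair.tree1, pair.tree2)
            assert (md == 0) == (rf == 0)

    def test_metric_properties_on_random_triples(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            ts = [simulate_tree_pair(7, 2, rng).tree2 for _ in range(3)]
            ts = [Tree(ts[0].taxa, t.splits) for t in ts]
            for d in (rf_distance, matching_distance):
                d01, d10 = d(ts[0], ts[1]), d(ts[1], ts[0])
                assert d01 == d10
                assert d(ts[0], ts[0]) == 0
                assert d01 <= d(ts[0], ts[2]) + d(ts[2], ts[1])


class TestMeanNND:
    def test_same_sets_zero(self):
        ts = [random_tree(6, s) for s in range(3)]
        ts = [Tree(ts[0].taxa, t.splits) for t in ts]
        assert mean_nnd(ts, ts, metric="RF") == 0

    def test_singletons_reduce_to_pairwise(self):
        a, b = simulate_tree_pair(7, 2, np.random.default_rng(0)).tree1, None
        pair = simulate_tree_pair(7, 2, np.random.default_rng(0))
        a, b = pair.tree1, pair.tree2
        assert mean_nnd([a], [b], metric="matching") == matching_distance(a, b)

    def test_asymmetric_sets_arithmetic(self):
        # A = {t1, t2}, B = {t1}, d(t1,t2) = 2 -> ((0+2)/2 + 0)/2 = 0.5
        t1 = T("((A,B),C,(D,E));")
        t2 = T("((A,C),B,(D,E));")
        assert rf_distance(t1, t2) == 2
        assert mean_nnd([t1, t2], [t1], metric="RF") == pytest.approx(0.5)
        assert mean_nnd([t1, t2], [t1], metric="RF",
                        symmetric=False) == pytest.approx(1.0)

    def test_duplicates_do_not_change_value(self):
        pair = simulate_tree_pair(7, 2, np.random.default_rng(4))
        a, b = pair.tree1, pair.tree2
        v1 = mean_nnd([a], [b], metric="matching")
        v2 = mean_nnd([a, a, a], [b, b], metric="matching")
        assert v1 == pytest.approx(v2)

    def test_cap_subsamples_deterministically(self):
        trees = [Tree(TAXA5, s.splits) for s in
                 (T("((A,B),C,(D,E));"), T("((A,C),B,(D,E));"),
                  T("((A,D),C,(B,E));"))]
        v1 = mean_nnd(trees, trees[:1], metric="RF", cap=2, seed=9)
        v2 = mean_nnd(trees, trees[:1], metric="RF", cap=2, seed=9)
        assert v1 == v2


class TestConsensus:
    def test_identical_trees_returned(self):
        t = random_tree(7, 5)
        assert majority_rule_consensus([t, t, t]) == t

    def test_majority_split_retained(self):
        a, b, c = (T("((A,B),C,(D,E));"), T("((A,B),D,(C,E));"),
                   T("((A,C),B,(D,E));"))
        cons = majority_rule_consensus([a, b, c], plus_compatible=False)
        assert 0b11100 in cons.splits          # AB|CDE, present in 2 of 3

    def test_plus_compatible_adds_minority_split(self):
        a = T("((A,B),C,(D,E));")
        b = T("((A,B),D,(C,E));")
        c = T("((A,B),E,(C,D));")
        plain = majority_rule_consensus([a, b, c], plus_compatible=False)
        plus = majority_rule_consensus([a, b, c], plus_compatible=True)
        assert len(plus.splits) == len(plain.splits) + 1

    def test_consensus_splits_mutually_compatible(self):
        from partcong.trees import splits_compatible
        for seed in range(5):
            rng = np.random.default_rng(seed)
            base = simulate_tree_pair(8, 0, rng).tree1
            trees = [base] + [
                Tree(base.taxa,
                     simulate_tree_pair(8, 2, np.random.default_rng(seed * 7 + i)).tree2.splits)
                for i in range(4)
            ]
            cons = majority_rule_consensus(trees)
            for s, t in itertools.combinations(cons.splits, 2):
                assert splits_compatible(s, t)


class TestShapeStats:
    def test_balanced_four_leaf(self):
        colless, res = tree_shape_stats("((A,B),(C,D));")
        assert colless == 0 and res == 100.0

    def test_ladder_four_leaf(self):
        colless, res = tree_shape_stats("(((A,B),C),D);")
        assert colless == 3 and res == 100.0

    def test_rooted_star_resolution(self):
        colless, res = tree_shape_stats("(A,B,C,D,E);")
        assert res == pytest.approx(25.0)
        assert colless == 0

    def test_unrooted_tree_rooted_on_taxon(self):
        t = T("((A,B),C,(D,E));")
        colless, res = tree_shape_stats(t, root_on="A")
        assert res == 100.0

    def test_missing_root_taxon_raises(self):
        t = T("((A,B),C,(D,E));")
        with pytest.raises(ValueError):
            tree_shape_stats(t, root_on="Z")
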