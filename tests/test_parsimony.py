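import itertools

import numpy as np
import pytest

from partcong.matrix_io import is_informative
from partcong.parsimony import (
    SearchConfig, DESK_CONFIG, TreeSet,
    fitch_length, character_step_bounds, heuristic_search,
    exhaustive_search, collapse_and_dedupe, ensemble_indices,
)
from partcong.trees import Tree
from conftest import make_matrix, random_binary_matrix, split_indicator_matrix

TAXA4 = list("ABCD")
GOOD = Tree(TAXA4, [0b1100])     # ((A,B),(C,D))
BAD = Tree(TAXA4, [0b1010])      # ((A,C),(B,D))


class TestFitchLength:
    def test_one_change_on_matching_tree(self):
        m = make_matrix([[0], [0], [1], [1]], taxa=TAXA4)
        assert fitch_length(GOOD, m, [0]) == 1

    def test_two_changes_on_conflicting_tree(self):
        m = make_matrix([[0], [0], [1], [1]], taxa=TAXA4)
        assert fitch_length(BAD, m, [0]) == 2

    def test_all_missing_costs_nothing(self):
        m = make_matrix(np.zeros((4, 1), int), taxa=TAXA4,
                        missing=[(i, 0) for i in range(4)])
        assert fitch_length(GOOD, m, [0]) == 0

    def test_polymorphic_cell_satisfiable_free(self):
        # B scored {0,1}: no change needed anywhere on ((A,B),(C,D))
        m = make_matrix([[0], [0], [1], [1]], taxa=TAXA4)
        masks = m.masks.copy()
        masks[1, 0] = 0b11
        m2 = make_matrix([[0], [0], [1], [1]], taxa=TAXA4)
        m2.masks[1, 0] = np.uint32(0b11)
        assert fitch_length(GOOD, m2, [0]) == 1
        assert fitch_length(BAD, m2, [0]) == 1   # B can take state 1

    def test_matches_brute_force_assignment_enumeration(self):
        """DP length equals the minimum over all internal state labellings."""
        rng = np.random.default_rng(7)
        for trial in range(3):
            k = 2 + trial % 2
            states = rng.integers(0, k, (6, 5))
            m = make_matrix(states, alphabet=k)
            tree = Tree(m.taxa, [0b000110, 0b011000, 0b111000])
            # rooted clades: internal nodes of the unrooted tree = 4
            from partcong.trees import RootedTree
            rt = RootedTree.from_unrooted(tree, root_on=m.taxa[0])
            internals = [v for v in rt.nodes() if v.children]

            def brute(char):
                best = None
                leaf = states[:, char]
                for assign in itertools.product(range(k), repeat=len(internals)):
                    lab = {id(v): s for v, s in zip(internals, assign)}
                    cost = 0
                    stack = [rt.root]
                    while stack:
                        v = stack.pop()
                        sv = lab[id(v)] if v.children else leaf[v.taxon]
                        for c in v.children:
                            sc = lab[id(c)] if c.children else leaf[c.taxon]
                            cost += sv != sc
                            stack.append(c)
                    best = cost if best is None else min(best, cost)
                return best

            expect = sum(brute(c) for c in range(5))
            assert fitch_length(tree, m, range(5)) == expect

    def test_invariant_to_taxon_order(self, rng):
        m = random_binary_matrix(rng, 6, 8, missing_rate=0.1)
        t = exhaustive_search(m, range(8)).trees[0]
        perm = list(rng.permutation(6))
        m2 = m.subset(taxa=[m.taxa[i] for i in perm])
        t2 = Tree(m2.taxa, [_remap_split(s, perm, 6) for s in t.splits])
        assert fitch_length(t, m, range(8)) == fitch_length(t2, m2, range(8))


def _remap_split(split, perm, n):
    out = 0
    for new_i, old_i in enumerate(perm):
        if split >> old_i & 1:
            out |= 1 << new_i
    return out


class TestStepBounds:
    @pytest.mark.parametrize("column, m_exp, g_exp", [
        ([0, 0, 1, 1], 1, 2),
        ([0, 0, 0, 0], 0, 0),
        ([0, 1, 2, 2], 2, 2),
    ])
    def test_examples(self, column, m_exp, g_exp):
        mat = make_matrix(np.array([column]).T, alphabet=3)
        assert character_step_bounds(mat, 0) == (m_exp, g_exp)

    def test_three_singleton_states(self):
        mat = make_matrix(np.array([[0], [1], [2]]), alphabet=3)
        assert character_step_bounds(mat, 0) == (2, 2)

    def test_polymorphic_cells_excluded(self):
        mat = make_matrix([[0], [0], [1], [1]])
        mat.masks[0, 0] = np.uint32(0b11)
        assert character_step_bounds(mat, 0) == (1, 1)


class TestHeuristicSearch:
    def test_matches_exhaustive_on_small_matrices(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 8))
            m = random_binary_matrix(rng, n, 12, missing_rate=0.15)
            hs = heuristic_search(m, range(12), DESK_CONFIG, seed=seed)
            ex = exhaustive_search(m, range(12))
            assert hs.score == ex.score

    def test_deterministic_given_seed(self, rng):
        m = random_binary_matrix(rng, 8, 15)
        a = heuristic_search(m, range(15), DESK_CONFIG, seed=5)
        b = heuristic_search(m, range(15), DESK_CONFIG, seed=5)
        assert a.score == b.score
        assert {t.splits for t in a} == {t.splits for t in b}

    def test_recovers_tree_from_congruent_characters(self, rng):
        from partcong.synthetic_data import simulate_tree_pair
        true = simulate_tree_pair(6, 0, rng).tree1
        m = split_indicator_matrix(true, copies=7)   # ~20 congruent chars
        ts = heuristic_search(m, range(m.n_chars), DESK_CONFIG, seed=0)
        assert len(ts) == 1
        assert ts.trees[0].splits == true.splits

    def test_star_tree_when_no_informative_characters(self):
        m = make_matrix([[0], [0], [0], [1]])
        with pytest.warns(UserWarning):
            ts = heuristic_search(m, [0], DESK_CONFIG, seed=0)
        assert len(ts) == 1 and not ts.trees[0].splits

    def test_too_few_taxa_raises(self):
        m = make_matrix([[0], [1], [0]])
        with pytest.raises(ValueError):
            heuristic_search(m, [0], DESK_CONFIG)

    def test_beats_random_trees(self, rng):
        from partcong.synthetic_data import simulate_tree_pair
        m = random_binary_matrix(rng, 9, 20, missing_rate=0.1)
        ts = heuristic_search(m, range(20), DESK_CONFIG, seed=3)
        for seed in range(5):
            t = simulate_tree_pair(9, 0, np.random.default_rng(seed)).tree1
            t = Tree(m.taxa, t.splits)
            assert ts.score <= fitch_length(t, m, range(20))


class TestCollapse:
    def test_unsupported_branch_collapses_to_polytomy(self):
        # only character 0011 supports AB|CD; characters cannot place E:
        # the E-adjacent branch has zero minimum length
        m = make_matrix([[0], [0], [1], [1], [0]], taxa=list("ABCDE"),
                        missing=[(4, 0)])
        binary = TreeSet([Tree(list("ABCDE"), [0b01100, 0b11100])], 1,
                         tuple("ABCDE"))
        out = collapse_and_dedupe(binary, m, [0])
        assert len(out.trees[0].splits) < 2

    def test_supported_tree_unchanged(self):
        m = make_matrix([[0, 0], [0, 0], [1, 0], [1, 1], [1, 1]],
                        taxa=list("ABCDE"))
        ts = TreeSet([Tree(list("ABCDE"), [0b11100, 0b11000])], 3,
                     tuple("ABCDE"))
        out = collapse_and_dedupe(ts, m, [0, 1])
        assert out.trees[0].splits == ts.trees[0].splits

    def test_collapse_merges_equivalent_placements(self):
        # the unscorable taxon E has many equally parsimonious placements;
        # collapsing ambiguous branches merges them
        m = make_matrix([[0], [0], [1], [1], [0]], taxa=list("ABCDE"),
                        missing=[(4, 0)])
        cfg = SearchConfig(n_random_additions=4, maxtrees=30,
                           collapse_zero=False)
        raw = heuristic_search(m, [0], cfg, seed=1)
        out = collapse_and_dedupe(raw, m, [0])
        assert len(out.trees) < len(raw.trees)
        exact_dup = TreeSet([raw.trees[0], raw.trees[0]], raw.score, raw.taxa)
        assert len(collapse_and_dedupe(exact_dup, m, [0]).trees) == 1

    def test_collapse_preserves_length(self, rng):
        m = random_binary_matrix(rng, 7, 10, missing_rate=0.25)
        ts = heuristic_search(
            m, range(10),
            SearchConfig(n_random_additions=3, maxtrees=10, collapse_zero=False),
            seed=2)
        out = collapse_and_dedupe(ts, m, range(10))
        for t in out.trees:
            assert fitch_length(t, m, range(10)) == ts.score


class TestEnsembleIndices:
    def test_no_homoplasy(self):
        m = make_matrix([[0, 0], [0, 0], [1, 1], [1, 1]], taxa=TAXA4)
        rep = ensemble_indices(TreeSet([GOOD], 2, tuple(TAXA4)), m, [0, 1])
        assert (rep.S, rep.M, rep.ci, rep.ri) == (2, 2, 1.0, 1.0)

    def test_maximal_homoplasy(self):
        m = make_matrix([[0, 0], [0, 0], [1, 1], [1, 1]], taxa=TAXA4)
        rep = ensemble_indices(TreeSet([BAD], 4, tuple(TAXA4)), m, [0, 1])
        assert (rep.S, rep.M, rep.G) == (4, 2, 4)
        assert rep.ci == 0.5 and rep.ri == 0.0

    def test_ci_identical_across_mpts(self, rng):
        m = random_binary_matrix(rng, 7, 12, missing_rate=0.2)
        ts = heuristic_search(m, range(12), DESK_CONFIG, seed=1)
        cis = set()
        for t in ts:
            rep = ensemble_indices(TreeSet([t], ts.score, ts.taxa), m, range(12))
            cis.add(round(rep.ci, 12))
        assert len(cis) == 1

    def test_bounds_m_le_s_le_g(self, rng):
        for seed in range(4):
            r = np.random.default_rng(seed)
            m = random_binary_matrix(r, 8, 15, missing_rate=0.2, alphabet=3)
            chars = [c for c in range(15) if is_informative(m, c)]
            if not chars:
                continue
            ts = heuristic_search(m, chars, DESK_CONFIG, seed=seed)
            rep = ensemble_indices(ts, m, chars)
            assert np.all(rep.m <= rep.s) and np.all(rep.s <= rep.g)
            assert 0.0 <= rep.ci <= 1.0
            if rep.ri_defined:
                assert 0.0 <= rep.ri <= 1.0

    def test_ri_undefined_when_no_retained_synapomorphy(self):
        # an autapomorphy alone has G == M, so RI is flagged undefined
        m = make_matrix([[0], [0], [0], [1]], taxa=TAXA4)
        rep = ensemble_indices(TreeSet([GOOD], 1, tuple(TAXA4)), m, [0],
                               include_uninformative=True)
        assert rep.G == rep.M == 1
        assert not rep.ri_defined and np.isnan(rep.ri)
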