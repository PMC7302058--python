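import textwrap

import numpy as np
import pytest

from partcong.matrix_io import (
    CharacterMatrix, CellState, MatrixValidationError, CRANIO, POST, OTHER,
    read_nexus, write_nexus, build_partition_scheme, matrix_overlap,
    curate_matrix, remove_uninformative, is_informative, is_variable,
)
from partcong.parsimony import fitch_length
from partcong.trees import Tree
from conftest import make_matrix, random_binary_matrix, halves_scheme

NEX = textwrap.dedent("""\
    #NEXUS
    BEGIN DATA;
      DIMENSIONS NTAX=4 NCHAR=3;
      FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;
      MATRIX
        A 01?
        B 0{01}1
        C 11-
        D 100
      ;
    END;
    BEGIN SETS;
      CHARSET cranio = 1-2;
      CHARSET post = 3;
    END;
    """)


def test_read_nexus_decodes_cells(tmp_path):
    p = tmp_path / "toy.nex"
    p.write_text(NEX)
    m = read_nexus(p)
    assert m.taxa == ("A", "B", "C", "D")
    assert m.n_chars == 3
    assert m.cell("A", 2) == CellState("missing")
    assert m.cell("C", 2) == CellState("inapplicable")
    assert m.cell("B", 1) == CellState("observed", frozenset({0, 1}))
    assert m.cell("D", 0) == CellState("observed", frozenset({1}))
    assert m.charsets == {"cranio": (0, 1), "post": (2,)}


def test_polymorphic_and_uncertain_decode_identically(tmp_path):
    a = tmp_path / "a.nex"
    b = tmp_path / "b.nex"
    a.write_text(NEX)
    b.write_text(NEX.replace("{01}", "(01)"))
    assert read_nexus(a) == read_nexus(b)


def test_write_read_roundtrip(tmp_path, rng):
    m = random_binary_matrix(rng, 6, 10, missing_rate=0.2, alphabet=3)
    m = CharacterMatrix(m.taxa, m.masks, m.kinds, alphabet=m.alphabet,
                        charsets={"cranio": range(5), "post": range(5, 10)})
    p = tmp_path / "round.nex"
    write_nexus(m, p)
    assert read_nexus(p) == m


def test_write_without_charsets_omits_sets_block(tmp_path, rng):
    m = random_binary_matrix(rng, 4, 3)
    p = tmp_path / "nosets.nex"
    write_nexus(m, p)
    text = p.read_text()
    assert "SETS" not in text
    assert read_nexus(p) == m


def test_inapplicable_written_as_gap(tmp_path):
    m = make_matrix([[0, 1], [1, 0], [0, 0], [1, 1]], inapplicable=[(0, 0)])
    p = tmp_path / "gap.nex"
    write_nexus(m, p)
    assert read_nexus(p) == m
    row = [l for l in p.read_text().splitlines() if l.strip().startswith("t0")][0]
    assert "-" in row


def test_build_partition_scheme_labels_and_other():
    m = make_matrix(np.zeros((4, 10), int))
    sch = build_partition_scheme(m, range(4), range(4, 9))
    assert sch.labels[9] == OTHER
    assert sch.cranio == tuple(range(4))
    assert sch.post == tuple(range(4, 9))
    assert 9 not in sch.analysed


def test_build_partition_scheme_overlap_error():
    m = make_matrix(np.zeros((4, 6), int))
    with pytest.raises(MatrixValidationError):
        build_partition_scheme(m, [0, 1, 2], [2, 3])


def test_named_charsets_match_explicit_indices():
    m = make_matrix(np.zeros((4, 6), int),
                    charsets={"cranio": [0, 1, 2], "post": [3, 4, 5]})
    assert (build_partition_scheme(m, "cranio", "post").labels
            == build_partition_scheme(m, [0, 1, 2], [3, 4, 5]).labels)


class TestMatrixOverlap:
    def test_self_is_100(self, rng):
        m = random_binary_matrix(rng, 5, 8)
        assert matrix_overlap(m, m) == 100.0

    def test_disjoint_taxa_is_0(self, rng):
        m1 = random_binary_matrix(rng, 5, 8)
        m2 = CharacterMatrix([f"x{i}" for i in range(5)], m1.masks, m1.kinds,
                             alphabet=m1.alphabet)
        assert matrix_overlap(m1, m2) == 0.0

    def test_partial_overlap_hand_count(self):
        # m1: 8 taxa x 5 chars (40 cells); m2: 20 x 10 sharing 5 taxa and
        # 4 characters -> 20 shared cells / 40 = 50%
        t1 = [f"s{i}" for i in range(8)]
        t2 = [f"s{i}" for i in range(5)] + [f"x{i}" for i in range(15)]
        c1 = [f"c{i}" for i in range(5)]
        c2 = [f"c{i}" for i in range(4)] + [f"d{i}" for i in range(6)]
        m1 = CharacterMatrix(t1, np.ones((8, 5), np.uint32),
                             np.zeros((8, 5), np.int8), 2, char_labels=c1)
        m2 = CharacterMatrix(t2, np.ones((20, 10), np.uint32),
                             np.zeros((20, 10), np.int8), 2, char_labels=c2)
        assert matrix_overlap(m1, m2) == pytest.approx(50.0)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(5):
            m1 = random_binary_matrix(rng, int(rng.integers(4, 9)), 6)
            m2 = random_binary_matrix(rng, int(rng.integers(4, 9)), 6)
            v = matrix_overlap(m1, m2)
            assert v == matrix_overlap(m2, m1)
            assert 0.0 <= v <= 100.0


class TestCuration:
    def toy(self):
        # chars 0-1 craniodental, 2-3 postcranial; taxon E is 50% unscored
        # in the craniodental partition; char 3 varies only in E
        states = np.array([
            [0, 0, 0, 0],
            [0, 1, 0, 0],
            [1, 0, 1, 0],
            [1, 1, 1, 0],
            [1, 0, 0, 1],
        ])
        m = make_matrix(states, taxa=list("ABCDE"), missing=[(4, 0)])
        sch = build_partition_scheme(m, [0, 1], [2, 3])
        return m, sch

    def test_overloaded_taxon_and_newly_invariant_char_removed(self):
        m, sch = self.toy()
        cur, sch2, rep = curate_matrix(m, sch)
        assert list(rep.removed_taxa) == ["E"]
        assert cur.n_taxa == 4
        assert cur.n_chars == 3           # char 3 became invariant
        assert len(rep.removed_characters) == 1
        assert rep.threshold == 0.40

    def test_threshold_one_removes_nothing(self):
        m, sch = self.toy()
        cur, _, rep = curate_matrix(m, sch, threshold=1.0)
        assert cur == m and not rep.removed_taxa

    def test_clean_matrix_unchanged(self, rng):
        m = random_binary_matrix(rng, 6, 8)
        sch = halves_scheme(8)
        cur, _, rep = curate_matrix(m, sch)
        assert cur == m
        assert not rep.removed_taxa and not rep.removed_characters

    def test_survivors_respect_threshold(self, rng):
        # single pass: surviving taxa obey the threshold on the original
        # character set (character removal happens after the taxon filter)
        for seed in range(4):
            r = np.random.default_rng(seed)
            m = random_binary_matrix(r, 10, 20, missing_rate=0.35)
            sch = halves_scheme(20)
            cur, _, _ = curate_matrix(m, sch)
            kept = m.subset(taxa=cur.taxa)
            for ti in range(kept.n_taxa):
                assert kept.unscored_fraction(ti, sch.cranio) <= 0.40
                assert kept.unscored_fraction(ti, sch.post) <= 0.40

    def test_iterated_curation_reaches_fixpoint(self, rng):
        m = random_binary_matrix(rng, 12, 24, missing_rate=0.2)
        sch = halves_scheme(24)
        cur, sch2, _ = curate_matrix(m, sch, iterate=True)
        again, _, rep = curate_matrix(cur, sch2, iterate=True)
        assert again == cur and not rep.removed_taxa

    def test_all_taxa_removed_raises(self):
        m = make_matrix(np.zeros((4, 4), int),
                        missing=[(i, j) for i in range(4) for j in range(2)])
        sch = build_partition_scheme(m, [0, 1], [2, 3])
        with pytest.raises(MatrixValidationError):
            curate_matrix(m, sch, threshold=0.3)


class TestUninformative:
    @pytest.mark.parametrize("column, keep", [
        ([0, 0, 0, 0], False),      # constant
        ([0, 0, 0, 1], False),      # autapomorphy
        ([0, 0, 1, 1], True),       # shared derived state
    ])
    def test_examples(self, column, keep):
        states = np.array([column, [0, 1, 0, 1]]).T
        m = make_matrix(states)
        out = remove_uninformative(m, mode="all")
        assert (out.n_chars == 2) == keep

    def test_uninformative_chars_add_constant_length(self, rng):
        m = random_binary_matrix(rng, 6, 15, missing_rate=0.1)
        informative = [c for c in range(15) if is_informative(m, c)]
        assert informative and len(informative) < 15
        stripped = remove_uninformative(m, mode="all")
        for seed in range(3):
            from partcong.synthetic_data import simulate_tree_pair
            t = simulate_tree_pair(6, 0, np.random.default_rng(seed)).tree1
            t = Tree(m.taxa, t.splits)
            full = fitch_length(t, m, range(15))
            part = fitch_length(t, stripped, range(stripped.n_chars))
            assert full - part == fitch_length(
                t, m, [c for c in range(15) if c not in informative])

    def test_is_variable(self):
        m = make_matrix([[0], [0], [1], [1]])
        assert is_variable(m, 0)
        m2 = make_matrix([[0], [0], [0], [0]])
        assert not is_variable(m2, 0)
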