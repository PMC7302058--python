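import numpy as np
import pytest

from partcong.matrix_io import CharacterMatrix, PartitionScheme, CRANIO, POST
from partcong.trees import Tree


def make_matrix(states, taxa=None, alphabet=None, missing=None,
                inapplicable=None, charsets=None):
    """Build a CharacterMatrix from an integer state array.

    `missing`/`inapplicable` are (taxon, char) index pairs overriding cells.
    """
    states = np.asarray(states, dtype=np.int64)
    n, c = states.shape
    if taxa is None:
        taxa = [f"t{i}" for i in range(n)]
    if alphabet is None:
        alphabet = max(2, int(states.max()) + 1)
    masks = (np.uint32(1) << states.astype(np.uint32)).astype(np.uint32)
    kinds = np.zeros((n, c), np.int8)
    for (ti, ci) in (missing or []):
        kinds[ti, ci] = 1
        masks[ti, ci] = 0
    for (ti, ci) in (inapplicable or []):
        kinds[ti, ci] = 2
        masks[ti, ci] = 0
    return CharacterMatrix(taxa, masks, kinds, alphabet=alphabet,
                           charsets=charsets)


def split_indicator_matrix(tree: Tree, copies=1):
    """Perfectly congruent binary characters: one per nontrivial split."""
    n = tree.n_taxa
    cols = []
    for s in sorted(tree.splits):
        col = [(s >> i) & 1 for i in range(n)]
        cols.extend([col] * copies)
    states = np.array(cols).T
    return make_matrix(states, taxa=tree.taxa, alphabet=2)


def random_binary_matrix(rng, n_taxa, n_chars, missing_rate=0.0, alphabet=2):
    states = rng.integers(0, alphabet, (n_taxa, n_chars))
    miss = []
    if missing_rate:
        u = rng.random((n_taxa, n_chars))
        miss = list(zip(*np.where(u < missing_rate)))
    return make_matrix(states, alphabet=alphabet, missing=miss)


def halves_scheme(n_chars):
    half = n_chars // 2
    return PartitionScheme(tuple([CRANIO] * half + [POST] * (n_chars - half)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
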