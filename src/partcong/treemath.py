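"""Tree comparison: splits, Robinson-Foulds and matching-split distances,
nearest-neighbour distances between tree sets, majority-rule consensus and
tree-shape statistics.

The matching distance pairs the two trees' split sets by a minimum-cost
perfect matching where the cost of pairing splits A|B and C|D is the
smaller symmetric difference min(|A xor C|, |A xor D|); when the trees have
unequal numbers of splits (common once zero-length branches are collapsed)
the shorter list is padded with dummy splits costing min(|A|, |B|) against
a real split and 0 against another dummy.  The assignment is solved exactly
with the Hungarian method.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .trees import Tree, RootedTree, splits_compatible, popcount

__all__ = [
    "tree_splits", "rf_distance", "matching_distance", "mean_nnd",
    "majority_rule_consensus", "tree_shape_stats",
]


def tree_splits(tree: Tree) -> frozenset:
    """Nontrivial splits (canonical bitmasks, side excluding taxon 0)."""
    if tree.n_taxa < 4:
        return frozenset()
    return tree.splits


def _check_leafsets(t1: Tree, t2: Tree):
    if t1.taxa != t2.taxa:
        if set(t1.taxa) == set(t2.taxa):
            raise ValueError("trees share leaves but index them differently; "
                             "build them on a common taxon ordering")
        raise ValueError("trees are on different leaf sets")


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Symmetric-difference (Robinson-Foulds) count of nontrivial splits."""
    _check_leafsets(t1, t2)
    return len(t1.splits ^ t2.splits)


def matching_distance(t1: Tree, t2: Tree) -> float:
    _check_leafsets(t1, t2)
    n = t1.n_taxa
    a = sorted(t1.splits)
    b = sorted(t2.splits)
    if not a and not b:
        return 0.0
    size = max(len(a), len(b))
    cost = np.zeros((size, size), np.int64)
    am = np.array(a, np.uint64).reshape(-1, 1) if a else np.empty((0, 1), np.uint64)
    bm = np.array(b, np.uint64).reshape(1, -1) if b else np.empty((1, 0), np.uint64)
    if a and b:
        x = np.bitwise_count(am ^ bm).astype(np.int64)
        cost[: len(a), : len(b)] = np.minimum(x, n - x)
    # dummy columns/rows: pairing a real split with a dummy costs the size
    # of its smaller side; dummy-dummy pairs cost 0
    for i, s in enumerate(a):
        p = popcount(s)
        cost[i, len(b):] = min(p, n - p)
    for j, s in enumerate(b):
        p = popcount(s)
        cost[len(a):, j] = min(p, n - p)
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum())


_METRICS = {"RF": rf_distance, "matching": matching_distance}


def _resolve_metric(metric):
    if callable(metric):
        return metric
    if metric in _METRICS:
        return _METRICS[metric]
    raise ValueError(f"unknown metric {metric!r} (use 'RF' or 'matching')")


def mean_nnd(
    setA: Sequence[Tree],
    setB: Sequence[Tree],
    metric="matching",
    cap: int | None = None,
    seed: int | None = None,
    symmetric: bool = True,
) -> float:
    """Mean nearest-neighbour distance between two tree sets.

    For each tree in A, the distance to its most similar tree in B is
    found; by default the two directed means are averaged (a one-directional
    variant is available via ``symmetric=False``).  Each set is uniformly
    subsampled to at most `cap` trees first (seeded).
    """
    A = list(setA)
    B = list(setB)
    if not A or not B:
        raise ValueError("tree sets must be nonempty")
    if cap is not None:
        rng = np.random.default_rng(seed)
        if len(A) > cap:
            A = [A[i] for i in rng.choice(len(A), cap, replace=False)]
        if len(B) > cap:
            B = [B[i] for i in rng.choice(len(B), cap, replace=False)]
    d = _resolve_metric(metric)
    mat = np.empty((len(A), len(B)))
    cache: dict = {}
    for i, ta in enumerate(A):
        for j, tb in enumerate(B):
            key = (ta.splits, tb.splits)
            if key not in cache:
                cache[key] = d(ta, tb)
            mat[i, j] = cache[key]
    ab = mat.min(axis=1).mean()
    if not symmetric:
        return float(ab)
    ba = mat.min(axis=0).mean()
    return float((ab + ba) / 2.0)


def majority_rule_consensus(trees: Sequence[Tree], plus_compatible: bool = True) -> Tree:
    """50% majority-rule consensus, optionally adding remaining splits in
    descending frequency when compatible with everything accepted."""
    trees = list(trees)
    if not trees:
        raise ValueError("need at least one tree")
    taxa = trees[0].taxa
    counts: dict = {}
    for t in trees:
        if t.taxa != taxa:
            raise ValueError("consensus requires a common leaf set")
        for s in t.splits:
            counts[s] = counts.get(s, 0) + 1
    half = len(trees) / 2.0
    accepted = [s for s, c in counts.items() if c > half]
    if plus_compatible:
        rest = sorted(
            (s for s, c in counts.items() if c <= half),
            key=lambda s: (-counts[s], s),
        )
        for s in rest:
            if all(splits_compatible(s, a) for a in accepted):
                accepted.append(s)
    return Tree(taxa, accepted)


def tree_shape_stats(tree, root_on: str | None = None) -> tuple:
    """(Colless index, % resolution) of a rooted tree.

    Accepts a RootedTree (or rooted Newick string) used as written, or an
    unrooted Tree plus `root_on`, which roots on that taxon's pendant edge.
    Colless sums |left - right| leaf counts over strictly bifurcating
    internal nodes; resolution is 100 x internal nodes / (terminals - 1).
    """
    rt = _as_rooted(tree, root_on)
    n = rt.n_taxa
    if n < 3:
        raise ValueError("need at least 3 leaves")
    colless = 0
    internal = 0
    for v in rt.internal_nodes():
        internal += 1
        if len(v.children) == 2:
            l0 = popcount(v.children[0].clade)
            l1 = popcount(v.children[1].clade)
            colless += abs(l0 - l1)
    resolution = 100.0 * internal / (n - 1)
    return colless, resolution


def _as_rooted(tree, root_on) -> RootedTree:
    if isinstance(tree, RootedTree):
        return tree
    if isinstance(tree, str):
        return RootedTree.from_newick(tree)
    if isinstance(tree, Tree):
        if root_on is None:
            raise ValueError("an unrooted tree needs root_on")
        return tree.rooted(root_on)
    raise TypeError(f"cannot interpret {type(tree).__name__} as a rooted tree")
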