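"""Maximum-parsimony scoring and heuristic tree search.

Characters are unordered and equally weighted.  Missing and inapplicable
cells are fully ambiguous (they can never force a step); polymorphic cells
enter optimisation as their state set, satisfiable at no cost by any
member.  The search replicates the classic protocol: random stepwise
addition holding a fixed number of best partial trees at each step,
followed by tree-bisection-and-reconnection (TBR) branch swapping, pooling
equal-best trees, collapsing branches whose minimum length over all optimal
state reconstructions is zero, and deduplicating the survivors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernel as K
from .matrix_io import CharacterMatrix, OBSERVED, is_informative
from .trees import Tree, canonical_split

__all__ = [
    "SearchConfig", "TreeSet", "ScoreReport",
    "fitch_length", "character_step_bounds", "heuristic_search",
    "exhaustive_search", "collapse_and_dedupe", "ensemble_indices",
]


@dataclass(frozen=True)
class SearchConfig:
    """Heuristic search settings (defaults follow the standard protocol of
    25 random addition sequences with TBR, holding 10 trees per step)."""

    n_random_additions: int = 25
    hold_per_step: int = 10
    maxtrees: int = 100_000
    nnd_tree_cap: int = 1000
    seed: int | None = None
    collapse_zero: bool = True

    def __post_init__(self):
        for name in ("n_random_additions", "hold_per_step", "maxtrees", "nnd_tree_cap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


#: settings scaled for interactive desk use; the full protocol is the default
DESK_CONFIG = SearchConfig(
    n_random_additions=5, hold_per_step=10, maxtrees=24, nnd_tree_cap=12
)


@dataclass
class TreeSet:
    """Equally optimal distinct topologies from one search."""

    trees: list
    score: int
    taxa: tuple
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


@dataclass
class ScoreReport:
    """Per-character observed steps s, minimum steps m and star-tree maximum
    g, with the ensemble consistency and retention indices they imply."""

    chars: tuple
    s: np.ndarray
    m: np.ndarray
    g: np.ndarray

    @property
    def S(self) -> int:
        return int(self.s.sum())

    @property
    def M(self) -> int:
        return int(self.m.sum())

    @property
    def G(self) -> int:
        return int(self.g.sum())

    @property
    def ci(self) -> float:
        return self.M / self.S if self.S else float("nan")

    @property
    def ri(self) -> float:
        den = self.G - self.M
        return (self.G - self.S) / den if den else float("nan")

    @property
    def ri_defined(self) -> bool:
        return self.G != self.M


# ---------------------------------------------------------------------------
# Scoring


def _leaf_sets(matrix: CharacterMatrix, chars: Sequence[int]) -> np.ndarray:
    sets = matrix.scoring_masks(chars)
    if sets.shape[1] == 0:
        raise ValueError("chars must be nonempty")
    return np.ascontiguousarray(sets)


def fitch_length(tree: Tree, matrix: CharacterMatrix, chars: Sequence[int]) -> int:
    """Minimum unordered state changes of `tree` summed over `chars`.

    Exact for multifurcating trees too (computed by 0/1-cost dynamic
    programming over the rooted form, which reduces to Fitch counting on
    binary trees).
    """
    missing = set(tree.taxa) - set(matrix.taxa)
    if missing:
        raise ValueError(f"tree leaves not in matrix: {sorted(missing)}")
    sub = [matrix.taxa.index(t) for t in tree.taxa]
    sets = _leaf_sets(matrix, chars)[sub, :]
    return int(_sankoff_lengths(tree, sets, matrix.alphabet).sum())


def _sankoff_lengths(tree: Tree, leaf_sets: np.ndarray, alphabet: int) -> np.ndarray:
    """Per-character minimum changes under unit costs, any node degrees."""
    from .trees import RootedTree
    rt = RootedTree.from_unrooted(tree, root_on=tree.taxa[0])
    C = leaf_sets.shape[1]
    k = alphabet
    INF = np.int32(1 << 20)

    def cost(node) -> np.ndarray:
        if node.taxon is not None:
            m = leaf_sets[node.taxon]                    # (C,)
            allowed = (m[:, None] >> np.arange(k)[None, :]) & 1
            return np.where(allowed == 1, 0, INF).astype(np.int32)
        acc = np.zeros((C, k), np.int32)
        for ch in node.children:
            cc = cost(ch)                                 # (C, k)
            best = cc.min(axis=1)                         # change allowed
            acc = acc + np.minimum(cc, best[:, None] + 1)
        return acc

    root_cost = cost(rt.root)
    return root_cost.min(axis=1)


def character_step_bounds(matrix: CharacterMatrix, char: int) -> tuple:
    """(m, g): minimum steps on any tree and steps on the star tree,
    computed over fixed (singleton) observed cells only."""
    col_m = matrix.masks[:, char]
    col_k = matrix.kinds[:, char]
    counts: dict = {}
    for mm, kk in zip(col_m, col_k):
        if kk == OBSERVED and int(mm).bit_count() == 1:
            counts[int(mm)] = counts.get(int(mm), 0) + 1
    if not counts:
        return 0, 0
    n_scored = sum(counts.values())
    m = max(len(counts) - 1, 0)
    g = n_scored - max(counts.values())
    return m, g


# ---------------------------------------------------------------------------
# Search


def _nbr_to_tree(nbr: np.ndarray, taxa: tuple, length: int | None = None) -> Tree:
    n = len(taxa)
    order = np.empty(nbr.shape[0], np.int32)
    parent = np.empty(nbr.shape[0], np.int32)
    masks, _ = K.edge_clades(nbr, n, order, parent)
    splits = [
        int(masks[v]) for v in range(n, nbr.shape[0])
        if nbr[v, 0] >= 0
    ]
    return Tree(taxa, splits, length=length)


def _canon(nbr: np.ndarray, n_leaves: int) -> frozenset:
    order = np.empty(nbr.shape[0], np.int32)
    parent = np.empty(nbr.shape[0], np.int32)
    masks, _ = K.edge_clades(nbr, n_leaves, order, parent)
    full = (1 << n_leaves) - 1
    out = []
    for v in range(n_leaves, nbr.shape[0]):
        if nbr[v, 0] < 0:
            continue
        m = int(masks[v])
        p = m.bit_count()
        if 2 <= p <= n_leaves - 2:
            out.append(canonical_split(m, n_leaves))
    return frozenset(out)


def _star_treeset(matrix, chars, taxa, config) -> TreeSet:
    sets = _leaf_sets(matrix, chars)
    star = Tree(taxa, [])
    score = fitch_length(star, matrix, chars)
    return TreeSet([star], score, tuple(taxa), meta={"star": True, "config": config})


def heuristic_search(
    matrix: CharacterMatrix,
    chars: Sequence[int],
    config: SearchConfig = SearchConfig(),
    seed: int | None = None,
) -> TreeSet:
    """Random-addition + TBR search for most parsimonious trees.

    Deterministic given `seed` (falls back to ``config.seed``).  Returns the
    pooled equal-best trees after zero-length-branch collapse and
    deduplication.
    """
    taxa = matrix.taxa
    L = len(taxa)
    if L < 4:
        raise ValueError("heuristic_search requires at least 4 taxa")
    if L > 64:
        raise ValueError("search supports at most 64 taxa")
    chars = list(chars)
    if not any(is_informative(matrix, c) for c in chars):
        warnings.warn("no parsimony-informative characters; returning star tree")
        return _star_treeset(matrix, chars, taxa, config)
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    sets = _leaf_sets(matrix, chars)
    N = 2 * L - 2
    C = sets.shape[1]

    pool: dict = {}
    best_score = None

    for _ in range(config.n_random_additions):
        addition = rng.permutation(L)
        held = [_init_triple(addition[:3], N)]
        next_internal = L + 1
        for step in range(3, L):
            leaf = int(addition[step])
            cands = []
            out_edges = np.empty((N, 2), np.int32)
            out_costs = np.empty(N, np.int64)
            for hi, nbr in enumerate(held):
                ne, _ = K.insertion_costs(
                    nbr, int(addition[0]), sets, leaf, out_edges, out_costs)
                for e in range(ne):
                    cands.append((int(out_costs[e]), rng.random(), hi,
                                  int(out_edges[e, 0]), int(out_edges[e, 1])))
            cands.sort(key=lambda t: (t[0], t[1]))
            held = [
                K.apply_insert(held[hi], next_internal, leaf, ea, eb)
                for _, _, hi, ea, eb in cands[: config.hold_per_step]
            ]
            next_internal += 1
        # TBR from each completed addition tree
        for nbr in held:
            score = int(K.tree_length(
                nbr, sets,
                np.empty((N, C), np.uint32),
                np.empty(N, np.int32), np.empty(N, np.int32)))
            best_score, pool = _tbr_descend(
                nbr, score, sets, L, config, best_score, pool)

    trees = [
        _nbr_to_tree(nbr, taxa, length=best_score) for nbr in pool.values()
    ]
    ts = TreeSet(trees, best_score, tuple(taxa),
                 meta={"seed": seed, "config": config})
    if config.collapse_zero:
        ts = collapse_and_dedupe(ts, matrix, chars)
    return ts


def _init_triple(leaves, N) -> np.ndarray:
    nbr = np.full((N, 3), -1, np.int32)
    L = (N + 2) // 2
    hub = L  # first internal node
    nbr[hub] = leaves
    for lf in leaves:
        nbr[lf, 0] = hub
    return nbr


_MOVE_CAP = 2048


def _tbr_descend(nbr, score, sets, n_leaves, config, best_score, pool):
    """Steepest-descent TBR with exhaustive plateau collection (bounded by
    config.maxtrees).  Merges results into the global pool, clearing it
    whenever a strictly better length is reached."""
    queue = [nbr]
    seen_local: set = set()
    scans = 0
    max_scans = 4 * config.maxtrees
    while queue and scans < max_scans:
        cur = queue.pop()
        key = _canon(cur, n_leaves)
        if key in seen_local:
            continue
        seen_local.add(key)
        scans += 1
        mlen, moves, nm = K.tbr_scan(cur, sets, _MOVE_CAP)
        mlen = int(mlen)
        if mlen < score:
            # strict improvement: restart the walk from the best neighbour
            m = moves[0]
            queue = [K.apply_tbr(cur, m[0], m[1], m[2], m[3], m[4], m[5])]
            seen_local = set()
            score = mlen
            continue
        # `cur` is a local optimum at `score`
        if best_score is None or score < best_score:
            best_score = score
            pool.clear()
        if score == best_score and len(pool) < config.maxtrees:
            pool[key] = cur
            if mlen == score:    # equal-best neighbours: walk the plateau
                for i in range(nm):
                    if len(pool) + len(queue) >= config.maxtrees:
                        break
                    m = moves[i]
                    nxt = K.apply_tbr(cur, m[0], m[1], m[2], m[3], m[4], m[5])
                    if _canon(nxt, n_leaves) not in seen_local:
                        queue.append(nxt)
    return best_score, pool


def exhaustive_search(matrix: CharacterMatrix, chars: Sequence[int]) -> TreeSet:
    """Exact minimum over all unrooted binary topologies (n <= 9)."""
    taxa = matrix.taxa
    L = len(taxa)
    if L > 9:
        raise ValueError("exhaustive enumeration is limited to 9 taxa")
    if L < 4:
        raise ValueError("need at least 4 taxa")
    sets = _leaf_sets(matrix, chars)
    N = 2 * L - 2
    C = sets.shape[1]
    down = np.empty((N, C), np.uint32)
    order = np.empty(N, np.int32)
    parent = np.empty(N, np.int32)

    best = None
    best_trees: list = []

    def recurse(nbr, next_leaf, next_internal):
        nonlocal best, best_trees
        if next_leaf == L:
            ln = int(K.tree_length(nbr, sets, down, order, parent))
            if best is None or ln < best:
                best = ln
                best_trees = [nbr.copy()]
            elif ln == best:
                best_trees.append(nbr.copy())
            return
        # insert next_leaf into every edge
        for u in range(N):
            for k in range(3):
                v = nbr[u, k]
                if v <= u:
                    continue
                recurse(K.apply_insert(nbr, next_internal, next_leaf, u, v),
                        next_leaf + 1, next_internal + 1)

    recurse(_init_triple(np.arange(3), N), 3, L + 1)
    trees = [_nbr_to_tree(nbr, taxa, length=best) for nbr in best_trees]
    # exhaustive enumeration can revisit topologies only if n < 4; dedupe anyway
    uniq = {t.splits: t for t in trees}
    return TreeSet(list(uniq.values()), best, tuple(taxa), meta={"exhaustive": True})


# ---------------------------------------------------------------------------
# Zero-length-branch collapse ("amb-" rule)


def _min_edge_lengths(tree: Tree, leaf_sets: np.ndarray, alphabet: int):
    """For each nontrivial split: the minimum number of changes on that edge
    over all jointly optimal reconstructions (summed over characters)."""
    from .trees import RootedTree
    rt = RootedTree.from_unrooted(tree, root_on=tree.taxa[0])
    C = leaf_sets.shape[1]
    k = alphabet
    INF = np.int32(1 << 20)
    n = tree.n_taxa
    full = (1 << n) - 1

    down: dict = {}

    def downpass(node):
        if node.taxon is not None:
            m = leaf_sets[node.taxon]
            allowed = (m[:, None] >> np.arange(k)[None, :]) & 1
            d = np.where(allowed == 1, 0, INF).astype(np.int32)
        else:
            d = np.zeros((C, k), np.int32)
            for ch in node.children:
                dc = downpass(ch)
                d = d + np.minimum(dc, dc.min(axis=1)[:, None] + 1)
        down[id(node)] = d
        return d

    downpass(rt.root)
    total = down[id(rt.root)].min(axis=1)        # (C,)

    # A(v)[c, s] = min cost of the tree minus subtree(v), with v's parent
    # assigned state s.  The edge above v carries a forced change for
    # character c iff no optimal reconstruction gives both endpoints the
    # same state, i.e. min_s(A[c, s] + D[c, s]) > total[c].
    result = {}

    def contrib(cost):
        return np.minimum(cost, cost.min(axis=1)[:, None] + 1)

    def uppass(node, A):
        d = down[id(node)]
        if node.children and 2 <= node.clade.bit_count() <= n - 2 and A is not None:
            same = (A + d).min(axis=1)
            result[canonical_split(node.clade, n)] = int(
                np.count_nonzero(same - total))
        for ch in node.children:
            acc = np.zeros((C, k), np.int32) if A is None else contrib(A)
            for other in node.children:
                if other is not ch:
                    acc = acc + contrib(down[id(other)])
            uppass(ch, acc)

    uppass(rt.root, None)
    return result


def collapse_and_dedupe(trees: TreeSet, matrix: CharacterMatrix, chars: Sequence[int]) -> TreeSet:
    """Contract every internal branch whose minimum length over all optimal
    reconstructions is zero, then merge identical topologies."""
    chars = list(chars)
    sub = [matrix.taxa.index(t) for t in trees.taxa]
    sets = _leaf_sets(matrix, chars)[sub, :]
    out: dict = {}
    for t in trees.trees:
        if not t.splits:
            out[t.splits] = t
            continue
        mins = _min_edge_lengths(t, sets, matrix.alphabet)
        keep = [s for s in t.splits if mins.get(s, 1) > 0]
        collapsed = Tree(trees.taxa, keep, length=trees.score)
        out[collapsed.splits] = collapsed
    meta = dict(trees.meta)
    meta["n_before_collapse"] = len(trees.trees)
    return TreeSet(list(out.values()), trees.score, trees.taxa, meta=meta)


# ---------------------------------------------------------------------------
# Ensemble homoplasy indices


def ensemble_indices(
    trees: TreeSet,
    matrix: CharacterMatrix,
    chars: Sequence[int],
    include_uninformative: bool = False,
) -> ScoreReport:
    """Ensemble CI = M/S and RI = (G-S)/(G-M) over `chars` on the optimal
    trees (S is shared by every tree in the set).  By default only
    parsimony-informative characters enter the sums; set
    `include_uninformative` to mirror scoring conventions that keep them."""
    chars = list(chars)
    if not include_uninformative:
        chars = [c for c in chars if is_informative(matrix, c)]
        if not chars:
            raise ValueError("no informative characters to index")
    t0 = trees.trees[0]
    sub = [matrix.taxa.index(t) for t in trees.taxa]
    sets = _leaf_sets(matrix, chars)[sub, :]
    s = _sankoff_lengths(t0, sets, matrix.alphabet)
    mg = np.array([character_step_bounds(matrix, c) for c in chars], np.int64)
    return ScoreReport(tuple(chars), s.astype(np.int64), mg[:, 0], mg[:, 1])
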