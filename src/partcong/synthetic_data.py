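"""Simulated partitioned morphological matrices with controlled congruence.

Characters evolve under a symmetric k-state Markov (Mk-style) process with
gamma-distributed among-character rate variation, the craniodental
partition on one generating tree and the postcranial partition on a second
tree a configurable number of random SPR moves away.  Missing entries are
injected at configurable per-partition rates, optionally concentrated in
particular taxa (partial skeletons) via a beta-distributed per-taxon
propensity.  Stratigraphic ranges are derived from the generating tree's
node ages with exponential undersampling noise.

Defaults emulate the dimensions of recent published dinosaur matrices:
20 taxa, 115 + 133 characters, 2-4 states per character, ~30% missing, and
enough homoplasy to put the ensemble consistency index in the 0.4-0.9
band typical of empirical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix_io import (
    CharacterMatrix, PartitionScheme, CRANIO, POST, MISSING, INAPPLICABLE, OBSERVED,
)
from .trees import Tree

__all__ = [
    "SimConfig", "SimTree", "SimResult", "TreePair",
    "simulate_tree_pair", "simulate_matrix", "simulate_strat_ranges",
]


@dataclass(frozen=True)
class SimConfig:
    n_taxa: int = 20
    n_cranio: int = 115
    n_post: int = 133
    #: probability of a character having 2, 3 or 4 states
    state_probs: tuple = ((2, 0.6), (3, 0.3), (4, 0.1))
    #: gamma shape of among-character rate variation (mean fixed at 1)
    gamma_shape: float = 1.0
    #: expected substitutions per character summed over the whole tree --
    #: the homoplasy dial (higher = more homoplasy, lower ensemble CI)
    expected_changes: float = 3.0
    #: override for the postcranial partition (None = same as craniodental);
    #: unequal rates plant a cleaner signal in one partition
    expected_changes_post: float | None = None
    #: fraction of postcranial characters evolved on the craniodental tree
    #: (mosaic evolution dial); with 0.5 the entire matrix's dominant signal
    #: is the craniodental tree at double weight
    post_frac_on_cranio_tree: float = 0.0
    #: SPR moves separating the two partitions' generating trees
    spr_separation: int = 2
    missing_cranio: float = 0.30
    missing_post: float = 0.30
    inapplicable_rate: float = 0.0
    #: if set, per-taxon missingness propensities are Beta(c, c)-scaled so
    #: missing entries concentrate in a few poorly preserved taxa
    taxon_concentration: float | None = None
    #: mean of the exponential undersampling noise on first appearances,
    #: as a fraction of total tree depth
    strat_noise: float = 0.25
    #: floor added to the exponential(1) branch lengths; raising it removes
    #: effectively unresolvable (near-zero) internal edges
    min_branch: float = 0.0
    #: redraw the SPR path until the two generating trees differ by at least
    #: this RF distance (0 = accept any outcome, including moves that cancel)
    min_separation_rf: int = 0
    seed: int | None = None

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.n_cranio < 1 or self.n_post < 1:
            raise ValueError("character counts must be positive")
        if self.spr_separation < 0 or self.expected_changes < 0:
            raise ValueError("rates and separations must be >= 0")


class SimTree:
    """A rooted binary simulation tree with branch lengths and node ages."""

    def __init__(self, taxa, parent, blen, children):
        self.taxa = tuple(taxa)          # leaf i <-> node i
        self.parent = parent             # int array, -1 at root
        self.blen = blen                 # branch length above each node
        self.children = children        # list of lists
        self.root = int(np.where(parent == -1)[0][0])
        # node ages (time before present): leaves at age depth - dist(root)
        n = len(parent)
        depth = np.zeros(n)
        order = self._preorder()
        for v in order:
            if v != self.root:
                depth[v] = depth[parent[v]] + blen[v]
        total = depth.max()
        self.age = total - depth

    def _preorder(self):
        out = [self.root]
        stack = [self.root]
        while stack:
            v = stack.pop()
            for c in self.children[v]:
                out.append(c)
                stack.append(c)
        return out

    def unrooted(self) -> Tree:
        n = len(self.taxa)
        splits = []

        def clade(v):
            if v < n:
                return 1 << v
            m = 0
            for c in self.children[v]:
                m |= clade(c)
            splits.append(m)
            return m

        clade(self.root)
        return Tree(self.taxa, splits)

    def rooted(self):
        """The generating tree as a RootedTree, keeping its own rooting."""
        from .trees import RootedTree, _Node
        n = len(self.taxa)

        def build(v):
            if v < n:
                return _Node(clade=1 << v, taxon=v)
            kids = [build(c) for c in self.children[v]]
            clade = 0
            for k in kids:
                clade |= k.clade
            return _Node(clade=clade, children=kids)

        return RootedTree(self.taxa, build(self.root))


def _random_topology(n, rng):
    """Uniform random unrooted binary topology as an edge list, returned
    rooted at an arbitrary edge midpoint."""
    # adjacency over nodes: leaves 0..n-1, internals allocated upward
    nbr = {0: [2 * n - 2], 1: [2 * n - 2], 2: [2 * n - 2]}
    nbr[2 * n - 2] = [0, 1, 2]
    next_internal = n
    edges = [(0, 2 * n - 2), (1, 2 * n - 2), (2, 2 * n - 2)]
    for leaf in range(3, n):
        a, b = edges[rng.integers(len(edges))]
        m = next_internal
        next_internal += 1
        nbr[a].remove(b)
        nbr[b].remove(a)
        nbr[a].append(m)
        nbr[b].append(m)
        nbr[m] = [a, b, leaf]
        nbr[leaf] = [m]
        edges.remove((a, b))
        edges += [(a, m), (b, m), (leaf, m)]
    return nbr


def _spr_move(nbr, n, rng, move=None):
    """One subtree-pruning-and-regrafting move in place.

    With `move=None` a random valid move is chosen (and returned as a
    replayable (u, v, x, y) tuple): the subtree on the `u` side of edge
    (u, v) is pruned, `v` is suppressed out of the remaining tree and then
    reused to subdivide target edge (x, y)."""
    if move is not None:
        u, v, x, y = move
        nbr[u].remove(v)
        nbr[v].remove(u)
        a, b = nbr[v]
        nbr[a].remove(v)
        nbr[b].remove(v)
        nbr[a].append(b)
        nbr[b].append(a)
        nbr[x].remove(y)
        nbr[y].remove(x)
        nbr[x].append(v)
        nbr[y].append(v)
        nbr[v] = [x, y, u]
        nbr[u].append(v)
        return move
    for _ in range(200):
        edges = [(u, v) for u in nbr for v in nbr[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        if len(nbr[v]) == 1:
            u, v = v, u              # v must be internal to be suppressed
        if len(nbr[v]) == 1:
            continue
        # remove edge (u, v); suppress v
        nbr[u].remove(v)
        nbr[v].remove(u)
        a, b = nbr[v]
        nbr[a].remove(v)
        nbr[b].remove(v)
        nbr[a].append(b)
        nbr[b].append(a)
        # reachable edges from a (the remaining component)
        comp = set()
        stack = [a]
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(nbr[x])
        cand = [(x, y) for x in comp for y in nbr[x] if x < y
                and not (set((x, y)) == set((a, b)))]
        if not cand:
            # undo and retry
            nbr[a].remove(b)
            nbr[b].remove(a)
            nbr[a].append(v)
            nbr[b].append(v)
            nbr[v] = [a, b, u]
            nbr[u].append(v)
            continue
        x, y = cand[rng.integers(len(cand))]
        nbr[x].remove(y)
        nbr[y].remove(x)
        nbr[x].append(v)
        nbr[y].append(v)
        nbr[v] = [x, y, u]
        nbr[u].append(v)
        return (u, v, x, y)
    raise RuntimeError("could not find a valid SPR move")


def _adjacency_splits(nbr, n):
    splits = []
    seen = set()

    def clade(v, parent):
        m = 1 << v if v < n else 0
        for w in nbr[v]:
            if w != parent:
                m |= clade(w, v)
        if v >= n and parent is not None:
            splits.append(m)
        return m

    anchor = nbr[0][0]
    clade(anchor, None)
    return splits


@dataclass
class TreePair:
    """Two generating topologies and the replayable SPR path between them."""

    tree1: Tree
    tree2: Tree
    moves: list
    _adjacency: dict = field(repr=False, default=None)

    def replay(self) -> Tree:
        """Re-apply the recorded moves to tree1's adjacency; must rebuild
        tree2 exactly."""
        nbr = {k: list(v) for k, v in self._adjacency.items()}
        n = self.tree1.n_taxa
        for mv in self.moves:
            _spr_move(nbr, n, None, move=mv)
        return Tree(self.tree1.taxa, _adjacency_splits(nbr, n))


def simulate_tree_pair(n_taxa: int, spr_separation: int, rng) -> TreePair:
    """A uniform random binary tree and a copy `spr_separation` random SPR
    moves away, with the move list recorded for replay."""
    if n_taxa < 4:
        raise ValueError("need >= 4 taxa")
    taxa = [f"t{i + 1:02d}" for i in range(n_taxa)]
    nbr = _random_topology(n_taxa, rng)
    t1 = Tree(taxa, _adjacency_splits(nbr, n_taxa))
    nbr2 = {k: list(v) for k, v in nbr.items()}
    moves = [_spr_move(nbr2, n_taxa, rng) for _ in range(spr_separation)]
    t2 = Tree(taxa, _adjacency_splits(nbr2, n_taxa))
    return TreePair(t1, t2, moves, _adjacency={k: list(v) for k, v in nbr.items()})


def _root_adjacency(nbr, n, rng, min_branch: float = 0.0) -> SimTree:
    """Root an adjacency tree on a random internal edge midpoint and draw
    exponential branch lengths."""
    taxa = [f"t{i + 1:02d}" for i in range(n)]
    ids = sorted(nbr)
    remap = {v: i for i, v in enumerate(ids)}
    size = len(ids) + 1
    parent = np.full(size, -1, int)
    children: list = [[] for _ in range(size)]
    root = size - 1
    # pick an edge to root on
    edges = [(u, v) for u in nbr for v in nbr[u] if u < v]
    u, v = edges[rng.integers(len(edges))]
    for child in (u, v):
        parent[remap[child]] = root
        children[root].append(remap[child])
    visit = [(u, v), (v, u)]
    while visit:
        cur, par = visit.pop()
        for w in nbr[cur]:
            if w != par:
                parent[remap[w]] = remap[cur]
                children[remap[cur]].append(remap[w])
                visit.append((w, cur))
    blen = min_branch + rng.exponential(1.0, size)
    blen[root] = 0.0
    return SimTree(taxa, parent, blen, children)


@dataclass
class SimResult:
    matrix: CharacterMatrix
    scheme: PartitionScheme
    tree_cranio: Tree
    tree_post: Tree
    sim_tree_cranio: SimTree
    sim_tree_post: SimTree
    config: SimConfig


def _evolve_partition(sim: SimTree, n_chars: int, cfg: SimConfig, rng,
                      expected_changes: float | None = None):
    """Simulate characters down `sim`; returns (states, n_states) arrays."""
    if expected_changes is None:
        expected_changes = cfg.expected_changes
    n = len(sim.taxa)
    ks, kp = zip(*cfg.state_probs)
    n_states = rng.choice(ks, size=n_chars, p=kp)
    rates = rng.gamma(cfg.gamma_shape, 1.0 / cfg.gamma_shape, size=n_chars)
    # rescale branch lengths so a rate-1 character expects
    # `expected_changes` substitutions over the whole tree
    tot = sim.blen.sum()
    scale = expected_changes / tot if tot > 0 else 0.0
    order = sim._preorder()
    states = np.zeros((len(sim.parent), n_chars), np.int64)
    states[sim.root] = rng.integers(0, n_states)
    k = n_states.astype(float)
    for v in order:
        if v == sim.root:
            continue
        t = sim.blen[v] * scale * rates
        # symmetric Mk: P(same) = 1/k + (k-1)/k * exp(-k/(k-1) * t)
        p_same = 1.0 / k + (k - 1.0) / k * np.exp(-k / (k - 1.0) * t)
        stay = rng.random(n_chars) < p_same
        jump = rng.integers(1, n_states)       # offset 1..k-1
        states[v] = np.where(
            stay, states[sim.parent[v]],
            (states[sim.parent[v]] + jump) % n_states)
    return states[:n], n_states


def simulate_matrix(config: SimConfig = SimConfig(), rng=None) -> SimResult:
    """Generate a partitioned matrix: craniodental characters on tree 1,
    postcranial characters on tree 2 (`spr_separation` moves away)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_taxa
    taxa = [f"t{i + 1:02d}" for i in range(n)]
    nbr = _random_topology(n, rng)
    base_splits = frozenset(Tree(taxa, _adjacency_splits(nbr, n)).splits)
    for _ in range(100):
        nbr2 = {k: list(v) for k, v in nbr.items()}
        for _ in range(config.spr_separation):
            _spr_move(nbr2, n, rng)
        t2_splits = frozenset(Tree(taxa, _adjacency_splits(nbr2, n)).splits)
        if len(base_splits ^ t2_splits) >= config.min_separation_rf:
            break
    else:
        raise RuntimeError("could not reach the requested tree separation")
    sim1 = _root_adjacency(nbr, n, rng, config.min_branch)
    sim2 = _root_adjacency(nbr2, n, rng, config.min_branch)
    s1, k1 = _evolve_partition(sim1, config.n_cranio, config, rng)
    n_shared = round(config.post_frac_on_cranio_tree * config.n_post)
    if n_shared:
        s2a, k2a = _evolve_partition(sim1, n_shared, config, rng,
                                     expected_changes=config.expected_changes_post)
        s2b, k2b = _evolve_partition(sim2, config.n_post - n_shared, config, rng,
                                     expected_changes=config.expected_changes_post)
        s2 = np.concatenate([s2a, s2b], axis=1)
        k2 = np.concatenate([k2a, k2b])
    else:
        s2, k2 = _evolve_partition(sim2, config.n_post, config, rng,
                                   expected_changes=config.expected_changes_post)
    states = np.concatenate([s1, s2], axis=1)
    nstates = np.concatenate([k1, k2])
    C = states.shape[1]
    masks = (np.uint32(1) << states.astype(np.uint32)).astype(np.uint32)
    kinds = np.zeros((n, C), np.int8)
    # missingness, optionally concentrated per taxon
    miss_rate = np.concatenate([
        np.full(config.n_cranio, config.missing_cranio),
        np.full(config.n_post, config.missing_post)])
    if config.taxon_concentration is not None:
        c = config.taxon_concentration
        w = rng.beta(c, c, size=n)
        w = w / w.mean() if w.mean() > 0 else np.ones(n)
        cell_rate = np.clip(np.outer(w, miss_rate), 0, 0.95)
    else:
        cell_rate = np.broadcast_to(miss_rate, (n, C))
    u = rng.random((n, C))
    kinds[u < cell_rate] = MISSING
    if config.inapplicable_rate > 0:
        v = rng.random((n, C))
        kinds[(u >= cell_rate) & (v < config.inapplicable_rate)] = INAPPLICABLE
    masks[kinds != OBSERVED] = 0
    charsets = {
        "cranio": list(range(config.n_cranio)),
        "post": list(range(config.n_cranio, C)),
    }
    matrix = CharacterMatrix(taxa, masks, kinds, alphabet=4, charsets=charsets)
    labels = tuple([CRANIO] * config.n_cranio + [POST] * config.n_post)
    return SimResult(
        matrix=matrix, scheme=PartitionScheme(labels),
        tree_cranio=sim1.unrooted(), tree_post=sim2.unrooted(),
        sim_tree_cranio=sim1, sim_tree_post=sim2, config=config,
    )


def simulate_strat_ranges(sim: SimTree, noise_scale: float, rng):
    """First appearances from the generating tree: each leaf's true lineage
    origination age (its parent node's age) minus exponential undersampling
    noise with mean `noise_scale` x tree depth, truncated at zero.  With
    zero noise the ranges are perfectly congruent with the tree
    (MIG = Gmin, GER = 1)."""
    from .stratigraphy import StratRanges
    n = len(sim.taxa)
    depth = sim.age.max()
    fad = {}
    for i, t in enumerate(sim.taxa):
        origin = sim.age[sim.parent[i]]
        noise = rng.exponential(noise_scale * depth) if noise_scale > 0 else 0.0
        fad[t] = max(0.0, origin - noise)
    return StratRanges(fad)
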