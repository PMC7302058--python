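"""Lightweight tree containers used throughout the package.

Unrooted topologies are stored as sets of splits (bipartitions of the leaf
set), which is the natural currency for the distance metrics, consensus
methods and permutation tests implemented here.  A split is encoded as an
integer bitmask over the taxon indices, canonicalised so that the stored
side never contains taxon 0.  Rooted trees (needed for stratigraphic
congruence and tree-shape statistics) are stored as an explicit parent/child
structure built either from a rooted Newick string or by rooting an
unrooted tree on the pendant edge of a named taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy


def popcount(x: int) -> int:
    return int(x).bit_count()


def canonical_split(mask: int, n_taxa: int) -> int:
    """Return the side of the bipartition that does not contain taxon 0."""
    full = (1 << n_taxa) - 1
    if mask & 1:
        mask = full & ~mask
    return mask


def is_nontrivial(mask: int, n_taxa: int) -> bool:
    p = popcount(mask)
    return 2 <= p <= n_taxa - 2


class Tree:
    """An unrooted (possibly multifurcating) tree on a fixed, ordered leaf set.

    Two trees compare equal iff they are on the same ordered taxon tuple and
    induce the same set of nontrivial splits.
    """

    __slots__ = ("taxa", "splits", "length")

    def __init__(self, taxa: Sequence[str], splits: Iterable[int], length: int | None = None):
        self.taxa = tuple(taxa)
        n = len(self.taxa)
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxon labels in tree")
        canon = frozenset(
            canonical_split(int(s), n) for s in splits if is_nontrivial(int(s), n)
        )
        self.splits = canon
        self.length = length

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Tree)
            and self.taxa == other.taxa
            and self.splits == other.splits
        )

    def __hash__(self) -> int:
        return hash((self.taxa, self.splits))

    def __repr__(self) -> str:
        return f"Tree({self.n_taxa} taxa, {len(self.splits)} splits)"

    def is_binary(self) -> bool:
        return len(self.splits) == self.n_taxa - 3

    @classmethod
    def from_newick(cls, newick: str, taxa: Sequence[str] | None = None) -> "Tree":
        rt = RootedTree.from_newick(newick, taxa=taxa)
        return rt.unrooted()

    def to_newick(self) -> str:
        """Serialise, rooted arbitrarily on the pendant edge of taxon 0."""
        return RootedTree.from_unrooted(self, root_on=self.taxa[0]).to_newick()

    def rooted(self, root_on: str) -> "RootedTree":
        return RootedTree.from_unrooted(self, root_on=root_on)


@dataclass
class _Node:
    clade: int                      # leaf bitmask of the subtree
    children: list = field(default_factory=list)
    taxon: int | None = None        # leaf index for terminals


class RootedTree:
    """A rooted tree with explicit internal nodes (polytomies allowed)."""

    def __init__(self, taxa: Sequence[str], root: _Node):
        self.taxa = tuple(taxa)
        self.root = root

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def nodes(self):
        """Preorder iteration over nodes."""
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(v.children)

    def internal_nodes(self):
        return [v for v in self.nodes() if v.children]

    @classmethod
    def from_newick(cls, newick: str, taxa: Sequence[str] | None = None) -> "RootedTree":
        """Parse a Newick string, honouring the rooting as written."""
        dt = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        labels = sorted(lf.taxon.label for lf in dt.leaf_node_iter())
        if taxa is None:
            taxa = labels
        elif sorted(taxa) != labels:
            raise ValueError("newick leaf set does not match the supplied taxa")
        index = {t: i for i, t in enumerate(taxa)}

        def build(dnode) -> _Node:
            if dnode.is_leaf():
                i = index[dnode.taxon.label]
                return _Node(clade=1 << i, taxon=i)
            kids = [build(c) for c in dnode.child_nodes()]
            clade = 0
            for k in kids:
                clade |= k.clade
            return _Node(clade=clade, children=kids)

        root = build(dt.seed_node)
        # a degree-2 root written as (A,(B,C)) is kept exactly as written
        return cls(taxa, root)

    @classmethod
    def from_unrooted(cls, tree: Tree, root_on: str) -> "RootedTree":
        """Root an unrooted tree on the pendant edge of `root_on`."""
        if root_on not in tree.taxa:
            raise ValueError(f"root taxon {root_on!r} not in tree")
        n = tree.n_taxa
        full = (1 << n) - 1
        ridx = tree.taxa.index(root_on)
        rbit = 1 << ridx
        # clades of the rooted tree: for every split, the side away from root_on
        clades = []
        for s in tree.splits:
            away = s if not (s & rbit) else (full & ~s)
            clades.append(away)
        rest = full & ~rbit
        if rest not in clades and popcount(rest) > 1:
            clades.append(rest)
        # laminar family -> forest; attach leaves, build nesting
        nodes = {c: _Node(clade=c) for c in set(clades)}
        for i in range(n):
            nodes[1 << i] = _Node(clade=1 << i, taxon=i)
        order = sorted(nodes, key=popcount)       # small to large
        placed = {}
        for c in order:
            # parent = smallest strict superset
            best = None
            for d in nodes:
                if d != c and (c & d) == c and (best is None or popcount(d) < popcount(best)):
                    best = d
            placed[c] = best
        for c, p in placed.items():
            if p is not None:
                nodes[p].children.append(nodes[c])
        root = _Node(clade=full, children=[nodes[rbit], nodes[rest]])
        return cls(tree.taxa, root)

    def unrooted(self) -> Tree:
        n = self.n_taxa
        splits = [v.clade for v in self.nodes() if v.children]
        return Tree(self.taxa, splits)

    def to_newick(self) -> str:
        def render(v: _Node) -> str:
            if v.taxon is not None:
                return _quote(self.taxa[v.taxon])
            return "(" + ",".join(render(c) for c in v.children) + ")"
        return render(self.root) + ";"


def _quote(label: str) -> str:
    if any(ch in label for ch in " (),:;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def tree_from_splits(taxa: Sequence[str], splits: Iterable[int], length: int | None = None) -> Tree:
    return Tree(taxa, splits, length=length)


def splits_compatible(a: int, b: int) -> bool:
    """Compatibility of two canonical splits (neither side contains taxon 0)."""
    return (a & b) == 0 or (a & b) == a or (a & b) == b
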