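"""Stratigraphic congruence of trees against first-appearance ages.

Ages are "time before present": larger is older.  Internal node ages are
the oldest first-appearance datum (FAD) among descendants, and the minimum
implied gap (MIG) sums, over the edges of the rooted tree, the ghost-lineage
durations those ages force.  The indices:

* GER  = 1 - (MIG - Gmin) / (Gmax - Gmin): MIG rescaled between the best
  (Gmin) and worst (Gmax) totals attainable for the same set of ages;
* MSM* = Gmin / MIG (1 when both are 0);
* SCI  = fraction of non-root internal nodes whose clade's oldest FAD is
  no older than the oldest FAD of its sister lineage(s);
* GER* = the proportion of random reassignments of the ages to the leaves
  whose MIG is at least the observed MIG (larger = more congruent than
  random), estimated by seeded permutation.

Trees may be given rooted (used as written) or unrooted with an explicit
outgroup taxon to root on.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .trees import RootedTree
from .treemath import _as_rooted

__all__ = [
    "StratRanges", "StratResult", "read_ranges",
    "mig", "strat_baselines", "strat_indices", "ger_star", "strat_summary",
]


@dataclass
class StratRanges:
    """First (and optionally last) appearance ages per taxon."""

    fad: dict
    lad: dict | None = None

    def __post_init__(self):
        for t, v in self.fad.items():
            if v < 0:
                raise ValueError(f"negative FAD for {t!r}")
            if self.lad and t in self.lad and not (v >= self.lad[t] >= 0):
                raise ValueError(f"FAD < LAD for {t!r}")

    def ages_for(self, taxa: Sequence[str]) -> np.ndarray:
        missing = [t for t in taxa if t not in self.fad]
        if missing:
            raise ValueError(f"no FAD for taxa: {missing}")
        return np.array([self.fad[t] for t in taxa], float)


def read_ranges(path) -> StratRanges:
    """Load a taxon,FAD[,LAD] CSV."""
    fad: dict = {}
    lad: dict = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            t = row["taxon"]
            fad[t] = float(row["FAD"])
            if row.get("LAD") not in (None, ""):
                lad[t] = float(row["LAD"])
    return StratRanges(fad, lad or None)


def _node_ages(rt: RootedTree, ages: np.ndarray) -> dict:
    """Node age = oldest descendant FAD."""
    out = {}

    def walk(v):
        if v.taxon is not None:
            out[id(v)] = ages[v.taxon]
        else:
            out[id(v)] = max(walk(c) for c in v.children)
        return out[id(v)]

    walk(rt.root)
    return out


def mig(tree, ranges: StratRanges, root_on: str | None = None) -> float:
    """Minimum implied gap: summed ghost-lineage durations on the rooted tree."""
    rt = _as_rooted(tree, root_on)
    ages = ranges.ages_for(rt.taxa)
    node_age = _node_ages(rt, ages)
    total = 0.0
    for v in rt.nodes():
        for c in v.children:
            total += max(0.0, node_age[id(v)] - node_age[id(c)])
    return total


def strat_baselines(ranges: StratRanges, taxa: Sequence[str]) -> tuple:
    """(Gmin, Gmax): the best and worst possible MIG for these ages.

    With ages sorted oldest-first t1 >= ... >= tn: Gmin = t1 - tn (a
    perfectly age-ordered pectinate tree) and Gmax = sum_{i>=2} (t1 - ti)
    (every younger lineage diverging straight from the oldest).
    """
    if len(taxa) < 3:
        raise ValueError("need at least 3 dated taxa")
    t = np.sort(ranges.ages_for(taxa))[::-1]
    gmin = float(t[0] - t[-1])
    gmax = float(np.sum(t[0] - t[1:]))
    return gmin, gmax


def strat_indices(tree, ranges: StratRanges, root_on: str | None = None) -> dict:
    """GER, MSM* and SCI for one rooted tree (plus MIG/Gmin/Gmax)."""
    rt = _as_rooted(tree, root_on)
    g = mig(rt, ranges)
    gmin, gmax = strat_baselines(ranges, rt.taxa)
    if gmax > gmin:
        ger = 1.0 - (g - gmin) / (gmax - gmin)
    else:
        ger = float("nan")
    msm = gmin / g if g > 0 else 1.0
    sci = _sci(rt, ranges)
    return {"MIG": g, "Gmin": gmin, "Gmax": gmax,
            "GER": ger, "MSM*": msm, "SCI": sci}


def _sci(rt: RootedTree, ranges: StratRanges) -> float:
    """Fraction of non-root internal nodes whose clade's oldest FAD is not
    older than its sister lineage's oldest; at a polytomy each internal
    child is judged against the oldest of its siblings."""
    ages = ranges.ages_for(rt.taxa)
    node_age = _node_ages(rt, ages)
    consistent = 0
    n_nodes = 0
    stack = [rt.root]
    while stack:
        v = stack.pop()
        for c in v.children:
            if c.children:          # internal, non-root by construction
                n_nodes += 1
                sib_age = max(node_age[id(s)] for s in v.children if s is not c)
                if node_age[id(c)] <= sib_age:
                    consistent += 1
            stack.append(c)
    if n_nodes == 0:
        return float("nan")
    return consistent / n_nodes


def ger_star(
    tree,
    ranges: StratRanges,
    root_on: str | None = None,
    permutations: int = 10_000,
    seed: int | None = None,
) -> float:
    """Permutation-calibrated gap excess: the proportion of random
    age-to-leaf reassignments with MIG >= the observed MIG."""
    rt = _as_rooted(tree, root_on)
    ages = ranges.ages_for(rt.taxa)
    observed = mig(rt, ranges)
    rng = np.random.default_rng(seed)
    count = 0
    taxa = rt.taxa
    for _ in range(permutations):
        perm = rng.permutation(len(taxa))
        shuffled = StratRanges({t: ages[perm[i]] for i, t in enumerate(taxa)})
        if mig(rt, shuffled) >= observed:
            count += 1
    return count / permutations


@dataclass
class StratResult:
    """Per-tree stratigraphic congruence plus means across a tree set."""

    per_tree: list                 # list of dicts (MIG, Gmin, Gmax, GER, MSM*, SCI, GER*)
    permutations: int
    seed: int | None
    means: dict = field(default_factory=dict)


def strat_summary(
    trees,
    ranges: StratRanges,
    root_on: str | None = None,
    permutations: int = 10_000,
    seed: int | None = None,
) -> StratResult:
    """Indices for every tree in a set, reported per tree and as means
    across the equally parsimonious trees."""
    rows = []
    for i, t in enumerate(trees):
        row = strat_indices(t, ranges, root_on)
        row["GER*"] = ger_star(t, ranges, root_on, permutations=permutations,
                               seed=None if seed is None else seed + i)
        rows.append(row)
    keys = rows[0].keys()
    means = {k: float(np.nanmean([r[k] for r in rows])) for k in keys}
    return StratResult(rows, permutations, seed, means)
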