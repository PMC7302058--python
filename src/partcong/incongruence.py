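"""Permutation tests of character-partition incongruence.

Two families are implemented over a shared engine:

* the incongruence length difference (ILD) test, whose statistic is the
  extra parsimony length required when both partitions are analysed
  together, L_AB - (L_A + L_B); and
* the incongruence relationship difference (IRD) test, whose statistic is
  a tree-to-tree distance (RF or matching) between the two partitions'
  optimal tree sets, either as a mean nearest-neighbour distance (NND) or
  as the distance between majority-rule-plus-compatible consensus trees
  (MR).

In both, the observed statistic is compared with its distribution over
random bipartitions of the analysed characters in the original
proportions, each re-searched identically, and the p-value uses the
add-one rule p = (1 + #{null >= observed}) / (R + 1), so the smallest
attainable p is 1/(R+1) and ties count toward rejection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matrix_io import CharacterMatrix, PartitionScheme
from .parsimony import SearchConfig, TreeSet, heuristic_search
from .treemath import mean_nnd, majority_rule_consensus, _resolve_metric

__all__ = [
    "IncongruenceResult", "ild_statistic", "ird_statistic",
    "random_bipartition", "ild_test", "ird_test", "incongruence_suite",
]


@dataclass
class IncongruenceResult:
    method: str                    # "ILD" | "IRD"
    metric: str                    # "steps" | "RF" | "matching"
    mode: str | None               # None | "NND" | "MR"
    observed: float
    null: np.ndarray
    replicates: int
    seed: int | None
    size_a: int
    size_b: int
    extra: dict = field(default_factory=dict)

    @property
    def p_value(self) -> float:
        null = np.asarray(self.null, float)
        return float((1 + np.sum(null >= self.observed)) / (len(null) + 1))


def ild_statistic(l_ab: int, l_a: int, l_b: int) -> int:
    """ILD = L_AB - (L_A + L_B); nonnegative when all lengths are optimal."""
    ild = int(l_ab) - int(l_a) - int(l_b)
    if ild < 0:
        warnings.warn(
            f"negative ILD ({ild}): one of the searches was not optimal")
    return ild


def ird_statistic(
    trees_a: TreeSet,
    trees_b: TreeSet,
    metric: str = "matching",
    mode: str = "NND",
    cap: int | None = None,
    seed: int | None = None,
) -> float:
    """Tree-distance incongruence statistic between two optimal tree sets."""
    if not len(trees_a) or not len(trees_b):
        raise ValueError("empty tree set")
    if mode == "NND":
        return mean_nnd(trees_a.trees, trees_b.trees, metric=metric,
                        cap=cap, seed=seed)
    if mode == "MR":
        d = _resolve_metric(metric)
        return float(d(majority_rule_consensus(trees_a.trees),
                       majority_rule_consensus(trees_b.trees)))
    raise ValueError(f"unknown mode {mode!r} (use 'NND' or 'MR')")


def random_bipartition(chars: Sequence[int], size_a: int, rng) -> tuple:
    """Uniform split of `chars` into disjoint sets of sizes (size_a, rest)."""
    chars = list(chars)
    if not 0 < size_a < len(chars):
        raise ValueError("size_a must be strictly between 0 and len(chars)")
    perm = rng.permutation(len(chars))
    a = sorted(chars[i] for i in perm[:size_a])
    b = sorted(chars[i] for i in perm[size_a:])
    return tuple(a), tuple(b)


def _child_seed(ss: np.random.SeedSequence, *key) -> int:
    return int(np.random.SeedSequence(
        entropy=ss.entropy, spawn_key=key).generate_state(1)[0] % (2 ** 31))


def incongruence_suite(
    matrix: CharacterMatrix,
    scheme: PartitionScheme,
    config: SearchConfig = SearchConfig(),
    ild_replicates: int = 999,
    ird_replicates: int = 99,
    metrics: Sequence[str] = ("RF", "matching"),
    modes: Sequence[str] = ("NND", "MR"),
    seed: int | None = None,
    run_ild: bool = True,
    run_ird: bool = True,
) -> dict:
    """Run the ILD and all requested IRD variants, sharing searches.

    All IRD variants reuse the same per-replicate searches; when
    ild_replicates == ird_replicates the ILD shares them too.  Returns a
    dict keyed by 'ILD' and 'IRD_{mode}+{metric}'.
    """
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    cranio = scheme.cranio
    post = scheme.post
    if not cranio or not post:
        raise ValueError("both partitions must be nonempty")
    analysed = scheme.analysed
    cap = config.nnd_tree_cap

    def search(chars, *key) -> TreeSet:
        return heuristic_search(matrix, chars, config, seed=_child_seed(ss, *key))

    trees_c = search(cranio, 0, 0)
    trees_p = search(post, 0, 1)
    trees_all = search(analysed, 0, 2) if run_ild else None

    results: dict = {}
    rng = np.random.default_rng(_child_seed(ss, 1))

    shared = run_ild and run_ird and ild_replicates == ird_replicates
    n_shared = max(ild_replicates if run_ild else 0,
                   ird_replicates if run_ird else 0) if shared else 0

    def replicate_searches(n, tag):
        for r in range(n):
            a, b = random_bipartition(analysed, len(cranio), rng)
            ta = search(a, tag, r, 0)
            tb = search(b, tag, r, 1)
            yield r, ta, tb

    if run_ild:
        obs_ild = ild_statistic(trees_all.score, trees_c.score, trees_p.score)
    if run_ird:
        obs_ird = {
            (mode, met): ird_statistic(
                trees_c, trees_p, metric=met, mode=mode, cap=cap,
                seed=_child_seed(ss, 2, i, j))
            for i, mode in enumerate(modes) for j, met in enumerate(metrics)
        }

    null_ild = []
    null_ird = {k: [] for k in obs_ird} if run_ird else {}

    if shared:
        for r, ta, tb in replicate_searches(n_shared, 3):
            null_ild.append(ta.score + tb.score)
            for i, mode in enumerate(modes):
                for j, met in enumerate(metrics):
                    null_ird[(mode, met)].append(ird_statistic(
                        ta, tb, metric=met, mode=mode, cap=cap,
                        seed=_child_seed(ss, 3, r, 2, i, j)))
        # ILD null: L_AB is fixed; null statistic is L_AB - (L_A' + L_B')
        null_ild = [trees_all.score - s for s in null_ild]
    else:
        if run_ild:
            for r, ta, tb in replicate_searches(ild_replicates, 4):
                null_ild.append(trees_all.score - ta.score - tb.score)
        if run_ird:
            for r, ta, tb in replicate_searches(ird_replicates, 5):
                for i, mode in enumerate(modes):
                    for j, met in enumerate(metrics):
                        null_ird[(mode, met)].append(ird_statistic(
                            ta, tb, metric=met, mode=mode, cap=cap,
                            seed=_child_seed(ss, 5, r, 2, i, j)))

    if run_ild:
        results["ILD"] = IncongruenceResult(
            "ILD", "steps", None, float(obs_ild),
            np.asarray(null_ild, float), len(null_ild), seed,
            len(cranio), len(post),
            extra={"L_AB": trees_all.score, "L_A": trees_c.score,
                   "L_B": trees_p.score},
        )
    if run_ird:
        for (mode, met), obs in obs_ird.items():
            results[f"IRD_{mode}+{met}"] = IncongruenceResult(
                "IRD", met, mode, float(obs),
                np.asarray(null_ird[(mode, met)], float),
                len(null_ird[(mode, met)]), seed, len(cranio), len(post),
            )
    return results


def ild_test(
    matrix: CharacterMatrix,
    scheme: PartitionScheme,
    config: SearchConfig = SearchConfig(),
    replicates: int = 999,
    seed: int | None = None,
) -> IncongruenceResult:
    """Incongruence length difference permutation test."""
    res = incongruence_suite(
        matrix, scheme, config, ild_replicates=replicates,
        seed=seed, run_ird=False)
    return res["ILD"]


def ird_test(
    matrix: CharacterMatrix,
    scheme: PartitionScheme,
    config: SearchConfig = SearchConfig(),
    metric: str = "matching",
    mode: str = "NND",
    replicates: int = 99,
    seed: int | None = None,
) -> IncongruenceResult:
    """Incongruence relationship difference permutation test."""
    res = incongruence_suite(
        matrix, scheme, config, ird_replicates=replicates,
        metrics=[metric], modes=[mode], seed=seed, run_ild=False)
    return res[f"IRD_{mode}+{metric}"]
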