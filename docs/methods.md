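# Methods

`partcong` implements a complete partition-incongruence analysis for
discrete morphological character matrices: given a taxon x character matrix
whose characters are labelled craniodental (skull + dentition) or
postcranial (vertebral column, girdles, limbs), it asks whether the two
anatomical partitions imply significantly different trees, which partition
the total-evidence signal follows, and how each partition's trees fare
against the fossil record.  This note documents the models, conventions and
numerical choices behind each stage, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Matrices and curation

Cells are observed state sets (singletons for fixed scores; multi-state
sets for polymorphism or uncertainty — the `{..}` and `(..)` NEXUS
notations are decoded identically), missing (`?`) or inapplicable (`-`).
Missing and inapplicable are stored separately so completeness filters can
count both, but they are interchangeable everywhere else: in parsimony
scoring both are fully ambiguous and can never force a step.

Curation is a single pass: first delete every taxon whose
missing+inapplicable fraction exceeds the threshold (default 0.40) within
*either* analysis partition; then delete characters the taxon removal has
degraded — rendered parsimony-uninformative (fewer than two states each
fixed in at least two taxa) or newly invariant, which also catches
autapomorphies that collapse to constant columns.  An `iterate` flag
repeats the pass to a fixpoint but defaults off, matching the stated
taxa-then-characters order.  Between-matrix overlap screening counts shared
(taxon, character) *positions* — not identical scores — as a percentage of
the smaller matrix's cells; character identity defaults to exact label
match, with an explicit mapping for curated/renumbered matrices.

## Parsimony scoring and search

All characters are unordered and equally weighted (source orderings are not
modelled; see Limitations).  Fixed-state alphabets up to 32 states are
encoded as bitmasks; polymorphic cells enter optimisation as their state
set, satisfiable at no cost by any member, while the per-character bounds
m (minimum steps on any tree) and g (star-tree steps) use only fixed
singleton scores to avoid ambiguity inflating the ensemble indices.
`fitch_length` is exact on multifurcating trees (unit-cost dynamic
programming; on binary trees it reduces to Fitch counting).

The heuristic search follows the classic protocol: random stepwise
addition holding the `hold_per_step` best partial trees (ties beyond the
hold broken by seeded jitter), then tree-bisection-and-reconnection
branch swapping.  TBR rescoring uses an exact identity: joining components
S1 and S2 by an edge subdividing e1 and e2 yields length
`L(S1) + L(S2) + #{characters whose e1 and e2 root state sets are
disjoint}`, where the root state set of an edge is the Fitch down-pass set
of the component rooted on that edge.  One down/up pass per component
yields every edge's root set, so each reconnection is scored in O(#chars)
— this is what makes thousands of permutation-replicate searches feasible
in pure Python + numba.  Equal-best trees are collected by exhaustive
plateau walking bounded by `maxtrees`.  Searches accept up to 64 taxa
(leaf-set bitmasks in a machine word).

Zero-length-branch collapse implements the "amb-" convention: an internal
branch is contracted when, for every character, some jointly optimal
reconstruction places no change on it (per character the test is
`min_s(A[s] + D[s]) == total`, with A and D the directional unit-cost DP
vectors).  Identical collapsed topologies are merged.  Collapse never
changes tree length.

Ensemble CI = M/S and RI = (G−S)/(G−M) are computed over
parsimony-informative characters by default (a flag includes uninformative
ones, since scoring conventions differ between programs); S is identical
across the equally optimal trees, so one tree is scored.  RI is flagged
undefined when G = M.

Two presets bundle the settings: the full protocol (25 additions, hold 10,
100,000 `maxtrees`, 1000-tree distance cap, 999 ILD / 99 IRD replicates,
100 jackknife resamples, 10,000 age permutations) and a desk preset
(5 additions, hold 10, 24 `maxtrees`, 12-tree cap, 49 replicates,
25 resamples, 1000 permutations) whose problem sizes keep a complete
simulated analysis in seconds; the test suite and all worked examples run
at desk scale.

## Tree comparison

Trees are stored as sets of nontrivial splits (bitmasks canonicalised to
the side not containing taxon 0).  RF distance is the symmetric-difference
count.  The matching distance solves a minimum-cost perfect matching
between the two split lists (Hungarian method) with pair cost
`min(|A xor C|, |A xor D|)`; when collapse leaves the trees with unequal
split counts the shorter list is padded with dummy splits costing
`min(|A|, |B|)` against a real split and 0 against another dummy.  Between
tree *sets*, the nearest-neighbour distance (NND) averages, over each tree
of one set, the distance to its most similar tree in the other set; both
directions are averaged by default (a one-directional variant is a flag),
and sets are first subsampled uniformly (seeded) to the configured cap.
Majority-rule consensus keeps splits in >50% of trees and, in the
plus-compatible variant, greedily adds remaining splits in descending
frequency (ties broken by canonical mask) when compatible with everything
accepted.  Colless's imbalance sums |left − right| leaf counts over
bifurcating nodes; % resolution is 100 x internal nodes / (terminals − 1)
on the rooted tree.

## Incongruence tests

The ILD statistic is `L_AB − (L_A + L_B)`; the IRD statistic is a
tree-distance (RF or matching) between the two partitions' optimal tree
sets, either as NND or as the distance between the two
majority-rule-plus-compatible consensus trees.  Both tests compare the
observed statistic with its distribution over random bipartitions of the
analysed characters in the original proportions ("other"-labelled
characters never enter), each bipartition re-searched with the same
settings under fresh seeds derived from the master seed.  The p-value uses
the add-one rule `p = (1 + #{null >= observed})/(R + 1)` with ties counting
toward rejection, so p lives on the grid k/(R+1) with minimum 1/(R+1).
The four IRD variants share one set of replicate searches, and the ILD
shares it too when the replicate counts agree.

Because the ILD statistic is a small integer, ties with the null are
common on weak data and the test is slightly conservative at desk scale —
the calibration run (100 signal-free 10x40 matrices, R = 49) lands at 2%
ILD and 5% IRD rejections at the 5% level, inside the 95% binomial band.

## The jackknife partition-vs-entire comparison

A larger partition contributes more characters to the entire matrix, so
raw partition-to-entire distances are biased.  Per resample the larger
partition is subsampled without replacement to the smaller partition's
size n (the smaller is used whole), and an entire-matrix sample of n
characters is drawn half from each partition, the extra character for odd
n alternating sides by resample index (odd indices favour craniodental).
Trees are inferred from all three samples — every comparison rests on
exactly n characters — and the mean NND matching distance from each
partition sample to the entire sample is recorded.  The winner is the side
with the smaller mean over resamples (medians are also reported); the
headline p-value is the paired Wilcoxon signed-rank test on the
per-resample pairs, with an unpaired Mann-Whitney U p-value alongside.
The entire-sample draw is independent of the larger-partition draw within
a resample.  Entire-matrix trees are re-inferred per resample, so all
three tree sets share the same sampling noise.

Two behavioural notes a user should know, both visible in the power
analysis below: the NND statistic mildly rewards diverse or poorly
resolved tree sets (a scattered set more often contains a near neighbour,
and dummy-split padding shrinks distances between poorly resolved trees),
so partitions of very unequal homoplasy are compared on resolution as much
as on signal; and label swapping is tested behaviourally (a planted winner
flips when the partition labels are swapped) rather than bit-exactly,
since RNG streams are keyed by position, not by label.

## Stratigraphic congruence

Ages are time before present (larger = older); every leaf needs a first
appearance (FAD).  Node age is the oldest descendant FAD, and MIG sums the
ghost-lineage durations the rooted tree forces.  With ages sorted
t1 >= ... >= tn, Gmin = t1 − tn and Gmax = sum(t1 − ti, i >= 2).
GER = 1 − (MIG − Gmin)/(Gmax − Gmin) (undefined when Gmax = Gmin);
MSM* = Gmin/MIG (1 when MIG = 0); SCI is the fraction of non-root internal
nodes whose clade's oldest FAD is no older than its sister lineage's — at
a polytomy each internal child is judged against the oldest of its
siblings.  GER* is the proportion of seeded random age-to-leaf
reassignments whose MIG is at least the observed (ties included), so
larger = more congruent; it is realised as a rank statistic rather than a
closed formula, and GER and GER* are invariant to affine rescaling of the
ages.  Trees can be supplied rooted (used as written) or unrooted with an
explicit outgroup to root on; per tree set, indices are reported per tree
and as means across the equally parsimonious trees.

## Cross-study statistics

The packaged 81-study table (one row per published dinosaur matrix:
partition sizes, five test p-values, missing percentages, ensemble CI/RI,
and the partition-vs-entire winner) is checksummed and validated on load.
On it the package computes significance tallies by clade, likelihood-ratio
G tests (`2 sum O ln(O/E)`, 0 ln 0 = 0, df = (r−1)(c−1)) of rate
heterogeneity, paired Wilcoxon signed-rank comparisons, exact two-sided
binomial tests (point-probability definition), Spearman rank correlations
(average ranks; the p-values in the table are printed to 2-3 decimals, so
rank ties are real and tie-corrected), and the dimension-corrected
homoplasy comparison: OLS of CI on log(#characters), log(#taxa) and their
interaction over the 162 pooled partition observations, followed by the
paired signed-rank test on craniodental vs postcranial residuals.  The
Wilcoxon statistic is reported as V = the sum of average ranks of
*positive* craniodental-minus-postcranial differences after dropping
zeros; the mirrored orientation gives the n(n+1)/2 complement.  Wilcoxon
and Mann-Whitney p-values use exact enumeration without ties/zeros and the
tie-corrected normal approximation otherwise; V, G and rho are the primary
quantities, p-values are secondary.  A 2x2 G test associates the
total-evidence winner with the stratigraphic winner across studies.

## Synthetic data

The generator's defaults emulate the dimensions of recent published
dinosaur matrices: 20 taxa (observed range ~12-35), 115 craniodental +
133 postcranial characters (the empirical means), 2-4 states per character
(60/30/10%), ~30% missing entries, and enough homoplasy
(`expected_changes = 3` substitutions per character over the whole tree,
gamma rate heterogeneity with shape 1) to put the ensemble CI in the
empirical 0.4-0.9 band.  Characters evolve under a symmetric k-state
Markov process (transition probability
`1/k + (k−1)/k exp(−k mu t/(k−1))` per branch) on a uniform random binary
topology; the postcranial generating tree is the craniodental tree moved
by `spr_separation` random SPR moves (the move list is recorded and
replayable; an optional RF floor redraws paths whose moves cancel).
Branch lengths are exponential(1) (optionally floored — near-zero internal
edges are irrecoverable in principle), rescaled so a rate-1 character
expects `expected_changes` changes.  Missingness is uniform per cell or
concentrated per taxon (beta-distributed propensities emulating partial
skeletons).  Two planted-signal dials exist: a per-partition rate override
(cleaner vs noisier signal) and a mosaic fraction routing part of the
postcranial partition onto the craniodental tree.  Stratigraphic ranges
set each leaf's FAD to its lineage origination (parent node) age minus
exponential undersampling noise (mean = `strat_noise` x tree depth),
truncated at zero.

What the generator does *not* emulate: real character correlation
structure beyond the two-partition split, ordered or weighted characters,
directional sampling biases in which anatomical regions get coded, and
non-exchangeable missingness tied to taxonomy.  Passing tests therefore
demonstrate that the machinery behaves correctly under a clean two-signal
model, not that any empirical effect size will be reproduced.

A point worth stating precisely: zero sampling noise does **not** imply
GER = 1 on an arbitrary topology.  GER = 1 requires MIG = Gmin, and on a
balanced tree the minimum MIG over *all* age assignments already exceeds
Gmin (ages 10,8,6,4 on ((A,B),(C,D)): best assignment gives MIG 8 vs
Gmin 6) — Gmin is attained only by age-ordered pectinate arrangements.
At zero noise the generator's ranges are perfectly congruent in the
attainable sense (FADs equal origination ages; congruence degrades
monotonically as noise grows), and GER = 1 holds exactly when the
generating tree is pectinate, which is what the tests assert.

## Calibration and power conditions

The suite's statistical checks run at documented desk-scale conditions:

* **Null calibration** — 100 matrices of i.i.d. binary states (10 taxa x
  40 characters, 20+20 split), ILD and IRD(NND+matching) with R = 49.
  Exchangeability makes the permutation test exact; rejection at the 5%
  level must stay in the 95% binomial band (observed: 2% ILD, 5% IRD).
* **IRD power** — generating trees 5 SPR apart, 20 taxa, 100+100
  characters, craniodental/postcranial expected changes 2.0/3.0, gamma
  shape 5, 3-4-state characters, branch floor 0.5, no missing data,
  R = 19.  The mild strength asymmetry matters: with two *equally* strong
  clean signals, random bipartitions resolve each contested clade
  bistably, the null distribution stretches to the observed distance, and
  no statistic of this family can sit reliably at the p-grid minimum —
  an intrinsic property of balanced clean conflict, not an implementation
  artefact.
* **Jackknife power** — same dimensions with 3 SPR separation, equal rates
  (3.0), and 30% of postcranial characters tracking the craniodental tree,
  so the entire matrix's dominant signal is craniodental while the
  postcranial partition keeps its own tree.  At 5 SPR the conflict is
  spread over many clades and parsimony's compromise trees for mixed
  samples sit no closer to the dominant signal than to the minority one,
  so a localized (3-move) conflict is the condition under which the
  planted winner is recoverable.

## Numerical choices and degenerate inputs

Master seeds fan out to every search, bipartition, subsample and
permutation through named `SeedSequence` spawn keys, so whole analyses are
bit-reproducible.  Searches with fewer than 4 taxa raise; with no
informative characters they return the star tree with a warning.  A single
jackknife resample reports a winner but a NaN p-value (flagged).  All-zero
Wilcoxon differences, constant Spearman inputs and G tables with empty
margins are flagged or raised rather than silently propagated.  RI is NaN
when G = M; GER is NaN when all ages are equal.  The matrix container
rejects duplicate taxa, out-of-alphabet states and malformed charsets at
construction.

## Limitations

Character ordering/weighting from source matrices is not modelled (all
characters unordered, equal weight).  The search's plateau collection is
bounded by `maxtrees`, so on very flat landscapes the MPT set is a
deterministic sample, not exhaustive.  Matrices are limited to 64 taxa in
the search kernel.  The NND statistic's diversity/resolution sensitivity
(above) means jackknife winners between partitions of very different
homoplasy should be read with care.  Stratigraphic range uncertainty
(interval FADs) and time-scaled trees are out of scope.
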