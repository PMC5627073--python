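# Methods

This note records the models, conventions and numerical choices behind
`parsimetrics`, in the order data flows through the package.

## Character model

Characters are discrete, unordered (non-additive) and equally weighted:
any state-to-state change costs one step, and no character outweighs
another. States are symbols from the NEXUS `SYMBOLS` list (default
`0123456789`), stored internally as bitmasks over symbol positions.

Missing data (`?`) and gaps (`-`) are both treated as "state unknown".
At a leaf, an unknown cell contributes the full set of states *observed
in that character's column* — never states that no taxon shows, so
missing data cannot invent evidence. Polymorphic cells such as `(01)`
are restricted state sets and behave in scoring exactly like a partial
unknown. A column in which every taxon is unknown carries no information
and is rejected at load time. Ordered (additive), weighted and
continuous characters are out of scope.

A character-type partition assigns every column to exactly one named
type. Partitions must be total and disjoint: an unlisted column is an
error rather than a silently defaulted one, because the contribution
metrics compare include/exclude subsets and an orphaned column would
silently bias both. Character indices are 0-based everywhere; NEXUS
`charset` input (1-based by convention) is converted on read, and
subsetting preserves each column's original index as metadata.

## Parsimony scoring

The length of a tree is the minimum number of state changes needed to
explain the matrix. On binary trees this is the classic Fitch
dynamic program (intersection if non-empty, else union, one step per
empty intersection). Multifurcating nodes — unavoidable in strict
consensus trees — are scored with Hartigan's frequency rule: count, for
each state, how many children's sets contain it; the node adds
`(number of children) − (maximum count)` steps and keeps the states
attaining the maximum. This is exact for minimum-mutation counts on
arbitrary trees and reduces to Fitch at binary nodes. Scoring roots the
tree on the edge of its lowest-indexed leaf (parsimony length is
rooting-invariant; the choice only fixes the traversal).

Correctness is established against an independent oracle that
enumerates every assignment of ancestral states (from the column's
observed alphabet) to internal nodes and counts changed edges —
exponential, but exact, and run over hundreds of seeded cases including
missing data and multifurcations. The suite also cross-checks the
engine against dendropy's Fitch implementation on binary trees.

Narrow matrices (≤ 48 characters) are scored with plain Python integer
bitmasks, wider ones with vectorised numpy; both paths share the same
recurrences and the threshold is a pure performance choice.

## Tree search

The heuristic follows the "traditional search" recipe:

* **Random addition.** Taxa are inserted in seeded random order, each at
  the attachment edge minimising the partial length; ties are broken by
  a seeded draw.
* **TBR swapping.** Every edge is bisected; the two parts are rejoined
  across every pair of their edges (a detached leaf reattaches
  directly). Strictly better trees restart the climb; equal-length (or
  within-margin) trees are queued breadth-wise up to the per-replicate
  cap, which explores plateaus of equally parsimonious trees.
* **Pooling.** Replicates are merged, deduplicated by bipartition set,
  filtered to the global margin and truncated to the buffer size, with
  a canonical deterministic ordering.

All randomness derives from one `SearchConfig.seed` through numpy's
`SeedSequence`, so identical configurations give bit-identical tree
sets. Shipped profiles: `traditional-150` and `traditional-10000`
(150 or 10 000 replicates, 200 trees per replicate, 30 000-tree buffer —
the two protocol profiles used in full-scale morphology studies), `fast`
(5 × 20, the desk-scale default) and `bootstrap-light` (2 × 5, the
default inside bootstrap pseudoreplicates).

`exhaustive_search` enumerates all `(2n−5)!!` unrooted binary topologies
(refusing more than 9 taxa, i.e. 135 135 topologies) and returns every
tree within an optional margin of the optimum. It is the ground truth
for heuristic optimality, Bremer values and metric fixtures in the test
suite and the acceptance script.

Trees are handled unrooted; a clade is the bipartition separating its
terminals from the rest, canonicalised as the side not containing the
lexicographically first taxon. Strict consensus keeps exactly the
bipartitions common to all inputs.

## Clade support

**Bootstrap.** Pseudoreplicate matrices resample the columns with
replacement; each is analysed with a (configurable, by default light)
search, and a clade counts iff it appears in that pseudoreplicate's
strict consensus — not frequency-weighted among tied trees. The
percentage is the fraction of counting pseudoreplicates. Because
pseudoreplicates are i.i.d., the Monte-Carlo standard error of the
percentage scales as `1/sqrt(B)`; the acceptance script measures this
empirically (100 vs 2500 pseudoreplicates, expected ≈ 5-fold
shrinkage).

**Bremer (decay).** The decay of a clade is the extra length of the best
tree *not* containing it. The default engine finds that tree by
converse-constrained search: candidate trees containing the clade are
rejected during swapping (and a start tree containing it is first moved
off it). The alternative reading — scanning a buffer of suboptimal
trees retained within a margin — is available as `engine="buffer"`, but
it can never report a decay larger than the margin, so large decay
values are structurally out of its reach; the constrained engine is
therefore the default and the buffer serves as a cross-check on small
cases. A clade absent from the strict consensus of the unconstrained
*optima* (a margin-retaining search also holds longer trees, which do
not define the consensus) has support 0 by convention, on both bases.

**Significance.** A clade is flagged significant iff bootstrap > 80%
AND Bremer > 3, both strictly: a clade at exactly 80% or exactly 3
steps does not qualify.

## Contribution metrics

For character type *i* and a clade with `n` terminal taxa:

* `Cs_i = S_i+ − S_i−`, where `S_i+` is the clade's support when only
  type-*i* columns are kept and `S_i−` its support when exactly those
  columns are removed. Positive `Cs_i` means the type carries clade
  signal that the rest of the matrix does not replace.
* `Cd_i = D_i+/(n−1) − D_i−/(n−1)`, where `D_i±` sum the support of
  resolved branches lying strictly inside the clade in the two
  analyses. For `n = 2` there are no internal branches and `Cd = 0`.

Both metrics are computed on the Bremer and the bootstrap basis; the
combined verdict is *positive overall* if any basis is positive.

Two readings of "within the clade" are possible: by default the clade's
own stem branch is excluded from the `D` sums (its support is exactly
what `Cs` measures, and counting it would mix the two metrics); the
`include_stem` flag implements the alternative. The divisor `n−1` is
applied literally as given, for either reading.

Each (type × include/exclude) subset analysis is run once and shared
across clades, metrics and bases, with its sub-seed derived
deterministically from the master seed and the subset's name — a full
metrics table is reproducible from a single integer.

## Synthetic fixtures

`plant_matrix` builds matrices with known answers on a known tree:

* a *clean* column marks one clade's terminals with state 1 — an
  uncontradicted synapomorphy costing exactly one step on the true
  tree. A clade planted with `k` clean columns and no conflicting
  signal has Bremer decay exactly `k`, which the support machinery must
  recover.
* a *homoplastic* column marks a random taxon subset forced to straddle
  the clade boundary (all four intersections with the clade split
  non-empty), guaranteeing character conflict.
* *filler* columns are constant and spread round-robin over the
  declared types so the partition stays total.
* optional noise flips one random cell of a planted column with a given
  probability.

Default type names ("general", "copulatory", "photophores") mirror a
three-type morphological matrix in roughly 116:74:59 proportions, so
metric tests exercise realistic type imbalance. Fixture generation is a
pure function of its `FixtureSpec`.

`mk_simulate` provides an unstructured noise model for robustness tests:
uniform root state, fixed per-edge probability of jumping to a
different uniform state, columns independent. Neither generator models
correlated characters, ordered states, asymmetric rates or
heterogeneity across lineages — passing tests demonstrate the
machinery's correctness on matrices with planted, separable signal, not
performance on real morphological data, where conflict structure is
richer.

## Problem sizes and tolerances

Desk-scale verification runs at 4–9 taxa, where exhaustive enumeration
is exact and fast: 200 oracle cases for scoring, 50 matrices for search
optimality, 15 planted-decay fixtures, 20 driver-type fixtures for Cs
sign recovery. Bootstrap checks use 200–2500 pseudoreplicates with the
1-replicate light profile. All scoring and search comparisons are
integer-exact; the only tolerance in the suite concerns the empirical
Monte-Carlo SE ratio, whose estimator from 16 + 8 runs is accepted in
the a-priori chi-square band [2.5, 10] around the theoretical 5, and a
factor-2.5 band around the binomial SE prediction.

## Known limitations

* No Sankoff (step-matrix) parsimony, implied weighting, ratchet,
  sectorial or driven search; plateau exploration is capped, so very
  large islands of equally parsimonious trees are sampled, not
  enumerated.
* Bootstrap percentages computed with the light per-pseudoreplicate
  profile can be mildly conservative on difficult matrices (a
  pseudoreplicate's search may miss its optimum); raise the profile for
  final analyses.
* Ancestral-state reconstructions and per-branch synapomorphy lists are
  not produced — lengths and support values only.
* The NEXUS dialect covers DATA/CHARACTERS + MATRIX, SETS/charset and
  TREES blocks; TNT-native files are not read.
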