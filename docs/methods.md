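# Methods

## The generative model

A dataset is `k` independent clusters.  Each cluster is built from one
species tree and `N_gen` observable gene trees evolved along it, selected so
the cluster's mean pairwise leaf-set overlap lies in an open band
`(p − tol, p + tol)` around the target level `p`.

### Species tree (Yule, planted root)

The species tree is a pure-birth tree: with `i` extant lineages the time to
the next split is exponential with rate `i·λ` and the splitting lineage is
uniform.  After the `n`-th lineage appears one further `Exp(n·λ)` waiting
time is added and all tips are cut there, so the tree is exactly ultrametric
and terminal branches are positive.  The root is *planted* (out-degree 1):
the stem length is the time of the first split, a single `Exp(λ)` draw.
Consequences used by the tests: a planted binary tree with `n` leaves has
`2n` nodes, and the expected height is `Σ_{i=1..n} 1/(i·λ)`.

`λ` defaults to 1.0; time units are arbitrary, and doubling `λ` halves all
heights.

### Sizing the species tree: the taxon universe

The species tree's leaf set is the cluster's taxon universe `U`; gene-tree
leaf sets are subsets of it.  The universe must be larger than the trees
themselves or small overlaps are *set-theoretically impossible*: two trees
with `n1`, `n2` leaves from a universe of size `U` share at least
`n1 + n2 − U` taxa, so e.g. two 12-leaf trees in a 15-leaf universe have
Jaccard overlap ≥ 9/15 = 0.6 no matter what the simulator does.  Within a
15-leaf universe virtually the only overlap-level value inside (0.49, 0.51)
is exactly 0.5 via counts (10, 11, c=7); rejection sampling there is
hopeless.  Published worked examples of this data type show the same thing
from the other side: clusters reported at `p = 0.5` with tree sizes 11–13
contain pairs whose union has 17–18 taxa.

We therefore size the species tree as

    U = max(L_max, round(nominal · (1 + p) / (2p))),   nominal ~ Uniform{L_min..L_max}.

The factor comes from a closed form: if each tree keeps a fraction
`r = n̄/U` of the universe, two independently retained leaf sets have
expected common count `n̄²/U` and expected Jaccard
`≈ r/(2 − r)`; setting this to `p` gives `r = 2p/(1 + p)`, i.e.
`U = n̄(1 + p)/(2p)`.  For `L = [10, 15]`, `p = 0.5` this yields `U ≈ 18`
and target retention `2/3` — the regime in which candidate overlaps spread
around `p` and the band is hit often.  `GeneratorConfig.species_size_inflation`
overrides the factor (`1.0` forces the species tree into `[L_min, L_max]`,
with the feasibility caveat above; the default `None` means automatic).

### Gene trees (birth–death with transfers)

One gene lineage enters at the species root.  The simulation is a single
chronological sweep (Gillespie): with `m` active lineages and total per-
lineage rate `R = δ + μ + τ + κ`, the next stochastic event occurs after
`Exp(m·R)` unless a species-branch boundary comes first.  Event semantics:

* **duplication** (`δ`, default 0) — the lineage splits in place;
* **loss** (`μ`) — the lineage ends;
* **hgt** (`τ`) — the lineage is copied into a species branch alive at the
  event time, uniform among branches other than the donor's (a silent no-op
  if none exists, e.g. on the stem).  With `replacing_transfers` (default)
  one resident copy of the recipient branch, if any, is terminated at that
  moment — this keeps observable trees single-labeled when `δ = 0`, and it
  also means a transfer can *re-seed* a branch whose copy had died;
* **conversion** (`κ`, default 0) — one paralogous copy in the same branch
  is replaced by a copy of this lineage (no-op without paralogs, so with
  `δ = 0` conversion never acts).

At species bifurcations every surviving lineage bifurcates; at tips it
becomes an extant copy labeled by the species.  Pruning removes loss leaves
and extinct subtrees and suppresses unary nodes, summing their branch
lengths; the stem remainder is kept as the root's branch length, so every
surviving leaf's root-to-leaf distance equals the species-tree height.  An
all-lost family returns `None`; the cluster assembler counts it as a
rejected candidate.

### Default rates

`δ = 0, μ = 0.3, τ = 0.2, κ = 0` (per lineage per unit time, with `λ = 1`).
Loss alone at `μ = 0.3` would retain each leaf with probability
`exp(−μ·height) ≈ 0.37` on trees of height ≈ 3.3, but replacing transfers
re-seed dead branches, lifting effective retention to ≈ 0.65 — close to the
`2p/(1+p) = 2/3` target at `p = 0.5`.  With the automatic universe sizing,
pilot runs at these defaults give candidate leaf counts mostly in `[10, 15]`
and pairwise overlap levels spread around 0.5–0.57, so the default
configuration assembles `p = 0.5` clusters in well under a second.  Targets
far from 0.5 shift the optimal retention; the loss rate is the knob to move
(the exact survival law `exp(−μ·d)` holds only when `τ = 0`).

### Acceptance rule

The acceptance statistic is the **running mean** of all pairwise overlaps in
the candidate cluster, required to lie strictly inside the open band: the
first tree is accepted unconditionally, the second iff its single pairwise
value is in band, and so on.  Individual pairwise values are free to range
widely (0.33–0.73 in the worked example) as long as the mean stays pinned —
which is exactly what published per-cluster tables of this data type show.
A strict per-pair variant is available (`strict_pairwise=True`).  Candidates
are compared only against already-accepted trees, with a cached sum of
accepted pairwise values, so a cluster costs `O(n · attempts · N_gen)` set
operations in leaf count `n`.

If `max_candidate_attempts` (default 10,000) candidates fail to complete a
cluster, a fresh species tree is drawn — important because the achievable
overlap depends strongly on the realized species tree — up to
`max_species_tree_restarts` (default 20) trees in total, after which a
`GenerationError` reports the counters and the nearest mean achieved.

## Numerical and format choices

* Branch lengths are serialized with `repr`, the shortest representation
  that round-trips the float exactly; same seed ⇒ byte-identical files.
* The Newick dialect is plain: no quoted labels, no comments, internal
  labels omitted, one statement per line; parsing is strict (unbalanced
  parentheses, empty clades, duplicate leaf labels are errors).
* Overlap values are stored at full precision; printed tables round half-up
  to 3 decimals (`round_half_up`), matching how such tables are printed
  (e.g. 7/16 → 0.438).
* The band is an open interval; the mean of `m+1` trees is computed over
  exactly `C(m+1, 2)` pairs.
* Per-cluster random streams are spawned from the master seed
  (`SeedSequence.spawn`), so cluster `i` of a `k`-cluster run is
  reproducible in isolation.
* `realize_leaf_sets` reconstructs concrete leaf sets from a printed
  leaf-count/common-leaf table by integer programming over membership-
  pattern atoms (HiGHS via scipy), minimizing the universe size.  It is the
  bridge from printed tables to executable fixtures in the tests.

## What the simulations do and do not show

The generator emulates the *structure* of real overlapping gene-tree
collections: variable leaf counts, controlled mean overlap, loss- and
transfer-shaped topological discordance with time-consistent transfers.  It
does not model sequence evolution, coalescent effects (incomplete lineage
sorting), rate heterogeneity across branches, or extinction in the species
tree; species trees are strictly ultrametric and clusters are independent
(no shared taxa semantics across clusters — leaf names repeat between
clusters).  Passing tests therefore validate the event process and the
overlap control, not fidelity to any particular empirical clade.

Problem sizes used in the test suite — up to 20-leaf species trees, 5,000
Monte-Carlo replicates for the distributional checks, and the full `k = 3`,
`N_gen = 6` integration run — are the package's chosen verification scale;
all closed-form comparisons (Yule height, loss-only survival, Poisson event
counts) are exact laws, not scale-dependent approximations.

## Known limitations

* Very high targets (`p → 1`) or very low ones (`p → 0.1` and below) need
  user-adjusted rates; the defaults are calibrated for the mid range.
* With `strict_pairwise=True` and the default tolerance 0.01 the band is
  rarely reachable (pairwise values are nearly discrete at these tree
  sizes); widen the tolerance in that mode.
* `max(L_max, ·)` in the universe size means `p` close to 1 degenerates to
  a universe of exactly `L_max`, where only near-complete trees can satisfy
  high overlap — generation then succeeds only with low loss rates.
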