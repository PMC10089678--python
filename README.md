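# phyloclustersim

Simulation of **clusters of overlapping phylogenetic gene trees** — benchmark
data for supertree inference and tree-clustering research.

Supertree methods combine rooted trees defined on *different but mutually
overlapping* taxon sets, and clustering algorithms for such trees need test
data in which the degree of leaf-set overlap is controlled.  Real collections
with a prescribed overlap level are scarce, so this package generates them:
`k` clusters of gene trees in Newick format, each tree with a leaf count in a
user range `[L_min, L_max]`, each cluster with a mean pairwise leaf-set
overlap pinned to a target level `p`, and with the biological events (gene
loss, horizontal gene transfer, optionally duplication and gene conversion)
that make simulated gene trees resemble real ones.

## Model

For each cluster:

1. **Species tree** — a Yule (pure-birth) tree with a *planted root* (the
   root has a single descendant): while `i` lineages are extant the waiting
   time to the next split is `Exp(i·λ)`.  The tree is ultrametric with
   absolute node times.  Its size is a nominal draw from `[L_min, L_max]`
   scaled by `(1+p)/(2p)` — the pool size at which two trees of nominal size
   have expected Jaccard overlap `p` (see `docs/methods.md`).
2. **Gene trees** — one gene lineage enters at the species root and evolves
   by a birth–death process: per lineage, events arrive at rate
   `δ + μ + τ + κ` (duplication, loss, transfer, conversion).  Transfers copy
   the lineage into a contemporaneous species branch chosen uniformly;
   by default they *replace* the recipient's resident copy, so with `δ = 0`
   observable trees are single-labeled.  Lost and extinct subtrees are
   pruned and unary nodes suppressed, giving the observable, species-labeled
   gene tree.
3. **Rejection sampling** — a candidate is kept iff its leaf count is in
   `[L_min, L_max]` and the cluster's mean pairwise overlap stays strictly
   inside `(p − tol, p + tol)` (default `tol = 0.01`).

Overlap between two trees with leaf counts `n1`, `n2` and `c` common leaves:

* overlap level (Jaccard): `OL = c / (n1 + n2 − c)`  — the default;
* overlap coefficient: `OC = c / min(n1, n2)`  — always `≥ OL`.

## Worked example

```sh
phyloclustersim -k 3 --min-leaves 10 --max-leaves 15 \
    --trees-per-cluster 6 --overlap 0.5 --seed 42 -o dataset.nwk
```

writes 3 cluster blocks (a species tree plus 6 gene trees each, one Newick
statement per line) and a `dataset.manifest.txt` side-car.  The same run
through the API (`examples/full_dataset.py`) prints:

```
cluster: 6 gene trees, leaf counts [13, 14, 10, 14, 10, 12], mean overlap 0.4990
cluster: 6 gene trees, leaf counts [15, 12, 13, 11, 11, 12], mean overlap 0.5085
cluster: 6 gene trees, leaf counts [13, 11, 12, 14, 15, 11], mean overlap 0.5014
```

Every leaf count is inside `[10, 15]` and every cluster's mean pairwise
overlap level is inside `(0.49, 0.51)` — recomputed from the output file, not
from the generator's bookkeeping.  `examples/single_cluster.py` prints one
cluster's full pairwise table, e.g.

```
Trees  Leaves  T1     T2     T3     T4     T5     T6
T1     13             8      9      7      9      9
T2     11      0.5           7      6      6      6
...
mean pairwise overlap: 0.4987  (target 0.5 within +/- 0.01)
```

with common-leaf counts above the diagonal and overlap levels below — note
the individual pairwise values range widely (0.375–0.692) while their mean is
controlled.  `examples/overlap_from_counts.py` evaluates the metrics on a
printed-style count table directly (mean 0.505 for the six-tree example).

## Layout

* `src/phyloclustersim/` — `trees` (rooted-tree model, Newick I/O),
  `species` (Yule simulator), `genes` (birth–death gene process),
  `overlap` (metrics, reports, leaf-set realizer), `clusters` (rejection
  sampler), `io`/`cli` (files and command line).
* `examples/` — one narrative script per capability.
* `docs/methods.md` — model details, parameter defaults and their
  calibration, numerical choices, limitations.
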