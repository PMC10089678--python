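"""Yule (pure-birth) species-tree simulation with a planted root.

The species tree is the backbone of a cluster: one tree per cluster, gene
trees are evolved along it.  The simulator runs the Yule process forward:
while ``i`` lineages are extant the waiting time to the next split is
exponential with rate ``i * birth_rate``; the splitting lineage is chosen
uniformly.  The process stops when the target leaf count is reached and
the tips are cut after one final exponential waiting time, so terminal
branches are nonzero and the tree is exactly ultrametric.

The root is *planted*: it has a single descendant, adding a stem edge
above the first bifurcation (the time of the first split is the stem
length, a single exponential(birth_rate) draw).

Absolute node times are stored on each node as ``node.time`` with the
root at time 0 and time increasing toward the leaves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .trees import RootedTree, TreeNode

__all__ = ["SpeciesTree", "draw_leaf_count", "simulate_species_tree"]


@dataclass
class SpeciesTree:
    """A timed, planted-root, binary, ultrametric rooted tree.

    ``tree.root.time == 0``; every leaf sits at ``height``.  The birth
    rate used to generate the tree is kept for provenance.
    """

    tree: RootedTree
    birth_rate: float

    @property
    def root(self) -> TreeNode:
        return self.tree.root

    @property
    def height(self) -> float:
        return max(leaf.time for leaf in self.tree.leaves())

    @property
    def n_leaves(self) -> int:
        return self.tree.n_leaves

    def leaf_labels(self) -> set[str]:
        return self.tree.leaf_labels()


def draw_leaf_count(l_min: int, l_max: int, rng: np.random.Generator) -> int:
    """Draw the species-tree leaf count uniformly from {l_min, ..., l_max}."""
    if l_min < 1:
        raise ParameterError(f"l_min must be >= 1, got {l_min}")
    if l_min > l_max:
        raise ParameterError(f"l_min ({l_min}) must not exceed l_max ({l_max})")
    return int(rng.integers(l_min, l_max + 1))


def simulate_species_tree(
    n_leaves: int,
    birth_rate: float = 1.0,
    rng: np.random.Generator | None = None,
    label_prefix: str = "S",
) -> SpeciesTree:
    """Simulate a planted-root Yule tree with exactly *n_leaves* leaves.

    Leaves are labeled ``{label_prefix}1 ... {label_prefix}n`` in lineage
    creation order.  A planted binary tree with n leaves has 2n nodes:
    n leaves, n-1 bifurcations, and the root of out-degree 1.
    """
    if n_leaves < 1:
        raise ParameterError(f"n_leaves must be >= 1, got {n_leaves}")
    if not (birth_rate > 0):
        raise ParameterError(f"birth_rate must be > 0, got {birth_rate}")
    if rng is None:
        rng = np.random.default_rng()

    root = TreeNode()
    root.time = 0.0
    # each entry is the node a currently-open lineage hangs from
    open_lineages: list[TreeNode] = [root]
    t = 0.0
    k = 1
    while k < n_leaves:
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        split = TreeNode(length=t - open_lineages[i].time)
        split.time = t
        open_lineages[i].add_child(split)
        open_lineages[i] = split
        open_lineages.append(split)
        k += 1
    t += rng.exponential(1.0 / (n_leaves * birth_rate))
    for j, parent in enumerate(open_lineages):
        leaf = TreeNode(label=f"{label_prefix}{j + 1}", length=t - parent.time)
        leaf.time = t
        parent.add_child(leaf)
    return SpeciesTree(tree=RootedTree(root), birth_rate=birth_rate)
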