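"""Shared fixtures: the printed six-tree cluster example and tree helpers.

The worked example is a cluster of six gene trees with leaf counts
(11, 13, 12, 11, 13, 11), the 15 pairwise common-leaf counts below, the
15 pairwise overlap-level values printed to 3 decimals, and mean
pairwise overlap 0.505.  Trees realizing these counts are reconstructed
at session start with the integer-programming leaf-set realizer.
"""

import numpy as np
import pytest

from phyloclustersim import realize_leaf_sets, tree_from_leaf_labels

TABLE1_LEAF_COUNTS = [11, 13, 12, 11, 13, 11]

# strict upper triangle, keys (i, j) with i < j, 0-based tree indices
TABLE1_COMMON = {
    (0, 1): 8, (0, 2): 8, (0, 3): 8, (0, 4): 8, (0, 5): 8,
    (1, 2): 8, (1, 3): 8, (1, 4): 11, (1, 5): 7,
    (2, 3): 7, (2, 4): 8, (2, 5): 9,
    (3, 4): 6, (3, 5): 8,
    (4, 5): 6,
}

# overlap level printed to 3 decimals
TABLE1_OL = {
    (0, 1): 0.5, (0, 2): 0.533, (0, 3): 0.571, (0, 4): 0.5, (0, 5): 0.571,
    (1, 2): 0.471, (1, 3): 0.5, (1, 4): 0.733, (1, 5): 0.412,
    (2, 3): 0.438, (2, 4): 0.471, (2, 5): 0.643,
    (3, 4): 0.333, (3, 5): 0.571,
    (4, 5): 0.333,
}

TABLE1_MEAN = 0.505


def table1_common_matrix() -> np.ndarray:
    m = np.zeros((6, 6), dtype=int)
    for (i, j), c in TABLE1_COMMON.items():
        m[i, j] = c
    return m


@pytest.fixture(scope="session")
def table1_matrix():
    return table1_common_matrix()


@pytest.fixture(scope="session")
def table1_trees(table1_matrix):
    """Six trees realizing the printed leaf counts and common-leaf counts."""
    sets = realize_leaf_sets(TABLE1_LEAF_COUNTS, table1_matrix)
    return [tree_from_leaf_labels(sorted(s), branch_length=1.0) for s in sets]


@pytest.fixture
def rng():
    return np.random.default_rng(20230303)


# --- canonical tree views, used as independent oracles -----------------

def clade_sets(tree):
    """Leaf-label set of every node with >= 2 children, plus singletons.

    Insensitive to planted roots and unary chains, so a species tree and
    an observable gene tree can be compared directly.
    """

    clades = set()

    def collect(node):
        if node.is_leaf():
            return frozenset([node.label])
        below = frozenset().union(*(collect(c) for c in node.children))
        if len(node.children) >= 2:
            clades.add(below)
        return below

    collect(tree.root)
    clades |= {frozenset([leaf.label]) for leaf in tree.leaves()}
    return clades


def leaf_depths(tree):
    """Root-to-leaf path length per label, including any root stem length."""
    depths = {}

    def walk(node, acc):
        acc += node.length or 0.0
        if node.is_leaf():
            depths[node.label] = acc
        for child in node.children:
            walk(child, acc)

    walk(tree.root, 0.0)
    return depths
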