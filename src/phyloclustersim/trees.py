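"""Rooted-tree data model and plain Newick serialization.

Every other module trades in :class:`RootedTree`: an ordered rooted tree
whose leaves carry taxon labels and whose edges carry optional nonnegative
branch lengths (arbitrary time units).  Simulators attach extra node
attributes (``time``, event annotations); this module ignores them.

The Newick dialect is deliberately plain: branch lengths as ``:<float>``,
internal node labels omitted on output, no quoted labels, no comments or
NHX annotations.  Child order is preserved exactly, so serialization is
byte-deterministic under a fixed simulation seed.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import dendropy

from .errors import NewickParseError, NewickWriteError

__all__ = [
    "TreeNode",
    "RootedTree",
    "parse_newick",
    "write_newick",
    "leaf_labels",
    "tree_from_leaf_labels",
    "trees_equal",
]

#: Characters that may not appear in a taxon label in the plain dialect.
_FORBIDDEN = set("(),:;[]'\"") | set(" \t\r\n")


def _check_label(label: str) -> None:
    if not label:
        raise NewickWriteError("empty taxon label")
    bad = _FORBIDDEN.intersection(label)
    if bad:
        raise NewickWriteError(
            f"label {label!r} contains Newick metacharacter(s) {sorted(bad)!r}"
        )


@dataclass
class TreeNode:
    """One node: optional label, optional branch length to its parent,
    ordered children.  Leaves are nodes without children."""

    label: Optional[str] = None
    length: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        self.children.append(child)
        return child

    def walk(self) -> Iterator["TreeNode"]:
        """Preorder traversal (iterative; simulated trees can be deep)."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


@dataclass
class RootedTree:
    """A rooted, ordered tree with labeled leaves.

    Invariants: single root, acyclic by construction, branch lengths
    (when present) nonnegative, every leaf labeled.  ``root.length`` may
    hold a stem length above the root (written as a root branch length).
    """

    root: TreeNode

    def walk(self) -> Iterator[TreeNode]:
        return self.root.walk()

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.walk() if n.is_leaf()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.walk() if n.is_leaf())

    def leaf_labels(self) -> set[str]:
        return {n.label for n in self.leaves() if n.label is not None}


def leaf_labels(tree: RootedTree) -> set[str]:
    """Set of taxon labels on the leaves of *tree*.

    Its size is the tree's leaf count n(T) whenever the tree is
    single-labeled (always true for observable trees generated with
    duplication rate 0).
    """
    return tree.leaf_labels()


def parse_newick(text: str) -> RootedTree:
    """Parse a single Newick statement into a :class:`RootedTree`.

    The statement must be terminated by ``;``.  Unlabeled internal nodes
    are allowed; an unlabeled leaf (an empty clade slot) or a duplicate
    leaf label raises :class:`NewickParseError`.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError("Newick statement must end with ';'")
    if stripped.count(";") != 1:
        raise NewickParseError("expected exactly one Newick statement")
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific subclasses
        raise NewickParseError(str(exc)) from exc

    def convert(dnode) -> TreeNode:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = TreeNode(label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.children.append(convert(child))
        return node

    root = convert(dtree.seed_node)
    seen: set[str] = set()
    for idx, node in enumerate(root.walk()):
        if node.is_leaf():
            if not node.label:
                raise NewickParseError(
                    f"empty clade: unlabeled leaf at node position {idx}"
                )
            if node.label in seen:
                raise NewickParseError(f"duplicate leaf label {node.label!r}")
            seen.add(node.label)
        if node.length is not None and node.length < 0:
            raise NewickParseError(
                f"negative branch length {node.length!r} at node position {idx}"
            )
    return RootedTree(root)


def write_newick(tree: RootedTree, branch_lengths: bool = True) -> str:
    """Serialize to a single-line Newick string terminated by ``;``.

    Branch lengths are written with :func:`repr` (shortest string that
    round-trips the float exactly); internal labels are omitted; child
    order is preserved.  A leaf without a label raises
    :class:`NewickWriteError`.
    """
    out = _io.StringIO()

    def emit(node: TreeNode) -> None:
        if node.is_leaf():
            if node.label is None:
                raise NewickWriteError("cannot serialize a leaf without a label")
            _check_label(node.label)
            out.write(node.label)
        else:
            out.write("(")
            for i, child in enumerate(node.children):
                if i:
                    out.write(",")
                emit(child)
            out.write(")")
        if branch_lengths and node.length is not None:
            out.write(f":{node.length!r}")

    emit(tree.root)
    out.write(";")
    return out.getvalue()


def tree_from_leaf_labels(
    labels: Sequence[str], branch_length: Optional[float] = None
) -> RootedTree:
    """Build a caterpillar tree over *labels* (in the given order).

    Convenience for constructing trees whose only relevant property is
    the leaf set, e.g. when reproducing printed leaf-count tables.
    """
    if not labels:
        raise NewickWriteError("cannot build a tree with no leaves")
    leaves = [TreeNode(label=l, length=branch_length) for l in labels]
    node = leaves[0]
    for leaf in leaves[1:]:
        node = TreeNode(length=branch_length, children=[node, leaf])
    node.length = None
    return RootedTree(node)


def trees_equal(a: RootedTree, b: RootedTree, rel_tol: float = 1e-9) -> bool:
    """Structural equality: same shape, labels, and branch lengths (to
    relative tolerance), honoring child order."""

    def eq(x: TreeNode, y: TreeNode) -> bool:
        if x.label != y.label or len(x.children) != len(y.children):
            return False
        if (x.length is None) != (y.length is None):
            return False
        if x.length is not None:
            denom = max(abs(x.length), abs(y.length), 1e-300)
            if abs(x.length - y.length) > rel_tol * max(denom, 1.0):
                return False
        return all(eq(cx, cy) for cx, cy in zip(x.children, y.children))

    return eq(a.root, b.root)
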