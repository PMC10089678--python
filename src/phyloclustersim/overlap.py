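"""Leaf-set overlap metrics between trees on different taxon sets.

Two metrics are offered for a pair of trees T1, T2 with leaf counts
n1 = n(T1), n2 = n(T2) and c = n(T1, T2) common leaves:

* overlap level (OL), the Jaccard similarity of the leaf sets::

      OL(T1, T2) = c / (n1 + n2 - c)

* overlap coefficient (OC), intersection over the smaller leaf set::

      OC(T1, T2) = c / min(n1, n2)

Both are symmetric, lie in [0, 1], are 0 iff the sets are disjoint, and
OC >= OL with equality only when c = 0 or the sets are identical.  OL is
the default metric.  Overlap is a property of label sets only; topology
and branch lengths are irrelevant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .trees import RootedTree

__all__ = [
    "Metric",
    "OverlapCounts",
    "OverlapReport",
    "common_leaf_count",
    "overlap_level",
    "overlap_coefficient",
    "metric_value",
    "pairwise_report",
    "report_from_counts",
    "mean_pairwise_overlap",
    "round_half_up",
    "format_report_table",
    "realize_leaf_sets",
]


class Metric(str, Enum):
    """Which overlap statistic to use."""

    OL = "OL"  # Jaccard overlap level (default)
    OC = "OC"  # overlap coefficient


@dataclass(frozen=True)
class OverlapCounts:
    """Leaf counts of two trees and their number of common leaves."""

    n1: int
    n2: int
    c: int

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.n2 < 0 or self.c < 0:
            raise ParameterError("overlap counts must be nonnegative")
        if self.c > min(self.n1, self.n2):
            raise ParameterError(
                f"common-leaf count {self.c} exceeds min(n1, n2) = "
                f"{min(self.n1, self.n2)}"
            )


def common_leaf_count(t1: RootedTree, t2: RootedTree) -> int:
    """Number of taxon labels shared by the leaf sets of the two trees."""
    return len(t1.leaf_labels() & t2.leaf_labels())


def overlap_level(counts: OverlapCounts) -> float:
    """Jaccard overlap level c / (n1 + n2 - c); undefined for two empty trees."""
    if counts.n1 + counts.n2 == 0:
        raise ParameterError("overlap level undefined for two empty trees")
    return counts.c / (counts.n1 + counts.n2 - counts.c)


def overlap_coefficient(counts: OverlapCounts) -> float:
    """Overlap coefficient c / min(n1, n2); undefined if either tree is empty."""
    if min(counts.n1, counts.n2) == 0:
        raise ParameterError("overlap coefficient undefined for an empty tree")
    return counts.c / min(counts.n1, counts.n2)


def metric_value(counts: OverlapCounts, metric: Metric = Metric.OL) -> float:
    if Metric(metric) is Metric.OL:
        return overlap_level(counts)
    return overlap_coefficient(counts)


@dataclass
class OverlapReport:
    """Pairwise overlap summary for N trees.

    ``common`` and ``values`` are symmetric N x N arrays (diagonal of
    ``values`` is 1 for nonempty trees); ``mean`` averages the strictly
    upper triangular metric values over the N(N-1)/2 pairs, at full
    precision (round only for display).
    """

    leaf_counts: np.ndarray
    common: np.ndarray
    values: np.ndarray
    metric: Metric
    mean: float


def report_from_counts(
    leaf_counts: Sequence[int],
    common: np.ndarray | Sequence[Sequence[int]],
    metric: Metric = Metric.OL,
) -> OverlapReport:
    """Build an :class:`OverlapReport` from printed-style count data.

    ``common`` is a square matrix of common-leaf counts; only its strict
    upper triangle is read (the matrix is symmetrized, diagonal set to
    the leaf counts).
    """
    n = len(leaf_counts)
    if n < 2:
        raise ParameterError("need at least 2 trees for a pairwise report")
    counts = np.asarray(leaf_counts, dtype=int)
    if np.any(counts <= 0):
        raise ParameterError("all trees must be nonempty")
    raw = np.asarray(common, dtype=int)
    if raw.shape != (n, n):
        raise ParameterError(f"common matrix must be {n}x{n}, got {raw.shape}")
    cm = np.triu(raw, k=1)
    cm = cm + cm.T + np.diag(counts)
    values = np.ones((n, n))
    total = 0.0
    for i, j in itertools.combinations(range(n), 2):
        v = metric_value(OverlapCounts(int(counts[i]), int(counts[j]), int(cm[i, j])), metric)
        values[i, j] = values[j, i] = v
        total += v
    return OverlapReport(
        leaf_counts=counts,
        common=cm,
        values=values,
        metric=Metric(metric),
        mean=total / (n * (n - 1) // 2),
    )


def pairwise_report(
    trees: Sequence[RootedTree], metric: Metric = Metric.OL
) -> OverlapReport:
    """Pairwise common-leaf and metric matrices for a list of trees."""
    if len(trees) < 2:
        raise ParameterError("need at least 2 trees for a pairwise report")
    label_sets = [t.leaf_labels() for t in trees]
    if any(not s for s in label_sets):
        raise ParameterError("all trees must be nonempty")
    n = len(trees)
    common = np.zeros((n, n), dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        common[i, j] = len(label_sets[i] & label_sets[j])
    return report_from_counts([len(s) for s in label_sets], common, metric)


def mean_pairwise_overlap(
    trees: Sequence[RootedTree], metric: Metric = Metric.OL
) -> float:
    """Mean metric value over all unordered tree pairs."""
    return pairwise_report(trees, metric).mean


def round_half_up(value: float, ndigits: int = 3) -> float:
    """Round with ties away from zero, as printed overlap tables do."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def format_report_table(
    report: OverlapReport, names: Sequence[str] | None = None
) -> str:
    """Tab-separated table: leaf counts, common counts in the upper
    triangle, metric values (3 d.p.) in the lower triangle."""
    n = len(report.leaf_counts)
    if names is None:
        names = [f"T{i + 1}" for i in range(n)]
    header = "Trees\tLeaves\t" + "\t".join(names)
    lines = [header]
    for i in range(n):
        cells = []
        for j in range(n):
            if j > i:
                cells.append(str(int(report.common[i, j])))
            elif j < i:
                cells.append(f"{round_half_up(report.values[i, j], 3):g}")
            else:
                cells.append("")
        lines.append(f"{names[i]}\t{int(report.leaf_counts[i])}\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"


def realize_leaf_sets(
    leaf_counts: Sequence[int],
    common: np.ndarray | Sequence[Sequence[int]],
    label_prefix: str = "S",
) -> list[set[str]]:
    """Construct label sets with prescribed sizes and pairwise intersections.

    Solves a small integer program over membership-pattern "atoms" (one
    variable per nonempty subset of trees, counting labels shared by
    exactly that subset), minimizing the universe size.  Useful for
    turning a printed leaf-count/common-leaf table back into concrete
    trees.  Raises :class:`ParameterError` if no family of sets realizes
    the counts.
    """
    from scipy.optimize import LinearConstraint, milp

    m = len(leaf_counts)
    if m < 2:
        raise ParameterError("need at least 2 sets")
    raw = np.asarray(common, dtype=int)
    cm = np.triu(raw, k=1)
    patterns = [p for p in range(1, 2 ** m)]
    rows, rhs = [], []
    for i in range(m):
        rows.append([1.0 if (p >> i) & 1 else 0.0 for p in patterns])
        rhs.append(float(leaf_counts[i]))
    for i, j in itertools.combinations(range(m), 2):
        mask = (1 << i) | (1 << j)
        rows.append([1.0 if (p & mask) == mask else 0.0 for p in patterns])
        rhs.append(float(cm[i, j]))
    a = np.array(rows)
    b = np.array(rhs)
    result = milp(
        c=np.ones(len(patterns)),
        constraints=LinearConstraint(a, b, b),
        integrality=np.ones(len(patterns)),
    )
    if not result.success:
        raise ParameterError(
            "no family of sets realizes the given leaf/common-leaf counts"
        )
    atom_counts = np.round(result.x).astype(int)
    sets: list[set[str]] = [set() for _ in range(m)]
    label_index = 0
    for pattern, count in zip(patterns, atom_counts):
        for _ in range(count):
            label_index += 1
            label = f"{label_prefix}{label_index}"
            for i in range(m):
                if (pattern >> i) & 1:
                    sets[i].add(label)
    return sets
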