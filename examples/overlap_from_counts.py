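"""Evaluate the two overlap metrics on a printed-style count table.

Takes the leaf counts and pairwise common-leaf counts of a six-tree
cluster and rebuilds the full pairwise overlap-level table plus its
mean — the statistic the cluster generator controls.
"""

import numpy as np

from phyloclustersim import (
    Metric,
    OverlapCounts,
    format_report_table,
    overlap_coefficient,
    overlap_level,
    report_from_counts,
    round_half_up,
)

leaf_counts = [11, 13, 12, 11, 13, 11]
common = np.zeros((6, 6), dtype=int)
upper = {
    (0, 1): 8, (0, 2): 8, (0, 3): 8, (0, 4): 8, (0, 5): 8,
    (1, 2): 8, (1, 3): 8, (1, 4): 11, (1, 5): 7,
    (2, 3): 7, (2, 4): 8, (2, 5): 9,
    (3, 4): 6, (3, 5): 8,
    (4, 5): 6,
}
for (i, j), c in upper.items():
    common[i, j] = c

report = report_from_counts(leaf_counts, common, Metric.OL)
print(format_report_table(report))
print(f"mean pairwise overlap level: {round_half_up(report.mean, 3)}")
print("-> the cluster generator accepts a cluster when this mean lies in")
print("   (p - tol, p + tol); 0.505 satisfies a p = 0.5, tol = 0.01 target.")

pair = OverlapCounts(11, 13, 8)
print(f"\nsingle pair (n1=11, n2=13, c=8): "
      f"OL = {overlap_level(pair)}, OC = {round_half_up(overlap_coefficient(pair), 3)}")
print("-> OC >= OL always: it divides by the smaller leaf count instead of")
print("   the union size.")
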