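"""Assemble one cluster of overlapping gene trees and inspect it.

Simulates a Yule species tree, evolves candidate gene trees along it
under loss + horizontal transfer, and rejection-samples six trees whose
mean pairwise leaf-set overlap lies in (0.49, 0.51).
"""

import numpy as np

from phyloclustersim import (
    GeneratorConfig,
    assemble_cluster,
    format_report_table,
    write_newick,
)

config = GeneratorConfig(k=1, l_min=10, l_max=15, n_gen=6, p=0.5, seed=42)
cluster = assemble_cluster(config, 0, np.random.default_rng(config.seed))

print(f"species tree ({cluster.species_tree.n_leaves} leaves, the cluster's "
      f"taxon universe):")
print(" ", write_newick(cluster.species_tree.tree, branch_lengths=False))
print(f"\naccepted {len(cluster.gene_trees)} gene trees after "
      f"{cluster.candidates_generated} candidates "
      f"({cluster.rejected} rejected):")
for tree in cluster.gene_trees:
    print(f"  {tree.n_leaves:2d} leaves  {write_newick(tree, branch_lengths=False)}")

print("\npairwise overlap report (common leaves above, overlap level below):")
print(format_report_table(cluster.report))
print(f"mean pairwise overlap: {cluster.mean_overlap:.4f}  "
      f"(target 0.5 within +/- 0.01)")
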