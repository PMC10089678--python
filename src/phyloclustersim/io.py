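"""Dataset file output and the run manifest.

Datasets are written as plain text, one Newick tree per line.  Clusters
are delimited by comment lines::

    # cluster 1 (species tree follows)
    <species tree Newick>
    <gene tree Newick>
    ...

With ``include_species=False`` the comment reads ``# cluster 1`` and the
species-tree line is omitted.  With ``per_cluster=True`` each cluster
goes to its own file (``<stem>.cluster<i><suffix>``).  A side-car
manifest in flat ``key=value`` form records the resolved configuration
and per-cluster summaries (achieved mean overlap, attempt counters).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from . import __version__
from .clusters import Dataset
from .trees import RootedTree, parse_newick, write_newick

__all__ = [
    "write_dataset",
    "build_manifest",
    "write_manifest",
    "read_dataset",
]

_SPECIES_MARK = "(species tree follows)"


def _cluster_lines(cluster, include_species: bool, branch_lengths: bool) -> list[str]:
    head = f"# cluster {cluster.index + 1}"
    if include_species:
        head += f" {_SPECIES_MARK}"
    lines = [head]
    if include_species:
        lines.append(write_newick(cluster.species_tree.tree, branch_lengths))
    lines.extend(write_newick(t, branch_lengths) for t in cluster.gene_trees)
    return lines


def write_dataset(
    dataset: Dataset,
    path: str | Path,
    per_cluster: bool = False,
    include_species: bool = True,
    branch_lengths: bool = True,
) -> list[Path]:
    """Write the dataset; returns the list of files written."""
    path = Path(path)
    if per_cluster:
        paths = []
        for cluster in dataset.clusters:
            cpath = path.with_name(
                f"{path.stem}.cluster{cluster.index + 1}{path.suffix}"
            )
            cpath.write_text(
                "\n".join(_cluster_lines(cluster, include_species, branch_lengths))
                + "\n"
            )
            paths.append(cpath)
        return paths
    lines: list[str] = []
    for cluster in dataset.clusters:
        lines.extend(_cluster_lines(cluster, include_species, branch_lengths))
    path.write_text("\n".join(lines) + "\n")
    return [path]


def build_manifest(dataset: Dataset, output_paths: list[Path]) -> dict[str, str]:
    """Resolved configuration plus per-cluster summaries, as flat strings."""
    cfg = dataset.config
    manifest: dict[str, str] = {
        "tool": f"phyloclustersim {__version__}",
        "k": str(cfg.k),
        "l_min": str(cfg.l_min),
        "l_max": str(cfg.l_max),
        "n_gen": str(cfg.n_gen),
        "p": repr(cfg.p),
        "tolerance": repr(cfg.tolerance),
        "metric": cfg.metric.value,
        "duplication_rate": repr(cfg.rates.duplication),
        "loss_rate": repr(cfg.rates.loss),
        "hgt_rate": repr(cfg.rates.hgt),
        "conversion_rate": repr(cfg.rates.conversion),
        "replacing_transfers": str(cfg.rates.replacing_transfers),
        "birth_rate": repr(cfg.birth_rate),
        "seed": str(cfg.seed),
        "max_candidate_attempts": str(cfg.max_candidate_attempts),
        "max_species_tree_restarts": str(cfg.max_species_tree_restarts),
        "strict_pairwise": str(cfg.strict_pairwise),
        "outputs": ",".join(str(p) for p in output_paths),
    }
    for cluster in dataset.clusters:
        i = cluster.index + 1
        counts = ",".join(str(t.n_leaves) for t in cluster.gene_trees)
        manifest[f"cluster_{i}_leaf_counts"] = counts
        manifest[f"cluster_{i}_mean_overlap"] = (
            "" if cluster.mean_overlap is None else repr(cluster.mean_overlap)
        )
        manifest[f"cluster_{i}_candidates"] = str(cluster.candidates_generated)
        manifest[f"cluster_{i}_rejected"] = str(cluster.rejected)
        manifest[f"cluster_{i}_species_tree_restarts"] = str(cluster.restarts)
    return manifest


def write_manifest(manifest: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("".join(f"{k}={v}\n" for k, v in manifest.items()))
    return path


def read_dataset(
    path: str | Path,
) -> list[tuple[Optional[RootedTree], list[RootedTree]]]:
    """Parse a dataset file back into (species tree or None, gene trees)
    per cluster.  Every non-comment line must be valid Newick."""
    clusters: list[tuple[Optional[RootedTree], list[RootedTree]]] = []
    species_expected = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            clusters.append((None, []))
            species_expected = _SPECIES_MARK in line
            continue
        tree = parse_newick(line)
        if not clusters:  # headerless file: single anonymous cluster
            clusters.append((None, []))
        species, genes = clusters[-1]
        if species_expected and species is None and not genes:
            clusters[-1] = (tree, genes)
        else:
            genes.append(tree)
    return clusters
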