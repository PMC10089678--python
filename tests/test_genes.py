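"""Gene-tree birth-death process: null behavior, loss survival closed
form, transfer semantics, pruning arithmetic, event statistics."""

import numpy as np
import pytest
from scipy import stats

from phyloclustersim import (
    ParameterError,
    RateConfig,
    RootedTree,
    SpeciesTree,
    TreeNode,
    event_log_tsv,
    prune_observable,
    simulate_full_gene_tree,
    simulate_gene_tree,
    simulate_species_tree,
    write_newick,
)
from conftest import clade_sets, leaf_depths

NO_EVENTS = RateConfig(duplication=0, loss=0, hgt=0, conversion=0)


def two_species_tree(split_time=0.5, tip_time=3.0):
    """Hand-built planted species tree: stem, one split, two tips."""
    root = TreeNode()
    root.time = 0.0
    mid = TreeNode(length=split_time)
    mid.time = split_time
    root.add_child(mid)
    for label in ("A", "B"):
        leaf = TreeNode(label=label, length=tip_time - split_time)
        leaf.time = tip_time
        mid.add_child(leaf)
    return SpeciesTree(RootedTree(root), birth_rate=1.0)


def test_rate_config_rejects_negative_rates():
    with pytest.raises(ParameterError):
        RateConfig(loss=-0.1)
    with pytest.raises(ParameterError):
        RateConfig(hgt=float("nan"))


def test_null_process_reproduces_species_tree(rng):
    """With all rates 0 the observable gene tree has the species tree's
    leaf set, clades, and root-to-leaf path lengths."""
    for _ in range(10):
        species = simulate_species_tree(int(rng.integers(2, 15)), 1.0, rng)
        gene = simulate_gene_tree(species, NO_EVENTS, rng)
        assert gene.leaf_labels() == species.leaf_labels()
        assert clade_sets(gene) == clade_sets(species.tree)
        sp_depths = leaf_depths(species.tree)
        for label, depth in leaf_depths(gene).items():
            assert depth == pytest.approx(sp_depths[label])


def test_loss_only_survival_matches_exponential_decay():
    """Under loss alone a species leaf survives iff no loss event hits
    the gene lineage on its root-to-leaf path, i.e. with probability
    exp(-mu*d); checked per leaf within 3 sigma over 5000 replicates."""
    rng = np.random.default_rng(0)
    mu, reps = 0.3, 5000
    species = simulate_species_tree(6, 1.0, rng)
    rates = RateConfig(duplication=0, loss=mu, hgt=0, conversion=0)
    counts = {label: 0 for label in species.leaf_labels()}
    for _ in range(reps):
        gene = simulate_gene_tree(species, rates, rng)
        if gene is not None:
            for label in gene.leaf_labels():
                counts[label] += 1
    depth = leaf_depths(species.tree)
    for label, hits in counts.items():
        expected = np.exp(-mu * depth[label])
        sigma = np.sqrt(expected * (1 - expected) / reps)
        assert abs(hits / reps - expected) < 3 * sigma


def test_replacing_transfers_keep_trees_single_labeled(rng):
    """duplication 0 + replacing HGT => one leaf per species, 100/100."""
    species = simulate_species_tree(12, 1.0, rng)
    rates = RateConfig(duplication=0, loss=0.3, hgt=0.5, conversion=0)
    seen = 0
    while seen < 100:
        gene = simulate_gene_tree(species, rates, rng)
        if gene is None:
            continue
        seen += 1
        labels = [leaf.label for leaf in gene.leaves()]
        assert len(labels) == len(set(labels))


def test_additive_transfers_can_multi_label(rng):
    species = simulate_species_tree(10, 1.0, rng)
    rates = RateConfig(duplication=0, loss=0, hgt=1.0, conversion=0,
                       replacing_transfers=False)
    multi = False
    for _ in range(50):
        gene = simulate_gene_tree(species, rates, rng)
        labels = [leaf.label for leaf in gene.leaves()]
        if len(labels) > len(set(labels)):
            multi = True
            break
    assert multi


def test_leaf_set_is_subset_of_species_leaves(rng):
    species = simulate_species_tree(15, 1.0, rng)
    labels = species.leaf_labels()
    for _ in range(1000):
        gene = simulate_gene_tree(species, RateConfig(), rng)
        if gene is not None:
            assert gene.leaf_labels() <= labels


def test_tuned_loss_keeps_counts_in_range(rng):
    """With loss tuned for ~0.8 retention on a 15-leaf species tree,
    most observable trees keep 10-15 leaves."""
    species = simulate_species_tree(15, 1.0, rng)
    mu = -np.log(0.8) / species.height
    rates = RateConfig(duplication=0, loss=mu, hgt=0, conversion=0)
    in_range = 0
    reps = 500
    for _ in range(reps):
        gene = simulate_gene_tree(species, rates, rng)
        if gene is not None and 10 <= gene.n_leaves <= 15:
            in_range += 1
    assert in_range > reps / 2


def test_full_tree_is_time_monotone(rng):
    species = simulate_species_tree(10, 1.0, rng)
    rates = RateConfig(duplication=0.1, loss=0.3, hgt=0.3, conversion=0.1)
    for _ in range(20):
        full = simulate_full_gene_tree(species, rates, rng)
        for node in full.root.walk():
            for child in node.children:
                assert child.time >= node.time
        for event in full.events:
            assert 0 <= event.time <= species.height


def test_pruning_preserves_leaf_path_lengths(rng):
    """Unary suppression sums the removed branch lengths, so every
    surviving leaf keeps its root-to-leaf distance (the species height,
    since extant tips all live at the same time)."""
    species = simulate_species_tree(12, 1.0, rng)
    rates = RateConfig(duplication=0, loss=0.4, hgt=0.3, conversion=0)
    checked = 0
    while checked < 30:
        full = simulate_full_gene_tree(species, rates, rng)
        gene = prune_observable(full)
        if gene is None:
            continue
        checked += 1
        for depth in leaf_depths(gene).values():
            assert depth == pytest.approx(species.height)
        for node in gene.walk():
            assert len(node.children) != 1


def test_all_lost_family_gives_none(rng):
    species = simulate_species_tree(3, 1.0, rng)
    rates = RateConfig(duplication=0, loss=50.0, hgt=0, conversion=0)
    assert simulate_gene_tree(species, rates, rng) is None


def test_conversion_without_paralogs_is_silent(rng):
    """With duplication 0 every species branch holds one gene copy, so
    conversion can never act: the tree is congruent and no event fires."""
    species = simulate_species_tree(8, 1.0, rng)
    rates = RateConfig(duplication=0, loss=0, hgt=0, conversion=2.0)
    full = simulate_full_gene_tree(species, rates, rng)
    assert full.events == []
    gene = prune_observable(full)
    assert clade_sets(gene) == clade_sets(species.tree)


def test_conversion_with_paralogs_fires_and_logs(rng):
    species = simulate_species_tree(6, 1.0, rng)
    rates = RateConfig(duplication=0.8, loss=0, hgt=0, conversion=0.8)
    fired = False
    for _ in range(50):
        full = simulate_full_gene_tree(species, rates, rng)
        if any(e.kind == "conversion" for e in full.events):
            fired = True
            break
    assert fired
    tsv = event_log_tsv(full)
    header, *rows = tsv.strip().split("\n")
    assert header == "kind\ttime\tdonor\trecipient"
    assert len(rows) == len(full.events)


def test_transfer_counts_are_poisson():
    """On a fixed two-tip species tree with transfer-only rates and
    replacing transfers, exactly two lineages exist after the split, so
    the number of transfer events in (split, tip] is Poisson with mean
    2 * tau * duration; chi-square over 4000 replicates."""
    rng = np.random.default_rng(11)
    tau, split, tip, reps = 0.4, 0.5, 3.0, 4000
    species = two_species_tree(split, tip)
    rates = RateConfig(duplication=0, loss=0, hgt=tau, conversion=0)
    counts = [
        len(simulate_full_gene_tree(species, rates, rng).events)
        for _ in range(reps)
    ]
    mean = 2 * tau * (tip - split)
    kmax = 8
    observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
    pmf = stats.poisson.pmf(np.arange(kmax), mean)
    expected = np.append(pmf, 1 - pmf.sum()) * reps
    assert stats.chisquare(observed, expected).pvalue > 1e-3


def test_same_seed_same_gene_tree():
    species = simulate_species_tree(10, 1.0, np.random.default_rng(3))
    out = []
    for _ in range(2):
        gene = simulate_gene_tree(species, RateConfig(), np.random.default_rng(5))
        out.append(write_newick(gene))
    assert out[0] == out[1]
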