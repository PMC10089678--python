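"""Cluster assembly by rejection sampling.

A cluster is one species tree (its "centroid") plus ``n_gen`` observable
gene trees generated from it.  Candidates are screened on leaf count
(must lie in [l_min, l_max]) and then on overlap: by default a candidate
is accepted iff the *mean* pairwise overlap of the enlarged cluster
stays strictly inside the open band (p - tolerance, p + tolerance).
The first tree is accepted unconditionally (no pair exists); the second
tree's single pairwise value is the mean.

The mean-based rule is what printed per-cluster overlap tables exhibit:
individual pairwise values can range far outside the band (0.333-0.733
in a cluster reported at p = 0.5) while the running average stays pinned
near p.  A strict per-pair alternative is available behind
``GeneratorConfig.strict_pairwise``.

If ``max_candidate_attempts`` candidates fail to complete a cluster, a
fresh species tree is drawn (the natural overlap of a cluster depends
strongly on the species tree's size, so restarts matter: see
docs/methods.md); after ``max_species_tree_restarts`` species trees the
assembler raises :class:`~phyloclustersim.errors.GenerationError`
carrying its counters and the nearest mean achieved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import GenerationError, ParameterError
from .genes import RateConfig, simulate_gene_tree
from .overlap import (
    Metric,
    OverlapCounts,
    OverlapReport,
    metric_value,
    pairwise_report,
)
from .species import SpeciesTree, draw_leaf_count, simulate_species_tree
from .trees import RootedTree

__all__ = [
    "GeneratorConfig",
    "TreeCluster",
    "Dataset",
    "candidate_is_acceptable",
    "assemble_cluster",
    "generate_dataset",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of a generation run.

    ``k`` clusters; gene-tree leaf counts bounded by [``l_min``,
    ``l_max``]; ``n_gen`` trees per cluster; target mean overlap ``p``
    with half-width ``tolerance`` (open band).  The species tree is
    sized by scaling a nominal draw from [l_min, l_max] — see
    ``species_size_inflation``: a cluster's taxon universe must exceed
    its tree sizes or small overlaps are set-theoretically impossible
    (two 12-leaf trees from a 15-leaf universe share at least 9 taxa).
    """

    k: int
    l_min: int
    l_max: int
    n_gen: int
    p: float
    tolerance: float = 0.01
    metric: Metric = Metric.OL
    rates: RateConfig = field(default_factory=RateConfig)
    birth_rate: float = 1.0
    seed: Optional[int] = None
    max_candidate_attempts: int = 10_000
    max_species_tree_restarts: int = 20
    strict_pairwise: bool = False
    #: Multiplier applied to the drawn nominal leaf count to size the
    #: species tree (the cluster's taxon universe).  ``None`` means
    #: automatic: (1 + p) / (2 p), the pool size at which two trees of
    #: ~nominal size drawn independently from the pool have expected
    #: Jaccard overlap p (never below l_max so counts up to l_max stay
    #: reachable).  Set to 1.0 to force the species tree itself into
    #: [l_min, l_max].
    species_size_inflation: Optional[float] = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError(f"k must be >= 1, got {self.k}")
        if self.l_min < 1 or self.l_min > self.l_max:
            raise ParameterError(
                f"need 1 <= l_min <= l_max, got [{self.l_min}, {self.l_max}]"
            )
        if self.n_gen < 1:
            raise ParameterError(f"n_gen must be >= 1, got {self.n_gen}")
        if not (0 < self.p < 1):
            raise ParameterError(f"p must be in (0, 1), got {self.p}")
        if not (self.tolerance > 0):
            raise ParameterError(f"tolerance must be > 0, got {self.tolerance}")
        if not (self.birth_rate > 0):
            raise ParameterError(f"birth_rate must be > 0, got {self.birth_rate}")
        if self.max_candidate_attempts < 1 or self.max_species_tree_restarts < 1:
            raise ParameterError("attempt and restart caps must be >= 1")
        if self.species_size_inflation is not None and not (
            self.species_size_inflation >= 1.0
        ):
            raise ParameterError("species_size_inflation must be >= 1")
        object.__setattr__(self, "metric", Metric(self.metric))

    @property
    def effective_inflation(self) -> float:
        if self.species_size_inflation is not None:
            return self.species_size_inflation
        return (1.0 + self.p) / (2.0 * self.p)

    def species_tree_size(self, nominal: int) -> int:
        """Species-tree leaf count for a nominal (target gene-tree) size."""
        return max(self.l_max, round(nominal * self.effective_inflation))

    def in_band(self, value: float) -> bool:
        return self.p - self.tolerance < value < self.p + self.tolerance


@dataclass
class TreeCluster:
    """One assembled cluster with its overlap report and work counters."""

    index: int
    species_tree: SpeciesTree
    gene_trees: list[RootedTree]
    report: Optional[OverlapReport]
    candidates_generated: int = 0
    rejected: int = 0
    restarts: int = 0
    overlap_evaluations: int = 0

    @property
    def mean_overlap(self) -> Optional[float]:
        return None if self.report is None else self.report.mean


@dataclass
class Dataset:
    """The full output: k clusters plus the configuration that made them."""

    clusters: list[TreeCluster]
    config: GeneratorConfig


def candidate_is_acceptable(
    cluster_so_far: list[RootedTree],
    candidate: RootedTree,
    config: GeneratorConfig,
) -> tuple[bool, dict]:
    """Reference acceptance predicate (recomputes overlaps from scratch).

    Returns ``(accepted, diagnostics)``; diagnostics carry the candidate
    leaf count, the would-be cluster mean, and the rejection reason.
    """
    cand_labels = candidate.leaf_labels()
    n = len(cand_labels)
    diag: dict = {"leaf_count": n, "mean": None, "reason": "accepted"}
    if n == 0:
        diag["reason"] = "empty"
        return False, diag
    if not (config.l_min <= n <= config.l_max):
        diag["reason"] = "leaf_count_out_of_range"
        return False, diag
    if not cluster_so_far:
        diag["reason"] = "first_tree"
        return True, diag
    sets = [t.leaf_labels() for t in cluster_so_far]
    new_vals = [
        metric_value(OverlapCounts(n, len(s), len(cand_labels & s)), config.metric)
        for s in sets
    ]
    pair_sum = 0.0
    m = len(sets)
    for i in range(m):
        for j in range(i + 1, m):
            pair_sum += metric_value(
                OverlapCounts(len(sets[i]), len(sets[j]), len(sets[i] & sets[j])),
                config.metric,
            )
    mean = (pair_sum + sum(new_vals)) / math.comb(m + 1, 2)
    diag["mean"] = mean
    if config.strict_pairwise:
        if all(config.in_band(v) for v in new_vals):
            return True, diag
        diag["reason"] = "pairwise_outside_band"
        return False, diag
    if config.in_band(mean):
        return True, diag
    diag["reason"] = "mean_outside_band"
    return False, diag


def assemble_cluster(
    config: GeneratorConfig,
    cluster_index: int = 0,
    rng: np.random.Generator | None = None,
) -> TreeCluster:
    """Rejection-sample one cluster.

    Keeps an incremental sum of accepted pairwise overlaps so each
    candidate costs only its ``m`` comparisons against the accepted
    trees (total work O(n * attempts * n_gen) in leaf size n).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    total_candidates = 0
    total_rejected = 0
    total_evals = 0
    nearest_mean: Optional[float] = None

    def track(mean: float) -> None:
        nonlocal nearest_mean
        if nearest_mean is None or abs(mean - config.p) < abs(nearest_mean - config.p):
            nearest_mean = mean

    for restart in range(config.max_species_tree_restarts):
        nominal = draw_leaf_count(config.l_min, config.l_max, rng)
        species = simulate_species_tree(
            config.species_tree_size(nominal), config.birth_rate, rng
        )
        accepted: list[RootedTree] = []
        label_sets: list[frozenset[str]] = []
        pair_sum = 0.0
        attempts = 0
        while attempts < config.max_candidate_attempts and len(accepted) < config.n_gen:
            attempts += 1
            total_candidates += 1
            gene = simulate_gene_tree(species, config.rates, rng)
            if gene is None:
                total_rejected += 1
                continue
            labels = frozenset(gene.leaf_labels())
            n = len(labels)
            if not (config.l_min <= n <= config.l_max):
                total_rejected += 1
                continue
            m = len(accepted)
            if m == 0:
                accepted.append(gene)
                label_sets.append(labels)
                continue
            new_vals = [
                metric_value(OverlapCounts(n, len(s), len(labels & s)), config.metric)
                for s in label_sets
            ]
            total_evals += m
            mean = (pair_sum + sum(new_vals)) / math.comb(m + 1, 2)
            track(mean)
            if config.strict_pairwise:
                ok = all(config.in_band(v) for v in new_vals)
            else:
                ok = config.in_band(mean)
            if ok:
                accepted.append(gene)
                label_sets.append(labels)
                pair_sum += sum(new_vals)
            else:
                total_rejected += 1
        if len(accepted) == config.n_gen:
            report = (
                pairwise_report(accepted, config.metric) if config.n_gen >= 2 else None
            )
            return TreeCluster(
                index=cluster_index,
                species_tree=species,
                gene_trees=accepted,
                report=report,
                candidates_generated=total_candidates,
                rejected=total_rejected,
                restarts=restart,
                overlap_evaluations=total_evals,
            )

    raise GenerationError(
        f"cluster {cluster_index}: exhausted {config.max_candidate_attempts} "
        f"candidates on each of {config.max_species_tree_restarts} species "
        f"trees (nearest mean overlap achieved: {nearest_mean}); consider "
        f"widening the tolerance or adjusting the event rates",
        candidates_generated=total_candidates,
        rejected=total_rejected,
        restarts=config.max_species_tree_restarts,
        nearest_mean=nearest_mean,
    )


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Generate all ``k`` clusters.

    Each cluster gets an independent random stream spawned from the
    master seed, so any single cluster is reproducible on its own.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.k)
    clusters = []
    for index, stream in enumerate(streams):
        clusters.append(
            assemble_cluster(config, index, np.random.default_rng(stream))
        )
    return Dataset(clusters=clusters, config=config)
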