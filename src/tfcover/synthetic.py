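"""Seeded generators for synthetic protein-DNA worlds.

The generator emulates the structural features of a yeast-scale ChIP-chip
binding graph that the solver exploits, without reproducing any particular
organism's network: gene in-degrees are drawn from a banded distribution
matching the cumulative profile of the real data (about 70% of genes bound
by at most 3 TFs, 85% by at most 5, 96% by at most 10), edge reliabilities
are uniform in a configurable range, and a known cooperative TF module can
be planted by wiring a chosen TF trio (or quartet) to a common gene set.
Perturbation instances mix planted targets with random background genes,
and an interaction network marks all within-module TF pairs as interacting
plus independent background pairs — giving ground truth for module-recovery
and interaction-enrichment tests.

A single global seed is split (via :class:`numpy.random.SeedSequence`) into
independent streams for the graph, the planting step, the instances and the
interactions, so each stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_model import PerturbationInstance, ProteinDnaGraph

__all__ = [
    "GeneratorConfig",
    "SyntheticWorld",
    "generate_graph",
    "plant_module",
    "generate_instances",
    "generate_interactions",
    "generate_world",
]

#: degree bands and band probabilities realizing the default cumulative
#: profile P(deg<=3)=0.70, P(deg<=5)=0.85, P(deg<=10)=0.96; uniform within
#: each band.
DEFAULT_DEGREE_QUANTILES = ((3, 0.70), (5, 0.85), (10, 0.96))
MAX_DEGREE = 15


@dataclass
class GeneratorConfig:
    """Parameters of a synthetic world.

    Defaults describe a yeast-scale study: a 100-TF x 2000-gene binding
    graph, ten perturbation experiments of 32 DE genes each, and one
    planted 3-TF module of modestly hub-like TFs (2x attachment) targeting
    30 genes whose edges are 2x more reliable than background.
    """

    n_tfs: int = 100
    n_genes: int = 2000
    degree_quantiles: tuple = DEFAULT_DEGREE_QUANTILES
    edge_weight_range: tuple = (0.5, 1.0)
    n_instances: int = 10
    genes_per_instance: int = 32
    planted_modules: tuple = (("TF000", "TF001", "TF002"), )
    planted_gene_count: int = 30
    planted_boost: float = 2.0
    planted_attachment: float = 2.0
    planted_genes_per_instance: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in ("n_tfs", "n_genes", "n_instances", "genes_per_instance"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.edge_weight_range
        if not (0 < lo <= hi):
            raise ValueError("edge_weight_range must be a positive interval")
        prev_d, prev_f = 0, 0.0
        for d, f in self.degree_quantiles:
            if d <= prev_d or f < prev_f or not (0 < f <= 1):
                raise ValueError("degree quantiles must increase in degree and fraction")
            prev_d, prev_f = d, f
        if self.genes_per_instance > self.n_genes:
            raise ValueError("genes_per_instance exceeds n_genes")
        if self.planted_genes_per_instance > self.genes_per_instance:
            raise ValueError("planted_genes_per_instance exceeds genes_per_instance")
        if self.planted_attachment < 1:
            raise ValueError("planted_attachment must be >= 1")

    def tf_ids(self):
        return [f"TF{i:03d}" for i in range(self.n_tfs)]

    def gene_ids(self):
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass
class SyntheticWorld:
    """A generated world plus its ground truth."""

    config: GeneratorConfig
    graph: ProteinDnaGraph
    instances: list
    interactions: set
    planted_modules: tuple
    planted_genes: dict = field(default_factory=dict)  # module tuple -> gene list


def _degree_bands(quantiles):
    """Convert cumulative quantiles into (lo, hi, probability) bands."""
    bands = []
    prev_d, prev_f = 0, 0.0
    for d, f in quantiles:
        bands.append((prev_d + 1, d, f - prev_f))
        prev_d, prev_f = d, f
    if prev_f < 1.0:
        bands.append((prev_d + 1, MAX_DEGREE, 1.0 - prev_f))
    return bands


def _sample_degrees(n, quantiles, rng):
    bands = _degree_bands(quantiles)
    probs = np.array([p for _, _, p in bands])
    probs = probs / probs.sum()
    idx = rng.choice(len(bands), size=n, p=probs)
    degs = np.empty(n, dtype=int)
    for i, b in enumerate(bands):
        mask = idx == i
        degs[mask] = rng.integers(b[0], b[1] + 1, size=mask.sum())
    return degs


def generate_graph(config: GeneratorConfig, rng=None) -> ProteinDnaGraph:
    """Sample a bipartite TF-gene graph with the configured degree profile.

    Each gene draws a degree from the banded distribution and attaches to
    that many TFs without replacement; attachment is uniform over TFs
    except for planted-module TFs, whose attachment propensity is scaled
    by ``planted_attachment`` — module TFs are master-regulator hubs
    binding a disproportionate share of the genome.  Edge weights are
    uniform in ``edge_weight_range``.  Every TF is guaranteed at least one
    edge.  Deterministic given the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    tfs = config.tf_ids()
    genes = config.gene_ids()
    degrees = np.minimum(_sample_degrees(config.n_genes, config.degree_quantiles, rng),
                         config.n_tfs)
    propensity = np.ones(config.n_tfs)
    planted_tfs = {tf for module in config.planted_modules for tf in module}
    for i, tf in enumerate(tfs):
        if tf in planted_tfs:
            propensity[i] = config.planted_attachment
    propensity = propensity / propensity.sum()
    lo, hi = config.edge_weight_range
    edges: dict = {}
    for gene, deg in zip(genes, degrees):
        chosen = rng.choice(config.n_tfs, size=deg, replace=False, p=propensity)
        for ti in chosen:
            edges[(tfs[ti], gene)] = float(rng.uniform(lo, hi))
    # bipartite invariant: every TF needs >= 1 edge
    attached = {tf for tf, _ in edges}
    for tf in tfs:
        if tf not in attached:
            gene = genes[int(rng.integers(config.n_genes))]
            edges[(tf, gene)] = float(rng.uniform(lo, hi))
    return ProteinDnaGraph(edges)


def plant_module(
    graph: ProteinDnaGraph,
    tf_ids,
    gene_count: int,
    boost: float,
    rng,
    *,
    edge_weight_range=(0.5, 1.0),
):
    """Wire a TF module to a common target-gene set.

    ``gene_count`` genes are chosen at random; each gains an edge to every
    module TF.  New edges draw a reliability from ``edge_weight_range``
    multiplied by ``boost``; existing module-TF edges to a planted gene are
    multiplied by ``boost`` as well (``boost >= 1`` makes module binding
    more reliable than background).  Returns ``(new_graph, planted_genes)``.
    """
    tf_ids = sorted(tf_ids)
    missing = set(tf_ids) - graph.tfs
    if missing:
        raise ValueError(f"module TFs not in graph: {sorted(missing)}")
    if boost < 1:
        raise ValueError("boost must be >= 1")
    genes = sorted(graph.genes)
    if gene_count > len(genes):
        raise ValueError("gene_count exceeds number of genes")
    picked = [genes[i] for i in rng.choice(len(genes), size=gene_count, replace=False)]
    lo, hi = edge_weight_range
    edges = dict(graph.edges)
    for gene in picked:
        for tf in tf_ids:
            if (tf, gene) in edges:
                edges[(tf, gene)] *= boost
            else:
                edges[(tf, gene)] = float(rng.uniform(lo, hi)) * boost
    return ProteinDnaGraph(edges), sorted(picked)


def generate_instances(
    graph: ProteinDnaGraph,
    config: GeneratorConfig,
    planted_gene_sets,
    rng=None,
):
    """Sample perturbation instances mixing planted and background genes.

    Every instance draws ``planted_genes_per_instance`` genes from each
    planted set (cycling through modules) and fills up to
    ``genes_per_instance`` with uniform background genes.  Deterministic
    given the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    all_genes = sorted(graph.genes)
    planted_flat = sorted({g for gs in planted_gene_sets for g in gs})
    background = [g for g in all_genes if g not in set(planted_flat)]
    instances = []
    for i in range(config.n_instances):
        chosen: set = set()
        if planted_gene_sets:
            module_genes = sorted(planted_gene_sets[i % len(planted_gene_sets)])
            k = min(config.planted_genes_per_instance, len(module_genes))
            chosen.update(
                module_genes[j]
                for j in rng.choice(len(module_genes), size=k, replace=False)
            )
        n_bg = config.genes_per_instance - len(chosen)
        if n_bg > len(background):
            raise ValueError("not enough background genes for the requested instance size")
        if n_bg > 0:
            chosen.update(
                background[j]
                for j in rng.choice(len(background), size=n_bg, replace=False)
            )
        instances.append(PerturbationInstance(f"pert{i:03d}", frozenset(chosen)))
    return instances


def generate_interactions(tf_ids, module_sets, background_rate: float, rng):
    """TF-TF interaction network: all within-module pairs plus independent
    background pairs at ``background_rate``."""
    import itertools

    if not (0 <= background_rate <= 1):
        raise ValueError("background_rate must be in [0, 1]")
    pairs: set = set()
    for module in module_sets:
        for p in itertools.combinations(sorted(module), 2):
            pairs.add(frozenset(p))
    for p in itertools.combinations(sorted(tf_ids), 2):
        fp = frozenset(p)
        if fp not in pairs and rng.uniform() < background_rate:
            pairs.add(fp)
    return pairs


def generate_world(
    config: GeneratorConfig, *, interaction_background_rate: float = 0.02
) -> SyntheticWorld:
    """Generate graph, planted modules, instances and interactions from one
    seed, each stage on its own RNG stream."""
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(config.seed).spawn(4)]
    graph = generate_graph(config, streams[0])
    planted_genes: dict = {}
    gene_sets = []
    for module in config.planted_modules:
        graph, genes = plant_module(
            graph, module, config.planted_gene_count, config.planted_boost,
            streams[1], edge_weight_range=config.edge_weight_range,
        )
        planted_genes[tuple(sorted(module))] = genes
        gene_sets.append(genes)
    instances = generate_instances(graph, config, gene_sets, streams[2])
    interactions = generate_interactions(
        config.tf_ids(), config.planted_modules, interaction_background_rate,
        streams[3],
    )
    return SyntheticWorld(
        config=config,
        graph=graph,
        instances=instances,
        interactions=interactions,
        planted_modules=tuple(tuple(sorted(m)) for m in config.planted_modules),
        planted_genes=planted_genes,
    )
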