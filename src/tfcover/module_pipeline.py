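"""System-level TF-module discovery from per-perturbation cover solutions.

Per perturbation, the exact t-cover solver yields a minimum-weight set of
cooperative TFs.  Across perturbations those solutions are accumulated into
a weighted TF-TF relation graph: two TFs gain an edge whenever they appear
together in an instance's solution and share at least one DE target gene
there, the weight summing common-target counts over all instances.  Highly
weighted 3- and 4-cliques of that graph ("soft" cliques) are candidate TF
modules reused across conditions.  "Hard" cliques are TF sets forming a
complete biclique with some DE gene set inside a single instance, weighted
by the shared-target count and summed over instances.  Cliques are
evaluated by how many of their member pairs show known protein-protein or
genetic interactions, against a random-group control.
"""

from __future__ import annotations

import itertools
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph_model import PerturbationInstance, ProteinDnaGraph, induce_instance
from .hitting_set import solve_weighted_t_cover

__all__ = [
    "TfTfGraph",
    "TfClique",
    "solve_instances",
    "common_targets",
    "build_tf_tf_graph",
    "enumerate_soft_cliques",
    "find_hard_cliques",
    "accumulate_hard_cliques",
    "evaluate_interactions",
]


@dataclass
class TfTfGraph:
    """Undirected TF cooperation graph; edge weights are cumulative
    common-target counts over perturbation instances."""

    edges: dict  # frozenset({tf1, tf2}) -> positive int

    def __post_init__(self):
        for pair, w in self.edges.items():
            if len(pair) != 2:
                raise ValueError(f"not an unordered TF pair: {set(pair)}")
            if w < 1:
                raise ValueError(f"edge {set(pair)} has weight {w} < 1")

    @property
    def nodes(self) -> set:
        out: set = set()
        for pair in self.edges:
            out |= pair
        return out

    def adjacency(self) -> dict:
        adj: dict = {}
        for pair in self.edges:
            a, b = sorted(pair)
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return adj

    def weight(self, tf1, tf2) -> int:
        return self.edges.get(frozenset((tf1, tf2)), 0)

    def total_weight(self) -> int:
        return sum(self.edges.values())

    def to_tsv(self, path) -> None:
        rows = sorted((min(p), max(p), w) for p, w in self.edges.items())
        pd.DataFrame(rows, columns=["tf_id_1", "tf_id_2", "weight"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "TfTfGraph":
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str,
                         names=["tf_id_1", "tf_id_2", "weight"])
        if not df.empty and df.iloc[0, 0] == "tf_id_1":
            df = df.iloc[1:]
        return cls({
            frozenset((r.tf_id_1, r.tf_id_2)): int(float(r.weight))
            for r in df.itertuples()
        })


@dataclass(frozen=True)
class TfClique:
    """A ranked 3- or 4-TF clique with its weight.

    ``kind`` is ``"soft"`` (weight = sum of TF-TF relation-graph edge
    weights over member pairs) or ``"hard"`` (weight = shared-target gene
    count, summed over instances).
    """

    members: frozenset
    weight: float
    kind: str
    rank: int | None = None


def _rank_cliques(cliques: Iterable, top: int | None = None):
    """Sort by weight descending, ties by lexicographic member tuple;
    assign 1-based ranks; truncate to ``top``."""
    ordered = sorted(cliques, key=lambda c: (-c.weight, tuple(sorted(c.members))))
    if top is not None:
        ordered = ordered[:top]
    return [
        TfClique(c.members, c.weight, c.kind, rank=i)
        for i, c in enumerate(ordered, 1)
    ]


def solve_instances(
    graph: ProteinDnaGraph,
    instances: Sequence,
    t: int,
    policy: str,
) -> dict:
    """Solve the t-cover problem per perturbation instance.

    Each instance is solved component-wise on the bipartite subgraph its DE
    genes induce; the instance's cooperative TF set is the union of the
    per-component optimal witnesses (padding dummies excluded).  Instances
    whose genes are all dropped yield the empty set with a warning.
    """
    from .graph_model import connected_components

    solutions: dict = {}
    for inst in instances:
        tf_union: set = set()
        comps = connected_components(graph, inst.de_genes)
        for _, comp_genes in comps:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub, report = induce_instance(graph, comp_genes, t, policy)
            if not sub.family:
                continue
            best = solve_weighted_t_cover(sub)[0].strip_dummies(sub.dummies)
            tf_union |= best.witness
        if not tf_union:
            warnings.warn(
                f"instance {inst.id!r}: no coverable gene at t={t}; empty solution",
                stacklevel=2,
            )
        solutions[inst.id] = frozenset(tf_union)
    return solutions


def common_targets(tf1, tf2, gene_set: Iterable, graph: ProteinDnaGraph) -> int:
    """Number of genes in ``gene_set`` bound by both TFs."""
    for tf in (tf1, tf2):
        if tf not in graph.tfs:
            raise KeyError(f"unknown TF {tf!r}")
    shared = graph.tf_neighborhood(tf1) & graph.tf_neighborhood(tf2)
    return len(shared & set(gene_set))


def build_tf_tf_graph(
    graph: ProteinDnaGraph,
    instances: Sequence,
    solutions: Mapping,
) -> TfTfGraph:
    """Accumulate the TF-TF relation graph over all instances.

    For every instance and every unordered TF pair in its solution, the
    pair's edge gains the count of their common targets among that
    instance's DE genes.  Pairs that never share a target contribute no
    edge (a zero-weight edge would manufacture spurious cliques).
    """
    edges: dict = {}
    by_id = {inst.id: inst for inst in instances}
    for inst_id, tf_set in solutions.items():
        inst = by_id[inst_id]
        de = inst.de_genes & graph.genes
        for tf1, tf2 in itertools.combinations(sorted(tf_set), 2):
            c = common_targets(tf1, tf2, de, graph)
            if c > 0:
                pair = frozenset((tf1, tf2))
                edges[pair] = edges.get(pair, 0) + c
    return TfTfGraph(edges)


def enumerate_soft_cliques(
    tftf: TfTfGraph, size: int, top: int | None = None
):
    """All 3- or 4-cliques of the TF-TF relation graph, ranked by weight.

    A clique's weight is the sum of its ``C(size, 2)`` edge weights.
    """
    if size not in (3, 4):
        raise ValueError("clique size must be 3 or 4")
    adj = tftf.adjacency()
    nodes = sorted(adj)
    triangles = []
    for a, b in (tuple(sorted(p)) for p in tftf.edges):
        for c in sorted(adj[a] & adj[b]):
            if c > b:
                triangles.append((a, b, c))
    if size == 3:
        raw = triangles
    else:
        raw = []
        for a, b, c in triangles:
            for d in sorted(adj[a] & adj[b] & adj[c]):
                if d > c:
                    raw.append((a, b, c, d))
    cliques = [
        TfClique(
            frozenset(members),
            sum(tftf.weight(x, y) for x, y in itertools.combinations(members, 2)),
            "soft",
        )
        for members in raw
    ]
    return _rank_cliques(cliques, top)


def find_hard_cliques(
    graph: ProteinDnaGraph,
    instance: PerturbationInstance,
    size: int,
    *,
    restrict_to: Iterable | None = None,
):
    """Hard TF cliques of one instance: TF sets whose members all bind a
    common non-empty set of the instance's DE genes (a biclique), weighted
    by that shared-target count.

    By default all TFs adjacent to the instance's genes are candidates;
    ``restrict_to`` limits candidates (e.g. to the instance's solution TFs).
    """
    if size not in (3, 4):
        raise ValueError("clique size must be 3 or 4")
    allowed = None if restrict_to is None else set(restrict_to)
    counts: dict = {}
    for gene in instance.de_genes & graph.genes:
        tfs = graph.gene_neighborhood(gene)
        if allowed is not None:
            tfs &= allowed
        if len(tfs) < size:
            continue
        for combo in itertools.combinations(sorted(tfs), size):
            counts[combo] = counts.get(combo, 0) + 1
    cliques = [
        TfClique(frozenset(combo), w, "hard") for combo, w in counts.items()
    ]
    return _rank_cliques(cliques)


def accumulate_hard_cliques(
    graph: ProteinDnaGraph,
    instances: Sequence,
    size: int,
    *,
    restrict_to: Mapping | None = None,
    top: int | None = None,
):
    """Sum each hard clique's weight over all instances and rank.

    ``restrict_to`` optionally maps instance id -> allowed TF set (e.g. the
    per-instance solutions).
    """
    totals: dict = {}
    for inst in instances:
        allowed = restrict_to.get(inst.id) if restrict_to is not None else None
        for c in find_hard_cliques(graph, inst, size, restrict_to=allowed):
            totals[c.members] = totals.get(c.members, 0) + c.weight
    cliques = [TfClique(m, w, "hard") for m, w in totals.items()]
    return _rank_cliques(cliques, top)


def evaluate_interactions(
    cliques: Sequence,
    interactions: Iterable,
    n_random: int,
    seed: int,
    tf_pool: Iterable,
) -> pd.DataFrame:
    """Cumulative interaction-enrichment table for a clique ranking.

    For each ``k`` from 0 to ``C(size, 2)``, the fraction of cliques whose
    member pairs include at least ``k`` known interactions, alongside the
    same fraction for ``n_random`` uniformly sampled TF groups of the same
    size drawn (without replacement within a group) from ``tf_pool``.

    Returns a DataFrame with columns ``k``, ``fraction_cliques``,
    ``fraction_random``.
    """
    if not cliques:
        raise ValueError("no cliques to evaluate")
    sizes = {len(c.members) for c in cliques}
    if len(sizes) != 1:
        raise ValueError(f"cliques of mixed sizes: {sorted(sizes)}")
    size = sizes.pop()
    pool = sorted(tf_pool)
    if len(pool) < size:
        raise ValueError(f"TF pool of {len(pool)} is smaller than group size {size}")
    inter = {frozenset(p) for p in interactions}
    max_k = size * (size - 1) // 2

    def n_interacting(members) -> int:
        return sum(
            1 for p in itertools.combinations(members, 2) if frozenset(p) in inter
        )

    clique_counts = [n_interacting(c.members) for c in cliques]
    rng = np.random.default_rng(seed)
    random_counts = [
        n_interacting(rng.choice(pool, size=size, replace=False))
        for _ in range(n_random)
    ]
    rows = []
    for k in range(max_k + 1):
        rows.append({
            "k": k,
            "fraction_cliques": np.mean([c >= k for c in clique_counts]),
            "fraction_random": np.mean([c >= k for c in random_counts]),
        })
    return pd.DataFrame(rows)
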