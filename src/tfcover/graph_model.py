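"""Protein-DNA bipartite graph model and hitting-set instance induction.

A protein-DNA graph links transcription factors (TFs) to the genes whose
promoters they bind, with a positive edge weight expressing the reliability
of the binding call (e.g. from ChIP-chip).  A TF's weight in the cover
problem is the reciprocal of the sum of its edge weights, so TFs that bind
many genes reliably are cheap and preferentially enter minimum-weight
covers.

Given a set of differentially expressed (DE) genes from one perturbation
experiment, each retained gene contributes one subset — its TF
neighborhood — to a weighted t-cover hitting set instance over the TFs.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .hitting_set import HittingSetInstance

__all__ = [
    "ProteinDnaGraph",
    "PerturbationInstance",
    "InductionReport",
    "compute_tf_weight",
    "induce_instance",
    "connected_components",
    "read_graph_tsv",
    "read_instances",
]

logger = logging.getLogger(__name__)

DUMMY_PREFIX = "__dummy__"


@dataclass
class ProteinDnaGraph:
    """Weighted bipartite TF-gene graph.

    ``edges`` maps ``(tf, gene)`` to a positive reliability weight.  The
    graph is strictly bipartite and every TF has at least one edge.
    """

    edges: dict

    _tf_targets: dict = field(init=False, repr=False)
    _gene_tfs: dict = field(init=False, repr=False)

    def __post_init__(self):
        tf_targets: dict = {}
        gene_tfs: dict = {}
        for (tf, gene), w in self.edges.items():
            if w <= 0:
                raise ValueError(f"edge ({tf}, {gene}) has non-positive weight {w}")
            tf_targets.setdefault(tf, {})[gene] = w
            gene_tfs.setdefault(gene, set()).add(tf)
        overlap = set(tf_targets) & set(gene_tfs)
        if overlap:
            raise ValueError(f"ids appear on both sides of the graph: {sorted(overlap)[:5]}")
        self._tf_targets = tf_targets
        self._gene_tfs = gene_tfs

    @property
    def tfs(self) -> set:
        return set(self._tf_targets)

    @property
    def genes(self) -> set:
        return set(self._gene_tfs)

    def tf_neighborhood(self, tf) -> set:
        """Genes bound by ``tf``."""
        return set(self._tf_targets[tf])

    def gene_neighborhood(self, gene) -> set:
        """TFs binding ``gene``."""
        return set(self._gene_tfs.get(gene, ()))

    def edge_weight(self, tf, gene) -> float:
        return self._tf_targets[tf][gene]

    def has_edge(self, tf, gene) -> bool:
        return gene in self._tf_targets.get(tf, ())

    def degree(self, gene) -> int:
        return len(self._gene_tfs.get(gene, ()))

    def to_tsv(self, path) -> None:
        rows = sorted((tf, g, w) for (tf, g), w in self.edges.items())
        pd.DataFrame(rows, columns=["tf_id", "gene_id", "edge_weight"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class PerturbationInstance:
    """One perturbation experiment: a label and its DE gene set."""

    id: str
    de_genes: frozenset

    def __post_init__(self):
        object.__setattr__(self, "de_genes", frozenset(self.de_genes))
        if not self.de_genes:
            raise ValueError(f"perturbation instance {self.id!r} has no genes")


@dataclass
class InductionReport:
    """What happened to each DE gene while building an instance."""

    retained: list = field(default_factory=list)
    dropped_low_degree: list = field(default_factory=list)
    missing_from_graph: list = field(default_factory=list)
    padded: dict = field(default_factory=dict)  # gene -> list of dummy ids


def compute_tf_weight(
    tf, graph: ProteinDnaGraph, *, restrict_to: set | None = None
) -> float:
    """TF weight = 1 / (sum of the TF's edge reliabilities).

    By default the sum runs over the TF's full neighborhood in the input
    graph; pass ``restrict_to`` (a gene set) to sum only over edges into
    those genes, e.g. for sensitivity analysis on an induced subgraph.
    """
    if tf not in graph.tfs:
        raise KeyError(f"unknown or isolated TF {tf!r}: weight undefined")
    targets = graph._tf_targets[tf]
    if restrict_to is None:
        total = sum(targets.values())
    else:
        total = sum(w for g, w in targets.items() if g in restrict_to)
    if total <= 0:
        raise ValueError(f"TF {tf!r} has no edges in the requested gene set")
    return 1.0 / total


def induce_instance(
    graph: ProteinDnaGraph,
    de_genes: Iterable,
    t: int,
    policy: str,
    *,
    induced_weights: bool = False,
):
    """Build a hitting-set instance from a DE gene set.

    Elements are the TFs adjacent to retained genes, weighted by
    :func:`compute_tf_weight` on the full graph (or on the induced gene set
    if ``induced_weights``).  Each retained gene contributes the subset of
    TFs binding it.  Genes of degree < t are handled per ``policy``:

    ``"drop"``
        remove the gene and report it (shrinks the instance);
    ``"pad"``
        add zero-weight dummy elements to raise the subset size to ``t``
        (effectively lowering that gene's coverage requirement); dummies
        are excluded from reported witnesses downstream.

    Returns ``(instance, report)``.  Genes absent from the graph are
    skipped with a warning.
    """
    if policy not in ("drop", "pad"):
        raise ValueError(f"policy must be 'drop' or 'pad', got {policy!r}")
    if t < 1:
        raise ValueError("t must be >= 1")
    de_genes = set(de_genes)
    if not de_genes:
        raise ValueError("de_genes must be non-empty")
    report = InductionReport()
    report.missing_from_graph = sorted(g for g in de_genes if g not in graph.genes)
    if report.missing_from_graph:
        warnings.warn(
            f"{len(report.missing_from_graph)} DE gene(s) absent from the "
            "graph were skipped",
            stacklevel=2,
        )
    present = sorted(de_genes & graph.genes)

    subsets = []
    dummies = set()
    for gene in present:
        nbrs = graph.gene_neighborhood(gene)
        if len(nbrs) < t:
            if policy == "drop":
                report.dropped_low_degree.append(gene)
                continue
            pads = [f"{DUMMY_PREFIX}{gene}_{i}" for i in range(t - len(nbrs))]
            report.padded[gene] = pads
            dummies.update(pads)
            nbrs = nbrs | set(pads)
        report.retained.append(gene)
        subsets.append(frozenset(nbrs))

    if not subsets:
        warnings.warn("no DE gene survived induction: empty instance", stacklevel=2)
        return HittingSetInstance((), {}, (), t), report

    tf_ids = sorted(set().union(*subsets) - dummies)
    restrict = set(report.retained) if induced_weights else None
    weights = {tf: compute_tf_weight(tf, graph, restrict_to=restrict) for tf in tf_ids}
    weights.update({d: 0.0 for d in dummies})
    instance = HittingSetInstance(
        elements=tuple(tf_ids) + tuple(sorted(dummies)),
        weights=weights,
        family=tuple(subsets),
        t=t,
        dummies=frozenset(dummies),
    )
    return instance, report


def connected_components(graph: ProteinDnaGraph, de_genes: Iterable):
    """Connected components of the subgraph induced by ``de_genes``.

    Returns a list of ``(tf_set, gene_set)`` pairs, ordered by the smallest
    member id of each component.  Genes absent from the graph are ignored.
    """
    present = sorted(set(de_genes) & graph.genes)
    if not present:
        return []
    g = nx.Graph()
    for gene in present:
        g.add_node(("gene", gene))
        for tf in graph.gene_neighborhood(gene):
            g.add_edge(("tf", tf), ("gene", gene))
    comps = []
    for comp in nx.connected_components(g):
        tfs = {name for kind, name in comp if kind == "tf"}
        genes = {name for kind, name in comp if kind == "gene"}
        comps.append((tfs, genes))
    comps.sort(key=lambda c: min(map(str, c[0] | c[1])))
    return comps


# ---------------------------------------------------------------------------
# file formats


def read_graph_tsv(path) -> ProteinDnaGraph:
    """Read a TSV edge list ``tf_id <TAB> gene_id <TAB> edge_weight``.

    A header line is detected by a non-numeric third column; '#'-prefixed
    comment lines are ignored.  Duplicate edges have their weights summed,
    with a warning.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, dtype=str,
        names=["tf_id", "gene_id", "edge_weight"],
    )
    if df.empty:
        raise ValueError(f"no edges in {path}")
    try:
        float(df.iloc[0, 2])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    if df.empty:
        raise ValueError(f"no edges in {path}")
    df = df.assign(edge_weight=df["edge_weight"].astype(float))
    dup = df.duplicated(subset=["tf_id", "gene_id"]).sum()
    if dup:
        warnings.warn(f"{dup} duplicate edge(s) in {path}: weights summed", stacklevel=2)
        df = df.groupby(["tf_id", "gene_id"], as_index=False)["edge_weight"].sum()
    edges = {(r.tf_id, r.gene_id): r.edge_weight for r in df.itertuples()}
    return ProteinDnaGraph(edges)


def read_instances(path) -> list:
    """Read perturbation instances from JSON or two-column TSV.

    JSON: an object ``{instance_id: [gene ids]}``.  TSV: two columns
    ``instance_id <TAB> gene_id``, one row per (instance, gene) pair.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        import json

        data = json.loads(path.read_text())
        items = [(str(k), frozenset(map(str, v))) for k, v in data.items()]
    else:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, dtype=str,
            names=["instance_id", "gene_id"],
        )
        if not df.empty and df.iloc[0, 0] == "instance_id":
            df = df.iloc[1:]
        items = [
            (str(k), frozenset(map(str, grp["gene_id"])))
            for k, grp in df.groupby("instance_id", sort=True)
        ]
    ids = [k for k, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate instance ids")
    return [PerturbationInstance(k, genes) for k, genes in items]
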