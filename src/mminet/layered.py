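"""Typed layered networks: the tripartite MMI graph and its projections.

The MMI (microbiota-metabolite-immune) network has three node layers --
taxa, metabolites and GO immune-system-process terms -- joined by
taxon-metabolite edges, metabolite-term edges (a metabolite is linked to
every significant term containing at least one of its target genes) and
term-term kappa edges.  Disease overlays extend the same container with
a GENE layer.  The graph is simple and undirected throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from mminet.enrichment import EnrichmentResult, TermGrouping
from mminet.hmdb import SENTINEL_TAXA

logger = logging.getLogger(__name__)

__all__ = [
    "NodeType",
    "EdgeType",
    "LayeredNetwork",
    "Projection",
    "build_mmi",
    "project",
]


class NodeType(str, Enum):
    TAXON = "TAXON"
    METABOLITE = "METABOLITE"
    GENE = "GENE"
    GOISP = "GOISP"


class EdgeType(str, Enum):
    TAXON_METABOLITE = "TAXON-METABOLITE"
    METABOLITE_GOISP = "METABOLITE-GOISP"
    METABOLITE_GENE = "METABOLITE-GENE"
    GENE_GENE = "GENE-GENE"
    GENE_GOISP = "GENE-GOISP"
    GOISP_GOISP = "GOISP-GOISP"


#: Endpoint node types each edge type may join (as an unordered pair).
EDGE_ENDPOINTS: dict[EdgeType, frozenset[NodeType]] = {
    EdgeType.TAXON_METABOLITE: frozenset({NodeType.TAXON, NodeType.METABOLITE}),
    EdgeType.METABOLITE_GOISP: frozenset({NodeType.METABOLITE, NodeType.GOISP}),
    EdgeType.METABOLITE_GENE: frozenset({NodeType.METABOLITE, NodeType.GENE}),
    EdgeType.GENE_GENE: frozenset({NodeType.GENE}),
    EdgeType.GENE_GOISP: frozenset({NodeType.GENE, NodeType.GOISP}),
    EdgeType.GOISP_GOISP: frozenset({NodeType.GOISP}),
}

_SENTINELS = frozenset(SENTINEL_TAXA.values())


class LayeredNetwork:
    """Simple undirected graph with typed nodes and typed edges.

    Thin wrapper over :class:`networkx.Graph` that validates edge
    endpoint types, forbids self-loops, and reports per-type counts.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    def add_node(self, node: str, node_type: NodeType) -> None:
        existing = self.graph.nodes.get(node)
        if existing is not None and existing["node_type"] != node_type:
            raise ValueError(
                f"node {node!r} already present with type {existing['node_type']}"
            )
        self.graph.add_node(node, node_type=node_type)

    def add_edge(self, u: str, v: str, edge_type: EdgeType) -> None:
        if u == v:
            raise ValueError(f"self loop on {u!r} not allowed")
        for node in (u, v):
            if node not in self.graph:
                raise KeyError(f"edge endpoint {node!r} is not a node")
        endpoint_types = frozenset(
            {self.graph.nodes[u]["node_type"], self.graph.nodes[v]["node_type"]}
        )
        if endpoint_types != EDGE_ENDPOINTS[edge_type]:
            raise ValueError(
                f"edge type {edge_type.value} cannot join {sorted(t.value for t in endpoint_types)}"
            )
        self.graph.add_edge(u, v, edge_type=edge_type)

    def node_type(self, node: str) -> NodeType:
        return self.graph.nodes[node]["node_type"]

    def nodes_of_type(self, node_type: NodeType) -> frozenset[str]:
        return frozenset(
            n for n, d in self.graph.nodes(data="node_type") if d == node_type
        )

    def node_counts(self) -> dict[str, int]:
        counts = {t.value: 0 for t in NodeType}
        for _, node_type in self.graph.nodes(data="node_type"):
            counts[node_type.value] += 1
        counts["total"] = self.graph.number_of_nodes()
        return counts

    def edge_counts(self) -> dict[str, int]:
        counts = {t.value: 0 for t in EdgeType}
        for _, _, edge_type in self.graph.edges(data="edge_type"):
            counts[edge_type.value] += 1
        counts["total"] = self.graph.number_of_edges()
        return counts

    def neighbors_of_type(self, node: str, node_type: NodeType) -> frozenset[str]:
        return frozenset(
            nbr
            for nbr in self.graph.neighbors(node)
            if self.graph.nodes[nbr]["node_type"] == node_type
        )

    def to_node_table(self) -> pd.DataFrame:
        rows = sorted(
            (n, d.value) for n, d in self.graph.nodes(data="node_type")
        )
        return pd.DataFrame(rows, columns=["node", "node_type"])

    def to_edge_table(self) -> pd.DataFrame:
        rows = sorted(
            (*sorted((u, v)), d.value)
            for u, v, d in self.graph.edges(data="edge_type")
        )
        return pd.DataFrame(rows, columns=["source", "target", "edge_type"])

    @classmethod
    def from_tables(
        cls, node_table: pd.DataFrame, edge_table: pd.DataFrame
    ) -> "LayeredNetwork":
        """Rebuild a network from its node/edge table exports."""
        net = cls()
        for row in node_table.itertuples(index=False):
            net.add_node(row.node, NodeType(row.node_type))
        for row in edge_table.itertuples(index=False):
            net.add_edge(row.source, row.target, EdgeType(row.edge_type))
        return net

    def to_graphml(self, path: str | Path) -> None:
        export = nx.Graph()
        for node, data in sorted(self.graph.nodes(data=True)):
            export.add_node(node, node_type=data["node_type"].value)
        for u, v, data in sorted(
            self.graph.edges(data=True), key=lambda e: tuple(sorted(e[:2]))
        ):
            export.add_edge(u, v, edge_type=data["edge_type"].value)
        nx.write_graphml(export, str(path))


@dataclass(frozen=True)
class Projection:
    """Entity-to-feature-set view of a layered network.

    Every entity key is a node of ``source_type`` and every feature set
    is non-empty.
    """

    mapping: Mapping[str, frozenset[str]]
    source_type: NodeType
    target_type: NodeType

    def __post_init__(self) -> None:
        for entity, features in self.mapping.items():
            if not features:
                raise ValueError(f"entity {entity!r} has an empty feature set")

    @property
    def entities(self) -> list[str]:
        return sorted(self.mapping)

    @property
    def features(self) -> list[str]:
        out: set[str] = set()
        for features in self.mapping.values():
            out |= features
        return sorted(out)


def build_mmi(
    taxon_metabolite: pd.DataFrame,
    gene_table: pd.DataFrame,
    enrichment: EnrichmentResult,
    grouping: TermGrouping,
) -> LayeredNetwork:
    """Assemble the tripartite microbiota-metabolite-immune network.

    A metabolite is linked to a significant term when at least one of
    its target genes is a query gene annotated to that term (existential
    rule, unweighted).  Metabolites with no term edge, and taxa left
    without metabolites, are pruned; the fixed point is independent of
    pruning order.  Term-term edges are the kappa edges from
    ``grouping``.  Unnamed sentinel taxa are kept as ordinary taxa.
    """
    known = set(taxon_metabolite["metabolite_id"])
    dangling = sorted(set(gene_table["metabolite_id"]) - known)
    if dangling:
        raise ValueError(
            f"gene table references metabolites absent from the taxon table: {dangling[:5]}"
        )

    targets: dict[str, set[str]] = {}
    for row in gene_table.itertuples(index=False):
        targets.setdefault(row.metabolite_id, set()).add(row.gene_symbol)

    significant = sorted(enrichment.significant_terms)
    net = LayeredNetwork()
    if not significant:
        logger.info("no significant terms: MMI network is empty")
        return net

    # metabolite-term edges via shared query genes
    metabolite_terms: dict[str, list[str]] = {}
    for metabolite, genes in sorted(targets.items()):
        hit_terms = [
            t for t in significant if genes & enrichment.query_hits[t]
        ]
        if hit_terms:
            metabolite_terms[metabolite] = hit_terms

    for term in significant:
        net.add_node(term, NodeType.GOISP)
    for metabolite, terms in metabolite_terms.items():
        net.add_node(metabolite, NodeType.METABOLITE)
        for term in terms:
            net.add_edge(metabolite, term, EdgeType.METABOLITE_GOISP)

    surviving = set(metabolite_terms)
    for row in taxon_metabolite.sort_values(["taxon", "metabolite_id"]).itertuples(
        index=False
    ):
        if row.metabolite_id in surviving:
            net.add_node(row.taxon, NodeType.TAXON)
            net.add_edge(row.taxon, row.metabolite_id, EdgeType.TAXON_METABOLITE)

    for a, b, _ in grouping.kappa_edges:
        if a in net.graph and b in net.graph:
            net.add_edge(a, b, EdgeType.GOISP_GOISP)

    logger.info("MMI counts: nodes=%s edges=%s", net.node_counts(), net.edge_counts())
    return net


def project(
    network: LayeredNetwork,
    source_type: NodeType,
    target_type: NodeType,
    include_sentinels: bool = False,
) -> Projection:
    """Extract an entity-to-feature-set projection from the network.

    Supported pairs: METABOLITE->GOISP and TAXON->METABOLITE (direct
    edges) and TAXON->GOISP (union over the taxon's metabolites of their
    term neighbours).  Taxon-source projections exclude the unnamed
    sentinel taxa unless ``include_sentinels`` is set, mirroring the
    restriction to named genera/species/strains.
    """
    pair = (source_type, target_type)
    mapping: dict[str, frozenset[str]] = {}
    if pair == (NodeType.METABOLITE, NodeType.GOISP):
        for m in network.nodes_of_type(NodeType.METABOLITE):
            features = network.neighbors_of_type(m, NodeType.GOISP)
            if features:
                mapping[m] = features
    elif pair == (NodeType.TAXON, NodeType.METABOLITE):
        for t in network.nodes_of_type(NodeType.TAXON):
            if not include_sentinels and t in _SENTINELS:
                continue
            features = network.neighbors_of_type(t, NodeType.METABOLITE)
            if features:
                mapping[t] = features
    elif pair == (NodeType.TAXON, NodeType.GOISP):
        for t in network.nodes_of_type(NodeType.TAXON):
            if not include_sentinels and t in _SENTINELS:
                continue
            terms: set[str] = set()
            for m in network.neighbors_of_type(t, NodeType.METABOLITE):
                terms |= network.neighbors_of_type(m, NodeType.GOISP)
            if terms:
                mapping[t] = frozenset(terms)
    else:
        raise ValueError(
            f"unsupported projection {source_type.value} -> {target_type.value}"
        )
    return Projection(mapping=mapping, source_type=source_type, target_type=target_type)
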