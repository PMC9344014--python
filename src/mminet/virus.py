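"""Virus-host interactome integration and virus-microbiota ISP comparison.

A virus-host network is a bipartite graph of viral proteins (carrying
strain labels) and human proteins.  Integrating it with a disease gene
set adds the disease genes and their intra-set PPIs; the enrichment
query is then the direct human targets of the virus plus their human
first neighbours in the integrated network.  Significantly enriched
virus terms are intersected with microbiota-modulated terms, and the
virus can be appended as an extra all-ones row over the common terms to
cluster it jointly with the taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from mminet.enrichment import EnrichmentResult
from mminet.disease import DiseaseGeneSet
from mminet.layered import Projection
from mminet.similarity import DendrogramResult, IncidenceMatrix, cluster, jaccard_distance

logger = logging.getLogger(__name__)

__all__ = [
    "VirusHostNetwork",
    "IntegratedVirusDiseaseNetwork",
    "CommonIspReport",
    "load_virus_ppi",
    "integrate_with_disease",
    "targets_plus_neighbors",
    "common_isps",
    "cluster_with_virus",
]

VIRUS_PPI_COLUMNS = ["viral_protein", "strain", "human_gene"]


@dataclass(frozen=True)
class VirusHostNetwork:
    """Deduplicated bipartite virus-host PPI network.

    Nodes carry ``side`` ("viral" or "human"); viral nodes carry their
    ``strain`` label.  Every edge joins one viral and one human node.
    """

    graph: nx.Graph
    strain_of: Mapping[str, str]

    @property
    def viral_proteins(self) -> frozenset[str]:
        return frozenset(n for n, d in self.graph.nodes(data="side") if d == "viral")

    @property
    def human_targets(self) -> frozenset[str]:
        return frozenset(n for n, d in self.graph.nodes(data="side") if d == "human")

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def strain_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for protein in self.viral_proteins:
            strain = self.strain_of[protein]
            counts[strain] = counts.get(strain, 0) + 1
        return dict(sorted(counts.items()))

    def summary(self) -> dict[str, int]:
        return {
            "viral_proteins": len(self.viral_proteins),
            "human_targets": len(self.human_targets),
            "total_nodes": self.graph.number_of_nodes(),
            "edges": self.n_edges,
        }


def load_virus_ppi(tables: pd.DataFrame | Sequence[pd.DataFrame]) -> VirusHostNetwork:
    """Merge virus-host PPI tables into one deduplicated bipartite network.

    Each table has columns ``viral_protein, strain, human_gene``.  Rows
    with a missing endpoint are rejected with a warning; duplicate
    edges (from either table) collapse; a viral protein seen with two
    different strain labels keeps the first and warns.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    graph = nx.Graph()
    strain_of: dict[str, str] = {}
    rejected = 0
    for table in tables:
        missing = set(VIRUS_PPI_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"virus PPI table missing columns: {sorted(missing)}")
        for row in table.itertuples(index=False):
            viral = str(row.viral_protein).strip()
            human = str(row.human_gene).strip().upper()
            if not viral or not human or viral.lower() == "nan" or human == "NAN":
                rejected += 1
                continue
            strain = str(row.strain).strip()
            if viral in strain_of and strain_of[viral] != strain:
                logger.warning(
                    "viral protein %s: conflicting strains %s / %s, keeping first",
                    viral,
                    strain_of[viral],
                    strain,
                )
            else:
                strain_of.setdefault(viral, strain)
            graph.add_node(viral, side="viral", strain=strain_of[viral])
            graph.add_node(human, side="human")
            graph.add_edge(viral, human)
    if rejected:
        logger.warning("rejected %d virus PPI rows with missing endpoints", rejected)
    net = VirusHostNetwork(graph=graph, strain_of=strain_of)
    logger.info("virus-host network: %s", net.summary())
    return net


@dataclass(frozen=True)
class IntegratedVirusDiseaseNetwork:
    """Virus-host network merged with one disease's genes and PPIs."""

    disease: str
    graph: nx.Graph
    direct_targets: frozenset[str]


def integrate_with_disease(
    virus: VirusHostNetwork, disease: DiseaseGeneSet
) -> IntegratedVirusDiseaseNetwork:
    """Union of the virus-host graph with disease gene nodes and PPIs."""
    graph = virus.graph.copy()
    for gene in disease.genes:
        if gene not in graph:
            graph.add_node(gene, side="human")
    for a, b, conf in disease.ppi_edges:
        graph.add_edge(a, b, confidence=conf)
    return IntegratedVirusDiseaseNetwork(
        disease=disease.name, graph=graph, direct_targets=virus.human_targets
    )


def targets_plus_neighbors(integrated: IntegratedVirusDiseaseNetwork) -> frozenset[str]:
    """Direct human targets plus their human first neighbours.

    Viral nodes never enter the result; in the absence of human-human
    edges the set equals the direct targets.
    """
    graph = integrated.graph
    out = set(integrated.direct_targets)
    for target in integrated.direct_targets:
        for nbr in graph.neighbors(target):
            if graph.nodes[nbr].get("side") == "human":
                out.add(nbr)
    return frozenset(out)


@dataclass(frozen=True)
class CommonIspReport:
    """Terms modulated by both the virus and the microbiota."""

    common_terms: frozenset[str]
    taxa_per_term: Mapping[str, tuple[str, ...]]

    @property
    def co_modulating_taxa(self) -> frozenset[str]:
        out: set[str] = set()
        for taxa in self.taxa_per_term.values():
            out |= set(taxa)
        return frozenset(out)


def common_isps(
    virus_result: EnrichmentResult,
    microbiota_result: EnrichmentResult,
    taxon_projection: Projection,
) -> CommonIspReport:
    """Intersect virus- and microbiota-significant terms.

    Both enrichments must share an annotation namespace.  For each
    common term the taxa whose term projection covers it are listed.
    """
    if virus_result.namespace != microbiota_result.namespace:
        raise ValueError(
            f"annotation namespace mismatch: {virus_result.namespace} vs "
            f"{microbiota_result.namespace}"
        )
    common = virus_result.significant_terms & microbiota_result.significant_terms
    taxa_per_term = {
        term: tuple(
            sorted(
                taxon
                for taxon, features in taxon_projection.mapping.items()
                if term in features
            )
        )
        for term in sorted(common)
    }
    return CommonIspReport(common_terms=frozenset(common), taxa_per_term=taxa_per_term)


def cluster_with_virus(
    taxon_projection: Projection,
    virus_terms: frozenset[str],
    k: int,
    virus_name: str = "VIRUS1",
) -> DendrogramResult:
    """Cluster taxa together with the virus over their common terms.

    Columns are the common terms (virus-significant terms that at least
    one taxon covers); taxa covering none are dropped; the virus enters
    as one extra all-ones row, so ``co_clustered(result, virus, taxon)``
    answers whether a taxon modulates the same common-term profile as
    the virus.
    """
    feature_union: set[str] = set()
    for features in taxon_projection.mapping.values():
        feature_union |= features
    common = sorted(virus_terms & feature_union)
    if not common:
        raise ValueError("no common terms between virus and taxon projection")
    taxa = [
        t
        for t in sorted(taxon_projection.mapping)
        if taxon_projection.mapping[t] & set(common)
    ]
    if k > len(taxa) + 1:
        raise ValueError(f"k={k} exceeds {len(taxa) + 1} entities")
    entities = taxa + [virus_name]
    values = np.zeros((len(entities), len(common)), dtype=bool)
    index = {term: j for j, term in enumerate(common)}
    for i, taxon in enumerate(taxa):
        for term in taxon_projection.mapping[taxon] & set(common):
            values[i, index[term]] = True
    values[-1, :] = True  # the common terms are exactly the virus's terms here
    matrix = IncidenceMatrix(
        entities=tuple(entities), features=tuple(common), values=values
    )
    # never request more clusters than distinct profiles: that would
    # arbitrarily split identical rows away from the virus
    n_distinct = len({tuple(row) for row in values})
    distances = jaccard_distance(matrix)
    return cluster(distances, entities, k=min(k, n_distinct))
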