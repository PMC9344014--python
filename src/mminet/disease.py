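"""Disease gene-set overlays on the microbiota-metabolite network.

For each disease, the top-N disease-associated genes (with intra-set
protein-protein interaction edges filtered at a confidence cutoff) are
intersected with the metabolite target genes.  Disease genes that are
also metabolite targets are *intersection nodes*; the subset annotated
to at least one significantly enriched disease term are *ISP-associated
intersection nodes*.  The overlay network (MMDI) keeps only metabolites
that target a disease gene and taxa that produce such a metabolite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from mminet.enrichment import EnrichmentResult
from mminet.layered import EdgeType, LayeredNetwork, NodeType

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseGeneSet",
    "MmdiNetwork",
    "CrossDiseaseComparison",
    "select_disease_genes",
    "build_mmdi",
    "compare_overlays",
]


@dataclass(frozen=True)
class DiseaseGeneSet:
    """Ranked disease-associated genes with filtered intra-set PPI edges."""

    name: str
    genes: tuple[str, ...]  # rank order, highest score first
    scores: Mapping[str, float]
    ppi_edges: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"disease {self.name!r}: duplicate genes in ranking")
        members = set(self.genes)
        for a, b, conf in self.ppi_edges:
            if not 0.0 <= conf <= 1.0:
                raise ValueError(f"PPI confidence {conf} outside [0, 1]")
            if a not in members or b not in members:
                raise ValueError(f"PPI edge ({a}, {b}) has an endpoint outside the set")


def select_disease_genes(
    name: str,
    scored: Sequence[tuple[str, float]],
    top_n: int,
    ppi_edges: Sequence[tuple[str, str, float]],
    confidence_cutoff: float = 0.8,
) -> DiseaseGeneSet:
    """Keep the ``top_n`` genes by score and the confident PPIs among them.

    Ties at the rank boundary are broken lexicographically (and logged).
    PPI edges survive when their confidence is at least the cutoff and
    both endpoints are retained; duplicates are canonicalized.
    """
    if len(scored) < top_n:
        raise ValueError(
            f"disease {name!r}: {len(scored)} scored genes < top_n={top_n}"
        )
    ordered = sorted(scored, key=lambda gs: (-gs[1], gs[0]))
    if len(ordered) > top_n and ordered[top_n - 1][1] == ordered[top_n][1]:
        logger.info(
            "disease %s: score tie at rank %d broken lexicographically", name, top_n
        )
    kept = ordered[:top_n]
    genes = tuple(g.upper() for g, _ in kept)
    scores = {g.upper(): float(s) for g, s in kept}
    members = set(genes)
    edges: dict[tuple[str, str], float] = {}
    for a, b, conf in ppi_edges:
        a, b = a.upper(), b.upper()
        if conf >= confidence_cutoff and a in members and b in members and a != b:
            key = (min(a, b), max(a, b))
            edges[key] = max(edges.get(key, 0.0), float(conf))
    return DiseaseGeneSet(
        name=name,
        genes=genes,
        scores=scores,
        ppi_edges=tuple((a, b, c) for (a, b), c in sorted(edges.items())),
    )


@dataclass(frozen=True)
class MmdiNetwork:
    """One disease's overlay network and its intersection accounting.

    ``isp_intersection_nodes`` is a subset of ``intersection_nodes``,
    which is a subset of the disease genes.  ``goisp_coverage`` is the
    set of disease terms reachable from ISP-associated intersection
    nodes (their pleiotropy footprint over ``disease_goisp_set``).
    """

    disease: str
    network: LayeredNetwork
    intersection_nodes: frozenset[str]
    isp_intersection_nodes: frozenset[str]
    disease_goisp_set: frozenset[str]
    goisp_coverage: frozenset[str]

    @property
    def taxa(self) -> frozenset[str]:
        return self.network.nodes_of_type(NodeType.TAXON)

    @property
    def metabolites(self) -> frozenset[str]:
        return self.network.nodes_of_type(NodeType.METABOLITE)

    @property
    def goisps(self) -> frozenset[str]:
        return self.network.nodes_of_type(NodeType.GOISP)

    def summary(self) -> dict[str, int]:
        counts = self.network.node_counts()
        return {
            "taxa": counts[NodeType.TAXON.value],
            "metabolites": counts[NodeType.METABOLITE.value],
            "intersection_nodes": len(self.intersection_nodes),
            "isp_intersection_nodes": len(self.isp_intersection_nodes),
            "disease_goisps": len(self.disease_goisp_set),
            "goisps_covered": len(self.goisp_coverage),
            "edges": self.network.edge_counts()["total"],
        }


def build_mmdi(
    disease: DiseaseGeneSet,
    gene_table: pd.DataFrame,
    taxon_metabolite: pd.DataFrame,
    disease_enrichment: EnrichmentResult,
) -> MmdiNetwork:
    """Overlay one disease gene set on the metabolite-target universe.

    Intersection nodes are disease genes targeted by at least one
    metabolite.  Metabolites are retained when they target a disease
    gene, and taxa when they keep at least one metabolite.  Gene-term
    edges come from the disease enrichment (significant terms only) and
    gene-gene edges are the disease set's filtered PPIs restricted to
    intersection nodes.  An empty intersection yields a valid empty
    overlay with a warning.
    """
    disease_genes = set(disease.genes)
    targets: dict[str, set[str]] = {}
    for row in gene_table.itertuples(index=False):
        targets.setdefault(row.metabolite_id, set()).add(row.gene_symbol)

    metabolite_hits = {
        m: genes & disease_genes for m, genes in targets.items() if genes & disease_genes
    }
    intersection = frozenset(set().union(*metabolite_hits.values()) if metabolite_hits else set())
    significant = disease_enrichment.significant_terms
    net = LayeredNetwork()
    if not intersection:
        logger.warning("disease %s: no intersection nodes, empty overlay", disease.name)
        return MmdiNetwork(
            disease=disease.name,
            network=net,
            intersection_nodes=frozenset(),
            isp_intersection_nodes=frozenset(),
            disease_goisp_set=frozenset(significant),
            goisp_coverage=frozenset(),
        )

    for gene in sorted(intersection):
        net.add_node(gene, NodeType.GENE)
    for metabolite in sorted(metabolite_hits):
        net.add_node(metabolite, NodeType.METABOLITE)
        for gene in sorted(metabolite_hits[metabolite]):
            net.add_edge(metabolite, gene, EdgeType.METABOLITE_GENE)

    surviving = set(metabolite_hits)
    for row in taxon_metabolite.sort_values(["taxon", "metabolite_id"]).itertuples(
        index=False
    ):
        if row.metabolite_id in surviving:
            net.add_node(row.taxon, NodeType.TAXON)
            net.add_edge(row.taxon, row.metabolite_id, EdgeType.TAXON_METABOLITE)

    # gene-term edges from the disease enrichment
    isp_nodes: set[str] = set()
    covered: set[str] = set()
    for term in sorted(significant):
        hit_genes = sorted(intersection & disease_enrichment.query_hits[term])
        if not hit_genes:
            continue
        net.add_node(term, NodeType.GOISP)
        covered.add(term)
        for gene in hit_genes:
            net.add_edge(gene, term, EdgeType.GENE_GOISP)
            isp_nodes.add(gene)

    for a, b, _ in disease.ppi_edges:
        if a in intersection and b in intersection:
            net.add_edge(a, b, EdgeType.GENE_GENE)

    return MmdiNetwork(
        disease=disease.name,
        network=net,
        intersection_nodes=intersection,
        isp_intersection_nodes=frozenset(isp_nodes),
        disease_goisp_set=frozenset(significant),
        goisp_coverage=frozenset(covered),
    )


@dataclass(frozen=True)
class CrossDiseaseComparison:
    """Entity-class intersections and pairwise overlaps across overlays."""

    diseases: tuple[str, ...]
    common: Mapping[str, frozenset[str]]  # per class: taxa/metabolites/goisps
    pairwise: Mapping[str, pd.DataFrame]

    def common_counts(self) -> dict[str, int]:
        return {cls: len(members) for cls, members in self.common.items()}


def compare_overlays(overlays: Sequence[MmdiNetwork]) -> CrossDiseaseComparison:
    """Intersections of taxa, metabolites and terms across disease overlays."""
    if len(overlays) < 2:
        raise ValueError("need at least 2 overlays to compare")
    names = [o.disease for o in overlays]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate disease names: {names}")

    classes = {
        "taxa": [o.taxa for o in overlays],
        "metabolites": [o.metabolites for o in overlays],
        "goisps": [o.goisps for o in overlays],
    }
    common = {
        cls: frozenset(set.intersection(*(set(s) for s in sets)))
        for cls, sets in classes.items()
    }
    pairwise = {}
    for cls, sets in classes.items():
        matrix = [
            [len(set(sets[i]) & set(sets[j])) for j in range(len(overlays))]
            for i in range(len(overlays))
        ]
        pairwise[cls] = pd.DataFrame(matrix, index=names, columns=names)
    return CrossDiseaseComparison(
        diseases=tuple(names), common=common, pairwise=pairwise
    )
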