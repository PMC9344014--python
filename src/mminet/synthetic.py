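"""Synthetic input universe with planted, recoverable structure.

The generator emits every input the pipeline consumes -- metabolite
records (as the XML dialect), taxon-metabolite and metabolite-gene
tables, GO ISP annotation in GMT form, scored disease gene sets with
intra-set PPIs, and a virus-host PPI table -- from a single seed, with
a ground-truth sidecar recording what was planted:

* **Taxon clusters** as a block model on the taxon-by-metabolite
  incidence: the metabolite pool is split into disjoint per-cluster
  core repertoires and every taxon carries its cluster's core, so at
  zero noise the within-cluster Jaccard distance is 0 and the
  between-cluster distance is 1, making the clustering stage's expected
  answer analytic.  Noise replaces each repertoire membership
  independently with probability ``noise_rate`` by a metabolite outside
  the repertoire.
* **One articulation taxon** carrying half of the cores of the first
  two clusters, so it is the only connection between two otherwise
  metabolite-disjoint taxon groups in the commonality graph.
* **Enriched terms**: ``n_enriched_terms`` annotation terms draw 90% of
  their genes from the realized metabolite-target gene set; the
  remaining terms draw uniformly from the gene universe and are
  therefore exactly null for the hypergeometric test.
* **Disease overlap**: a known fraction of each disease's genes comes
  from the metabolite-target set, fixing the expected intersection-node
  set of each disease overlay.
* **Viral targets** drawn partly from disease genes, with one virus
  whose proteins carry four strain labels.

Everything is deterministic given the seed; sets are materialized in
sorted order before any random draw or file write.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lxml import etree

from mminet.associations import GENE_TABLE_COLUMNS, TAXON_TABLE_COLUMNS, make_gene_table
from mminet.enrichment import Annotation, write_gmt
from mminet.hmdb import (
    Biofluid,
    Kingdom,
    MetaboliteRecord,
    SENTINEL_TAXA,
)
from mminet.virus import VIRUS_PPI_COLUMNS

__all__ = [
    "UniverseConfig",
    "UniverseBundle",
    "generate_universe",
    "write_hmdb_dialect_xml",
    "write_bundle",
]

_BIOFLUID_LABEL = {
    Biofluid.FECES: "Feces",
    Biofluid.SERUM: "Serum",
    Biofluid.CSF: "Cerebrospinal Fluid (CSF)",
}
_KINGDOM_LABEL = {Kingdom.BACTERIA: "Bacteria", Kingdom.FUNGI: "Fungi"}

VIRUS_STRAINS = ("STRAIN_A", "STRAIN_B", "STRAIN_C", "STRAIN_D")

#: Fraction of each planted term's genes drawn from the metabolite
#: target set (comfortably above the 80%-overlap recovery regime).
PLANTED_TERM_OVERLAP = 0.9


@dataclass(frozen=True)
class UniverseConfig:
    """Parameters of the synthetic input universe.

    Defaults describe a desk-scale universe: 60 taxa in 3 planted
    clusters over 90 metabolites (12 per repertoire), 300 genes of
    which 30% form the metabolite-target pool, 30 annotation terms with
    5 planted enriched, four diseases of 40 genes each with half their
    genes drawn from metabolite targets, and 20 viral proteins.
    """

    seed: int = 0
    n_taxa: int = 60
    n_metabolites: int = 90
    n_genes: int = 300
    n_terms: int = 30
    k_clusters: int = 3
    repertoire_size: int = 12
    noise_rate: float = 0.0
    term_size_range: tuple[int, int] = (6, 15)
    n_enriched_terms: int = 5
    n_diseases: int = 4
    disease_overlap_frac: float = 0.5
    n_disease_genes: int = 40
    virus_target_frac: float = 0.5
    n_viral_proteins: int = 20

    def __post_init__(self) -> None:
        for name in (
            "n_taxa",
            "n_metabolites",
            "n_genes",
            "n_terms",
            "k_clusters",
            "n_enriched_terms",
            "n_diseases",
            "n_disease_genes",
            "n_viral_proteins",
        ):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.repertoire_size < 2:
            raise ValueError(
                f"repertoire_size must be >= 2, got {self.repertoire_size}"
            )
        for name in ("noise_rate", "disease_overlap_frac", "virus_target_frac"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        if self.k_clusters > self.n_taxa:
            raise ValueError(
                f"k_clusters ({self.k_clusters}) must not exceed n_taxa ({self.n_taxa})"
            )
        lo, hi = self.term_size_range
        if not 1 <= lo <= hi <= self.n_genes:
            raise ValueError(
                f"term_size_range must satisfy 1 <= lo <= hi <= n_genes, got {self.term_size_range}"
            )
        if self.n_enriched_terms > self.n_terms:
            raise ValueError(
                f"n_enriched_terms ({self.n_enriched_terms}) must not exceed n_terms ({self.n_terms})"
            )
        if self.k_clusters * self.repertoire_size > self.n_metabolites:
            raise ValueError(
                "n_metabolites must be at least k_clusters * repertoire_size"
            )


@dataclass
class UniverseBundle:
    """All generated inputs plus the ground-truth sidecar."""

    config: UniverseConfig
    records: list[MetaboliteRecord]
    taxon_metabolite: pd.DataFrame
    gene_table: pd.DataFrame
    annotation: Annotation
    disease_gene_tables: dict[str, pd.DataFrame]
    disease_ppi_tables: dict[str, pd.DataFrame]
    virus_ppi: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)


def _taxon_name(i: int) -> str:
    genus = f"Genus{i:03d}"
    # mix genus-only and genus+species forms to exercise normalization
    return genus if i % 2 == 0 else f"{genus} species{i:03d}"


def generate_universe(config: UniverseConfig) -> UniverseBundle:
    """Generate a complete, internally consistent input universe.

    Fully deterministic given ``config.seed``; the ground-truth sidecar
    records planted cluster labels, the planted articulation taxon (if
    the configuration leaves room for one), planted enriched terms, the
    realized query genes and each disease's planted intersection genes.
    """
    rng = np.random.default_rng(config.seed)
    k, r = config.k_clusters, config.repertoire_size

    metabolite_ids = [f"M{i + 1:06d}" for i in range(config.n_metabolites)]
    cores = [metabolite_ids[c * r : (c + 1) * r] for c in range(k)]

    has_bridge = k >= 2 and config.n_taxa > k
    n_members = config.n_taxa - (1 if has_bridge else 0)
    taxa = [_taxon_name(i) for i in range(config.n_taxa)]
    members = taxa[:n_members]
    bridge = taxa[-1] if has_bridge else None

    cluster_labels = {
        taxon: int(i * k // n_members) for i, taxon in enumerate(members)
    }
    repertoires: dict[str, set[str]] = {
        taxon: set(cores[cluster_labels[taxon]]) for taxon in members
    }
    if bridge is not None:
        repertoires[bridge] = set(cores[0][: r // 2]) | set(cores[1][: r // 2])

    # independent membership noise: swap with a metabolite outside the set
    if config.noise_rate > 0:
        for taxon in taxa if bridge is not None else members:
            repertoire = repertoires[taxon]
            outside = sorted(set(metabolite_ids) - repertoire)
            swaps = []
            for metabolite in sorted(repertoire):
                if rng.random() < config.noise_rate:
                    swaps.append(metabolite)
            for metabolite in swaps:
                if not outside:
                    break
                pick = int(rng.integers(len(outside)))
                repertoire.discard(metabolite)
                repertoire.add(outside.pop(pick))

    taxon_kingdom = {
        taxon: Kingdom.FUNGI if rng.random() < 0.15 else Kingdom.BACTERIA
        for taxon in taxa
    }

    rows = []
    for taxon in taxa:
        for metabolite in sorted(repertoires[taxon]):
            rows.append((taxon, _KINGDOM_LABEL[taxon_kingdom[taxon]], metabolite))
    produced = {m for _, _, m in rows}
    for metabolite in metabolite_ids:
        if metabolite not in produced:
            kingdom = Kingdom.BACTERIA if rng.random() < 0.85 else Kingdom.FUNGI
            rows.append((SENTINEL_TAXA[kingdom], _KINGDOM_LABEL[kingdom], metabolite))
    taxon_metabolite = (
        pd.DataFrame(rows, columns=TAXON_TABLE_COLUMNS)
        .sort_values(TAXON_TABLE_COLUMNS)
        .reset_index(drop=True)
    )

    producers: dict[str, list[tuple[str, str]]] = {}
    for taxon, kingdom, metabolite in taxon_metabolite.itertuples(index=False):
        producers.setdefault(metabolite, []).append((taxon, kingdom))

    records = []
    for i, metabolite in enumerate(metabolite_ids):
        kingdoms = frozenset(
            Kingdom.BACTERIA if kng == "Bacteria" else Kingdom.FUNGI
            for _, kng in producers[metabolite]
        )
        taxa_names = frozenset(
            taxon
            for taxon, _ in producers[metabolite]
            if taxon not in SENTINEL_TAXA.values()
        )
        fluids = {
            fluid
            for fluid, p in (
                (Biofluid.FECES, 0.9),
                (Biofluid.SERUM, 0.7),
                (Biofluid.CSF, 0.35),
            )
            if rng.random() < p
        } or {Biofluid.FECES}
        records.append(
            MetaboliteRecord(
                metabolite_id=metabolite,
                name=f"metabolite-{i + 1:04d}",
                biofluids=frozenset(fluids),
                kingdoms=kingdoms,
                source_taxa=taxa_names,
            )
        )

    # metabolite-gene table over a restricted target pool
    genes = [f"G{i + 1:06d}" for i in range(config.n_genes)]
    pool = genes[: max(2, int(round(0.3 * config.n_genes)))]
    gene_rows = []
    covered = [m for m in metabolite_ids if rng.random() < 0.75]
    if not covered:
        covered = [metabolite_ids[0]]
    for metabolite in covered:
        n_g = int(rng.integers(2, min(7, len(pool) + 1)))
        for gene in rng.choice(pool, size=n_g, replace=False):
            evidence = "HMDB" if rng.random() < 0.5 else "STITCH"
            gene_rows.append((metabolite, gene, evidence))
    gene_table = make_gene_table(gene_rows)
    query = sorted(set(gene_table["gene_symbol"]))

    # annotation: planted terms overlap the query, the rest are null
    lo, hi = config.term_size_range
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    planted_terms = []
    non_query = sorted(set(genes) - set(query))
    for j in range(config.n_terms):
        term_id = f"TERM{j + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        if j < config.n_enriched_terms:
            n_from_query = min(max(1, math.ceil(PLANTED_TERM_OVERLAP * size)), len(query), size)
            chosen = list(rng.choice(query, size=n_from_query, replace=False))
            n_rest = min(size - n_from_query, len(non_query))
            if n_rest > 0:
                chosen += list(rng.choice(non_query, size=n_rest, replace=False))
            planted_terms.append(term_id)
        else:
            chosen = list(rng.choice(genes, size=min(size, len(genes)), replace=False))
        terms[term_id] = (f"immune process {j + 1}", frozenset(chosen))
    annotation = Annotation(terms=terms, universe=frozenset(genes))

    # disease gene sets with a planted metabolite-target overlap; overlap
    # genes are drawn from the planted terms' query genes first, so the
    # disease sets carry the immune-process signal they are meant to model
    disease_gene_tables: dict[str, pd.DataFrame] = {}
    disease_ppi_tables: dict[str, pd.DataFrame] = {}
    disease_intersection: dict[str, list[str]] = {}
    planted_pool = sorted(
        set(query) & {g for t in planted_terms for g in terms[t][1]}
    )
    n_overlap = int(round(config.disease_overlap_frac * config.n_disease_genes))
    n_overlap = min(n_overlap, len(query))
    for d in range(config.n_diseases):
        name = f"DISEASE_{d + 1:02d}"
        n_planted = min(n_overlap, len(planted_pool))
        overlap = list(rng.choice(planted_pool, size=n_planted, replace=False))
        extra_pool = sorted(set(query) - set(overlap))
        if n_overlap - n_planted > 0:
            overlap += list(
                rng.choice(extra_pool, size=n_overlap - n_planted, replace=False)
            )
        n_rest = config.n_disease_genes - n_overlap
        rest = list(rng.choice(non_query, size=min(n_rest, len(non_query)), replace=False))
        disease_genes = overlap + rest
        scores = np.sort(rng.uniform(0.5, 1.0, size=len(disease_genes)))[::-1]
        order = list(rng.permutation(len(disease_genes)))
        gene_score = pd.DataFrame(
            {
                "gene": [disease_genes[i] for i in order],
                "score": [float(scores[i]) for i in order],
            }
        )
        ppi_rows = []
        for _ in range(2 * config.n_disease_genes):
            a, b = rng.choice(disease_genes, size=2, replace=False)
            ppi_rows.append((a, b, float(rng.uniform(0.5, 1.0))))
        disease_gene_tables[name] = gene_score
        disease_ppi_tables[name] = pd.DataFrame(
            ppi_rows, columns=["gene_a", "gene_b", "confidence"]
        )
        disease_intersection[name] = sorted(overlap)

    # virus-host PPI table: one virus, four strain labels; the disease-
    # derived share of viral targets favours the immune-relevant (planted
    # term) disease genes, so the virus carries recoverable term signal
    disease_pool = sorted(
        {g for table in disease_gene_tables.values() for g in table["gene"]}
    )
    immune_pool = sorted(set(disease_pool) & set(planted_pool)) or disease_pool
    virus_rows = []
    for v in range(config.n_viral_proteins):
        protein = f"VP{v + 1:03d}"
        strain = VIRUS_STRAINS[v % len(VIRUS_STRAINS)]
        n_t = int(rng.integers(3, 11))
        for _ in range(n_t):
            if immune_pool and rng.random() < config.virus_target_frac:
                gene = str(rng.choice(immune_pool))
            else:
                gene = str(rng.choice(genes))
            virus_rows.append((protein, strain, gene))
    virus_ppi = (
        pd.DataFrame(virus_rows, columns=VIRUS_PPI_COLUMNS)
        .drop_duplicates()
        .reset_index(drop=True)
    )

    ground_truth = {
        "cluster_labels": {t: cluster_labels[t] for t in sorted(cluster_labels)},
        "articulation_taxon": bridge,
        "planted_terms": sorted(planted_terms),
        "metabolites_with_genes": sorted(covered),
        "query_genes": query,
        "disease_intersection": disease_intersection,
    }
    return UniverseBundle(
        config=config,
        records=records,
        taxon_metabolite=taxon_metabolite,
        gene_table=gene_table,
        annotation=annotation,
        disease_gene_tables=disease_gene_tables,
        disease_ppi_tables=disease_ppi_tables,
        virus_ppi=virus_ppi,
        ground_truth=ground_truth,
    )


def write_hmdb_dialect_xml(
    records: Sequence[MetaboliteRecord], path: str | Path
) -> None:
    """Serialize records to the XML dialect parsed by :mod:`mminet.hmdb`.

    The written file round-trips: parsing it reproduces the records'
    ids, names, biofluid sets, kingdom sets and source-taxon sets
    exactly.  Each kingdom is emitted once as a bare ``<source>`` so the
    kingdom set survives even when no taxon of that kingdom is named.
    """
    if not records:
        raise ValueError("records must be non-empty")
    root = etree.Element("metabolites")
    for rec in records:
        elem = etree.SubElement(root, "metabolite")
        etree.SubElement(elem, "accession").text = rec.metabolite_id
        etree.SubElement(elem, "name").text = rec.name
        locations = etree.SubElement(elem, "biospecimen_locations")
        for fluid in sorted(rec.biofluids, key=lambda f: f.value):
            etree.SubElement(locations, "biospecimen").text = _BIOFLUID_LABEL[fluid]
        disposition = etree.SubElement(elem, "biological_disposition")
        kingdoms = sorted(rec.kingdoms, key=lambda kng: kng.value)
        for kingdom in kingdoms:
            etree.SubElement(
                disposition, "source", kingdom=_KINGDOM_LABEL[kingdom]
            )
        for taxon in sorted(rec.source_taxa):
            src = etree.SubElement(
                disposition, "source", kingdom=_KINGDOM_LABEL[kingdoms[0]]
            )
            src.text = taxon
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def write_bundle(bundle: UniverseBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle artifact to ``outdir``; returns name -> path.

    Emits one XML export per biofluid (records are written in full, so
    merging the parsed exports reproduces the record set), the two
    association TSVs, the GMT annotation, per-disease gene and PPI
    TSVs, the virus PPI TSV and the ground-truth JSON sidecar.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for fluid, stem in (
        (Biofluid.FECES, "feces"),
        (Biofluid.SERUM, "serum"),
        (Biofluid.CSF, "csf"),
    ):
        subset = [r for r in bundle.records if fluid in r.biofluids]
        path = outdir / f"metabolites_{stem}.xml"
        if subset:
            write_hmdb_dialect_xml(subset, path)
        else:
            write_hmdb_dialect_xml(bundle.records[:1], path)  # degenerate fluid
        paths[f"xml_{stem}"] = path

    paths["taxon_metabolite"] = outdir / "taxon_metabolite.tsv"
    bundle.taxon_metabolite.to_csv(paths["taxon_metabolite"], sep="\t", index=False)
    paths["gene_table"] = outdir / "metabolite_gene.tsv"
    bundle.gene_table.to_csv(paths["gene_table"], sep="\t", index=False)
    paths["annotation"] = outdir / "annotation.gmt"
    write_gmt(bundle.annotation, paths["annotation"])
    paths["universe"] = outdir / "gene_universe.txt"
    paths["universe"].write_text(
        "\n".join(sorted(bundle.annotation.universe)) + "\n"
    )

    for name in sorted(bundle.disease_gene_tables):
        gpath = outdir / f"disease_{name}_genes.tsv"
        bundle.disease_gene_tables[name].to_csv(gpath, sep="\t", index=False)
        paths[f"disease_{name}_genes"] = gpath
        ppath = outdir / f"disease_{name}_ppi.tsv"
        bundle.disease_ppi_tables[name].to_csv(ppath, sep="\t", index=False)
        paths[f"disease_{name}_ppi"] = ppath

    paths["virus_ppi"] = outdir / "virus_ppi.tsv"
    bundle.virus_ppi.to_csv(paths["virus_ppi"], sep="\t", index=False)

    paths["ground_truth"] = outdir / "ground_truth.json"
    sidecar = dict(bundle.ground_truth)
    sidecar["config"] = asdict(bundle.config)
    paths["ground_truth"].write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
    return paths
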