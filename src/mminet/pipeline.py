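"""End-to-end pipeline orchestration with a reproducible run manifest.

``run_pipeline`` executes every stage in order -- simulate/load, parse,
associations, enrichment, MMI construction, projections + clustering,
commonality, per-disease overlays, virus integration, pairwise
rewiring -- writing each stage's outputs under the configured output
directory and recording a manifest of parameter values and per-file
SHA-256 checksums.  Rerunning an identical configuration reproduces
identical checksums: all randomness flows from the single seed and all
collections are materialized in sorted order before writing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from mminet import similarity as sim
from mminet.associations import coverage_summary, merge_gene_associations
from mminet.commonality import build_commonality, topology
from mminet.disease import build_mmdi, compare_overlays, select_disease_genes
from mminet.enrichment import (
    Annotation,
    hypergeometric_ora,
    kappa_group_terms,
    read_gmt,
)
from mminet.hmdb import (
    biofluid_overlap,
    merge_biofluid_collections,
    parse_metabolite_xml,
    partition_by_kingdom,
)
from mminet.layered import NodeType, build_mmi, project
from mminet.rewiring import rank_pairs
from mminet.synthetic import UniverseConfig, generate_universe, write_bundle
from mminet.virus import (
    cluster_with_virus,
    common_isps,
    integrate_with_disease,
    load_virus_ppi,
    targets_plus_neighbors,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

STAGES = (
    "inputs",
    "parse",
    "associations",
    "enrichment",
    "mmi",
    "similarity",
    "commonality",
    "mmdi",
    "virus",
    "rewiring",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Structured configuration for a full pipeline run.

    Either ``simulate`` embeds a :class:`UniverseConfig`, or ``inputs``
    supplies paths: ``xml`` (list of metabolite XML exports),
    ``taxon_metabolite``, ``gene_tables`` (list of TSVs), ``annotation``
    (GMT), ``diseases`` (name -> {genes, ppi} TSV paths) and
    ``virus_ppi``.
    """

    outdir: str
    simulate: UniverseConfig | None = None
    inputs: dict[str, Any] = field(default_factory=dict)
    alpha: float = 0.05
    kappa_threshold: float = 0.4
    linkage_methods: tuple[str, ...] = sim.DEFAULT_LINKAGE_METHODS
    k_taxa: int | None = None
    k_metabolites: int | None = None
    k_virus: int | None = None
    top_n: int = 10
    disease_top_n: int | None = None
    confidence_cutoff: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not -1 <= self.kappa_threshold <= 1:
            raise ValueError(
                f"kappa_threshold must lie in [-1, 1], got {self.kappa_threshold}"
            )
        if not 0 <= self.confidence_cutoff <= 1:
            raise ValueError(
                f"confidence_cutoff must lie in [0, 1], got {self.confidence_cutoff}"
            )
        if self.top_n < 1:
            raise ValueError(f"top_n must be >= 1, got {self.top_n}")
        if self.simulate is None:
            required = ("xml", "taxon_metabolite", "gene_tables", "annotation")
            for name in required:
                if name not in self.inputs:
                    raise ValueError(f"inputs missing required field: {name!r}")
        if self.simulate is None and self.k_taxa is None:
            raise ValueError("k_taxa is required when not simulating")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        simulate = raw.pop("simulate", None)
        if simulate is not None:
            if "term_size_range" in simulate:
                simulate["term_size_range"] = tuple(simulate["term_size_range"])
            simulate = UniverseConfig(**simulate)
        if "linkage_methods" in raw:
            raw["linkage_methods"] = tuple(raw["linkage_methods"])
        return cls(simulate=simulate, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload: Any) -> Path:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path

def _write_tsv(path: Path, frame: pd.DataFrame) -> Path:
    frame.to_csv(path, sep="\t", index=False)
    return path


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full pipeline and return the run manifest.

    Each stage writes its outputs under ``config.outdir``; the manifest
    (also written as ``manifest.json``) records the seed, parameter
    values and a SHA-256 checksum per output file.  Any stage failure
    raises :class:`PipelineError` naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage_files: dict[str, list[Path]] = {name: [] for name in STAGES}
    state: dict[str, Any] = {}

    def run_stage(name, fn):
        try:
            stage_files[name] = list(fn())
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    def stage_inputs():
        indir = out / "inputs"
        if config.simulate is not None:
            bundle = generate_universe(config.simulate)
            paths = write_bundle(bundle, indir)
            state["bundle"] = bundle
            state["xml_paths"] = [
                paths["xml_feces"], paths["xml_serum"], paths["xml_csf"]
            ]
            state["taxon_metabolite"] = bundle.taxon_metabolite
            state["gene_tables"] = [bundle.gene_table]
            state["annotation"] = bundle.annotation
            state["diseases_raw"] = {
                name: (bundle.disease_gene_tables[name], bundle.disease_ppi_tables[name])
                for name in sorted(bundle.disease_gene_tables)
            }
            state["virus_ppi"] = bundle.virus_ppi
            return paths.values()
        inputs = config.inputs
        state["xml_paths"] = [Path(p) for p in inputs["xml"]]
        state["taxon_metabolite"] = pd.read_csv(inputs["taxon_metabolite"], sep="\t")
        state["gene_tables"] = [
            pd.read_csv(p, sep="\t") for p in inputs["gene_tables"]
        ]
        annotation = read_gmt(inputs["annotation"])
        if inputs.get("universe"):
            universe = frozenset(
                line.strip().upper()
                for line in Path(inputs["universe"]).read_text().splitlines()
                if line.strip()
            )
            annotation = Annotation(
                terms=annotation.terms,
                universe=universe,
                namespace=annotation.namespace,
            )
        state["annotation"] = annotation
        state["diseases_raw"] = {
            name: (
                pd.read_csv(entry["genes"], sep="\t"),
                pd.read_csv(entry["ppi"], sep="\t"),
            )
            for name, entry in sorted(inputs.get("diseases", {}).items())
        }
        virus_path = inputs.get("virus_ppi")
        state["virus_ppi"] = (
            pd.read_csv(virus_path, sep="\t") if virus_path else None
        )
        return []

    def stage_parse():
        collections = [parse_metabolite_xml(str(p)) for p in state["xml_paths"]]
        while len(collections) < 3:
            collections.append([])
        records = merge_biofluid_collections(*collections[:3])
        state["records"] = records
        partition = partition_by_kingdom(records)
        payload = {
            "kingdom_partition": partition.to_dict(),
            "biofluid_overlap": {
                kingdom: biofluid_overlap(records, kingdom).to_dict()
                for kingdom in ("BACTERIA", "FUNGI")
            },
            "n_records": len(records),
        }
        return [_write_json(out / "hmdb_summary.json", payload)]

    def stage_associations():
        merged = merge_gene_associations(state["gene_tables"])
        state["gene_table"] = merged
        n_with, n_without = coverage_summary(state["records"], merged)
        return [
            _write_tsv(out / "metabolite_gene_merged.tsv", merged),
            _write_json(
                out / "associations_summary.json",
                {"with_associations": n_with, "without_associations": n_without,
                 "total": n_with + n_without, "pairs": len(merged)},
            ),
        ]

    def stage_enrichment():
        query = sorted(set(state["gene_table"]["gene_symbol"]))
        result = hypergeometric_ora(query, state["annotation"], alpha=config.alpha)
        grouping = kappa_group_terms(
            result, state["annotation"], kappa_threshold=config.kappa_threshold
        )
        state["enrichment"] = result
        state["grouping"] = grouping
        table = result.table.copy()
        assignment = grouping.assignment
        table["group"] = table["term_id"].map(lambda t: assignment.get(t, -1))
        groups_payload = [
            {
                "leading_term": g.leading_term,
                "terms": list(g.terms),
                "percent_of_terms": round(g.percent_of_terms, 2),
            }
            for g in grouping.groups
        ]
        return [
            _write_tsv(out / "enrichment.tsv", table),
            _write_json(out / "term_groups.json", groups_payload),
        ]

    def stage_mmi():
        net = build_mmi(
            state["taxon_metabolite"],
            state["gene_table"],
            state["enrichment"],
            state["grouping"],
        )
        state["mmi"] = net
        return [
            _write_tsv(out / "mmi_nodes.tsv", net.to_node_table()),
            _write_tsv(out / "mmi_edges.tsv", net.to_edge_table()),
            _write_json(
                out / "mmi_counts.json",
                {"nodes": net.node_counts(), "edges": net.edge_counts()},
            ),
        ]

    def stage_similarity():
        net = state["mmi"]
        k_default = config.simulate.k_clusters if config.simulate else None
        outputs = []
        for label, source, target, k in (
            ("taxa", NodeType.TAXON, NodeType.GOISP, config.k_taxa or k_default),
            (
                "metabolites",
                NodeType.METABOLITE,
                NodeType.GOISP,
                config.k_metabolites or config.k_taxa or k_default,
            ),
        ):
            projection = project(net, source, target)
            state[f"projection_{label}"] = projection
            if len(projection.mapping) < 2:
                logger.warning("similarity: <2 %s entities, skipping", label)
                continue
            matrix = sim.incidence_from_projection(projection)
            distances = sim.jaccard_distance(matrix)
            k_eff = min(k, len(matrix.entities))
            result = sim.cluster(
                distances, matrix.entities, methods=config.linkage_methods, k=k_eff
            )
            state[f"dendrogram_{label}"] = result
            outputs.append(
                _write_tsv(out / f"clusters_{label}.tsv", result.to_label_frame())
            )
            newick_path = out / f"dendrogram_{label}.nwk"
            newick_path.write_text(sim.to_newick(result) + "\n")
            outputs.append(newick_path)
            outputs.append(
                _write_json(
                    out / f"cophenetic_{label}.json",
                    {"selected": result.method,
                     "correlations": {m: (None if pd.isna(r) else round(r, 6))
                                      for m, r in result.cophenetic.items()}},
                )
            )
        state["projection_taxon_metabolite"] = project(
            net, NodeType.TAXON, NodeType.METABOLITE
        )
        return outputs

    def stage_commonality():
        projection = state["projection_taxon_metabolite"]
        if not projection.mapping:
            return [_write_json(out / "commonality_summary.json", {"nodes": 0})]
        graph = build_commonality(
            {t: set(fs) for t, fs in sorted(projection.mapping.items())}
        )
        report = topology(graph, top_n=config.top_n)
        state["commonality_report"] = report
        edges = pd.DataFrame(
            sorted((min(u, v), max(u, v), d) for u, v, d in graph.edges(data="weight")),
            columns=["taxon_a", "taxon_b", "shared_metabolites"],
        )
        return [
            _write_tsv(out / "commonality_edges.tsv", edges),
            _write_tsv(out / "commonality_topology.tsv", report.to_frame()),
            _write_json(
                out / "commonality_summary.json",
                {
                    "nodes": graph.number_of_nodes(),
                    "edges": graph.number_of_edges(),
                    "articulation_points": sorted(report.articulation_points),
                    "modules": len(set(report.modules.values())),
                },
            ),
        ]

    def stage_mmdi():
        overlays = {}
        outputs = []
        for name, (gene_score, ppi) in state["diseases_raw"].items():
            scored = list(zip(gene_score["gene"], gene_score["score"]))
            top_n = config.disease_top_n or len(scored)
            edges = list(
                zip(ppi["gene_a"], ppi["gene_b"], ppi["confidence"])
            )
            disease = select_disease_genes(
                name, scored, top_n, edges, config.confidence_cutoff
            )
            enr = hypergeometric_ora(
                disease.genes, state["annotation"], alpha=config.alpha
            )
            overlay = build_mmdi(
                disease, state["gene_table"], state["taxon_metabolite"], enr
            )
            overlays[name] = overlay
            outputs.append(
                _write_json(out / f"mmdi_{name}_summary.json", overlay.summary())
            )
            outputs.append(
                _write_tsv(out / f"mmdi_{name}_edges.tsv", overlay.network.to_edge_table())
            )
            state.setdefault("diseases", {})[name] = disease
        state["overlays"] = overlays
        if len(overlays) >= 2:
            comparison = compare_overlays(list(overlays.values()))
            outputs.append(
                _write_json(
                    out / "mmdi_comparison.json",
                    {
                        "common_counts": comparison.common_counts(),
                        "common": {
                            cls: sorted(members)
                            for cls, members in comparison.common.items()
                        },
                    },
                )
            )
        return outputs

    def stage_virus():
        table = state.get("virus_ppi")
        if table is None or not len(table):
            return [_write_json(out / "virus_summary.json", {"skipped": True})]
        virus_net = load_virus_ppi(table)
        virus_enr = hypergeometric_ora(
            virus_net.human_targets, state["annotation"], alpha=config.alpha
        )
        projection = state.get("projection_taxa")
        payload: dict[str, Any] = {
            "network": virus_net.summary(),
            "strain_counts": virus_net.strain_counts(),
            "significant_terms": sorted(virus_enr.significant_terms),
        }
        if projection is not None and projection.mapping:
            report = common_isps(virus_enr, state["enrichment"], projection)
            payload["common_isps"] = sorted(report.common_terms)
            payload["co_modulating_taxa"] = len(report.co_modulating_taxa)
            if report.common_terms:
                k_virus = config.k_virus or config.k_taxa or (
                    config.simulate.k_clusters if config.simulate else 2
                )
                n_entities = len(
                    [t for t in projection.mapping
                     if projection.mapping[t] & report.common_terms]
                ) + 1
                result = cluster_with_virus(
                    projection, report.common_terms, k=min(k_virus, n_entities)
                )
                virus_cluster = result.labels["VIRUS1"]
                payload["taxa_co_clustered_with_virus"] = sorted(
                    e for e, lab in result.labels.items()
                    if lab == virus_cluster and e != "VIRUS1"
                )
        neighbor_counts = {}
        for name, disease in state.get("diseases", {}).items():
            integrated = integrate_with_disease(virus_net, disease)
            neighbor_counts[name] = len(targets_plus_neighbors(integrated))
        payload["targets_plus_neighbors_per_disease"] = neighbor_counts
        return [_write_json(out / "virus_summary.json", payload)]

    def stage_rewiring():
        overlays = state.get("overlays", {})
        if len(overlays) < 2:
            return [_write_json(out / "rewiring.json", {"pairs": []})]
        table = rank_pairs({name: o.network for name, o in overlays.items()})
        return [
            _write_tsv(out / "rewiring_pairs.tsv", table),
            _write_json(
                out / "rewiring.json",
                {"pairs": table.to_dict(orient="records")},
            ),
        ]

    run_stage("inputs", stage_inputs)
    run_stage("parse", stage_parse)
    run_stage("associations", stage_associations)
    run_stage("enrichment", stage_enrichment)
    run_stage("mmi", stage_mmi)
    run_stage("similarity", stage_similarity)
    run_stage("commonality", stage_commonality)
    run_stage("mmdi", stage_mmdi)
    run_stage("virus", stage_virus)
    run_stage("rewiring", stage_rewiring)

    parameters = asdict(config)
    manifest = {
        "seed": config.simulate.seed if config.simulate else None,
        "parameters": parameters,
        "stages": {
            name: {Path(p).name: _sha256(Path(p)) for p in sorted(map(str, files))}
            for name, files in stage_files.items()
        },
    }
    _write_json(out / "manifest.json", manifest)
    return manifest
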