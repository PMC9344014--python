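"""Disease overlays, virus-microbiota common terms and pairwise rewiring.

Builds one overlay network per disease (intersection of disease genes
with metabolite targets), intersects virus-significant immune terms with
microbiota-modulated ones, clusters the virus jointly with taxa, and
ranks disease pairs by rewiring score.
"""

from mminet import (
    UniverseConfig,
    build_mmdi,
    build_mmi,
    cluster_with_virus,
    common_isps,
    compare_overlays,
    generate_universe,
    hypergeometric_ora,
    kappa_group_terms,
    load_virus_ppi,
    project,
    rank_pairs,
    select_disease_genes,
)
from mminet.layered import NodeType

bundle = generate_universe(UniverseConfig(seed=1))
micro_result = hypergeometric_ora(
    sorted(set(bundle.gene_table["gene_symbol"])), bundle.annotation
)
grouping = kappa_group_terms(micro_result, bundle.annotation)
mmi = build_mmi(bundle.taxon_metabolite, bundle.gene_table, micro_result, grouping)

overlays = {}
for name in sorted(bundle.disease_gene_tables):
    gene_score = bundle.disease_gene_tables[name]
    ppi = bundle.disease_ppi_tables[name]
    disease = select_disease_genes(
        name,
        list(zip(gene_score["gene"], gene_score["score"])),
        len(gene_score),
        list(zip(ppi["gene_a"], ppi["gene_b"], ppi["confidence"])),
        confidence_cutoff=0.8,
    )
    enr = hypergeometric_ora(disease.genes, bundle.annotation)
    overlay = build_mmdi(disease, bundle.gene_table, bundle.taxon_metabolite, enr)
    overlays[name] = overlay
    s = overlay.summary()
    print(
        f"{name}: {s['intersection_nodes']} intersection genes "
        f"({s['isp_intersection_nodes']} ISP-associated), {s['taxa']} taxa, "
        f"{s['metabolites']} metabolites"
    )

comparison = compare_overlays(list(overlays.values()))
print("common across all diseases:", comparison.common_counts())

virus_net = load_virus_ppi(bundle.virus_ppi)
virus_result = hypergeometric_ora(virus_net.human_targets, bundle.annotation)
taxon_terms = project(mmi, NodeType.TAXON, NodeType.GOISP)
report = common_isps(virus_result, micro_result, taxon_terms)
print(
    f"virus-microbiota common immune terms: {sorted(report.common_terms)} "
    f"co-modulated by {len(report.co_modulating_taxa)} taxa"
)
if report.common_terms:
    joint = cluster_with_virus(taxon_terms, report.common_terms, k=3)
    together = [
        t for t, lab in joint.labels.items()
        if lab == joint.labels["VIRUS1"] and t != "VIRUS1"
    ]
    print(f"taxa co-clustered with the virus: {len(together)}")

ranking = rank_pairs({name: o.network for name, o in overlays.items()})
print("disease pairs by rewiring score (1 = edge-disjoint overlays):")
print(ranking.to_string(index=False))
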