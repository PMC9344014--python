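"""Virus-host network loading, neighbor expansion and joint clustering."""

from __future__ import annotations

import pandas as pd
import pytest

from mminet.disease import DiseaseGeneSet
from mminet.enrichment import hypergeometric_ora
from mminet.layered import NodeType, Projection
from mminet.similarity import co_clustered
from mminet.virus import (
    cluster_with_virus,
    common_isps,
    integrate_with_disease,
    load_virus_ppi,
    targets_plus_neighbors,
)


def _ppi(rows):
    return pd.DataFrame(rows, columns=["viral_protein", "strain", "human_gene"])


class TestLoadVirusPpi:
    def test_duplicate_rows_collapse(self):
        net = load_virus_ppi(
            _ppi([("VP1", "S1", "G1"), ("VP1", "S1", "G1"), ("VP1", "S1", "G2")])
        )
        assert net.n_edges == 2

    def test_missing_endpoint_rejected(self, caplog):
        with caplog.at_level("WARNING"):
            net = load_virus_ppi(_ppi([("VP1", "S1", ""), ("VP2", "S1", "G1")]))
        assert net.summary()["edges"] == 1

    def test_counts_match_brute_force_recount(self, default_bundle):
        table = default_bundle.virus_ppi
        net = load_virus_ppi(table)
        assert net.summary()["viral_proteins"] == table["viral_protein"].nunique()
        assert net.summary()["human_targets"] == table["human_gene"].nunique()
        assert net.n_edges == len(
            table[["viral_protein", "human_gene"]].drop_duplicates()
        )
        expected_strains = (
            table.drop_duplicates("viral_protein")["strain"].value_counts().to_dict()
        )
        assert net.strain_counts() == dict(sorted(expected_strains.items()))

    def test_merging_two_tables_deduplicates(self, default_bundle):
        table = default_bundle.virus_ppi
        half = len(table) // 2
        merged = load_virus_ppi([table.iloc[:half], table])
        assert merged.n_edges == load_virus_ppi(table).n_edges


class TestTargetsPlusNeighbors:
    def _disease(self, genes, edges=()):
        return DiseaseGeneSet(
            name="X",
            genes=tuple(genes),
            scores={g: 1.0 for g in genes},
            ppi_edges=tuple(edges),
        )

    def test_no_disease_edges_gives_direct_targets_only(self):
        net = load_virus_ppi(_ppi([("VP1", "S1", "G1"), ("VP2", "S1", "G2")]))
        integrated = integrate_with_disease(net, self._disease(["G9"]))
        assert targets_plus_neighbors(integrated) == {"G1", "G2"}

    def test_star_of_disease_genes_around_target(self):
        net = load_virus_ppi(_ppi([("VP1", "S1", "G1")]))
        genes = ["G1", "G2", "G3", "G4"]
        edges = [("G1", g, 0.9) for g in genes[1:]]
        integrated = integrate_with_disease(net, self._disease(genes, edges))
        assert targets_plus_neighbors(integrated) == set(genes)

    def test_matches_one_step_bfs_oracle(self, default_bundle):
        name = sorted(default_bundle.disease_gene_tables)[0]
        gene_score = default_bundle.disease_gene_tables[name]
        ppi = default_bundle.disease_ppi_tables[name]
        genes = tuple(g.upper() for g in gene_score["gene"])
        edges = tuple(
            (str(a).upper(), str(b).upper(), float(c))
            for a, b, c in zip(ppi["gene_a"], ppi["gene_b"], ppi["confidence"])
            if a != b
        )
        disease = DiseaseGeneSet(
            name=name, genes=genes, scores={g: 1.0 for g in genes}, ppi_edges=edges
        )
        net = load_virus_ppi(default_bundle.virus_ppi)
        integrated = integrate_with_disease(net, disease)
        result = targets_plus_neighbors(integrated)

        graph = integrated.graph
        oracle = set(net.human_targets)
        for target in net.human_targets:
            for nbr in graph.neighbors(target):
                if graph.nodes[nbr].get("side") == "human":
                    oracle.add(nbr)
        assert result == oracle
        # adding edges never shrinks the set
        bare = integrate_with_disease(net, self._disease(["G000001"]))
        assert targets_plus_neighbors(bare) <= result | net.human_targets


class TestCommonIsps:
    def _result(self, query, annotation):
        return hypergeometric_ora(query, annotation)

    def test_identical_sets_all_common(self, default_bundle):
        query = sorted(set(default_bundle.gene_table["gene_symbol"]))
        result = self._result(query, default_bundle.annotation)
        projection = Projection(
            mapping={"Taxon a": frozenset(result.significant_terms)},
            source_type=NodeType.TAXON,
            target_type=NodeType.GOISP,
        )
        report = common_isps(result, result, projection)
        assert report.common_terms == result.significant_terms
        assert report.co_modulating_taxa == {"Taxon a"}

    def test_namespace_mismatch_raises(self, default_bundle):
        from dataclasses import replace

        query = sorted(set(default_bundle.gene_table["gene_symbol"]))
        result = self._result(query, default_bundle.annotation)
        other = replace(result, namespace="KEGG")
        projection = Projection(
            mapping={"Taxon a": frozenset({"TERM0001"})},
            source_type=NodeType.TAXON,
            target_type=NodeType.GOISP,
        )
        with pytest.raises(ValueError, match="namespace"):
            common_isps(result, other, projection)

    def test_taxa_lists_match_projection_recount(self, default_bundle):
        query = sorted(set(default_bundle.gene_table["gene_symbol"]))
        result = self._result(query, default_bundle.annotation)
        terms = sorted(result.significant_terms)
        projection = Projection(
            mapping={
                "Taxon a": frozenset(terms[:2]),
                "Taxon b": frozenset(terms[1:]),
            },
            source_type=NodeType.TAXON,
            target_type=NodeType.GOISP,
        )
        report = common_isps(result, result, projection)
        assert report.taxa_per_term[terms[1]] == ("Taxon a", "Taxon b")
        assert report.taxa_per_term[terms[0]] == ("Taxon a",)


class TestClusterWithVirus:
    def _projection(self, mapping):
        return Projection(
            mapping={k: frozenset(v) for k, v in mapping.items()},
            source_type=NodeType.TAXON,
            target_type=NodeType.GOISP,
        )

    def test_full_coverage_taxon_co_clusters_with_virus(self):
        terms = {"T1", "T2", "T3"}
        projection = self._projection(
            {"Full": terms, "Partial": {"T1"}, "Other": {"T2"}}
        )
        result = cluster_with_virus(projection, frozenset(terms), k=2)
        assert co_clustered(result, "Full", "VIRUS1")

    def test_zero_coverage_taxon_excluded(self):
        projection = self._projection({"Covers": {"T1"}, "Misses": {"T9"}})
        result = cluster_with_virus(projection, frozenset({"T1"}), k=2)
        assert "Misses" not in result.labels

    def test_three_full_coverage_taxa_share_virus_label(self):
        terms = {"T1", "T2"}
        mapping = {f"Full{i}": terms for i in range(3)}
        mapping["Weak"] = {"T1"}
        result = cluster_with_virus(self._projection(mapping), frozenset(terms), k=2)
        virus_label = result.labels["VIRUS1"]
        for i in range(3):
            assert result.labels[f"Full{i}"] == virus_label
        assert result.labels["Weak"] != virus_label

    def test_identical_profiles_never_split_from_virus(self):
        """When every taxon matches the virus profile, any requested k
        keeps them together (cut capped at distinct profiles)."""
        terms = {"T1", "T2"}
        mapping = {f"Full{i}": terms for i in range(4)}
        result = cluster_with_virus(self._projection(mapping), frozenset(terms), k=3)
        for i in range(4):
            assert co_clustered(result, f"Full{i}", "VIRUS1")

    def test_no_common_terms_raises(self):
        projection = self._projection({"A": {"T1"}})
        with pytest.raises(ValueError, match="no common terms"):
            cluster_with_virus(projection, frozenset({"T9"}), k=1)

    def test_k_too_large_raises(self):
        projection = self._projection({"A": {"T1"}})
        with pytest.raises(ValueError, match="exceeds"):
            cluster_with_virus(projection, frozenset({"T1"}), k=5)
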