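"""Shared fixtures: synthetic universes and small hand-built inputs."""

from __future__ import annotations

import pytest

from mminet import UniverseConfig, generate_universe
from mminet.hmdb import Biofluid, Kingdom, MetaboliteRecord


@pytest.fixture(scope="session")
def default_bundle():
    """A default-sized noiseless universe, shared read-only across tests."""
    return generate_universe(UniverseConfig(seed=11))


@pytest.fixture(scope="session")
def small_config():
    """A fast desk-scale configuration for repeated-simulation tests."""
    return dict(
        n_taxa=12,
        n_metabolites=24,
        n_genes=150,
        n_terms=20,
        k_clusters=2,
        repertoire_size=6,
        n_enriched_terms=4,
        n_diseases=2,
        n_disease_genes=20,
        n_viral_proteins=8,
    )


def make_record(
    metabolite_id: str,
    biofluids=(Biofluid.FECES,),
    kingdoms=(Kingdom.BACTERIA,),
    source_taxa=(),
    name: str | None = None,
) -> MetaboliteRecord:
    return MetaboliteRecord(
        metabolite_id=metabolite_id,
        name=name or f"compound {metabolite_id}",
        biofluids=frozenset(biofluids),
        kingdoms=frozenset(kingdoms),
        source_taxa=frozenset(source_taxa),
    )
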