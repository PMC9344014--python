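"""Metabolite-gene and taxon-metabolite association tables.

Tables are plain :class:`pandas.DataFrame` objects with fixed columns:

* metabolite-gene: ``metabolite_id``, ``gene_symbol``, ``evidence``
* taxon-metabolite: ``taxon``, ``kingdom``, ``metabolite_id``

Gene identity is the uppercased symbol string; no alias resolution is
attempted.  Merging is a pair-level set union: when the same
(metabolite, gene) pair arrives from several sources the evidence tags
are concatenated with ``+``.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from mminet.hmdb import MetaboliteRecord

logger = logging.getLogger(__name__)

GENE_TABLE_COLUMNS = ["metabolite_id", "gene_symbol", "evidence"]
TAXON_TABLE_COLUMNS = ["taxon", "kingdom", "metabolite_id"]

__all__ = [
    "GENE_TABLE_COLUMNS",
    "TAXON_TABLE_COLUMNS",
    "make_gene_table",
    "merge_gene_associations",
    "coverage_summary",
]


def make_gene_table(rows: Iterable[tuple[str, str, str]]) -> pd.DataFrame:
    """Build a validated metabolite-gene table from (id, gene, evidence) rows.

    Gene symbols are uppercased; rows with an empty gene symbol are
    rejected with a warning; duplicate (metabolite, gene) pairs collapse
    to one row with concatenated evidence.
    """
    clean: dict[tuple[str, str], list[str]] = {}
    for metabolite_id, gene, evidence in rows:
        gene = str(gene).strip().upper()
        if not gene:
            logger.warning("metabolite %s: empty gene symbol rejected", metabolite_id)
            continue
        tags = clean.setdefault((str(metabolite_id), gene), [])
        if evidence and evidence not in tags:
            tags.append(str(evidence))
    data = [
        (mid, gene, "+".join(tags) if tags else "")
        for (mid, gene), tags in sorted(clean.items())
    ]
    return pd.DataFrame(data, columns=GENE_TABLE_COLUMNS)


def merge_gene_associations(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Union metabolite-gene tables with pair-level deduplication.

    The operation is commutative, associative and idempotent on the set
    of (metabolite, gene) pairs.  Evidence tags for a pair seen in
    several tables are concatenated in first-seen order.
    """
    if not tables:
        return pd.DataFrame(columns=GENE_TABLE_COLUMNS)
    rows: list[tuple[str, str, str]] = []
    for table in tables:
        missing = set(GENE_TABLE_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        rows.extend(
            (r.metabolite_id, r.gene_symbol, r.evidence)
            for r in table.itertuples(index=False)
        )
    merged = make_gene_table(rows)
    n_raw = sum(len(t) for t in tables)
    logger.info("merged %d raw rows into %d unique pairs", n_raw, len(merged))
    return merged


def coverage_summary(
    records: Sequence[MetaboliteRecord], gene_table: pd.DataFrame
) -> tuple[int, int]:
    """Split metabolites into those with and without gene associations.

    Returns ``(n_with_associations, n_without)``; the two always sum to
    the number of records.
    """
    with_genes = set(gene_table["metabolite_id"]) if len(gene_table) else set()
    n_with = sum(1 for rec in records if rec.metabolite_id in with_genes)
    return n_with, len(records) - n_with
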