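"""Hypergeometric over-representation with BH control and kappa grouping.

The over-representation test asks, for each annotated term, whether the
query gene set hits the term's genes more often than a uniform draw of
the same size from the universe would: ``raw_p = P(X >= k)`` with ``X ~
Hypergeometric(N, K, n)`` for universe size ``N``, term size ``K`` and
query size ``n``.  P-values are corrected across terms with the
Benjamini-Hochberg step-up procedure and thresholded at ``alpha``.

Significant terms are then grouped by functional similarity: Cohen's
kappa is computed between every pair of significant terms on the 2x2
contingency of query-gene membership, pairs with kappa at or above the
threshold (default 0.4) are linked, and the connected components of the
resulting term graph form the groups.  Each group is labelled by its
leading term (smallest adjusted p; ties broken by larger term size,
then lexicographic term id) and reported with its percentage of all
significant terms.  This hard partition by components is a deliberate
simplification of iterative group-merging schemes used by interactive
enrichment tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "Annotation",
    "EnrichmentResult",
    "TermGroup",
    "TermGrouping",
    "read_gmt",
    "write_gmt",
    "hypergeometric_ora",
    "bh_adjust",
    "cohen_kappa_binary",
    "kappa_group_terms",
]


@dataclass(frozen=True)
class Annotation:
    """Term-to-gene-set annotation with an explicit gene universe.

    ``terms`` maps a term id to ``(term_name, frozenset of genes)``.  By
    default the universe is the union of all term gene sets (the
    annotation space); a larger explicit universe may be supplied.
    """

    terms: Mapping[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = field(default_factory=frozenset)
    namespace: str = "GO_ISP"

    def __post_init__(self) -> None:
        union: set[str] = set()
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {term_id!r} has an empty gene set")
            union |= genes
        universe = self.universe or frozenset(union)
        if not union <= universe:
            raise ValueError("annotation contains genes outside the supplied universe")
        object.__setattr__(self, "universe", frozenset(universe))

    def term_name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def genes(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]


def read_gmt(source: str | Path | IO[str], namespace: str = "GO_ISP") -> Annotation:
    """Read a GMT file (``term_id <tab> term_name <tab> gene ...``)."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line with fewer than 3 fields: {line!r}")
        term_id, name, *genes = parts
        terms[term_id] = (name, frozenset(g.upper() for g in genes if g))
    return Annotation(terms=terms, namespace=namespace)


def write_gmt(annotation: Annotation, path: str | Path) -> None:
    """Write annotation as GMT with sorted terms and genes."""
    with open(path, "w") as handle:
        for term_id in sorted(annotation.terms):
            name, genes = annotation.terms[term_id]
            handle.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term over-representation statistics.

    ``table`` has one row per term with columns ``term_id, term_name,
    k, K, n, N, raw_p, adjusted_p, significant``, sorted by adjusted p
    then term id.  ``query_hits`` maps each term to the query genes
    annotated to it (the overlap realizing ``k``).
    """

    table: pd.DataFrame
    alpha: float
    namespace: str
    query: frozenset[str]
    query_hits: Mapping[str, frozenset[str]]

    @property
    def significant_terms(self) -> frozenset[str]:
        mask = self.table["significant"]
        return frozenset(self.table.loc[mask, "term_id"])

    def adjusted_p(self, term_id: str) -> float:
        row = self.table.loc[self.table["term_id"] == term_id]
        if row.empty:
            raise KeyError(term_id)
        return float(row["adjusted_p"].iloc[0])


def bh_adjust(raw_p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    Every input must lie in (0, 1].
    """
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def hypergeometric_ora(
    query: Iterable[str],
    annotation: Annotation,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation of ``query`` per term.

    The query is first intersected with the annotation universe; an
    empty effective query or an empty annotation is an error.  Terms
    with zero overlap receive ``raw_p = 1``.
    """
    if not annotation.terms:
        raise ValueError("annotation has no terms")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    effective = frozenset(g.upper() for g in query) & annotation.universe
    if not effective:
        raise ValueError("query is empty after intersecting with the universe")

    N = len(annotation.universe)
    n = len(effective)
    rows = []
    hits: dict[str, frozenset[str]] = {}
    for term_id in sorted(annotation.terms):
        name, genes = annotation.terms[term_id]
        overlap = effective & genes
        k, K = len(overlap), len(genes)
        raw_p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, N, K, n))
        raw_p = min(max(raw_p, np.nextafter(0.0, 1.0)), 1.0)
        rows.append((term_id, name, k, K, n, N, raw_p))
        hits[term_id] = frozenset(overlap)
    table = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "raw_p"]
    )
    table["adjusted_p"] = bh_adjust(table["raw_p"].to_numpy())
    table["significant"] = table["adjusted_p"] <= alpha
    table = table.sort_values(["adjusted_p", "term_id"], kind="mergesort").reset_index(
        drop=True
    )
    return EnrichmentResult(
        table=table,
        alpha=alpha,
        namespace=annotation.namespace,
        query=effective,
        query_hits=hits,
    )


def cohen_kappa_binary(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's kappa for two binary membership vectors.

    When chance agreement is 1 (both vectors constant and identical)
    kappa is defined as 1.0.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("membership vectors must have equal length")
    m = a.size
    po = float(np.mean(a == b))
    pa1, pb1 = float(a.mean()), float(b.mean())
    pe = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if pe >= 1.0:
        return 1.0
    del m
    return (po - pe) / (1 - pe)


@dataclass(frozen=True)
class TermGroup:
    """One functional group of significant terms."""

    terms: tuple[str, ...]
    leading_term: str
    percent_of_terms: float


@dataclass(frozen=True)
class TermGrouping:
    """Partition of significant terms into kappa-linked groups.

    ``kappa_edges`` lists the term pairs whose kappa met the threshold,
    with the kappa value; these are also the term-term edges of the
    layered network.
    """

    groups: tuple[TermGroup, ...]
    kappa_edges: tuple[tuple[str, str, float], ...]
    kappa_threshold: float

    @property
    def assignment(self) -> dict[str, int]:
        return {
            term: i for i, group in enumerate(self.groups) for term in group.terms
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (i, group.leading_term, term, group.percent_of_terms)
            for i, group in enumerate(self.groups)
            for term in group.terms
        ]
        return pd.DataFrame(
            rows, columns=["group", "leading_term", "term_id", "percent_of_terms"]
        )


def kappa_group_terms(
    result: EnrichmentResult,
    annotation: Annotation,
    query: Iterable[str] | None = None,
    kappa_threshold: float = 0.4,
) -> TermGrouping:
    """Group significant terms by kappa agreement of query-gene membership.

    For each pair of significant terms a 2x2 contingency over the query
    genes (in term A / in term B) yields Cohen's kappa; pairs with kappa
    at or above the threshold are linked and connected components form
    the groups.
    """
    if not -1.0 <= kappa_threshold <= 1.0:
        raise ValueError(f"kappa threshold must lie in [-1, 1], got {kappa_threshold}")
    significant = sorted(result.significant_terms)
    if not significant:
        raise ValueError("no significant terms to group")
    query_genes = sorted(
        frozenset(g.upper() for g in query) & annotation.universe
        if query is not None
        else result.query
    )
    membership = {
        t: np.array([g in annotation.genes(t) for g in query_genes], dtype=bool)
        for t in significant
    }
    graph = nx.Graph()
    graph.add_nodes_from(significant)
    edges: list[tuple[str, str, float]] = []
    for i, a in enumerate(significant):
        for b in significant[i + 1 :]:
            kappa = cohen_kappa_binary(membership[a], membership[b])
            if kappa >= kappa_threshold:
                graph.add_edge(a, b)
                edges.append((a, b, kappa))

    adj = {t: result.adjusted_p(t) for t in significant}
    sizes = {t: len(annotation.genes(t)) for t in significant}
    groups = []
    for component in nx.connected_components(graph):
        terms = tuple(sorted(component))
        leading = min(terms, key=lambda t: (adj[t], -sizes[t], t))
        groups.append(
            TermGroup(
                terms=terms,
                leading_term=leading,
                percent_of_terms=100.0 * len(terms) / len(significant),
            )
        )
    groups.sort(key=lambda g: (-len(g.terms), g.leading_term))
    return TermGrouping(
        groups=tuple(groups),
        kappa_edges=tuple(edges),
        kappa_threshold=kappa_threshold,
    )
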