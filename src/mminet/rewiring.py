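"""Pairwise network rewiring: common and condition-specific nodes/edges.

Two condition-specific networks are compared by set algebra on node ids
and canonicalized undirected edges (sorted endpoint pair plus edge
type, ignoring other attributes).  The scalar rewiring score is the
Jaccard distance of the edge sets -- 0 for identical networks, 1 for
edge-disjoint ones -- this package's summary of how much wiring the two
conditions share, not any external tool's statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from mminet.layered import LayeredNetwork

__all__ = ["RewiringReport", "compare_networks", "rank_pairs"]

Edge = tuple[str, str, str]


def _edge_set(network: LayeredNetwork) -> set[Edge]:
    return {
        (*sorted((u, v)), d.value)
        for u, v, d in network.graph.edges(data="edge_type")
    }


@dataclass(frozen=True)
class RewiringReport:
    """Common / left-only / right-only node and edge classes with a score."""

    left_name: str
    right_name: str
    common_nodes: frozenset[str]
    left_only_nodes: frozenset[str]
    right_only_nodes: frozenset[str]
    common_edges: frozenset[Edge]
    left_only_edges: frozenset[Edge]
    right_only_edges: frozenset[Edge]
    rewiring_score: float

    def counts(self) -> dict[str, int]:
        return {
            "common_nodes": len(self.common_nodes),
            "left_only_nodes": len(self.left_only_nodes),
            "right_only_nodes": len(self.right_only_nodes),
            "common_edges": len(self.common_edges),
            "left_only_edges": len(self.left_only_edges),
            "right_only_edges": len(self.right_only_edges),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls, nodes in (
            ("common", self.common_nodes),
            ("left_only", self.left_only_nodes),
            ("right_only", self.right_only_nodes),
        ):
            rows.extend(("node", n, cls) for n in sorted(nodes))
        for cls, edges in (
            ("common", self.common_edges),
            ("left_only", self.left_only_edges),
            ("right_only", self.right_only_edges),
        ):
            rows.extend(("edge", f"{u}|{v}|{t}", cls) for u, v, t in sorted(edges))
        return pd.DataFrame(rows, columns=["kind", "id", "class"])


def compare_networks(
    left: LayeredNetwork,
    right: LayeredNetwork,
    left_name: str = "left",
    right_name: str = "right",
) -> RewiringReport:
    """Classify nodes and edges as common or condition-specific.

    ``rewiring_score = 1 - |common edges| / |edge union|`` (0 when both
    edge sets are empty).  Swapping the arguments swaps the left/right
    classes and preserves the score.
    """
    left_nodes = set(left.graph.nodes)
    right_nodes = set(right.graph.nodes)
    left_edges = _edge_set(left)
    right_edges = _edge_set(right)
    union = left_edges | right_edges
    common = left_edges & right_edges
    score = 0.0 if not union else 1.0 - len(common) / len(union)
    return RewiringReport(
        left_name=left_name,
        right_name=right_name,
        common_nodes=frozenset(left_nodes & right_nodes),
        left_only_nodes=frozenset(left_nodes - right_nodes),
        right_only_nodes=frozenset(right_nodes - left_nodes),
        common_edges=frozenset(common),
        left_only_edges=frozenset(left_edges - right_edges),
        right_only_edges=frozenset(right_edges - left_edges),
        rewiring_score=score,
    )


def rank_pairs(
    networks: Mapping[str, LayeredNetwork] | Sequence[tuple[str, LayeredNetwork]],
) -> pd.DataFrame:
    """Score every unordered pair, sorted by descending rewiring.

    Ties are broken by the (lexicographically ordered) name pair.
    """
    items = list(networks.items()) if isinstance(networks, Mapping) else list(networks)
    names = [name for name, _ in items]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate network names: {names}")
    if len(items) < 2:
        raise ValueError("need at least 2 networks to rank")
    rows = []
    for (name_a, net_a), (name_b, net_b) in combinations(sorted(items), 2):
        report = compare_networks(net_a, net_b, name_a, name_b)
        rows.append((name_a, name_b, report.rewiring_score))
    frame = pd.DataFrame(rows, columns=["network_a", "network_b", "rewiring_score"])
    return frame.sort_values(
        ["rewiring_score", "network_a", "network_b"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
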