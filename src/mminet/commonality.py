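"""Shared-item commonality graphs with degree, strength and articulation points.

Two entities (taxa) are joined by an edge when their item sets
(metabolite repertoires) intersect; the edge weight is the number of
shared items.  The topology report gives per-node degree and strength
(sum of incident weights), connected-component module membership,
articulation points (nodes whose removal disconnects their module,
found in linear time via biconnected components), and deterministic
top-N rankings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Set

import networkx as nx
import pandas as pd

__all__ = ["CommonalityGraph", "TopologyReport", "build_commonality", "topology"]

#: A commonality graph is a plain undirected weighted networkx graph
#: with integer ``weight`` edge attributes.
CommonalityGraph = nx.Graph


def build_commonality(
    entity_items: Mapping[str, Set[str]],
    min_shared: int = 1,
) -> nx.Graph:
    """Weighted entity-entity graph from pairwise item-set intersections.

    Edge (a, b) exists when the two entities share at least
    ``min_shared`` items, weighted by the intersection size.  Entities
    sharing nothing are kept as isolated (degree-0) nodes.
    """
    if not entity_items:
        raise ValueError("entity_items must be non-empty")
    if min_shared < 1:
        raise ValueError(f"min_shared must be >= 1, got {min_shared}")
    for entity, items in entity_items.items():
        if not items:
            raise ValueError(f"entity {entity!r} has an empty item set")
    graph = nx.Graph()
    names = sorted(entity_items)
    graph.add_nodes_from(names)
    for i, a in enumerate(names):
        items_a = entity_items[a]
        for b in names[i + 1 :]:
            shared = len(items_a & entity_items[b])
            if shared >= min_shared:
                graph.add_edge(a, b, weight=shared)
    return graph


@dataclass(frozen=True)
class TopologyReport:
    """Degree/strength centralities, modules and articulation points."""

    degree: Mapping[str, int]
    strength: Mapping[str, int]
    articulation_points: frozenset[str]
    modules: Mapping[str, int]
    top_degree: tuple[tuple[str, int], ...]
    top_strength: tuple[tuple[str, int], ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                node,
                self.degree[node],
                self.strength[node],
                node in self.articulation_points,
                self.modules[node],
            )
            for node in sorted(self.degree)
        ]
        return pd.DataFrame(
            rows, columns=["node", "degree", "strength", "is_articulation", "module"]
        )


def topology(graph: nx.Graph, top_n: int = 10) -> TopologyReport:
    """Topological summary of a commonality graph.

    Modules are connected components, numbered by decreasing size then
    by smallest member name; rankings break ties by higher value then
    lexicographic node name.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    degree = {n: int(d) for n, d in graph.degree()}
    strength = {n: int(s) for n, s in graph.degree(weight="weight")}
    articulation = frozenset(nx.articulation_points(graph))
    components = sorted(
        (set(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), min(c)),
    )
    modules = {node: i for i, comp in enumerate(components) for node in comp}

    def ranked(values: Mapping[str, int]) -> tuple[tuple[str, int], ...]:
        order = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
        return tuple(order[:top_n])

    return TopologyReport(
        degree=degree,
        strength=strength,
        articulation_points=articulation,
        modules=modules,
        top_degree=ranked(degree),
        top_strength=ranked(strength),
    )
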