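"""Jaccard-distance agglomerative clustering with cophenetic validation.

Entities (taxa or metabolites) are described by binary feature profiles
over GO ISP terms or metabolites; the Jaccard distance ``1 - |A&B|/|A|B|``
between profiles feeds agglomerative hierarchical clustering.  Several
candidate linkage methods are fitted and the one whose cophenetic
distances correlate best (Pearson) with the input distances is selected,
the standard validity check for a linkage choice.  Trees are cut either
to an exact number of clusters ``k`` or at a merge-height threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, cut_tree, fcluster, linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from mminet.layered import Projection

__all__ = [
    "IncidenceMatrix",
    "DendrogramResult",
    "incidence_from_projection",
    "jaccard_distance",
    "cluster",
    "co_clustered",
    "to_newick",
]

DEFAULT_LINKAGE_METHODS = ("average", "complete", "single", "ward")


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary entity-by-feature membership matrix with ordered labels."""

    entities: tuple[str, ...]
    features: tuple[str, ...]
    values: np.ndarray  # bool, shape (n_entities, n_features)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=bool)
        if values.shape != (len(self.entities), len(self.features)):
            raise ValueError("matrix shape does not match label lengths")
        if len(set(self.entities)) != len(self.entities):
            raise ValueError("entity labels must be unique")
        if len(set(self.features)) != len(self.features):
            raise ValueError("feature labels must be unique")
        if values.size and not values.any(axis=1).all():
            zero = [e for e, row in zip(self.entities, values) if not row.any()]
            raise ValueError(f"all-zero rows not allowed: {zero[:5]}")
        object.__setattr__(self, "values", values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.astype(int), index=list(self.entities), columns=list(self.features)
        )


def incidence_from_projection(projection: Projection) -> IncidenceMatrix:
    """Binary matrix with sorted entity rows and sorted feature columns."""
    if not projection.mapping:
        raise ValueError("projection is empty")
    entities = tuple(projection.entities)
    features = tuple(projection.features)
    index = {f: j for j, f in enumerate(features)}
    values = np.zeros((len(entities), len(features)), dtype=bool)
    for i, entity in enumerate(entities):
        for feature in projection.mapping[entity]:
            values[i, index[feature]] = True
    return IncidenceMatrix(entities=entities, features=features, values=values)


def jaccard_distance(matrix: IncidenceMatrix) -> np.ndarray:
    """Symmetric pairwise Jaccard distance matrix of the entity rows."""
    if len(matrix.entities) < 2:
        raise ValueError("need at least 2 entities for pairwise distances")
    condensed = pdist(matrix.values, metric="jaccard")
    return squareform(condensed)


@dataclass(frozen=True)
class DendrogramResult:
    """Agglomerative tree with the validated linkage and cut labels."""

    entities: tuple[str, ...]
    linkage_matrix: np.ndarray
    method: str
    cophenetic: Mapping[str, float]
    labels: Mapping[str, int]
    k: int

    def to_label_frame(self) -> pd.DataFrame:
        rows = sorted(self.labels.items())
        return pd.DataFrame(rows, columns=["entity", "cluster"])


def cluster(
    distances: np.ndarray,
    entities: Sequence[str],
    methods: Sequence[str] = DEFAULT_LINKAGE_METHODS,
    k: int | None = None,
    height: float | None = None,
) -> DendrogramResult:
    """Agglomerative clustering with cophenetic linkage selection.

    Each candidate linkage method is fitted; the Pearson correlation
    between its cophenetic distances and the input distances is computed
    and the best-correlated method wins (ties broken by candidate
    order).  The selected tree is cut to exactly ``k`` clusters, or at
    ``height`` when given instead.
    """
    distances = np.asarray(distances, dtype=float)
    n = distances.shape[0]
    if distances.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if len(entities) != n:
        raise ValueError("entity labels must match the distance matrix")
    if k is None and height is None:
        raise ValueError("either k or height must be given")
    if k is not None and not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    if not methods:
        raise ValueError("at least one linkage method required")

    condensed = squareform(distances, checks=False)
    trees: dict[str, np.ndarray] = {}
    correlations: dict[str, float] = {}
    for method in methods:
        Z = linkage(condensed, method=method)
        with np.errstate(invalid="ignore"):
            r, _ = cophenet(Z, condensed)
        trees[method] = Z
        correlations[method] = float(r)

    # ties (and NaN from constant distances) resolved by candidate order
    best = max(
        methods,
        key=lambda m: (np.nan_to_num(correlations[m], nan=-np.inf),
                       -list(methods).index(m)),
    )
    Z = trees[best]
    if k is not None:
        flat = cut_tree(Z, n_clusters=k).ravel() + 1
    else:
        flat = fcluster(Z, t=height, criterion="distance")
    labels = {entity: int(label) for entity, label in zip(entities, flat)}
    return DendrogramResult(
        entities=tuple(entities),
        linkage_matrix=Z,
        method=best,
        cophenetic=correlations,
        labels=labels,
        k=int(len(set(flat))),
    )


def co_clustered(result: DendrogramResult, entity_a: str, entity_b: str) -> bool:
    """True when the two entities share a cut label."""
    for entity in (entity_a, entity_b):
        if entity not in result.labels:
            raise KeyError(f"unknown entity {entity!r}")
    return result.labels[entity_a] == result.labels[entity_b]


def to_newick(result: DendrogramResult) -> str:
    """Newick serialization of the dendrogram with branch lengths."""
    tree = to_tree(result.linkage_matrix)
    names = result.entities

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
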