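"""Jaccard distances, UPGMA heights, cophenetic selection and cut labels."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from mminet.layered import NodeType, Projection
from mminet.similarity import (
    IncidenceMatrix,
    cluster,
    co_clustered,
    incidence_from_projection,
    jaccard_distance,
    to_newick,
)


def _matrix(rows: dict[str, set[str]]) -> IncidenceMatrix:
    projection = Projection(
        mapping={k: frozenset(v) for k, v in rows.items()},
        source_type=NodeType.TAXON,
        target_type=NodeType.GOISP,
    )
    return incidence_from_projection(projection)


class TestIncidence:
    def test_disjoint_single_features_give_identity_pattern(self):
        matrix = _matrix({"a": {"f1"}, "b": {"f2"}})
        assert matrix.to_frame().to_numpy().tolist() == [[1, 0], [0, 1]]

    def test_full_row(self):
        matrix = _matrix({"a": {"f1", "f2", "f3"}, "b": {"f1"}})
        assert matrix.to_frame().loc["a"].tolist() == [1, 1, 1]

    def test_matches_membership_recount(self, default_bundle):
        from mminet.enrichment import hypergeometric_ora, kappa_group_terms
        from mminet.layered import build_mmi, project

        result = hypergeometric_ora(
            sorted(set(default_bundle.gene_table["gene_symbol"])),
            default_bundle.annotation,
        )
        grouping = kappa_group_terms(result, default_bundle.annotation)
        net = build_mmi(
            default_bundle.taxon_metabolite, default_bundle.gene_table, result, grouping
        )
        projection = project(net, NodeType.TAXON, NodeType.GOISP)
        matrix = incidence_from_projection(projection)
        frame = matrix.to_frame()
        for entity in matrix.entities:
            for feature in matrix.features:
                assert frame.loc[entity, feature] == (
                    feature in projection.mapping[entity]
                )

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            IncidenceMatrix(
                entities=("a",), features=("f",), values=np.array([[False]])
            )


class TestJaccard:
    def test_identical_rows_distance_zero(self):
        matrix = _matrix({"a": {"x", "y"}, "b": {"x", "y"}})
        assert jaccard_distance(matrix)[0, 1] == 0.0

    def test_partial_overlap_two_thirds(self):
        matrix = _matrix({"a": {"x", "y"}, "b": {"y", "z"}})
        assert jaccard_distance(matrix)[0, 1] == pytest.approx(2 / 3)

    def test_disjoint_rows_distance_one(self):
        matrix = _matrix({"a": {"x"}, "b": {"z"}})
        assert jaccard_distance(matrix)[0, 1] == 1.0

    def test_single_row_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            jaccard_distance(_matrix({"a": {"x"}}))

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_triangle_inequality_on_random_binary_matrices(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.random((6, 8)) < 0.5
        values[~values.any(axis=1), 0] = True  # no all-zero rows
        matrix = IncidenceMatrix(
            entities=tuple(f"e{i}" for i in range(6)),
            features=tuple(f"f{j}" for j in range(8)),
            values=values,
        )
        d = jaccard_distance(matrix)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestCluster:
    def test_two_entities_single_merge(self):
        matrix = _matrix({"a": {"x"}, "b": {"z"}})
        result = cluster(jaccard_distance(matrix), matrix.entities, k=2)
        assert result.labels["a"] != result.labels["b"]
        assert result.method == "average"  # ties broken by candidate order

    def test_average_linkage_heights_match_hand_upgma(self):
        """5-point fixture: merge heights 0.1, 0.3, 0.5, 0.9 by hand."""
        labels = ["a", "b", "c", "d", "e"]
        D = np.zeros((5, 5))
        pairs = {
            ("a", "b"): 0.1,
            ("a", "c"): 0.4,
            ("b", "c"): 0.6,
            ("a", "d"): 0.8,
            ("b", "d"): 0.8,
            ("c", "d"): 0.8,
            ("a", "e"): 1.0,
            ("b", "e"): 1.0,
            ("c", "e"): 1.0,
            ("d", "e"): 0.3,
        }
        for (x, y), v in pairs.items():
            i, j = labels.index(x), labels.index(y)
            D[i, j] = D[j, i] = v
        result = cluster(D, labels, methods=("average",), k=2)
        heights = sorted(result.linkage_matrix[:, 2])
        # by hand: ab at 0.1; de at 0.3; ab+c at (0.4+0.6)/2=0.5;
        # abc+de at mean of 6 cross distances = (0.8*3 + 1.0*3)/6 = 0.9
        assert heights == pytest.approx([0.1, 0.3, 0.5, 0.9])

    def test_planted_blocks_recovered_exactly(self, default_bundle):
        table = default_bundle.taxon_metabolite
        gt = default_bundle.ground_truth["cluster_labels"]
        items: dict[str, set[str]] = {}
        for row in table.itertuples(index=False):
            if not row.taxon.startswith("Unnamed"):
                items.setdefault(row.taxon, set()).add(row.metabolite_id)
        matrix = _matrix(items)
        result = cluster(
            jaccard_distance(matrix),
            matrix.entities,
            k=default_bundle.config.k_clusters,
        )
        taxa = sorted(gt)
        ari = adjusted_rand_score(
            [gt[t] for t in taxa], [result.labels[t] for t in taxa]
        )
        assert ari == 1.0

    def test_k_larger_than_n_raises(self):
        matrix = _matrix({"a": {"x"}, "b": {"z"}})
        with pytest.raises(ValueError, match="k must lie"):
            cluster(jaccard_distance(matrix), matrix.entities, k=5)

    def test_cophenetic_reported_for_every_candidate(self):
        rng = np.random.default_rng(2)
        values = rng.random((8, 10)) < 0.4
        values[~values.any(axis=1), 0] = True
        matrix = IncidenceMatrix(
            entities=tuple(f"e{i}" for i in range(8)),
            features=tuple(f"f{j}" for j in range(10)),
            values=values,
        )
        result = cluster(jaccard_distance(matrix), matrix.entities, k=3)
        assert set(result.cophenetic) == {"average", "complete", "single", "ward"}
        best = max(
            result.cophenetic.values(),
            key=lambda r: -np.inf if np.isnan(r) else r,
        )
        assert result.cophenetic[result.method] == best


class TestCoClustered:
    def test_entity_with_itself(self):
        matrix = _matrix({"a": {"x"}, "b": {"z"}})
        result = cluster(jaccard_distance(matrix), matrix.entities, k=2)
        assert co_clustered(result, "a", "a")

    def test_k_one_all_together(self):
        matrix = _matrix({"a": {"x"}, "b": {"z"}, "c": {"y"}})
        result = cluster(jaccard_distance(matrix), matrix.entities, k=1)
        assert co_clustered(result, "a", "b") and co_clustered(result, "b", "c")

    def test_different_planted_blocks_not_co_clustered(self, default_bundle):
        gt = default_bundle.ground_truth["cluster_labels"]
        by_block: dict[int, str] = {}
        for taxon, block in sorted(gt.items()):
            by_block.setdefault(block, taxon)
        items: dict[str, set[str]] = {}
        for row in default_bundle.taxon_metabolite.itertuples(index=False):
            if not row.taxon.startswith("Unnamed"):
                items.setdefault(row.taxon, set()).add(row.metabolite_id)
        matrix = _matrix(items)
        result = cluster(
            jaccard_distance(matrix), matrix.entities, k=default_bundle.config.k_clusters
        )
        reps = list(by_block.values())
        assert not co_clustered(result, reps[0], reps[1])

    def test_unknown_entity_raises(self):
        matrix = _matrix({"a": {"x"}, "b": {"z"}})
        result = cluster(jaccard_distance(matrix), matrix.entities, k=2)
        with pytest.raises(KeyError):
            co_clustered(result, "a", "nope")


def test_identical_rows_always_co_cluster():
    """Entities with identical profiles share a label at every k < n."""
    matrix = _matrix(
        {"a": {"x", "y"}, "b": {"x", "y"}, "c": {"z"}, "d": {"w"}, "e": {"x", "w"}}
    )
    d = jaccard_distance(matrix)
    for k in range(1, 5):
        result = cluster(d, matrix.entities, k=k)
        assert co_clustered(result, "a", "b")


def test_newick_contains_all_leaves():
    matrix = _matrix({"a": {"x"}, "b": {"x", "y"}, "c": {"z"}})
    result = cluster(jaccard_distance(matrix), matrix.entities, k=2)
    newick = to_newick(result)
    assert newick.endswith(";")
    for leaf in matrix.entities:
        assert leaf in newick


def test_row_permutation_equivariance():
    """Permuting entity order permutes labels consistently."""
    rows = {"a": {"x", "y"}, "b": {"x"}, "c": {"z", "w"}, "d": {"z"}}
    m1 = _matrix(rows)
    result1 = cluster(jaccard_distance(m1), m1.entities, k=2)
    # reversed insertion order; incidence sorts entities, so same result
    m2 = _matrix(dict(reversed(list(rows.items()))))
    result2 = cluster(jaccard_distance(m2), m2.entities, k=2)
    partition1 = {frozenset(e for e in rows if result1.labels[e] == lab)
                  for lab in set(result1.labels.values())}
    partition2 = {frozenset(e for e in rows if result2.labels[e] == lab)
                  for lab in set(result2.labels.values())}
    assert partition1 == partition2
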