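"""Jaccard-distance clustering of taxa with cophenetic linkage validation.

Clusters taxa by their metabolite repertoires, validates the linkage
method via cophenetic correlation and compares the cut labels with the
generator's planted cluster assignment (adjusted Rand index).
"""

from sklearn.metrics import adjusted_rand_score

from mminet import (
    UniverseConfig,
    cluster,
    generate_universe,
    incidence_from_projection,
    jaccard_distance,
)
from mminet.layered import NodeType, Projection

bundle = generate_universe(UniverseConfig(seed=1, noise_rate=0.05))
items: dict[str, set[str]] = {}
for row in bundle.taxon_metabolite.itertuples(index=False):
    if not row.taxon.startswith("Unnamed"):
        items.setdefault(row.taxon, set()).add(row.metabolite_id)

projection = Projection(
    mapping={t: frozenset(s) for t, s in items.items()},
    source_type=NodeType.TAXON,
    target_type=NodeType.METABOLITE,
)
matrix = incidence_from_projection(projection)
result = cluster(jaccard_distance(matrix), matrix.entities, k=3)

print("cophenetic correlation per linkage method:")
for method, r in result.cophenetic.items():
    marker = " <- selected" if method == result.method else ""
    print(f"  {method:9s} {r:.4f}{marker}")

gt = bundle.ground_truth["cluster_labels"]
taxa = sorted(gt)
ari = adjusted_rand_score([gt[t] for t in taxa], [result.labels[t] for t in taxa])
print(f"adjusted Rand index vs planted clusters (5% noise): {ari:.3f}")
print(
    "-> 1.0 means the cut reproduces the planted taxon blocks exactly; the "
    "selected linkage is the one whose tree distances track the Jaccard "
    "distances best."
)
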