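"""Hypergeometric term enrichment of a cluster.

Annotates the synthetic genes with their generating class ("periodic" /
"aperiodic") and asks whether each cluster found by the pipeline is enriched
for either term — a stand-in for testing gene-ontology terms on real data.
"""

import numpy as np

from waveclust import AnnotationMap, bregman_kmeans, build_W, encode, enrich_all
from waveclust import eigen_embed, normalize_stochastic, sparsify_symmetric_knn
from waveclust.simulate import SyntheticSpec, generate

dataset, labels, _ = generate(SyntheticSpec(seed=1))
graph = sparsify_symmetric_knn(build_W(encode(dataset, n=64)), k=10)
emb = eigen_embed(normalize_stochastic(graph, "markov"), d=3, gene_ids=dataset.gene_ids)
clusters = bregman_kmeans(emb.coords, K=4, restarts=5, seed=1, gene_ids=dataset.gene_ids)

annotations = AnnotationMap(
    terms={
        "periodic": {g for g, l in zip(dataset.gene_ids, labels) if l < 3},
        "aperiodic": {g for g, l in zip(dataset.gene_ids, labels) if l == 3},
    },
    background=set(dataset.gene_ids),
)
table = enrich_all(clusters.labels, dataset.gene_ids, annotations)
print(table.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print(
    "\nk of K_t annotated genes fell in a cluster of n_c genes (background G_b);"
    "\np is the upper-tail hypergeometric probability, q its BH adjustment."
    "\nClusters made of one planted class show p near machine precision."
)
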