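"""Spectral manifold embedding and per-gene local-dimension scores.

Builds the similarity graph for a synthetic dataset, embeds the gene Markov
chain in 3-D, and compares local-dimension scores of tightly co-regulated
(periodic) genes against aperiodic genes across noise levels: constrained
neighborhoods need few principal axes, while measurement noise pushes every
score toward the ambient dimension.
"""

import numpy as np

from waveclust import (
    build_W,
    encode,
    eigen_embed,
    local_dimension,
    normalize_stochastic,
    sparsify_symmetric_knn,
)
from waveclust.simulate import SyntheticSpec, generate

for noise in (0.05, 0.2):
    dataset, labels, _ = generate(SyntheticSpec(seed=1, noise_sd=noise))
    features = encode(dataset, n=64)
    graph = sparsify_symmetric_knn(build_W(features), k=10)
    N = normalize_stochastic(graph, "markov")
    emb = eigen_embed(N, d=3, gene_ids=dataset.gene_ids)
    scores = local_dimension(features, emb.coords, k_nb=30, tau=0.95)
    print(f"noise sd {noise}:")
    print(f"  top eigenvalues of the gene Markov chain: {np.round(emb.eigenvalues, 4)}")
    print(f"  mean local dimension, periodic genes:  {scores[labels < 3].mean():.2f}")
    print(f"  mean local dimension, aperiodic genes: {scores[labels == 3].mean():.2f}")

print(
    "\nAt low noise the 1-D periodic families score well below the aperiodic"
    "\nrandom walks; added noise inflates both toward the ambient dimension,"
    "\nwhich is exactly what the score is designed to flag."
)
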