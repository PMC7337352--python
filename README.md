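# waveclust

Geometric clustering of synchronized time-series gene expression.

Given a gene × time-point expression matrix — e.g. a yeast culture profiled
over repeated metabolic cycles — `waveclust` answers the question *which
genes move together, and how tightly?* without assuming stationarity,
a fixed number of patterns, or a hand-picked distance function:

1. **Wavelet encoding.** Each gene's profile is resampled onto a dyadic grid
   and expanded in the orthonormal Haar basis (n = 64 coefficients by
   default), so similarity is computed on the whole signal shape.
2. **Similarity graph.** Pairwise similarity is the cosine of the angle
   between coefficient vectors mapped onto [0, 1], W_ij = (1 + cos θ_ij)/2;
   the dense matrix is sparsified by k-symmetric nearest neighbors
   (k = 10): keep (i, j) iff j is in i's top-k *or* i is in j's top-k.
3. **Manifold learning.** The sparse graph is normalized into a
   row-stochastic matrix N = D⁻¹W — the transition matrix of a Markov chain
   whose states are genes (symmetric and Sinkhorn doubly-stochastic
   normalizations are also available).  The right eigenvectors of N give
   diffusion-map coordinates, coordinate j = λ_{j+1} v_{j+1}, d = 3 by
   default.  A per-gene **local-dimension score** — the number of principal
   axes needed to explain 95 % of the variance of the gene's manifold
   neighborhood in feature space — flags tightly constrained co-regulation
   (low score) versus noise (score near the ambient dimension).
4. **Clustering battery.** Bregman k-means (Lloyd under squared-Euclidean or
   KL divergence, k-means++ initialization, best-of-restarts, elbow rule
   over K = 3..15), non-negative matrix factorization with multiplicative
   updates, and Frey–Dueck affinity propagation.
5. **Network extraction.** The Delaunay triangulation of the 3-D coordinates
   is scored edge-wise with the Pearson correlation of the raw profiles
   (two-sided t test, T − 2 df) and filtered at p ≤ 0.001; significant
   edges shorter than average confirm that correlated genes were embedded
   close together.
6. **Reproducibility.** Every run writes a replayable `scenario.txt`
   recording each operation, its parameters, seeds and input digests;
   replaying reproduces all outputs byte for byte.

A hypergeometric over-representation test (with Benjamini–Hochberg
adjustment) scores user-supplied annotation terms within each cluster, and a
synthetic-data generator produces ground-truthed datasets that mimic the
periodic/aperiodic design of cycling cultures.

## Worked example

`examples/01_simulate_and_cluster.py` generates three phase-offset periodic
gene groups (50 genes each, the first 10 of each group noise-free
"sentinels") plus 150 aperiodic genes — 300 genes over 36 time points
spanning 3 cycles of 300 minutes — and runs the default protocol with K = 4:

```
genes: 300, time points: 36
adjusted Rand index vs planted groups: 0.970
   set  n  majority_cluster  correct  collision
group0 10                 2    100.0        0.0
group1 10                 3    100.0        0.0
group2 10                 0    100.0        0.0
```

The adjusted Rand index of 0.97 means the clustering almost perfectly
recovers the four planted groups (three phases plus the aperiodic
contingent); `correct = 100` / `collision = 0` means every sentinel set was
co-assigned to a single cluster — the audit a biologist would run with
experimentally validated phase markers.

The other scripts in `examples/` each demonstrate one capability: wavelet
encoding and Parseval, the manifold and local-dimension scores, the filtered
Delaunay network, cluster enrichment, and scenario replay.

## Command line

The same pipeline is scriptable from a shell:

```sh
waveclust simulate --seed 1 --out expr.tsv
waveclust run expr.tsv --outdir out --k 4 --seed 1
waveclust replay out/scenario.txt --outdir out2
```

Stage subcommands (`encode`, `similarity`, `embed`, `cluster-kmeans`,
`cluster-nnmf`, `cluster-ap`, `triangulate`, `enrich`) expose the individual
steps, and `batch` executes a text file of subcommand lines.

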