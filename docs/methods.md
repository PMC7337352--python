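# Methods

This note documents the model behind `waveclust`, the parameters that
matter, the numerical choices made where the design was genuinely open, and
what the synthetic benchmarks do and do not demonstrate.

## Signal model and encoding

The input is a synchronized collection of time series: G genes measured at
the same T time stamps (minutes), with no assumption of stationarity,
uniform spacing, or a particular autocorrelation shape.  Because T is
rarely a power of two, each profile is first resampled by piecewise-linear
interpolation onto a uniform grid of n points over [t₁, t_T] (n = 64 by
default; n must be a power of two).  The resampled signal is then expanded
in the **orthonormal** Haar basis: the pair (a, b) maps to
((a+b)/√2, (a−b)/√2), applied recursively to the running averages.
Orthonormality matters for two reasons: Parseval holds exactly (coefficient
energy equals signal energy, asserted to 1e−9 in the tests), and inner
products — hence the cosine similarities downstream — are identical in
signal space and coefficient space.  Halving n to 32 moves the similarity
matrix of smooth periodic profiles by less than 0.05, so the default is not
delicate.  Profiles are not standardized before encoding (cosine similarity
is already scale-invariant); a `center_genes` switch subtracts the mean
first for users who want offset-invariance too.

## Similarity graph

The dense similarity is W_ij = (1 + cos θ_ij)/2 where θ is the angle
between coefficient vectors.  The affine map is the only monotone map of
the cosine onto [0, 1] with 1 ⇔ zero angle and 0 ⇔ opposite profiles;
orthogonal profiles land at 0.5.  An alternative heat-kernel similarity
exp(−‖u−v‖²/2σ²) is provided for users who want magnitude sensitivity.

Sparsification keeps, for each gene, its k largest off-diagonal
similarities and symmetrizes by union with the transpose ("k-symmetric
nearest neighbors", k = 10 by default).  Ties at the k-th value break
toward the lower gene index, which makes the mask deterministic and
monotone in k (mask(k) ⊆ mask(k+1)).  Entries outside the mask are zeroed;
the diagonal is kept, which adds a small lazy-walk component to the Markov
chain and guarantees positive row sums.

## Manifold embedding

The sparse W is normalized to a row-stochastic N; three normalizations are
implemented: `markov` (N = D⁻¹W, the default), `symmetric`
(D^(−1/2)WD^(−1/2), rows rescaled), and `sinkhorn` (alternating row/column
scaling to a doubly stochastic matrix, tolerance 1e−8, at most 10⁴ sweeps;
non-convergence raises with the residual).  N is the transition matrix of a
Markov chain over genes; its right eigenvectors, ordered by descending real
eigenvalue, give the embedding.  The trivial constant eigenvector
(eigenvalue 1) is discarded and coordinate j is λ_{j+1}·v_{j+1}
(diffusion-map scaling, so directions with slower-mixing structure get more
weight).  d = 3 by default — the natural space for visual exploration.

Numerical details: eigenvectors are unit-normalized with the sign fixed so
the largest-magnitude entry is positive, making the output deterministic up
to machine rounding.  A disconnected graph makes eigenvalue 1 degenerate;
the degenerate subspace is re-orthonormalized starting from the constant
vector so the remaining coordinates separate components by sign, and a
warning reports the component count.  Complex eigenvalues (possible for
non-symmetric N) are truncated to real parts with a warning; for
similarity-derived N the spectrum is real because N is similar to a
symmetric matrix.

## Local-dimension score

For each gene, its k_nb = 30 nearest neighbors *on the manifold* define a
neighborhood whose rows are examined *in wavelet-feature space* — so the
score can exceed the embedding dimension d.  Let λ₁ ≥ λ₂ ≥ … be the
neighborhood PCA variances; the score is the smallest m whose cumulative
variance fraction reaches τ = 0.95, linearly interpolated between m−1 and m
to give a continuous value.  A 1-D family scores ≈ τ ≈ 1; an isotropic
cloud in D dimensions scores ≈ D − 0.5.

Plain sample covariance over a few dozen points spreads its eigenvalues
well beyond the population values (Marchenko–Pastur), which undercounts
dimensions on isotropic data.  The variances are therefore taken from a
Ledoit–Wolf-shrunk covariance, with one modification: shrinkage is confined
to the observed rank-r = min(n−1, D) eigen-subspace.  Full shrinkage toward
the identity would assign variance to directions no neighborhood of n
points has observed, and in the common n < D regime that floods the
spectrum and pushes every score toward the ambient dimension.  With the
rank restriction the score is bounded by the neighborhood size, isotropic
benchmarks are debiased (mean 9.47 on a 10-D cloud with k_nb = 60), and
anisotropic neighborhoods are left nearly untouched (a noiseless 1-D line
scores 0.975).

Interpretation: low scores mean few latent degrees of freedom — tightly
constrained, robust co-regulation; scores near the ambient dimension mean
the neighborhood is indistinguishable from noise.  The score is a
*neighborhood* property: a noise-free gene surrounded by noisy ones
inherits a noisy neighborhood, and added measurement noise inflates all
scores (the suite checks this monotonicity explicitly).

## Clustering

**Bregman k-means.**  Lloyd iterations under a Bregman divergence; the
centroid minimizing total divergence is the arithmetic mean for *every*
Bregman divergence, so only the assignment step depends on the choice
(squared Euclidean by default; generalized KL available, with a documented
minimum-shift when coordinates are not strictly positive).  Initialization
is k-means++ (each next center sampled proportional to squared distance to
the nearest chosen center).  Runs stop when labels stabilize or after 300
iterations; empty clusters are re-seeded at the point farthest from its
center.  The reported result is the best of `restarts` independent runs
(5 by default) by potential, and the per-iteration potential history is
kept so monotonicity is testable.

**Model selection.**  For each K in a range (3..15 by default) the mean and
standard deviation of the per-restart potentials are recorded; the elbow is
the K maximizing the ratio of the mean-potential drop *into* K over the
drop *out of* K — a sharp decrease before, mild decrease after.  The ratio
rule is a documented choice; on four well-separated planted blobs it
selects K = 4 reliably, while on data with a diffuse noise cloud the curve
flattens and the selection becomes seed-sensitive, which is why the
headline fixture analysis fixes K explicitly.

**NNMF.**  Multiplicative updates for ‖X − FH‖² on the (non-negative)
sparse similarity matrix; the objective is non-increasing at every update
(asserted to 1e−9 relative).  Gene labels are the argmax factor loading,
ties to the lower index.  Manifold coordinates can be negative, so the
similarity matrix — not the embedding — is what gets factorized.

**Affinity propagation.**  Frey–Dueck responsibility/availability message
passing with damping (0.9 default), preference defaulting to the median
off-diagonal similarity, convergence declared when the exemplar set is
stable for 25 sweeps.  A seeded perturbation of relative size ~1e−14 is
added to the similarities, as reference implementations do: exactly
symmetric inputs (duplicated points) otherwise balance the fixed point
exactly on the exemplar threshold r(k,k) + a(k,k) = 0 and no exemplar ever
emerges.  The output is invariant to adding a constant to all similarities
when the preference is shifted equally.

## Delaunay network

The Delaunay triangulation of the 3-D coordinates (via Qhull) defines
geometric neighbor pairs.  Each edge carries the Pearson correlation r of
the two genes' **raw** T-point profiles — raw rather than wavelet space so
that edge sign matches the biologist-facing notion of co-regulation — and a
two-sided p-value from t = r√((T−2)/(1−r²)) on T−2 df (a permutation
alternative is available).  Edges touching a zero-variance profile are
dropped with a warning.  Filtering keeps edges with p ≤ 0.001 by default;
no multiple-testing correction is applied to the edge set by default
(raw-p thresholds are conventional here), and the mean length of
significant edges versus all edges is reported: a ratio well below 1 is the
sanity check that the embedding pulls correlated genes together.  Exactly
degenerate point sets get one retry with a deterministic seeded jitter of
1e−9 × coordinate range.

## Enrichment

For a cluster of size n_c from a background of G_b genes, a term annotating
K_t background genes and k cluster genes scores p = P[X ≥ k],
X ~ Hypergeometric(G_b, K_t, n_c) (upper tail: over-representation only),
with Benjamini–Hochberg q-values across the terms tested within the
cluster.  Annotations are user-supplied two-column files; no ontology-graph
propagation is attempted.

## Scenario recording

Every pipeline run appends one record per operation — name, parameter map
including seeds, SHA-256 digests of files read — to a tab-separated
`scenario.txt`.  Replaying a scenario re-executes the pipeline with the
recorded parameters; because all randomness flows through recorded seeds
and all writers use fixed float formatting, the replayed TSV outputs are
byte-identical.  Input-digest mismatches warn by default and raise in
strict mode.

## Synthetic data: what it does and does not show

The generator emulates a metabolically cycling culture: `n_groups` periodic
groups at evenly spaced phase offsets φ_g = 2πg/n_groups, profiles
a·sin(2π·c·t/total + φ_g) + ε with per-gene amplitude a ~ U(0.75, 1.25),
ε ~ N(0, noise_sd²), plus `n_aperiodic` smoothed, standardized random walks
scaled to the rms of a unit sinusoid.  Defaults (3 groups × 50 genes,
150 aperiodic, T = 36 over 3 cycles of 300 minutes, noise_sd = 0.2,
10 noise-free sentinels per group) mirror the repeated-cycle design of
whole-culture yeast experiments at desk scale.  The time grid is
t_j = j·total/T so that cycles tile the axis exactly and noiseless profiles
repeat across cycles to 1e−12.  The amplitude range is a fixed modeling
choice: periodic-gene catalogs are defined by fold-change cutoffs, not by a
published per-gene amplitude distribution, and cosine similarity is
amplitude-invariant anyway.

What passing the planted-recovery benchmark shows: the full chain —
encoding, graph, spectrum, clustering — separates phase-offset periodic
families from each other and from structured non-periodic signals at
realistic noise, and sentinel sets are co-assigned.  What it does not show:
robustness to missing data patterns, platform normalization artifacts,
unequal group sizes, partially synchronized cultures, or dose × time
factorial designs; real expression noise is neither Gaussian nor
homoscedastic.  Benchmark sizes (G = 300, T = 36) were chosen so that the
whole suite and the acceptance script run in seconds while every
qualitative property of the method is still exercised.

## Known limitations

- Dense eigendecomposition of N is O(G³); comfortable to a few thousand
  genes, beyond which an iterative eigensolver would be the next step.
- The elbow rule assumes a single dominant scale; flat potential curves
  (heavy noise clouds) make the selected K seed-sensitive.
- Local-dimension scores are neighborhood properties and saturate near the
  neighborhood rank min(k_nb, D); comparisons are meaningful within one
  dataset and parameter setting, not across different k_nb or n.
- Edge p-values treat time points as independent samples; autocorrelated
  profiles make them optimistic, which is one reason the default threshold
  is strict (0.001) and a permutation option exists.
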