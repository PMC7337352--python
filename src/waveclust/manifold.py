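"""Manifold learning on the sparse similarity graph.

The sparsified similarity matrix is normalized into a row-stochastic matrix
N — the transition matrix of a Markov chain whose states are genes — whose
eigendecomposition yields diffusion-map coordinates.  A per-gene local
dimension score (local PCA in feature space over manifold neighborhoods)
estimates the local number of principal axes: low scores indicate tightly
constrained co-regulation, scores near the ambient dimension indicate noise.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.spatial import cKDTree

from .similarity import SimilarityGraph
from .wavelets import FeatureMatrix

logger = logging.getLogger(__name__)

NORMALIZATIONS = ("markov", "symmetric", "sinkhorn")


@dataclass
class ManifoldEmbedding:
    """Diffusion coordinates and spectrum of the gene Markov chain."""

    gene_ids: list[str]
    eigenvalues: np.ndarray  # descending, length d+1 incl. the trivial 1
    coords: np.ndarray  # (G, d)
    local_dim: np.ndarray | None = None
    normalization: str = "markov"
    meta: dict = field(default_factory=dict)

    @property
    def d(self) -> int:
        return self.coords.shape[1]


def normalize_stochastic(graph: SimilarityGraph | np.ndarray, method: str = "markov") -> np.ndarray:
    """Turn the (sparse) similarity matrix into a row-stochastic matrix N.

    methods
    -------
    markov    : N = D^-1 W (random-walk normalization)
    symmetric : D^-1/2 W D^-1/2, then rows rescaled to sum to 1
    sinkhorn  : alternating row/column scaling to a doubly stochastic matrix
                (row and column sums 1 within 1e-8, at most 10000 sweeps)
    """
    W = graph.W if isinstance(graph, SimilarityGraph) else np.asarray(graph, dtype=float)
    gene_ids = graph.gene_ids if isinstance(graph, SimilarityGraph) else None
    if method not in NORMALIZATIONS:
        raise ValueError(f"unknown normalization {method!r}; choose from {NORMALIZATIONS}")
    rowsum = W.sum(axis=1)
    dead = np.nonzero(rowsum <= 0)[0]
    if dead.size:
        names = [gene_ids[i] for i in dead] if gene_ids else list(dead)
        raise ValueError(f"isolated genes (zero similarity row): {names}")

    if method == "markov":
        N = W / rowsum[:, None]
    elif method == "symmetric":
        dinv = 1.0 / np.sqrt(rowsum)
        S = dinv[:, None] * W * dinv[None, :]
        N = S / S.sum(axis=1)[:, None]
    else:  # sinkhorn
        N = _sinkhorn(W, tol=1e-8, max_iter=10_000)
    # defensively re-normalize rounding residue
    N = N / N.sum(axis=1)[:, None]
    return N


def _sinkhorn(W: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    r = np.ones(W.shape[0])
    c = np.ones(W.shape[1])
    for _ in range(max_iter):
        r = 1.0 / (W @ c)
        c = 1.0 / (W.T @ r)
        N = (r[:, None] * W) * c[None, :]
        res = max(
            np.abs(N.sum(axis=1) - 1.0).max(), np.abs(N.sum(axis=0) - 1.0).max()
        )
        if res <= tol:
            return N
    raise RuntimeError(
        f"Sinkhorn scaling did not converge in {max_iter} iterations (residual {res:.3g})"
    )


def _fix_sign(v: np.ndarray) -> np.ndarray:
    i = np.argmax(np.abs(v))
    return -v if v[i] < 0 else v


def eigen_embed(
    N: np.ndarray,
    d: int = 3,
    gene_ids: list[str] | None = None,
    normalization: str = "markov",
) -> ManifoldEmbedding:
    """Diffusion-map coordinates from the spectrum of N.

    Right eigenvectors of N are sorted by descending real eigenvalue; the
    trivial constant eigenvector (eigenvalue 1) is dropped and coordinate j
    is ``lambda_{j+1} * v_{j+1}`` for j = 1..d.  If eigenvalue 1 is
    degenerate (disconnected graph) the degenerate subspace is
    re-orthonormalized starting from the constant vector, so the remaining
    vectors separate the components by sign; a warning reports the component
    count.
    """
    N = np.asarray(N, dtype=float)
    G = N.shape[0]
    if d >= G:
        raise ValueError(f"d={d} must be smaller than the number of genes G={G}")
    lam, V = scipy.linalg.eig(N)
    if np.abs(lam.imag).max() > 1e-8:
        warnings.warn("complex eigenvalues encountered; taking real parts")
    lam = lam.real
    V = V.real
    order = np.argsort(-lam)
    lam = lam[order]
    V = V[:, order]

    # handle a degenerate leading eigenspace (reducible chain)
    mult = int(np.sum(lam > lam[0] - 1e-8))
    if mult > 1:
        warnings.warn(f"graph appears disconnected: eigenvalue 1 has multiplicity {mult}")
        block = np.column_stack([np.ones(G)] + [V[:, j] for j in range(mult)])
        Q, _ = np.linalg.qr(block)
        V[:, :mult] = Q[:, :mult]

    V = V / np.linalg.norm(V, axis=0)
    coords = np.empty((G, d))
    for j in range(1, d + 1):
        coords[:, j - 1] = lam[j] * _fix_sign(V[:, j])
    return ManifoldEmbedding(
        gene_ids=list(gene_ids) if gene_ids is not None else [str(i) for i in range(G)],
        eigenvalues=lam[: d + 1],
        coords=coords,
        normalization=normalization,
    )


def local_dimension(
    features: FeatureMatrix | np.ndarray,
    coords: np.ndarray,
    k_nb: int = 30,
    tau: float = 0.95,
) -> np.ndarray:
    """Pointwise local-dimension score for every gene.

    For each gene, its ``k_nb`` nearest neighbors on the manifold
    (``coords``) define a neighborhood; PCA of the neighborhood's rows in
    feature space gives variances lambda_1 >= lambda_2 >= ...; the score is
    the smallest m whose cumulative variance fraction reaches ``tau``,
    linearly interpolated between m-1 and m for a continuous value.  Scores
    are bounded by the ambient feature dimension, so they can exceed the
    embedding dimension d.
    """
    X = features.coeffs if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    coords = np.asarray(coords, dtype=float)
    G = coords.shape[0]
    if X.shape[0] != G:
        raise ValueError("features and coords disagree on the number of genes")
    if not 0 < tau <= 1:
        raise ValueError("tau must lie in (0, 1]")
    if k_nb >= G:
        raise ValueError(f"k_nb={k_nb} must be smaller than G={G}")
    if k_nb < coords.shape[1] + 1:
        raise ValueError("k_nb must be at least d+1")

    tree = cKDTree(coords)
    _, nb = tree.query(coords, k=k_nb + 1)  # includes the point itself
    scores = np.empty(G)
    for g in range(G):
        var = _shrunk_variances(X[nb[g]])
        total = var.sum()
        if total <= 0:
            logger.warning("zero-variance neighborhood for gene %d; local_dim=0", g)
            scores[g] = 0.0
            continue
        frac = np.cumsum(var) / total
        m = int(np.searchsorted(frac, tau - 1e-12) + 1)
        lo = frac[m - 2] if m >= 2 else 0.0
        hi = frac[m - 1]
        scores[g] = (m - 1) + (tau - lo) / (hi - lo) if hi > lo else float(m)
    return scores


def _shrunk_variances(block: np.ndarray) -> np.ndarray:
    """Descending PCA variances of a neighborhood, with Ledoit-Wolf-style
    eigenvalue shrinkage restricted to the observed rank-r subspace.

    Plain sample covariance over a few dozen points spreads its eigenvalues
    far beyond the population values, biasing the cumulative-variance
    dimension count downward; shrinking the eigenvalues toward their mean
    (with the Ledoit-Wolf intensity) removes that small-sample bias while
    leaving genuinely anisotropic neighborhoods almost untouched.  Shrinkage
    is confined to the top r = min(n-1, D) eigenvalues: with fewer points
    than dimensions the orthogonal complement is unobserved, and spreading
    mass into it would report dimensions no neighborhood of n points can
    support.
    """
    n, D = block.shape
    Xc = block - block.mean(axis=0)
    S = Xc.T @ Xc / n
    lam = np.maximum(np.linalg.eigvalsh(S)[::-1], 0.0)
    r = min(n - 1, D)
    mu = lam[:r].sum() / r
    d2 = float(np.sum((lam[:r] - mu) ** 2))
    if d2 <= 0:
        return lam
    # sum_k ||x_k x_k^T - S||_F^2 = sum ||x_k||^4 - n ||S||_F^2
    b2 = np.sum(np.sum(Xc**2, axis=1) ** 2) / n**2 - np.linalg.norm(S, "fro") ** 2 / n
    rho = min(max(b2, 0.0), d2) / d2
    out = np.zeros_like(lam)
    out[:r] = (1.0 - rho) * lam[:r] + rho * mu
    return out
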