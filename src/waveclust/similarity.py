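"""Gene-gene similarity graph: [0,1]-normalized cosine, k-symmetric NN sparsification.

The dense similarity between two genes is the cosine of the angle between
their wavelet representations, mapped affinely onto [0,1] so that 1 means a
zero angle (maximal similarity) and 0 an angle of pi.  The dense matrix is
sparsified by keeping, for every gene, its k largest off-diagonal
similarities and symmetrizing by logical-or of that relation with its
transpose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .wavelets import FeatureMatrix


@dataclass
class SimilarityGraph:
    """Symmetric gene x gene weights in [0,1] plus an optional sparsity mask.

    ``W`` keeps its value at masked-in entries and is 0 elsewhere once
    sparsified; the diagonal stays 1 throughout.  ``k`` is None for the dense
    graph.
    """

    gene_ids: list[str]
    W: np.ndarray
    sparse_mask: np.ndarray | None = None
    k: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return self.W.shape[0]


def cosine01(u, v, name_u: str = "u", name_v: str = "v") -> float:
    """(1 + cos angle(u, v)) / 2, in [0,1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0:
        raise ValueError(f"zero feature vector for {name_u}")
    if nv == 0:
        raise ValueError(f"zero feature vector for {name_v}")
    c = float(np.dot(u, v) / (nu * nv))
    return min(1.0, max(0.0, 0.5 * (1.0 + c)))


def build_W(features: FeatureMatrix) -> SimilarityGraph:
    """Dense [0,1] cosine similarity matrix over all gene pairs."""
    X = features.coeffs
    norms = np.linalg.norm(X, axis=1)
    zero = np.nonzero(norms == 0)[0]
    if zero.size:
        bad = [features.gene_ids[i] for i in zero]
        raise ValueError(f"all-zero feature rows for genes: {bad}")
    U = X / norms[:, None]
    W = 0.5 * (1.0 + U @ U.T)
    np.clip(W, 0.0, 1.0, out=W)
    W = 0.5 * (W + W.T)  # kill rounding asymmetry
    np.fill_diagonal(W, 1.0)
    return SimilarityGraph(gene_ids=list(features.gene_ids), W=W)


def heat_kernel_W(features: FeatureMatrix, sigma: float) -> SimilarityGraph:
    """Alternative similarity: exp(-||u - v||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    X = features.coeffs
    sq = np.sum(X**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (X @ X.T), 0.0)
    W = np.exp(-d2 / (2.0 * sigma**2))
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 1.0)
    return SimilarityGraph(
        gene_ids=list(features.gene_ids), W=W, meta={"similarity": "heat", "sigma": sigma}
    )


def sparsify_symmetric_knn(graph: SimilarityGraph, k: int = 10) -> SimilarityGraph:
    """k-symmetric nearest-neighbor sparsification of the dense graph.

    Entry (i, j) is kept iff j is among the k largest off-diagonal
    similarities of row i OR i is among those of row j; ties at the k-th
    value break toward the lower gene index.  Masked-out entries are zeroed;
    the diagonal is kept.
    """
    G = graph.n_genes
    if k < 1:
        raise ValueError("k must be positive")
    if k >= G:
        raise ValueError(f"k={k} must be smaller than the number of genes G={G}")
    W = graph.W
    asym = np.zeros((G, G), dtype=bool)
    for i in range(G):
        row = W[i].copy()
        row[i] = -np.inf
        # stable sort on (-similarity, index): deterministic tie-break
        order = np.lexsort((np.arange(G), -row))
        asym[i, order[:k]] = True
    mask = asym | asym.T
    np.fill_diagonal(mask, True)
    Ws = np.where(mask, W, 0.0)
    return SimilarityGraph(
        gene_ids=list(graph.gene_ids), W=Ws, sparse_mask=mask, k=k, meta=dict(graph.meta)
    )
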