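"""Filtered Delaunay triangulation of the manifold.

Edges of the Delaunay triangulation of the 3-D manifold coordinates connect
geometric neighbors; each edge is scored with the Pearson correlation of the
two genes' raw expression profiles and a two-sided p-value, then filtered at
a p threshold (default 0.001).  Significant edges being short relative to
the average edge indicates that strongly correlated genes were indeed drawn
close on the manifold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from scipy.stats import t as t_dist

from .io import ExpressionDataset

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["gene_i", "gene_j", "length", "r", "p", "sign"]


@dataclass
class TriangulationResult:
    """Signed, p-valued Delaunay edge list plus length statistics."""

    edges: pd.DataFrame  # columns EDGE_COLUMNS (+ significant after filtering)
    p_threshold: float | None = None
    stats: dict = field(default_factory=dict)


def delaunay_edges(coords: np.ndarray, jitter: bool = True, seed: int = 0) -> np.ndarray:
    """Unique undirected edges (i < j) of the Delaunay triangulation.

    Degenerate inputs (coplanar or duplicated points) get one retry with a
    deterministic seeded jitter of 1e-9 x coordinate range when ``jitter``
    is enabled, else an error.
    """
    coords = np.asarray(coords, dtype=float)
    G = coords.shape[0]
    if G < 4:
        raise ValueError(f"need at least 4 points for a 3-D triangulation, got {G}")
    try:
        tri = Delaunay(coords)
    except QhullError:
        if not jitter:
            raise
        rng = np.random.default_rng(seed)
        span = np.ptp(coords, axis=0)
        span[span == 0] = 1.0
        logger.info("degenerate point set; retrying Delaunay with 1e-9 jitter")
        try:
            tri = Delaunay(coords + 1e-9 * span * rng.standard_normal(coords.shape))
        except QhullError as exc:
            raise ValueError(f"points remain degenerate after jitter: {exc}") from exc
    edges = set()
    for simplex in tri.simplices:
        for a in range(len(simplex)):
            for b in range(a + 1, len(simplex)):
                i, j = int(simplex[a]), int(simplex[b])
                edges.add((min(i, j), max(i, j)))
    return np.array(sorted(edges), dtype=int)


def score_edges(
    edges: np.ndarray,
    dataset: ExpressionDataset,
    coords: np.ndarray,
    p_method: str = "ttest",
    n_perm: int = 1000,
    seed: int = 0,
) -> TriangulationResult:
    """Attach length, Pearson r, two-sided p and sign to every edge.

    Correlation is computed on the raw T-length expression profiles.  With
    ``p_method='ttest'`` the p-value comes from t = r sqrt((T-2)/(1-r^2)) on
    T-2 degrees of freedom; ``'permutation'`` uses ``n_perm`` profile
    permutations instead.  Zero-variance profiles make r undefined: those
    edges are dropped with a warning.
    """
    T = dataset.n_time_points
    if T < 3:
        raise ValueError("need at least 3 time points to score correlations")
    X = dataset.values
    sd = X.std(axis=1)
    centered = X - X.mean(axis=1, keepdims=True)
    rows = []
    rng = np.random.default_rng(seed)
    n_dropped = 0
    for i, j in edges:
        if sd[i] == 0 or sd[j] == 0:
            n_dropped += 1
            continue
        r = float(np.dot(centered[i], centered[j]) / (T * sd[i] * sd[j]))
        r = min(1.0, max(-1.0, r))
        if p_method == "ttest":
            p = _ttest_p(r, T)
        elif p_method == "permutation":
            p = _perm_p(X[i], X[j], r, n_perm, rng)
        else:
            raise ValueError(f"unknown p_method {p_method!r}")
        rows.append(
            {
                "gene_i": dataset.gene_ids[i],
                "gene_j": dataset.gene_ids[j],
                "length": float(np.linalg.norm(coords[i] - coords[j])),
                "r": r,
                "p": p,
                "sign": "positive" if r > 0 else "negative",
            }
        )
    if n_dropped:
        logger.warning("dropped %d edge(s) with zero-variance profiles", n_dropped)
    return TriangulationResult(edges=pd.DataFrame(rows, columns=EDGE_COLUMNS))


def _ttest_p(r: float, T: int) -> float:
    if abs(r) >= 1.0:
        return float(np.nextafter(0, 1))
    t = r * np.sqrt((T - 2) / (1.0 - r * r))
    p = 2.0 * t_dist.sf(abs(t), T - 2)
    return float(max(min(p, 1.0), np.nextafter(0, 1)))


def _perm_p(x: np.ndarray, y: np.ndarray, r_obs: float, n_perm: int, rng) -> float:
    count = 0
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    for _ in range(n_perm):
        rp = np.dot(xc, rng.permutation(yc)) / denom
        if abs(rp) >= abs(r_obs) - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def filter_and_stats(result: TriangulationResult, p_threshold: float = 0.001) -> TriangulationResult:
    """Mark significant edges (p <= threshold) and summarize edge lengths."""
    edges = result.edges.copy()
    edges["significant"] = edges["p"] <= p_threshold
    sig = edges[edges["significant"]]
    stats = {
        "n_edges": int(len(edges)),
        "n_significant": int(len(sig)),
        "mean_length_all": float(edges["length"].mean()) if len(edges) else float("nan"),
        "mean_length_significant": float(sig["length"].mean()) if len(sig) else float("nan"),
    }
    return TriangulationResult(edges=edges, p_threshold=p_threshold, stats=stats)
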