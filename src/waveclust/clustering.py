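"""Hard and soft clustering on manifold coordinates.

Three families are provided:

* Bregman k-means (Lloyd iterations under a Bregman divergence, for which the
  optimal centroid is always the arithmetic mean) with k-means++
  (Arthur-Vassilvitskii) initialization, best-of-restarts selection and an
  elbow rule over a range of K;
* non-negative matrix factorization with multiplicative updates, labels by
  argmax factor loading;
* affinity propagation (damped responsibility/availability message passing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ClusteringResult:
    gene_ids: list[str]
    labels: np.ndarray  # ints in [0, K)
    K: int
    potential: float | None = None
    centers: np.ndarray | None = None
    method: str = ""
    params: dict = field(default_factory=dict)
    seed: int | None = None
    #: per-iteration potential of the winning run (k-means) or objective
    #: sequence (NNMF)
    history: np.ndarray | None = None


@dataclass
class SelectionCurve:
    k_values: list[int]
    mean_potential: np.ndarray
    sd_potential: np.ndarray
    best: dict[int, ClusteringResult]
    best_k: int


# ---------------------------------------------------------------------------
# Bregman divergences.  The centroid minimizing total divergence is the
# arithmetic mean for every Bregman divergence, so Lloyd's update is shared.

def _sqeuclidean(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(C**2, axis=1)[None, :]
        - 2.0 * X @ C.T
    )
    return np.maximum(d2, 0.0)


def _kl(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    # generalized KL: sum x log(x/c) - x + c; requires strictly positive input
    xlogx = np.sum(X * np.log(X), axis=1)
    return (
        xlogx[:, None] - X @ np.log(C).T - np.sum(X, axis=1)[:, None] + np.sum(C, axis=1)[None, :]
    )


DIVERGENCES = {"squared_euclidean": _sqeuclidean, "kl": _kl}


def _prepare_points(points: np.ndarray, divergence: str) -> np.ndarray:
    X = np.asarray(points, dtype=float)
    if divergence == "kl" and X.min() <= 0:
        shift = 1e-6 - X.min()
        logger.info("KL divergence: shifting coordinates by %.3g to make them positive", shift)
        X = X + shift
    return X


def kmeanspp_init(points: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Arthur-Vassilvitskii seeding: first center uniform, each next center
    sampled with probability proportional to squared distance to the nearest
    chosen center."""
    X = np.asarray(points, dtype=float)
    n_distinct = np.unique(X, axis=0).shape[0]
    if K > n_distinct:
        raise ValueError(f"K={K} exceeds the number of distinct points {n_distinct}")
    centers = np.empty((K, X.shape[1]))
    centers[0] = X[rng.integers(X.shape[0])]
    d2 = _sqeuclidean(X, centers[:1]).ravel()
    for j in range(1, K):
        total = d2.sum()
        probs = d2 / total
        centers[j] = X[rng.choice(X.shape[0], p=probs)]
        d2 = np.minimum(d2, _sqeuclidean(X, centers[j : j + 1]).ravel())
    return centers


def _lloyd(
    X: np.ndarray,
    centers: np.ndarray,
    div,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    K = centers.shape[0]
    labels = np.full(X.shape[0], -1)
    history: list[float] = []
    for _ in range(max_iter):
        D = div(X, centers)
        new_labels = np.argmin(D, axis=1)
        # re-seed empty clusters at the farthest point from its center
        for k in range(K):
            if not np.any(new_labels == k):
                far = int(np.argmax(D[np.arange(X.shape[0]), new_labels]))
                logger.info("empty cluster %d re-seeded at point %d", k, far)
                centers[k] = X[far]
                D = div(X, centers)
                new_labels = np.argmin(D, axis=1)
        history.append(float(D[np.arange(X.shape[0]), new_labels].sum()))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for k in range(K):
            centers[k] = X[labels == k].mean(axis=0)
    D = div(X, centers)
    potential = float(D[np.arange(X.shape[0]), labels].sum())
    history.append(potential)
    return labels, centers, potential, history


def bregman_kmeans(
    points: np.ndarray,
    K: int,
    divergence: str = "squared_euclidean",
    restarts: int = 1,
    seed: int | None = None,
    max_iter: int = 300,
    gene_ids: list[str] | None = None,
) -> ClusteringResult:
    """Best-of-``restarts`` Bregman k-means with k-means++ initialization."""
    if divergence not in DIVERGENCES:
        raise ValueError(f"unknown divergence {divergence!r}")
    X = _prepare_points(points, divergence)
    div = DIVERGENCES[divergence]
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        centers = kmeanspp_init(X, K, rng)
        labels, centers, potential, history = _lloyd(X, centers.copy(), div, max_iter)
        if best is None or potential < best[2]:
            best = (labels, centers, potential, history)
    labels, centers, potential, history = best
    return ClusteringResult(
        gene_ids=list(gene_ids) if gene_ids is not None else [str(i) for i in range(X.shape[0])],
        labels=labels,
        K=K,
        potential=potential,
        centers=centers,
        method="bregman_kmeans",
        params={"divergence": divergence, "restarts": restarts, "max_iter": max_iter},
        seed=seed,
        history=np.asarray(history),
    )


def selection_curve(
    points: np.ndarray,
    k_values,
    restarts: int = 5,
    seed: int | None = None,
    divergence: str = "squared_euclidean",
    gene_ids: list[str] | None = None,
) -> SelectionCurve:
    """Potential-vs-K curve with an elbow rule.

    For each K the mean and sd of the per-restart potentials are recorded
    along with the best run.  The elbow is the K maximizing the ratio of the
    mean-potential drop into K over the drop out of K — a sharp decrease
    before, mild decrease after.
    """
    k_values = sorted(int(k) for k in k_values)
    X = np.asarray(points, dtype=float)
    if k_values[0] < 2 or k_values[-1] >= X.shape[0]:
        raise ValueError("K range must lie within [2, G)")
    rng = np.random.default_rng(seed)
    means, sds, best = [], [], {}
    for K in k_values:
        pots = []
        best_k = None
        for _ in range(restarts):
            res = bregman_kmeans(
                X,
                K,
                divergence=divergence,
                restarts=1,
                seed=int(rng.integers(2**31 - 1)),
                gene_ids=gene_ids,
            )
            pots.append(res.potential)
            if best_k is None or res.potential < best_k.potential:
                best_k = res
        means.append(float(np.mean(pots)))
        sds.append(float(np.std(pots)))
        best[K] = best_k
    means_arr = np.asarray(means)
    if len(k_values) >= 3:
        drops = means_arr[:-1] - means_arr[1:]
        eps = 1e-12 * max(means_arr.max(), 1.0)
        ratios = drops[:-1] / np.maximum(drops[1:], eps)
        best_k_value = k_values[int(np.argmax(ratios)) + 1]
    else:
        best_k_value = k_values[int(np.argmin(means_arr))]
    return SelectionCurve(
        k_values=k_values,
        mean_potential=means_arr,
        sd_potential=np.asarray(sds),
        best=best,
        best_k=best_k_value,
    )


# ---------------------------------------------------------------------------
# NNMF

def nnmf_cluster(
    X: np.ndarray,
    K: int,
    iters: int = 500,
    tol: float = 1e-9,
    seed: int | None = None,
    gene_ids: list[str] | None = None,
) -> tuple[ClusteringResult, np.ndarray, np.ndarray]:
    """Multiplicative-update NNMF ``X ~ F H`` with argmax-loading labels.

    Minimizes the Frobenius reconstruction error; the objective is
    non-increasing at every update.  Gene g's label is the factor with the
    largest loading in row g of F (ties go to the lower index).
    Returns (result, F, H).
    """
    X = np.asarray(X, dtype=float)
    if X.min() < 0:
        raise ValueError("NNMF input must be elementwise non-negative")
    rng = np.random.default_rng(seed)
    G, M = X.shape
    scale = np.sqrt(max(X.mean(), 1e-12) / K)
    F = scale * rng.random((G, K)) + 1e-6
    H = scale * rng.random((K, M)) + 1e-6
    eps = 1e-12
    history = [float(np.linalg.norm(X - F @ H) ** 2)]
    for _ in range(iters):
        H *= (F.T @ X) / (F.T @ F @ H + eps)
        F *= (X @ H.T) / (F @ H @ H.T + eps)
        obj = float(np.linalg.norm(X - F @ H) ** 2)
        history.append(obj)
        if history[-2] - obj <= tol * max(history[0], 1.0):
            break
    labels = np.argmax(F, axis=1)
    result = ClusteringResult(
        gene_ids=list(gene_ids) if gene_ids is not None else [str(i) for i in range(G)],
        labels=labels,
        K=K,
        potential=history[-1],
        method="nnmf",
        params={"iters": iters, "tol": tol},
        seed=seed,
        history=np.asarray(history),
    )
    return result, F, H


# ---------------------------------------------------------------------------
# Affinity propagation

def affinity_propagation(
    S: np.ndarray,
    preference: float | str = "median",
    damping: float = 0.9,
    max_iter: int = 500,
    conv_iter: int = 25,
    gene_ids: list[str] | None = None,
    seed: int = 0,
) -> tuple[ClusteringResult, np.ndarray]:
    """Frey-Dueck affinity propagation on a similarity matrix.

    ``preference`` (the self-similarity controlling the number of exemplars)
    defaults to the median of the off-diagonal similarities.  Messages are
    damped by ``damping`` in [0.5, 1); iteration stops when the exemplar set
    is stable for ``conv_iter`` sweeps.  A seeded noise of relative size
    ~1e-16 breaks the exact symmetries (e.g. duplicated points) that
    otherwise leave the message fixed point balanced on the exemplar
    threshold.  Returns (result, exemplar indices).
    """
    S = np.array(S, dtype=float)
    n = S.shape[0]
    if S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if not 0.5 <= damping < 1:
        raise ValueError("damping must lie in [0.5, 1)")
    if n == 1:
        res = ClusteringResult(
            gene_ids=list(gene_ids) if gene_ids is not None else ["0"],
            labels=np.zeros(1, dtype=int),
            K=1,
            method="affinity_propagation",
        )
        return res, np.array([0])
    if preference == "median":
        off = S[~np.eye(n, dtype=bool)]
        preference = float(np.median(off))
    np.fill_diagonal(S, preference)
    rng = np.random.default_rng(seed)
    scale = np.abs(S).max() or 1.0
    S = S + (100 * np.finfo(float).eps * scale + np.finfo(float).tiny * 100) * rng.standard_normal((n, n))

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    rows = np.arange(n)
    stable = 0
    exemplars = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        # responsibilities
        AS = A + S
        idx = np.argmax(AS, axis=1)
        first = AS[rows, idx]
        AS[rows, idx] = -np.inf
        second = AS.max(axis=1)
        Rnew = S - first[:, None]
        Rnew[rows, idx] = S[rows, idx] - second
        R = damping * R + (1 - damping) * Rnew
        # availabilities
        Rp = np.maximum(R, 0)
        Rp[rows, rows] = R[rows, rows]
        colsum = Rp.sum(axis=0)
        Anew = np.minimum(0.0, colsum[None, :] - Rp)
        Anew[rows, rows] = colsum - R[rows, rows]
        A = damping * A + (1 - damping) * Anew

        new_exemplars = (np.diag(R) + np.diag(A)) > 0
        if np.array_equal(new_exemplars, exemplars) and new_exemplars.any():
            stable += 1
            if stable >= conv_iter:
                break
        else:
            stable = 0
        exemplars = new_exemplars
    ex = np.nonzero(exemplars)[0]
    if ex.size == 0:
        raise RuntimeError(
            "affinity propagation found no exemplars; try a higher preference"
        )
    labels_ex = np.argmax(S[:, ex], axis=1)
    labels_ex[ex] = np.arange(ex.size)
    result = ClusteringResult(
        gene_ids=list(gene_ids) if gene_ids is not None else [str(i) for i in range(n)],
        labels=labels_ex,
        K=ex.size,
        method="affinity_propagation",
        params={"preference": preference, "damping": damping},
    )
    return result, ex
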