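"""Haar wavelet encoding of expression time series.

Each gene's profile is first resampled onto a uniform dyadic grid of length
``n`` (a power of two, default 64) by piecewise-linear interpolation, then
transformed with the orthonormal Haar wavelet basis.  Orthonormality means
the transform preserves inner products and energy (Parseval), so cosine
similarities computed downstream on coefficients equal those on the
resampled signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionDataset

_SQRT2 = np.sqrt(2.0)


@dataclass
class FeatureMatrix:
    """Per-gene Haar coefficient vectors.

    ``coeffs`` has shape (G, n) with rows ordered as the input genes; columns
    hold the final scaling coefficient followed by detail coefficients from
    coarsest to finest scale.
    """

    gene_ids: list[str]
    coeffs: np.ndarray
    n: int
    basis: str = "haar"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n & (self.n - 1) or self.n < 2:
            raise ValueError(f"n must be a power of 2 >= 2, got {self.n}")
        if self.coeffs.shape != (len(self.gene_ids), self.n):
            raise ValueError("coeffs shape does not match gene_ids / n")


def _check_pow2(n: int) -> None:
    if n < 2 or n & (n - 1):
        raise ValueError(f"length must be a power of 2 >= 2, got {n}")


def resample_series(times, values, n: int) -> np.ndarray:
    """Linearly interpolate (times, values) onto n uniform points.

    Grid point j sits at ``times[0] + j * (times[-1] - times[0]) / (n - 1)``.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 time points to resample")
    if times.size != values.size:
        raise ValueError("times and values differ in length")
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    grid = np.linspace(times[0], times[-1], n)
    return np.interp(grid, times, values)


def haar_dwt(signal: np.ndarray) -> np.ndarray:
    """Full orthonormal Haar transform of a length-2^m signal.

    Accepts a 1-D signal or a 2-D array transformed along the last axis.
    Equivalent to multiplying by the n x n orthonormal Haar matrix: the pair
    (a, b) maps to ((a+b)/sqrt2, (a-b)/sqrt2) recursively on averages.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    n = x.shape[-1]
    _check_pow2(n)
    a = x
    details = []
    while a.shape[-1] > 1:
        even, odd = a[..., 0::2], a[..., 1::2]
        details.append((even - odd) / _SQRT2)
        a = (even + odd) / _SQRT2
    out = np.concatenate([a] + details[::-1], axis=-1)
    return out[0] if np.ndim(signal) == 1 else out


def haar_idwt(coeffs: np.ndarray) -> np.ndarray:
    """Inverse of :func:`haar_dwt`; exact up to floating-point rounding."""
    c = np.atleast_2d(np.asarray(coeffs, dtype=float))
    n = c.shape[-1]
    _check_pow2(n)
    a = c[..., :1]
    pos = 1
    while pos < n:
        d = c[..., pos : 2 * pos]
        out = np.empty(a.shape[:-1] + (2 * pos,), dtype=float)
        out[..., 0::2] = (a + d) / _SQRT2
        out[..., 1::2] = (a - d) / _SQRT2
        a = out
        pos *= 2
    return a[0] if np.ndim(coeffs) == 1 else a


def encode(dataset: ExpressionDataset, n: int = 64, center_genes: bool = False) -> FeatureMatrix:
    """Encode every gene profile as n Haar coefficients.

    Row g of the result is ``haar_dwt(resample_series(t, values[g], n))``;
    gene order is preserved.  With ``center_genes`` each resampled profile is
    mean-centered before the transform (off by default: the downstream cosine
    similarity is already scale-invariant).
    """
    _check_pow2(n)
    grid = np.linspace(dataset.time_stamps[0], dataset.time_stamps[-1], n)
    resampled = np.vstack(
        [np.interp(grid, dataset.time_stamps, row) for row in dataset.values]
    )
    if center_genes:
        resampled = resampled - resampled.mean(axis=1, keepdims=True)
    coeffs = haar_dwt(resampled)
    return FeatureMatrix(
        gene_ids=list(dataset.gene_ids),
        coeffs=coeffs,
        n=n,
        meta={"center_genes": center_genes},
    )
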