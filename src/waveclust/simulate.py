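"""Synthetic time-series expression datasets with ground-truth structure.

The generator emulates a metabolically cycling culture profiled over several
repeated cycles: a few periodic gene groups at evenly spaced phase offsets
plus a larger aperiodic contingent (smoothed random walks), with additive
Gaussian noise.  The first genes of every periodic group form a noiseless
"sentinel" core, mirroring the experimentally validated phase-marker probes
used to audit clusterings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionDataset


@dataclass
class SyntheticSpec:
    """Study-condition parameters of the generator.

    Defaults mimic the yeast-metabolic-cycle design: 36 time points over
    300 minutes spanning 3 repeated cycles, three phase-offset periodic
    groups, and an aperiodic contingent making the periodic genes a minority
    of roughly one half here (one third in the full-genome case).
    """

    n_groups: int = 3
    genes_per_group: int = 50
    n_aperiodic: int = 150
    n_time_points: int = 36
    n_cycles: int = 3
    total_minutes: float = 300.0
    noise_sd: float = 0.2
    amplitude_range: tuple[float, float] = (0.75, 1.25)
    n_sentinels: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_groups, self.genes_per_group, self.n_time_points) < 1:
            raise ValueError("counts must be positive")
        if self.n_aperiodic < 0 or self.n_sentinels < 0:
            raise ValueError("counts must be non-negative")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_sentinels > self.genes_per_group:
            raise ValueError("n_sentinels cannot exceed genes_per_group")


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, np.ndarray, dict[str, list[str]]]:
    """Generate (dataset, true labels, sentinel sets) deterministically.

    Periodic group g has profiles ``a * sin(2 pi n_cycles t / total + phi_g)
    + eps`` with ``phi_g = 2 pi g / n_groups``, amplitude a drawn per gene
    from ``amplitude_range`` and eps ~ N(0, noise_sd^2); the first
    ``n_sentinels`` genes of each group are noise-free.  Aperiodic genes are
    smoothed, standardized random walks.  True label of group g is g;
    aperiodic genes get label ``n_groups``.
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.n_time_points
    # grid chosen so that cycles tile the time axis exactly: t_{j + T/c} = t_j + period
    t = np.arange(T) * spec.total_minutes / T
    omega = 2.0 * np.pi * spec.n_cycles / spec.total_minutes

    gene_ids: list[str] = []
    profiles: list[np.ndarray] = []
    labels: list[int] = []
    sentinels: dict[str, list[str]] = {}
    lo, hi = spec.amplitude_range
    for g in range(spec.n_groups):
        phi = 2.0 * np.pi * g / spec.n_groups
        base = np.sin(omega * t + phi)
        group_sent = []
        for i in range(spec.genes_per_group):
            amp = rng.uniform(lo, hi)
            noise = (
                np.zeros(T) if i < spec.n_sentinels
                else rng.normal(0.0, spec.noise_sd, size=T)
            )
            gid = f"P{g}_{i:03d}"
            gene_ids.append(gid)
            profiles.append(amp * base + noise)
            labels.append(g)
            if i < spec.n_sentinels:
                group_sent.append(gid)
        if group_sent:
            sentinels[f"group{g}"] = group_sent
    for i in range(spec.n_aperiodic):
        walk = np.cumsum(rng.normal(size=T))
        kernel = np.ones(5) / 5.0
        smooth = np.convolve(walk, kernel, mode="same")
        smooth = smooth - smooth.mean()
        sd = smooth.std()
        if sd > 0:
            smooth = smooth / sd
        amp = rng.uniform(lo, hi) * 0.7  # match the rms of a unit sinusoid
        gene_ids.append(f"A_{i:03d}")
        profiles.append(amp * smooth + rng.normal(0.0, spec.noise_sd, size=T))
        labels.append(spec.n_groups)

    dataset = ExpressionDataset(
        gene_ids=gene_ids,
        time_stamps=t,
        values=np.vstack(profiles),
        meta={"generator": "waveclust.simulate", "seed": spec.seed},
    )
    return dataset, np.asarray(labels), sentinels


def write_truth(labels, gene_ids, path) -> None:
    pd.DataFrame({"gene_id": gene_ids, "true_label": labels}).to_csv(path, sep="\t", index=False)


def sentinel_report(
    gene_ids, labels, sentinel_sets: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-sentinel-set assignment purity.

    ``correct`` is 100 x the fraction of the set landing in its majority
    cluster; ``collision`` is the complementary percentage — a set split
    across clusters counts the minority fraction as collisions.
    """
    idx = {g: i for i, g in enumerate(gene_ids)}
    labels = np.asarray(labels)
    rows = []
    for name, genes in sorted(sentinel_sets.items()):
        unknown = [g for g in genes if g not in idx]
        if unknown:
            raise ValueError(f"unknown sentinel id(s) in set {name!r}: {unknown}")
        assigned = labels[[idx[g] for g in genes]]
        values, counts = np.unique(assigned, return_counts=True)
        majority = int(values[np.argmax(counts)])
        correct = 100.0 * counts.max() / len(genes)
        rows.append(
            {
                "set": name,
                "n": len(genes),
                "majority_cluster": majority,
                "correct": correct,
                "collision": 100.0 - correct,
            }
        )
    return pd.DataFrame(rows, columns=["set", "n", "majority_cluster", "correct", "collision"])
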