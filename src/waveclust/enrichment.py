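"""Hypergeometric over-representation test of annotation terms in a cluster.

For a cluster of size n_c drawn from a background of G_b genes, a term
annotating K_t background genes and k cluster genes gets the upper-tail
probability P[X >= k] with X ~ Hypergeometric(G_b, K_t, n_c).
Benjamini-Hochberg q-values are attached across the terms tested within the
cluster.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import AnnotationMap

ENRICHMENT_COLUMNS = ["term", "cluster", "k", "K_t", "n_c", "G_b", "p", "q"]


def enrich(cluster_genes, annotations: AnnotationMap, cluster_name="cluster") -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of every term in one cluster.

    Returns a DataFrame sorted by p with BH-adjusted q-values; one row per
    term that annotates at least one background gene.
    """
    cluster = set(cluster_genes)
    stray = cluster - annotations.background
    if stray:
        raise ValueError(f"cluster genes absent from background: {sorted(stray)}")
    G_b = len(annotations.background)
    n_c = len(cluster)
    rows = []
    for term, genes in sorted(annotations.terms.items()):
        K_t = len(genes)
        k = len(cluster & genes)
        p = float(hypergeom.sf(k - 1, G_b, K_t, n_c))
        rows.append(
            {"term": term, "cluster": cluster_name, "k": k, "K_t": K_t,
             "n_c": n_c, "G_b": G_b, "p": min(p, 1.0)}
        )
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    else:
        df["q"] = np.array([], dtype=float)
    return df


def enrich_all(labels, gene_ids, annotations: AnnotationMap) -> pd.DataFrame:
    """Run :func:`enrich` for every cluster label and concatenate."""
    labels = np.asarray(labels)
    frames = []
    for c in np.unique(labels):
        genes = [g for g, l in zip(gene_ids, labels) if l == c]
        frames.append(enrich(genes, annotations, cluster_name=int(c)))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=ENRICHMENT_COLUMNS)
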