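"""End-to-end pipeline: expression table -> manifold, clusters, network.

Chains wavelet encoding, similarity-graph construction, stochastic
normalization, spectral embedding, local-dimension scoring, clustering,
Delaunay triangulation and (optionally) enrichment, writing all tabular
outputs plus a replayable scenario into an output directory.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, enrichment, io, manifold, similarity, triangulation, wavelets
from .scenario import Scenario, file_digest

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow the reference analysis protocol
    (64 Haar coefficients, k=10 symmetric nearest neighbors, Markov
    normalization, 3-D embedding, 5 k-means restarts over K in 3..15,
    Delaunay filter at p <= 0.001)."""

    wavelet_n: int = 64
    center_genes: bool = False
    similarity: str = "cosine"  # or "heat"
    sigma: float = 1.0
    knn: int = 10
    normalization: str = "markov"
    dims: int = 3
    ld_neighbors: int = 30
    ld_tau: float = 0.95
    k: int | None = None
    k_range: tuple[int, int] | None = (3, 15)
    restarts: int = 5
    divergence: str = "squared_euclidean"
    p_threshold: float = 0.001
    missing_policy: str = "drop_gene"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    dataset: io.ExpressionDataset
    features: wavelets.FeatureMatrix
    graph: similarity.SimilarityGraph
    embedding: manifold.ManifoldEmbedding
    clusters: clustering.ClusteringResult
    selection: clustering.SelectionCurve | None
    network: triangulation.TriangulationResult
    enrichment: pd.DataFrame | None
    scenario: Scenario
    outdir: Path
    outputs: dict = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig,
    expression_path,
    outdir,
    annotations_path=None,
) -> PipelineResult:
    """Run every stage on one expression table and write all outputs.

    Writes manifold.tsv, clusters.tsv, edges.tsv, selection.tsv (when a K
    range is scanned), enrichment.tsv (when annotations are given),
    scenario.txt and run.log under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("waveclust")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    scen = Scenario()
    try:
        dataset = io.read_expression(expression_path, missing_policy=config.missing_policy)
        scen.record(
            "read_expression",
            {"expression_path": str(expression_path), "missing_policy": config.missing_policy},
            {"in:expression": file_digest(expression_path)},
        )

        features = wavelets.encode(dataset, n=config.wavelet_n, center_genes=config.center_genes)
        scen.record("encode", {"wavelet_n": config.wavelet_n, "center_genes": config.center_genes})

        if config.similarity == "cosine":
            dense = similarity.build_W(features)
        elif config.similarity == "heat":
            dense = similarity.heat_kernel_W(features, sigma=config.sigma)
        else:
            raise ValueError(f"unknown similarity {config.similarity!r}")
        scen.record("similarity", {"similarity": config.similarity, "sigma": config.sigma})

        graph = similarity.sparsify_symmetric_knn(dense, k=config.knn)
        scen.record("sparsify", {"knn": config.knn})

        N = manifold.normalize_stochastic(graph, method=config.normalization)
        scen.record("normalize", {"normalization": config.normalization})

        embedding = manifold.eigen_embed(
            N, d=config.dims, gene_ids=dataset.gene_ids, normalization=config.normalization
        )
        scen.record("embed", {"dims": config.dims})

        embedding.local_dim = manifold.local_dimension(
            features, embedding.coords, k_nb=config.ld_neighbors, tau=config.ld_tau
        )
        scen.record("local_dimension", {"ld_neighbors": config.ld_neighbors, "ld_tau": config.ld_tau})

        selection = None
        if config.k is not None:
            clusters = clustering.bregman_kmeans(
                embedding.coords,
                K=config.k,
                divergence=config.divergence,
                restarts=config.restarts,
                seed=config.seed,
                gene_ids=dataset.gene_ids,
            )
            scen.record(
                "cluster_kmeans",
                {"k": config.k, "restarts": config.restarts,
                 "divergence": config.divergence, "seed": config.seed},
            )
        else:
            lo, hi = config.k_range
            selection = clustering.selection_curve(
                embedding.coords,
                range(lo, hi + 1),
                restarts=config.restarts,
                seed=config.seed,
                divergence=config.divergence,
                gene_ids=dataset.gene_ids,
            )
            clusters = selection.best[selection.best_k]
            scen.record(
                "selection_curve",
                {"k_range": [lo, hi], "restarts": config.restarts,
                 "divergence": config.divergence, "seed": config.seed,
                 "selected_k": selection.best_k},
            )

        edges = triangulation.delaunay_edges(embedding.coords, seed=config.seed)
        scored = triangulation.score_edges(edges, dataset, embedding.coords, seed=config.seed)
        network = triangulation.filter_and_stats(scored, p_threshold=config.p_threshold)
        scen.record("triangulate", {"p_threshold": config.p_threshold, "seed": config.seed})

        enr = None
        if annotations_path is not None:
            ann = io.read_annotations(annotations_path)
            keep = [g in ann.background for g in dataset.gene_ids]
            enr = enrichment.enrich_all(
                clusters.labels[np.asarray(keep)],
                [g for g, k in zip(dataset.gene_ids, keep) if k],
                ann,
            )
            scen.record(
                "enrich",
                {"annotations_path": str(annotations_path)},
                {"in:annotations": file_digest(annotations_path)},
            )

        outputs = _write_outputs(outdir, dataset, embedding, clusters, selection, network, enr)
        scen.save(outdir / "scenario.txt")
        outputs["scenario"] = outdir / "scenario.txt"
        return PipelineResult(
            dataset=dataset,
            features=features,
            graph=graph,
            embedding=embedding,
            clusters=clusters,
            selection=selection,
            network=network,
            enrichment=enr,
            scenario=scen,
            outdir=outdir,
            outputs=outputs,
        )
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _write_outputs(outdir, dataset, embedding, clusters, selection, network, enr) -> dict:
    outputs = {}
    coords_df = pd.DataFrame(
        embedding.coords, columns=[f"c{j + 1}" for j in range(embedding.d)]
    )
    coords_df.insert(0, "gene_id", dataset.gene_ids)
    io.write_table(coords_df, outdir / "manifold.tsv")
    outputs["manifold"] = outdir / "manifold.tsv"

    clusters_df = pd.DataFrame(
        {
            "gene_id": dataset.gene_ids,
            "cluster": clusters.labels,
            "local_dimension": embedding.local_dim,
        }
    )
    io.write_table(clusters_df, outdir / "clusters.tsv")
    outputs["clusters"] = outdir / "clusters.tsv"

    io.write_table(network.edges, outdir / "edges.tsv")
    outputs["edges"] = outdir / "edges.tsv"

    if selection is not None:
        sel_df = pd.DataFrame(
            {
                "K": selection.k_values,
                "mean_potential": selection.mean_potential,
                "sd_potential": selection.sd_potential,
            }
        )
        io.write_table(sel_df, outdir / "selection.tsv")
        outputs["selection"] = outdir / "selection.tsv"
    if enr is not None:
        io.write_table(enr, outdir / "enrichment.tsv")
        outputs["enrichment"] = outdir / "enrichment.tsv"
    return outputs
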