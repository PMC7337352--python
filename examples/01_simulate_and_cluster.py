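"""Full pipeline on a synthetic metabolically cycling culture.

Generates 3 phase-offset periodic gene groups (50 genes each, 10 noiseless
sentinels per group) plus 150 aperiodic genes over 36 time points / 3 cycles,
runs the default protocol (64 Haar coefficients, k=10 symmetric NN, Markov
normalization, 3-D embedding, K=4 Bregman k-means with 5 restarts), and
audits the result against the planted ground truth.
"""

import tempfile
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from waveclust import PipelineConfig, run_pipeline, sentinel_report
from waveclust.simulate import SyntheticSpec, generate

spec = SyntheticSpec(seed=1)
dataset, truth, sentinels = generate(spec)

with tempfile.TemporaryDirectory() as tmp:
    expr = Path(tmp) / "expression.tsv"
    df = pd.DataFrame(dataset.values, columns=[f"{t:g}" for t in dataset.time_stamps])
    df.insert(0, "gene_id", dataset.gene_ids)
    df.to_csv(expr, sep="\t", index=False)

    result = run_pipeline(PipelineConfig(k=4, k_range=None, seed=1), expr, Path(tmp) / "out")

ari = adjusted_rand_score(truth, result.clusters.labels)
print(f"genes: {dataset.n_genes}, time points: {dataset.n_time_points}")
print(f"adjusted Rand index vs planted groups: {ari:.3f}")
print(sentinel_report(dataset.gene_ids, result.clusters.labels, sentinels).to_string(index=False))
print(
    "\nARI near 1 means the 4 planted groups (3 phases + aperiodic) were recovered;"
    "\ncorrect=100/collision=0 means each noiseless sentinel core stayed in one cluster."
)
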