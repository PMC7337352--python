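import numpy as np
import pandas as pd
import pytest

from waveclust import PipelineConfig, run_pipeline
from waveclust.simulate import SyntheticSpec, generate


def write_expression_tsv(dataset, path):
    df = pd.DataFrame(dataset.values, columns=[f"{t:g}" for t in dataset.time_stamps])
    df.insert(0, "gene_id", dataset.gene_ids)
    df.to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def tiny_tsv(tmp_path):
    """3-gene, 4-time-point expression table with no gaps."""
    p = tmp_path / "tiny.tsv"
    p.write_text(
        "gene_id\t0\t10\t20\t30\n"
        "g1\t1.0\t2.0\t3.0\t4.0\n"
        "g2\t0.5\t0.5\t0.5\t0.5\n"
        "g3\t4.0\t3.0\t2.0\t1.0\n"
    )
    return p


@pytest.fixture(scope="session")
def ymc_like():
    """The planted-structure study fixture: 3 phase groups x 50 genes +
    150 aperiodic genes, T=36 over 3 cycles of 300 minutes, noise sd 0.2."""
    spec = SyntheticSpec(seed=1)
    dataset, labels, sentinels = generate(spec)
    return spec, dataset, labels, sentinels


@pytest.fixture(scope="session")
def ymc_run(ymc_like, tmp_path_factory):
    """One full default-protocol pipeline run (K=4) on the planted fixture,
    shared across tests that only read its outputs."""
    _, dataset, labels, sentinels = ymc_like
    root = tmp_path_factory.mktemp("ymc_run")
    expr = write_expression_tsv(dataset, root / "expression.tsv")
    config = PipelineConfig(k=4, k_range=None, seed=1)
    result = run_pipeline(config, expr, root / "out")
    return {
        "expression": expr,
        "config": config,
        "labels": labels,
        "sentinels": sentinels,
        "result": result,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
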