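"""Scenario recording and replay.

Every pipeline run appends one record per executed operation — operation
name, full parameter map including the RNG seed, and digests of the files it
read or wrote — to a line-oriented text scenario.  Loading a scenario and
replaying it reproduces the full analysis: deterministic stages are
bit-identical, stochastic stages are identical given the recorded seeds.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__

#: operations a scenario may legally contain
REGISTERED_OPS = frozenset(
    {
        "generate",
        "read_expression",
        "encode",
        "similarity",
        "sparsify",
        "normalize",
        "embed",
        "local_dimension",
        "cluster_kmeans",
        "selection_curve",
        "cluster_nnmf",
        "cluster_ap",
        "triangulate",
        "enrich",
    }
)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class ScenarioRecord:
    step: int
    op: str
    params: dict
    digests: dict = field(default_factory=dict)


@dataclass
class Scenario:
    records: list[ScenarioRecord] = field(default_factory=list)
    version: str = __version__

    def record(self, op: str, params: dict, digests: dict | None = None) -> ScenarioRecord:
        if op not in REGISTERED_OPS:
            raise ValueError(f"unregistered operation {op!r}")
        rec = ScenarioRecord(
            step=len(self.records) + 1,
            op=op,
            params=dict(params),
            digests=dict(digests or {}),
        )
        self.records.append(rec)
        return rec

    def save(self, path) -> None:
        lines = [f"#waveclust-scenario\tversion={self.version}"]
        for rec in self.records:
            lines.append(
                "\t".join(
                    [
                        str(rec.step),
                        rec.op,
                        json.dumps(rec.params, sort_keys=True),
                        json.dumps(rec.digests, sort_keys=True),
                    ]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n")

    #: merged parameter map over all records (later steps win)
    def merged_params(self) -> dict:
        out: dict = {}
        for rec in self.records:
            out.update(rec.params)
        return out


def load(path) -> Scenario:
    """Parse a scenario file; malformed lines raise with their line number."""
    scenario = Scenario()
    text = Path(path).read_text().splitlines()
    expected_step = 1
    for ln, line in enumerate(text, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}:{ln}: expected 4 tab-separated fields, got {len(parts)}")
        try:
            step = int(parts[0])
            params = json.loads(parts[2])
            digests = json.loads(parts[3])
        except (ValueError, json.JSONDecodeError) as exc:
            raise ValueError(f"{path}:{ln}: malformed record: {exc}") from exc
        op = parts[1]
        if op not in REGISTERED_OPS:
            raise ValueError(f"{path}:{ln}: unknown operation {op!r}")
        if step != expected_step:
            raise ValueError(f"{path}:{ln}: step {step}, expected {expected_step}")
        expected_step += 1
        scenario.records.append(ScenarioRecord(step=step, op=op, params=params, digests=digests))
    return scenario


def replay(scenario: Scenario, outdir, data_paths: dict | None = None, strict: bool = False):
    """Re-execute a recorded pipeline run.

    ``data_paths`` may override the recorded ``expression`` / ``annotations``
    input paths.  Input digests are verified against the recording: a
    mismatch warns, or raises when ``strict``.  Returns the
    :class:`~waveclust.pipeline.PipelineResult` of the re-run.
    """
    from .pipeline import PipelineConfig, run_pipeline

    data_paths = data_paths or {}
    merged = scenario.merged_params()
    expression = data_paths.get("expression", merged.get("expression_path"))
    annotations = data_paths.get("annotations", merged.get("annotations_path"))
    if expression is None:
        raise ValueError("scenario records no expression path and none was supplied")
    if not Path(expression).exists():
        raise FileNotFoundError(expression)

    for rec in scenario.records:
        for name, digest in rec.digests.items():
            if name.startswith("in:"):
                target = data_paths.get("expression") if name == "in:expression" else None
                target = target or rec.params.get("expression_path") or name[3:]
                if Path(target).exists() and file_digest(target) != digest:
                    msg = f"input digest mismatch for {target} (step {rec.step})"
                    if strict:
                        raise ValueError(msg)
                    warnings.warn(msg)

    config_fields = set(PipelineConfig.__dataclass_fields__)
    config = PipelineConfig(**{k: v for k, v in merged.items() if k in config_fields})
    if "k_range" in merged and merged["k_range"] is not None:
        config.k_range = tuple(merged["k_range"])
    return run_pipeline(config, expression, outdir, annotations_path=annotations)
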