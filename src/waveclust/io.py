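"""Reading and writing expression matrices, annotation maps, and tabular outputs.

Expression input is a TSV/CSV table whose first column holds gene (probe)
identifiers and whose header row carries the time stamps in minutes.  All
pipeline outputs are plain TSV so that every writer has a matching reader
and results round-trip exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tokens treated as missing values in expression tables
MISSING_TOKENS = ("", "NA", "NaN", "nan")

#: float format used by every table writer; 10 significant digits round-trip
#: well within the 1e-9 tolerance the writers promise
FLOAT_FORMAT = "%.10g"


@dataclass
class ExpressionDataset:
    """A gene x time-point expression matrix.

    Parameters
    ----------
    gene_ids
        Unique gene/probe identifiers, one per row of ``values``.
    time_stamps
        Strictly increasing time stamps in minutes, one per column.
    values
        Expression matrix of shape (G, T), no missing values.
    meta
        Free-form key/value header information.
    """

    gene_ids: list[str]
    time_stamps: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_stamps = np.asarray(self.time_stamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        g, t = self.values.shape
        if g < 2:
            raise ValueError(f"need at least 2 genes, got {g}")
        if t < 2:
            raise ValueError(f"need at least 2 time points, got {t}")
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length does not match values rows")
        if len(self.time_stamps) != t:
            raise ValueError("time_stamps length does not match values columns")
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise ValueError(f"duplicate gene ids: {sorted(dupes)}")
        if np.any(np.diff(self.time_stamps) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if np.isnan(self.values).any():
            raise ValueError("expression values contain NaN after loading")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_time_points(self) -> int:
        return self.values.shape[1]


@dataclass
class AnnotationMap:
    """Term -> gene-set annotation map with an explicit background."""

    terms: dict[str, set[str]]
    background: set[str]

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} annotates no genes")
            stray = genes - self.background
            if stray:
                raise ValueError(
                    f"term {term!r} annotates genes absent from background: {sorted(stray)}"
                )


def _duplicates(items) -> set:
    seen: set = set()
    dup: set = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_expression(path, missing_policy: str = "drop_gene") -> ExpressionDataset:
    """Load an expression table.

    The first column is the gene id; the header row carries numeric time
    stamps.  If the header is not numeric, uniform integer stamps 0..T-1 are
    substituted with a warning.  Missing cells (empty, ``NA``, ``NaN``) are
    handled per ``missing_policy``: ``drop_gene`` removes the affected rows,
    ``interpolate`` fills each gap by linear interpolation along the row
    (edge gaps take the nearest observed value).
    """
    path = Path(path)
    if missing_policy not in ("drop_gene", "interpolate"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    sep = _sniff_sep(path)
    df = pd.read_csv(
        path, sep=sep, index_col=0, dtype=str, keep_default_na=False, skipinitialspace=True
    )
    if df.shape[1] < 2:
        raise ValueError(f"need at least 2 time-point columns, got {df.shape[1]}")
    gene_ids = [str(g) for g in df.index]
    dupes = _duplicates(gene_ids)
    if dupes:
        raise ValueError(f"duplicate gene id(s) in {path.name}: {sorted(dupes)}")

    try:
        stamps = np.array([float(c) for c in df.columns])
    except ValueError:
        logger.warning(
            "non-numeric time-stamp header in %s; using uniform stamps 0..%d",
            path.name,
            df.shape[1] - 1,
        )
        stamps = np.arange(df.shape[1], dtype=float)
    else:
        if np.any(np.diff(stamps) <= 0):
            raise ValueError("time stamps in header are not strictly increasing")

    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    missing = np.zeros(raw.shape, dtype=bool)
    for (i, j), tok in np.ndenumerate(raw):
        tok = tok.strip()
        if tok in MISSING_TOKENS:
            missing[i, j] = True
            values[i, j] = np.nan
        else:
            values[i, j] = float(tok)  # non-numeric cell raises here

    bad_rows = missing.any(axis=1)
    n_bad = int(bad_rows.sum())
    if n_bad:
        if missing_policy == "drop_gene":
            logger.info("dropped %d gene(s) with missing values", n_bad)
            keep = ~bad_rows
            gene_ids = [g for g, k in zip(gene_ids, keep) if k]
            values = values[keep]
        else:
            for i in np.nonzero(bad_rows)[0]:
                ok = ~missing[i]
                if ok.sum() < 2:
                    raise ValueError(
                        f"gene {gene_ids[i]!r} has fewer than 2 observed values"
                    )
                values[i, missing[i]] = np.interp(
                    stamps[missing[i]], stamps[ok], values[i, ok]
                )
            logger.info("interpolated missing values in %d gene(s)", n_bad)

    return ExpressionDataset(
        gene_ids=gene_ids,
        time_stamps=stamps,
        values=values,
        meta={"source": str(path), "missing_policy": missing_policy, "n_repaired": n_bad},
    )


def read_annotations(path) -> AnnotationMap:
    """Load a two-column gene<TAB>term file into an :class:`AnnotationMap`.

    The background is the set of all genes seen in the file.  Blank lines are
    skipped with a log message.
    """
    path = Path(path)
    terms: dict[str, set[str]] = {}
    background: set[str] = set()
    n_lines = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                logger.info("skipping blank line %d in %s", ln, path.name)
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path.name}:{ln}: expected gene<TAB>term, got {line!r}")
            gene, term = parts[0].strip(), parts[1].strip()
            terms.setdefault(term, set()).add(gene)
            background.add(gene)
            n_lines += 1
    if n_lines == 0:
        raise ValueError(f"annotation file {path.name} is empty")
    return AnnotationMap(terms=terms, background=background)


def write_table(rows, path, columns: list[str] | None = None) -> None:
    """Write tabular records as TSV with stable float formatting.

    ``rows`` may be a DataFrame or a list of dicts.  An empty record list
    yields a header-only file (``columns`` must then be given or rows must be
    a DataFrame).
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows), columns=columns)
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
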