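"""Readers and writers: data matrices, edge-list/SIF networks, result tables."""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .network import DirectedNetwork, PathwayRanking
from .simulation import EvaluationResult

__all__ = [
    "read_data_matrix",
    "read_network",
    "write_ranking",
    "write_evaluation_table",
    "file_digest",
]

logger = logging.getLogger("mccsp")

_HEADER_TOKENS = {("from", "to"), ("source", "target"), ("from", "interaction", "to")}


def file_digest(path) -> str:
    """Short sha256 digest of a file, for run logging."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def read_data_matrix(path) -> pd.DataFrame:
    """Samples x nodes matrix from delimited text (CSV or TSV) with a header row.

    Rows containing any missing value are dropped (count logged).  Duplicate
    column names or non-numeric cells raise a ConfigurationError naming the
    offender.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    names = [h.strip() for h in header]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ConfigurationError(f"duplicate column names in {path.name}: {dupes}")
    df = pd.read_csv(path, sep=sep)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ConfigurationError(
                    f"non-numeric value {df[col].iloc[row]!r} at row {row + 2}, "
                    f"column '{col}' of {path.name}")
            df[col] = coerced
    n_before = df.shape[0]
    df = df.dropna(axis=0, how="any").reset_index(drop=True)
    if df.shape[0] < n_before:
        logger.warning("dropped %d row(s) with missing values from %s",
                       n_before - df.shape[0], path.name)
    return df


def read_network(path, source: str, sink: str) -> DirectedNetwork:
    """Validated DAG from a 2-column TSV edge list or a 3-column SIF file.

    SIF lines are ``from <interaction> to``; the middle token is ignored.
    A header line (``from\\tto`` or similar) is skipped if present.
    """
    path = Path(path)
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and tuple(p.lower() for p in parts) in _HEADER_TOKENS:
                continue
            if len(parts) == 2:
                edges.append((parts[0], parts[1]))
            elif len(parts) == 3:  # SIF: from interaction to
                edges.append((parts[0], parts[2]))
            else:
                raise ConfigurationError(
                    f"{path.name}:{lineno}: expected 2 (edge list) or 3 (SIF) "
                    f"columns, got {len(parts)}")
    if not edges:
        raise ConfigurationError(f"no edges found in {path.name}")
    nodes = sorted({n for e in edges for n in e})
    return DirectedNetwork(nodes, edges, source=source, sink=sink)


def _fmt(x: float | None) -> str:
    return "NA" if x is None else f"{x:.4g}"


def write_ranking(ranking: PathwayRanking, path) -> None:
    """Tab-separated ranking table: rank, pathway, effect, total_weight, PIS."""
    lines = ["rank\tpathway\teffect\ttotal_weight\tPIS"]
    for i, p in enumerate(ranking.pathways, start=1):
        lines.append("\t".join([str(i), "->".join(p.nodes), _fmt(p.effect),
                                _fmt(p.total_weight), _fmt(p.pis)]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_evaluation_table(results: list[EvaluationResult], path) -> None:
    """Benchmark summary table: rows sample x criterion, columns methods."""
    methods = sorted({r.method for r in results})
    sizes = sorted({r.sample_size for r in results})
    by_key = {(r.sample_size, r.method): r for r in results}
    lines = ["sample\tcriterion\t" + "\t".join(methods)]
    for n in sizes:
        for crit, attr in (("all-right", "all_right_count"),
                           ("range-right", "range_right_count")):
            cells = []
            for m in methods:
                r = by_key.get((n, m))
                cells.append(str(getattr(r, attr)) if r is not None else "NA")
            lines.append(f"{n}\t{crit}\t" + "\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")
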