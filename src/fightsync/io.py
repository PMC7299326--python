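"""Plain-text readers and writers for the pipeline's tabular artifacts.

Count matrices travel as TSV (first column = gene id, header = sample ids),
sample designs and behavioral event logs as CSV. Every writer accepts an
optional ``header_comments`` mapping that is emitted as ``# key=value``
lines before the table, so provenance (seed, thresholds, config hash) rides
along with the data.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping

import pandas as pd

DESIGN_COLUMNS = ["sample_id", "group", "pair_id", "fish_id"]
EVENT_COLUMNS = ["pair_id", "fish_id", "behavior", "start_min", "duration_min"]


def _write_with_comments(df: pd.DataFrame, path, sep: str, index: bool,
                         header_comments: Mapping[str, object] | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    if header_comments:
        for key, val in header_comments.items():
            buf.write(f"# {key}={val}\n")
    df.to_csv(buf, sep=sep, index=index)
    path.write_text(buf.getvalue())


def write_counts(counts: pd.DataFrame, path, header_comments=None) -> None:
    """Write a gene-by-sample count matrix as TSV (index column = gene id)."""
    df = counts.copy()
    df.index.name = df.index.name or "gene_id"
    _write_with_comments(df, path, sep="\t", index=True,
                         header_comments=header_comments)


def read_counts(path) -> pd.DataFrame:
    """Read a gene-by-sample count matrix written by :func:`write_counts`."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups[:5]}")
    return df


def write_design(design: pd.DataFrame, path, header_comments=None) -> None:
    _write_with_comments(design[DESIGN_COLUMNS], path, sep=",", index=False,
                         header_comments=header_comments)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"pair_id": "string"})
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"design table {path} lacks columns: {sorted(missing)}")
    return df[DESIGN_COLUMNS]


def write_events(events: pd.DataFrame, path, duration_min: float,
                 header_comments=None) -> None:
    comments = {"observation_duration_min": duration_min}
    if header_comments:
        comments.update(header_comments)
    _write_with_comments(events[EVENT_COLUMNS], path, sep=",", index=False,
                         header_comments=comments)


def read_events(path) -> tuple[pd.DataFrame, float]:
    """Read an event-log CSV; returns (events, observation duration in min)."""
    duration = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "observation_duration_min":
                duration = float(val)
    df = pd.read_csv(path, comment="#")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event log {path} lacks columns: {sorted(missing)}")
    if duration is None:
        duration = float((df["start_min"] + df["duration_min"]).max())
    return df[EVENT_COLUMNS], duration


def write_gene_set(genes, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_set(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines()
            if line.strip() and not line.startswith("#")]
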