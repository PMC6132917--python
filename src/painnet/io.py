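"""Readers and writers for the pipeline's tabular formats.

All files are UTF-8 tab-separated values with a header row and '.' decimal:
time series (frames x nodes, header = node labels), motion traces (frames x
6, standard column names), labeled square adjacency matrices, cohort tables
and topology summaries.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .types import MOTION_COLUMNS, AdjacencyMatrix, MotionTrace, RoiTimeSeries


def read_timeseries_tsv(path: str | Path, tr_seconds: float = 2.15) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return RoiTimeSeries(df.to_numpy(dtype=float), tuple(df.columns), tr_seconds)


def read_motion_tsv(path: str | Path) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"motion file {path} lacks columns: {missing}")
    return MotionTrace(df[list(MOTION_COLUMNS)].to_numpy(dtype=float))


def write_adjacency_tsv(adj: AdjacencyMatrix, path: str | Path) -> None:
    labels = list(adj.node_labels)
    pd.DataFrame(adj.weights, index=labels, columns=labels).to_csv(
        path, sep="\t", index_label="node"
    )


def read_adjacency_tsv(path: str | Path) -> AdjacencyMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AdjacencyMatrix(df.to_numpy(dtype=float), tuple(df.columns))


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_summary_tsv(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_summary_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
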