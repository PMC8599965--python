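"""Delimited-text I/O for timecourses, tables and matrices.

All tables are TSV with a header row; timecourse files have channels as
columns and volumes as rows; square matrices are written as TSV with node
labels.  Floats round-trip bit-identically (written with 17 significant
digits); NaN markers are preserved.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_table",
    "write_table",
    "read_matrix",
    "write_matrix",
]

_FLOAT_FMT = "%.17g"


def write_timeseries(data: np.ndarray, path, channel_names=None) -> None:
    data = np.asarray(data)
    if channel_names is None:
        channel_names = [f"IC{j:02d}" for j in range(data.shape[1])]
    pd.DataFrame(data, columns=channel_names).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_timeseries(path) -> tuple[np.ndarray, list]:
    """Read a channels-as-columns TSV; returns (T x C array, channel names)."""
    df = _read_tsv(path)
    return df.to_numpy(dtype=float), list(df.columns)


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_matrix(M: np.ndarray, path, labels=None) -> None:
    M = np.asarray(M)
    if labels is None:
        labels = [f"node{j}" for j in range(M.shape[0])]
    pd.DataFrame(M, index=labels, columns=labels).to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_matrix(path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), list(df.columns)


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != ncol:
                raise ValueError(f"{path}: row {lineno} has wrong column count")
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
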