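"""Tabular I/O helpers (TSV conventions shared by all stages)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "read_expression",
    "write_matrix",
    "read_matrix",
    "read_groups",
    "write_labels",
    "read_labels",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples expression TSV (header = sample ids)."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if expr.empty:
        raise ValueError(f"{path}: empty expression matrix")
    if (expr.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression values")
    return expr


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    matrix.rename_axis(index_label).to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_groups(path: str | Path) -> pd.Series:
    """Read a two-column sample_id / group TSV into a Series."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    series = table.iloc[:, 0].astype(str)
    bad = set(series.unique()) - {"normal", "tumor"}
    if bad:
        raise ValueError(f"{path}: unknown group labels {sorted(bad)}")
    series.name = "group"
    return series


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename("subtype").rename_axis("sample_id").to_frame().to_csv(path, sep="\t")


def read_labels(path: str | Path) -> pd.Series:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return table.iloc[:, 0]
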