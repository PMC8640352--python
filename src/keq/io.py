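"""Readers and writers for delimited score-frequency tables.

Two schemas are supported (TSV or CSV, header required):

* univariate — columns ``score, count``;
* bivariate — columns ``x_score, a_score, count``.

Scores must be integers and counts nonnegative integers; interior score
points missing from the file are padded with zero counts so the grid is
always complete.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import BivariateScoreTable, DiscreteScoreDistribution

__all__ = ["read_frequency_table", "write_frequency_table"]


class ParseError(ValueError):
    pass


def _read_delimited(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def _check_integer(df: pd.DataFrame, col: str, path, nonneg=False) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() | (vals != np.floor(vals)) | (nonneg & (vals < 0))
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ParseError(f"{path}: invalid {col!r} value on line {line}")
    return vals.to_numpy(dtype=int)


def read_frequency_table(path):
    """Read a frequency table, returning the matching domain type."""
    path = Path(path)
    df = _read_delimited(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if cols == ["score", "count"]:
        scores = _check_integer(df, "score", path)
        counts = _check_integer(df, "count", path, nonneg=True)
        if np.unique(scores).size != scores.size:
            raise ParseError(f"{path}: duplicate score rows")
        grid = np.arange(scores.min(), scores.max() + 1)
        full = np.zeros(grid.size)
        full[scores - scores.min()] = counts
        return DiscreteScoreDistribution.from_counts(grid, full)
    if cols == ["x_score", "a_score", "count"]:
        x = _check_integer(df, "x_score", path)
        a = _check_integer(df, "a_score", path)
        counts = _check_integer(df, "count", path, nonneg=True)
        if pd.DataFrame({"x": x, "a": a}).duplicated().any():
            raise ParseError(f"{path}: duplicate (x_score, a_score) rows")
        xg = np.arange(x.min(), x.max() + 1)
        ag = np.arange(a.min(), a.max() + 1)
        table = np.zeros((xg.size, ag.size))
        table[x - x.min(), a - a.min()] = counts
        return BivariateScoreTable.from_counts(xg, ag, table)
    raise ParseError(
        f"{path}: expected columns (score, count) or (x_score, a_score, count),"
        f" got {cols}")


def write_frequency_table(obj, path) -> None:
    """Write a distribution or bivariate table in the matching schema."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    if isinstance(obj, DiscreteScoreDistribution):
        counts = obj.counts if obj.counts is not None else obj.probs * (obj.n or 1)
        df = pd.DataFrame({"score": obj.scores.astype(int),
                           "count": np.round(counts).astype(int)})
    elif isinstance(obj, BivariateScoreTable):
        counts = obj.counts if obj.counts is not None else obj.probs * (obj.n or 1)
        xg, ag = np.meshgrid(obj.x_scores.astype(int), obj.a_scores.astype(int),
                             indexing="ij")
        df = pd.DataFrame({"x_score": xg.ravel(), "a_score": ag.ravel(),
                           "count": np.round(counts).astype(int).ravel()})
    else:
        raise TypeError("expected a DiscreteScoreDistribution or BivariateScoreTable")
    df.to_csv(path, sep=sep, index=False)
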