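"""Delimited-text formats and result serialization.

Conventions: expression/series matrices are variables-in-rows tables
whose first column holds the variable name and whose header row holds
time labels (TSV or CSV). Ground-truth networks are two-column edge
lists (source, target), one directed edge per line, ``#`` comments
allowed. Score matrices round-trip at 12 significant digits; ROC results
serialize to JSON at 6.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError

__all__ = [
    "TimeSeriesMatrix",
    "read_timeseries",
    "write_timeseries",
    "read_edges",
    "write_edges",
    "read_matrix",
    "write_matrix",
    "write_roc",
    "write_calls",
]


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """A G-by-T block of observations: G named variables, T time labels.

    Missing values are rejected outright: with ~10 samples per series
    any imputation would dominate the analysis.
    """

    names: tuple[str, ...]
    times: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "times", tuple(self.times))
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape != (len(names), len(self.times)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(names)} names x {len(self.times)} times"
            )
        if len(names) < 1:
            raise ValueError("need at least one variable")
        if len(self.times) < 3:
            raise ValueError("need at least 3 time points")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate variable names: {dupes}")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite (no missing entries)")

    @property
    def n_variables(self) -> int:
        return len(self.names)

    @property
    def n_timepoints(self) -> int:
        return len(self.times)

    def series(self, name: str) -> np.ndarray:
        return self.values[self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.names), columns=list(self.times))


def _dialect_sep(path: str | Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if str(path).lower().endswith(".csv") else "tsv"
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r} (use 'tsv' or 'csv')")
    return "," if dialect == "csv" else "\t"


def read_timeseries(
    path: str | Path,
    dialect: str | None = None,
    orientation: str = "variables-in-rows",
) -> TimeSeriesMatrix:
    """Read a delimited series matrix; see module docstring for layout.

    ``orientation='time-in-rows'`` transposes on read. Parse failures
    (ragged rows, non-numeric cells, duplicated names) raise
    :class:`ParseError` citing the offending line of the file.
    """
    sep = _dialect_sep(path, dialect)
    try:
        raw = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if raw.index.isnull().any() or raw.isnull().any().any():
        line = int(np.flatnonzero(raw.isnull().any(axis=1) | raw.index.isnull())[0]) + 2
        raise ParseError(f"{path}: ragged or empty row at line {line}")
    labels = [str(v) for v in raw.index]
    seen: dict[str, int] = {}
    for pos, name in enumerate(labels):
        if name in seen:
            raise ParseError(
                f"{path}: duplicate name {name!r} at line {pos + 2} "
                f"(first seen at line {seen[name] + 2})"
            )
        seen[name] = pos
    values = np.empty(raw.shape)
    for i, (name, row) in enumerate(raw.iterrows()):
        for j, cell in enumerate(row):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at line {i + 2}, "
                    f"column {raw.columns[j]!r}"
                ) from None
    times: tuple = tuple(raw.columns)
    if orientation == "time-in-rows":
        labels, times, values = list(times), tuple(labels), values.T
    elif orientation != "variables-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return TimeSeriesMatrix(names=tuple(labels), times=times, values=values)


def write_timeseries(
    data: TimeSeriesMatrix, path: str | Path, dialect: str | None = None
) -> None:
    sep = _dialect_sep(path, dialect)
    data.to_frame().to_csv(path, sep=sep, index_label="name", float_format="%.12g")


def read_edges(path: str | Path, names: tuple[str, ...] | None = None):
    """Read a two-column directed edge list into a ground-truth network.

    Lines starting with ``#`` and blank lines are skipped. If ``names``
    is omitted, the variable universe is the set of endpoints seen.
    """
    from .simulators import GroundTruthNetwork

    edges: set[tuple[str, str]] = set()
    seen: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.replace(",", "\t").split("\t")
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) != 2:
                raise ParseError(
                    f"{path}: expected two columns (source, target) at line {lineno}"
                )
            src, tgt = parts
            edges.add((src, tgt))
            for v in (src, tgt):
                if v not in seen:
                    seen.append(v)
    universe = tuple(names) if names is not None else tuple(seen)
    unknown = sorted({v for e in edges for v in e if v not in universe})
    if unknown:
        raise ParseError(f"{path}: edges reference unknown variables: {unknown}")
    return GroundTruthNetwork(names=universe, edges=frozenset(edges))


def write_edges(truth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# source\ttarget\n")
        for src, tgt in sorted(truth.edges):
            fh.write(f"{src}\t{tgt}\n")


def read_matrix(path: str | Path, dialect: str | None = None):
    """Read a square score matrix (rows -> columns) written by write_matrix."""
    from .tep import CausalityMatrix

    sep = _dialect_sep(path, dialect)
    frame = pd.read_csv(path, sep=sep, header=0, index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ParseError(f"{path}: row and column names disagree")
    return CausalityMatrix(names=tuple(str(n) for n in frame.index), scores=frame.to_numpy(float))


def write_matrix(matrix, path: str | Path, dialect: str | None = None) -> None:
    sep = _dialect_sep(path, dialect)
    matrix.to_frame().to_csv(path, sep=sep, index_label="name", float_format="%.12g")


def write_roc(result, path: str | Path) -> None:
    """Serialize a ROC result as JSON (curve arrays, AUC, class counts)."""
    payload = {
        "fpr": [round(float(v), 6) for v in result.fpr],
        "tpr": [round(float(v), 6) for v in result.tpr],
        "auc": round(float(result.auc), 6),
        "n_positive": int(result.n_positive),
        "n_negative": int(result.n_negative),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def write_calls(names, calls: np.ndarray, path: str | Path) -> None:
    """Write a binary call matrix (rows -> columns) as 0/1 TSV; the
    diagonal is left empty (self-causation undefined)."""
    frame = pd.DataFrame(calls.astype(int), index=list(names), columns=list(names))
    frame = frame.astype(object)
    for i in range(len(names)):
        frame.iat[i, i] = ""
    frame.to_csv(path, sep="\t", index_label="name")
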