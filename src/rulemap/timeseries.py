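"""GDAT/CDAT time-series containers and I/O.

Both formats are whitespace-delimited numeric tables, first column time,
with an optional ``#``-prefixed header naming the columns — GDAT for
observables, CDAT for individual species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import BnglError, Diagnostic


@dataclass
class TimeSeries:
    times: np.ndarray
    values: np.ndarray               # shape (len(times), n_columns)
    labels: list[str] = field(default_factory=list)
    solver_ok: bool = True
    diagnostics: list[Diagnostic] = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.times.shape[0]:
            raise BnglError(Diagnostic(
                "error", f"time series shape mismatch: {len(self.times)} "
                f"times vs {self.values.shape[0]} rows"))
        if np.any(np.diff(self.times) < 0):
            raise BnglError(Diagnostic(
                "error", "time column must be non-decreasing"))
        if not self.labels:
            self.labels = [f"col{i + 1}"
                           for i in range(self.values.shape[1])]

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.values, index=self.times,
                            columns=self.labels)


def write_timeseries(ts: TimeSeries) -> str:
    """Render in the GDAT/CDAT convention: '#' header, padded scientific."""
    width = 18
    header = "#" + "".join(
        f"{name:>{width}}" for name in ["time"] + list(ts.labels))
    lines = [header]
    for t, row in zip(ts.times, ts.values):
        cells = [f"{t:{width}.8e}"] + [f"{v:{width}.8e}" for v in row]
        lines.append(" " + "".join(cells))
    return "\n".join(lines) + "\n"


def read_timeseries(text: str) -> TimeSeries:
    labels: list[str] = []
    rows: list[list[float]] = []
    times: list[float] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            fields = line[1:].split()
            if fields and fields[0] == "time":
                fields = fields[1:]
            labels = fields
            continue
        cells = line.split()
        try:
            row = [float(c) for c in cells]
        except ValueError as exc:
            raise BnglError(Diagnostic(
                "error", f"non-numeric cell: {exc}", lineno)) from exc
        if rows and len(row) != len(rows[0]) + 1:
            raise BnglError(Diagnostic(
                "error", f"ragged row: {len(row)} columns, expected "
                f"{len(rows[0]) + 1}", lineno))
        rows.append(row[1:])
        times.append(row[0])
    if not rows:
        raise BnglError(Diagnostic("error", "empty time-series document"))
    values = np.array(rows)
    if labels and len(labels) != values.shape[1]:
        labels = []
    return TimeSeries(np.array(times), values, labels)
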