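"""Time-series container, validation and plain-text I/O.

A :class:`TimeSeries` holds one observed trace ``d(t_1) ... d(t_N)`` on
strictly increasing time points ``t_i`` in seconds.  Sampling intervals may
be nonuniform; nothing in this package ever resamples or interpolates the
data.  Input files are two numeric columns (time, value) in CSV or TSV form,
with an optional header row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "TimeSeriesError",
    "ParseError",
    "read_timeseries",
    "write_spectrum",
    "MIN_POINTS",
]

#: Fewest points on which a spectrum is meaningful (two harmonic functions
#: plus at least two residual degrees of freedom).
MIN_POINTS = 4


class TimeSeriesError(ValueError):
    """Invalid time-series content (ordering, duplicates, length, NaNs)."""


class ParseError(TimeSeriesError):
    """A file cell could not be interpreted as a number."""


@dataclass(frozen=True)
class TimeSeries:
    """One observed trace on discrete, strictly increasing time points.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing, length ``N >= 4``.
    values
        Measured values (arbitrary units), same length, finite, non-constant.
    label
        Free-text description carried through to outputs.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise TimeSeriesError("times and values must be 1-D")
        if times.size != values.size:
            raise TimeSeriesError(
                f"length mismatch: {times.size} times vs {values.size} values"
            )
        if times.size < MIN_POINTS:
            raise TimeSeriesError(
                f"need at least {MIN_POINTS} points, got {times.size}"
            )
        if not np.all(np.isfinite(times)):
            raise TimeSeriesError("non-finite time points")
        if not np.all(np.isfinite(values)):
            raise TimeSeriesError("non-finite values")
        dt = np.diff(times)
        if np.any(dt == 0):
            raise TimeSeriesError("duplicate time points")
        if np.any(dt < 0):
            raise TimeSeriesError("time points not strictly increasing")
        if np.var(values, ddof=1) == 0.0:
            raise TimeSeriesError("values are constant (zero sample variance)")

    @property
    def n(self) -> int:
        """Number of data points ``N``."""
        return self.times.size

    @property
    def duration(self) -> float:
        """Record length ``t_N - t_1`` in seconds."""
        return float(self.times[-1] - self.times[0])


def _infer_sep(path: Path, dialect: str) -> str | None:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    if dialect == "auto":
        # Python engine with sep=None sniffs the delimiter.
        return None
    raise ValueError(f"unknown dialect {dialect!r} (use csv, tsv or auto)")


def read_timeseries(path: str | Path, dialect: str = "auto") -> TimeSeries:
    """Read a two-column (time, value) table into a :class:`TimeSeries`.

    The first row is skipped automatically when it is non-numeric (a
    header).  Rows out of time order are sorted with a warning; duplicate
    time points are an error because every projection statistic downstream
    assumes distinct ``t_i``.

    Parameters
    ----------
    path
        File with at least two numeric columns; extra columns are ignored.
    dialect
        ``"csv"``, ``"tsv"`` or ``"auto"`` (sniff the delimiter).

    Returns
    -------
    TimeSeries
        Column 1 as times (seconds), column 2 as values.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such file: {path}")
    sep = _infer_sep(path, dialect)
    try:
        raw = pd.read_csv(
            path,
            sep=sep,
            engine="python",
            header=None,
            comment="#",
            skip_blank_lines=True,
            dtype=str,
            skipinitialspace=True,
        )
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: need at least 2 columns, found {raw.shape[1]}")

    table = raw.iloc[:, :2]
    start_row = 0
    try:
        table.iloc[0].astype(float)
    except (TypeError, ValueError):
        start_row = 1  # header row
    body = table.iloc[start_row:]
    if body.shape[0] < MIN_POINTS:
        raise TimeSeriesError(
            f"{path}: need at least {MIN_POINTS} data rows, found {body.shape[0]}"
        )

    data = np.empty((body.shape[0], 2), dtype=float)
    for k, (idx, row) in enumerate(body.iterrows()):
        for c in (0, 1):
            cell = row.iloc[c]
            try:
                data[k, c] = float(cell)
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} in row {idx + 1}, column {c + 1}"
                ) from exc

    times, values = data[:, 0], data[:, 1]
    if np.any(np.diff(times) < 0):
        warnings.warn(
            f"{path}: rows are not in time order; sorting by time", stacklevel=2
        )
        order = np.argsort(times, kind="stable")
        times, values = times[order], values[order]
    if np.any(np.diff(times) == 0):
        raise TimeSeriesError(f"{path}: duplicate time points")
    return TimeSeries(times=times, values=values, label=path.stem)


def write_spectrum(spectrum, path: str | Path) -> None:
    """Write a normalized posterior spectrum as TSV (omega, period, density).

    ``omega`` is in rad/s, ``period`` = 2*pi/omega in seconds, ``density``
    the posterior density per rad/s.  Values are printed with 17 significant
    digits so a read-back reproduces them exactly.
    """
    omegas = np.asarray(spectrum.grid.omegas, dtype=float)
    density = np.asarray(spectrum.density, dtype=float)
    if omegas.size == 0:
        raise ValueError("cannot write an empty spectrum (grid length 0)")
    integral = np.trapezoid(density, omegas)
    if not np.isclose(integral, 1.0, atol=1e-6):
        raise ValueError(
            f"spectrum is not normalized (trapezoid integral {integral:.8g})"
        )
    table = np.column_stack([omegas, 2.0 * np.pi / omegas, density])
    header = "omega\tperiod\tdensity"
    np.savetxt(path, table, delimiter="\t", header=header, comments="", fmt="%.17g")
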