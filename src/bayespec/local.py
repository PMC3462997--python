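"""Time-resolved frequency analysis by sliding-window posteriors.

For series whose dominant period drifts (calcium oscillations slowing down,
for instance), a single global spectrum blurs the change.  Here the record
is scanned with a rectangular window; each window's points are analysed
with the full marginalized posterior, producing a 2-D density over (window
centre time, omega).  The Legendre background is re-mapped onto each
window's own time span, so baseline drift is fitted locally — no detrending
of the data is ever needed.

Windows are rectangular (boxcar): a taper would reweight the data and break
the uniform-noise assumption behind the marginalized posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import ModelSpec
from .spectrum import FrequencyGrid, posterior_spectrum
from .timeseries import TimeSeries, TimeSeriesError

__all__ = [
    "LocalSpectrogram",
    "local_spectrogram",
    "ridge",
    "write_spectrogram",
    "write_ridge",
]


@dataclass(frozen=True)
class LocalSpectrogram:
    """2-D posterior over (window centre, omega).

    ``density[i]`` is the normalized frequency posterior of the window
    centred at ``centers[i]``; each row trapezoid-integrates to 1 over the
    shared grid.  ``skipped_centers`` lists windows dropped for holding
    fewer than ``m + 2`` points (or otherwise unusable data).
    """

    centers: np.ndarray  # seconds, strictly increasing
    grid: FrequencyGrid
    density: np.ndarray  # (n_centers, n_samples)
    window_length: float
    step: float
    spec: ModelSpec
    skipped_centers: tuple[float, ...] = ()


def local_spectrogram(
    ts: TimeSeries,
    grid: FrequencyGrid,
    spec: ModelSpec,
    window_length: float | None = None,
    step: float | None = None,
) -> LocalSpectrogram:
    """Sliding-window frequency posterior.

    Parameters
    ----------
    ts, grid, spec
        As for the global spectrum; the same grid is reused in every window.
    window_length
        Window width in seconds; must cover at least the longest period on
        the grid (``2 pi / omega_min``) so every window can hold one full
        cycle.  Default: twice that longest period.
    step
        Centre-to-centre increment in seconds; default ``window_length / 8``.

    Windows run from ``t_min + window_length/2`` to ``t_max -
    window_length/2``; a window longer than the record degenerates to a
    single all-points window, reproducing the global spectrum.  Windows
    with fewer than ``m + 2`` points are skipped and reported in
    ``skipped_centers``.
    """
    longest_period = 2.0 * np.pi / grid.omega_min
    if window_length is None:
        window_length = 2.0 * longest_period
    if step is None:
        step = window_length / 8.0
    if window_length < longest_period:
        raise ValueError(
            f"window_length={window_length:.6g} s is shorter than the longest "
            f"period of interest ({longest_period:.6g} s)"
        )
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")

    t_min, t_max = float(ts.times[0]), float(ts.times[-1])
    half = window_length / 2.0
    if t_max - t_min <= window_length:
        candidate_centers = np.array([(t_min + t_max) / 2.0])
    else:
        candidate_centers = np.arange(t_min + half, t_max - half + 1e-9 * step, step)

    kept: list[float] = []
    rows: list[np.ndarray] = []
    skipped: list[float] = []
    min_points = max(spec.m + 2, 4)
    for c in candidate_centers:
        mask = np.abs(ts.times - c) <= half * (1.0 + 1e-12)
        if int(mask.sum()) < min_points:
            skipped.append(float(c))
            continue
        try:
            sub = TimeSeries(ts.times[mask], ts.values[mask], label=ts.label)
        except TimeSeriesError:
            skipped.append(float(c))
            continue
        rows.append(posterior_spectrum(sub, grid, spec).density)
        kept.append(float(c))
    if not rows:
        raise ValueError(
            "no window held enough points; enlarge window_length or reduce "
            "the model order"
        )
    return LocalSpectrogram(
        centers=np.array(kept),
        grid=grid,
        density=np.vstack(rows),
        window_length=float(window_length),
        step=float(step),
        spec=spec,
        skipped_centers=tuple(skipped),
    )


def ridge(ls: LocalSpectrogram) -> pd.DataFrame:
    """Per-window posterior mode, in omega and period.

    Returns a DataFrame with columns ``center_time`` (s), ``mode_omega``
    (rad/s) and ``mode_period`` (s) — the path of maximum posterior density
    through the spectrogram.
    """
    idx = np.argmax(ls.density, axis=1)
    mode_omega = ls.grid.omegas[idx]
    return pd.DataFrame(
        {
            "center_time": ls.centers,
            "mode_omega": mode_omega,
            "mode_period": 2.0 * np.pi / mode_omega,
        }
    )


def write_spectrogram(ls: LocalSpectrogram, path) -> None:
    """Write the spectrogram in long format: center_time, omega, period, density."""
    n_c, n_w = ls.density.shape
    out = pd.DataFrame(
        {
            "center_time": np.repeat(ls.centers, n_w),
            "omega": np.tile(ls.grid.omegas, n_c),
            "period": np.tile(2.0 * np.pi / ls.grid.omegas, n_c),
            "density": ls.density.ravel(),
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_ridge(ridge_df: pd.DataFrame, path) -> None:
    """Write a ridge table (center_time, mode_omega, mode_period) as TSV."""
    ridge_df.to_csv(path, sep="\t", index=False, float_format="%.17g")
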