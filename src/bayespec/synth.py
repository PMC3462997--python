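"""Seedable generators of oscillatory test series.

Generated data follow the additive structure the analysis assumes:
``d(t_i) = s(t_i) + g(t_i) + e(t_i)`` — a deterministic oscillatory signal,
a slow background trend, and i.i.d. noise.  Components cover the two
phenomenologies the package targets: short sparse sinusoidal records (cell
cycle expression profiles) and dense drifting-period traces with a
bleaching baseline (calcium oscillations in root cells).

Chirps interpolate the *period* linearly over the record — oscillations
that "slow down" do so roughly linearly in period — and the phase is the
exact integral of the instantaneous angular frequency, which gives tests a
closed-form instantaneous period at any time.

Every generator call is driven by a single integer seed and is
bit-reproducible; the random stream is consumed in a fixed order (sample
times first, then noise), so two specs differing only in their
deterministic parts (e.g. with and without a trend) share identical times
and noise for the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .timeseries import TimeSeries

__all__ = [
    "Sinusoid",
    "Chirp",
    "PolynomialTrend",
    "ExponentialTrend",
    "GenSpec",
    "GroundTruth",
    "generate",
    "presets",
    "write_ground_truth",
]


@dataclass(frozen=True)
class Sinusoid:
    """Fixed-period component ``amplitude * sin(2 pi t / period + phase)``."""

    amplitude: float
    period: float  # seconds
    phase: float = 0.0  # radians


@dataclass(frozen=True)
class Chirp:
    """Component whose period drifts linearly from period_start to period_end.

    The instantaneous period is ``T(t) = T0 + (T1 - T0) * t / duration`` and
    the signal is ``amplitude * sin(phase + integral_0^t 2 pi / T(u) du)``.
    """

    amplitude: float
    period_start: float  # seconds, at t = 0
    period_end: float  # seconds, at t = duration
    phase: float = 0.0


@dataclass(frozen=True)
class PolynomialTrend:
    """Trend ``sum_k c_k t^k`` with coefficients low order first (t in s)."""

    coefficients: tuple[float, ...]


@dataclass(frozen=True)
class ExponentialTrend:
    """Decaying baseline ``scale * exp(-rate * t)`` (fluorescence bleaching)."""

    scale: float
    rate: float  # 1/s


@dataclass(frozen=True)
class GenSpec:
    """Full description of one synthetic series.

    ``sampling`` is ``"uniform"`` (even grid over [0, duration]),
    ``"jittered"`` (even grid plus Gaussian jitter of sd ``jitter_sd``
    seconds, re-drawn until strictly increasing) or ``"random"`` (sorted
    uniform draws).  ``noise_kind`` is ``"gaussian"`` (sd ``noise_sd``) or
    ``"uniform"`` (zero-mean, half-width ``noise_sd * sqrt(3)`` so the
    standard deviation still equals ``noise_sd``).
    """

    n_points: int
    duration: float  # seconds
    sampling: str = "uniform"
    jitter_sd: float = 0.0
    components: tuple = ()
    trend: PolynomialTrend | ExponentialTrend | None = None
    noise_sd: float = 0.0
    noise_kind: str = "gaussian"
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise ValueError(f"n_points must be >= 4, got {self.n_points}")
        if not self.duration > 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.sampling not in ("uniform", "jittered", "random"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")
        if self.noise_kind not in ("gaussian", "uniform"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")
        if self.sampling == "jittered" and not self.jitter_sd > 0:
            raise ValueError("jittered sampling needs jitter_sd > 0")
        for comp in self.components:
            if isinstance(comp, Sinusoid):
                if comp.period <= 0:
                    raise ValueError(f"period must be positive, got {comp.period}")
            elif isinstance(comp, Chirp):
                if comp.period_start <= 0 or comp.period_end <= 0:
                    raise ValueError("chirp periods must be positive")
            else:
                raise ValueError(f"unknown component {comp!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to score a recovery test without re-derivation."""

    times: np.ndarray
    clean_signal: np.ndarray  # sum of components, no trend, no noise
    trend_values: np.ndarray
    noise: np.ndarray
    period_at: Callable[[float], float] | None  # instantaneous period of
    # the first oscillatory component, defined for any t in [0, duration]
    spec: GenSpec


def _component_values(comp, t: np.ndarray, duration: float) -> np.ndarray:
    if isinstance(comp, Sinusoid):
        return comp.amplitude * np.sin(2.0 * np.pi * t / comp.period + comp.phase)
    t0, t1 = comp.period_start, comp.period_end
    if t0 == t1:
        phase = 2.0 * np.pi * t / t0
    else:
        # integral of 2 pi / T(u) du with T linear in u
        phase = 2.0 * np.pi * duration / (t1 - t0) * np.log(
            (t0 + (t1 - t0) * t / duration) / t0
        )
    return comp.amplitude * np.sin(comp.phase + phase)


def _component_period(comp, duration: float) -> Callable[[float], float]:
    if isinstance(comp, Sinusoid):
        return lambda t: comp.period
    t0, t1 = comp.period_start, comp.period_end
    return lambda t: t0 + (t1 - t0) * min(max(t, 0.0), duration) / duration


def _draw_times(gs: GenSpec, rng: np.random.Generator) -> np.ndarray:
    if gs.sampling == "uniform":
        return np.linspace(0.0, gs.duration, gs.n_points)
    for _ in range(100):
        if gs.sampling == "jittered":
            t = np.linspace(0.0, gs.duration, gs.n_points)
            t = np.sort(t + rng.normal(0.0, gs.jitter_sd, size=gs.n_points))
        else:
            t = np.sort(rng.uniform(0.0, gs.duration, size=gs.n_points))
        if np.all(np.diff(t) > 0):
            return t
    raise RuntimeError("could not draw strictly increasing times in 100 tries")


def generate(gs: GenSpec) -> tuple[TimeSeries, GroundTruth]:
    """Generate one series plus its ground-truth record.

    Identical ``GenSpec`` (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(gs.seed)
    t = _draw_times(gs, rng)

    if gs.noise_kind == "gaussian":
        noise = rng.normal(0.0, gs.noise_sd, size=gs.n_points) if gs.noise_sd else np.zeros(gs.n_points)
    else:
        half_width = gs.noise_sd * math.sqrt(3.0)
        noise = rng.uniform(-half_width, half_width, size=gs.n_points)

    clean = np.zeros(gs.n_points)
    for comp in gs.components:
        clean += _component_values(comp, t, gs.duration)

    if gs.trend is None:
        trend = np.zeros(gs.n_points)
    elif isinstance(gs.trend, PolynomialTrend):
        trend = np.polynomial.polynomial.polyval(t, gs.trend.coefficients)
    elif isinstance(gs.trend, ExponentialTrend):
        trend = gs.trend.scale * np.exp(-gs.trend.rate * t)
    else:
        raise ValueError(f"unknown trend {gs.trend!r}")

    ts = TimeSeries(times=t, values=clean + trend + noise, label=gs.label)
    period_at = (
        _component_period(gs.components[0], gs.duration) if gs.components else None
    )
    truth = GroundTruth(
        times=t,
        clean_signal=clean,
        trend_values=trend,
        noise=noise,
        period_at=period_at,
        spec=gs,
    )
    return ts, truth


def presets() -> dict[str, GenSpec]:
    """Named, fully specified generator settings.

    - ``cellcycle_like``: 20 evenly spaced points over 5 h, one sinusoid
      of period 150 min — a short, sparsely sampled expression profile.
    - ``calcium_like``: 300 points over 30 min, period slowing from 60 s to
      110 s, with a decaying exponential baseline (bleaching) three times
      the oscillation amplitude.
    - ``null_noise``: no signal at all — uniform random values between 1
      and 2 (trend 1.5, zero-mean uniform noise of half-width 0.5).

    Seeds are fixed (101, 202, 303) so the presets are reproducible;
    ``dataclasses.replace`` changes the seed for replicate draws.
    """
    return {
        "cellcycle_like": GenSpec(
            n_points=20,
            duration=18000.0,
            components=(Sinusoid(amplitude=1.0, period=9000.0, phase=0.3),),
            noise_sd=0.25,
            seed=101,
            label="cellcycle_like",
        ),
        "calcium_like": GenSpec(
            n_points=300,
            duration=1800.0,
            components=(Chirp(amplitude=1.0, period_start=60.0, period_end=110.0),),
            trend=ExponentialTrend(scale=3.0, rate=1.0 / 1200.0),
            noise_sd=0.15,
            seed=202,
            label="calcium_like",
        ),
        "null_noise": GenSpec(
            n_points=100,
            duration=600.0,
            components=(),
            trend=PolynomialTrend(coefficients=(1.5,)),
            noise_sd=0.5 / math.sqrt(3.0),
            noise_kind="uniform",
            seed=303,
            label="null_noise",
        ),
    }


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Write the ground-truth record as TSV (sidecar to the series file)."""
    periods = (
        np.array([truth.period_at(t) for t in truth.times])
        if truth.period_at is not None
        else np.full(truth.times.size, np.nan)
    )
    table = np.column_stack(
        [truth.times, truth.clean_signal, truth.trend_values, truth.noise, periods]
    )
    header = "time\tclean_signal\ttrend\tnoise\tinstantaneous_period"
    np.savetxt(path, table, delimiter="\t", header=header, comments="", fmt="%.17g")
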