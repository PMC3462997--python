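import numpy as np
import pytest

from bayespec import FrequencyGrid, ModelSpec
from bayespec.synth import GenSpec, Sinusoid, generate


@pytest.fixture
def std_grid() -> FrequencyGrid:
    """300-sample grid over periods 20-200 s, the package's working default."""
    return FrequencyGrid.from_periods(20.0, 200.0, 300)


@pytest.fixture
def sinusoid_factory():
    """Factory for a noisy 60 s sinusoid: 100 points over 600 s, sd 0.5."""

    def make(seed: int = 1, noise_sd: float = 0.5, period: float = 60.0):
        gs = GenSpec(
            n_points=100,
            duration=600.0,
            components=(Sinusoid(amplitude=1.0, period=period, phase=0.3),),
            noise_sd=noise_sd,
            seed=seed,
        )
        return generate(gs)

    return make


@pytest.fixture
def noisy_sinusoid(sinusoid_factory):
    ts, _ = sinusoid_factory(seed=1)
    return ts


@pytest.fixture
def harmonic_spec() -> ModelSpec:
    return ModelSpec(n_background=0)


def random_nonuniform_times(rng: np.random.Generator, n: int, span: float = 600.0):
    t = np.sort(rng.uniform(0.0, span, size=n))
    while np.any(np.diff(t) <= 0):
        t = np.sort(rng.uniform(0.0, span, size=n))
    return t
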