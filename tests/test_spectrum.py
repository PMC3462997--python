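import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayespec import (
    FrequencyGrid,
    ModelSpec,
    ModelTooLargeError,
    PosteriorSpectrum,
    TimeSeries,
    build_ortho_basis,
    log_posterior_at,
    posterior_spectrum,
    sufficient_stats,
    summarize,
    to_period_spectrum,
)
from bayespec.synth import GenSpec, Sinusoid, generate
from conftest import random_nonuniform_times


class TestFrequencyGrid:
    def test_period_construction(self):
        grid = FrequencyGrid.from_periods(20.0, 200.0, 300)
        assert grid.omega_min == pytest.approx(2 * np.pi / 200)
        assert grid.omega_max == pytest.approx(2 * np.pi / 20)
        assert grid.omegas.size == 300
        assert np.all(np.diff(grid.omegas) > 0)

    @pytest.mark.parametrize("start,stop", [(0.0, 10.0), (10.0, 10.0), (20.0, 10.0)])
    def test_bad_period_range(self, start, stop):
        with pytest.raises(ValueError):
            FrequencyGrid.from_periods(start, stop, 100)


class TestSufficientStats:
    def test_basis_row_projects_to_unit_vector(self):
        t = np.linspace(0, 600, 32)
        basis = build_ortho_basis(0.1, t, ModelSpec(1))
        ts = TimeSeries(t, basis.phi[0])
        stats = sufficient_stats(ts, basis)
        np.testing.assert_allclose(stats.h, [1.0, 0.0, 0.0], atol=1e-10)

    def test_linearity_in_data_scale(self):
        rng = np.random.default_rng(3)
        t = random_nonuniform_times(rng, 24)
        d = rng.normal(size=24)
        basis = build_ortho_basis(0.07, t, ModelSpec(2))
        s1 = sufficient_stats(TimeSeries(t, d), basis)
        s2 = sufficient_stats(TimeSeries(t, 3.5 * d), basis)
        np.testing.assert_allclose(s2.h, 3.5 * s1.h, rtol=1e-12)
        assert s2.h2bar == pytest.approx(3.5**2 * s1.h2bar, rel=1e-12)
        assert s2.d2bar == pytest.approx(3.5**2 * s1.d2bar, rel=1e-12)

    def test_against_direct_summation(self):
        """h_j, h2bar, d2bar recomputed with explicit loops must agree."""
        rng = np.random.default_rng(11)
        t = random_nonuniform_times(rng, 16)
        d = rng.normal(size=16)
        basis = build_ortho_basis(0.21, t, ModelSpec(1))
        stats = sufficient_stats(TimeSeries(t, d), basis)
        h_loop = np.array(
            [sum(d[i] * basis.phi[j, i] for i in range(16)) for j in range(basis.m)]
        )
        np.testing.assert_allclose(stats.h, h_loop, atol=1e-12)
        assert stats.h2bar == pytest.approx(
            sum(hj**2 for hj in h_loop) / basis.m, abs=1e-12
        )
        assert stats.d2bar == pytest.approx(sum(x**2 for x in d) / 16, abs=1e-12)


class TestLogPosterior:
    def test_least_squares_oracle(self):
        """exp(log posterior) must equal (RSS/TSS)^((m-N)/2) from an
        independent least-squares fit of the raw harmonics."""
        rng = np.random.default_rng(5)
        n = 40
        t = np.linspace(0, 600, n)
        d = np.sin(2 * np.pi * t / 60) + rng.normal(0, 0.5, n)
        ts = TimeSeries(t, d)
        spec = ModelSpec(0)
        for omega in rng.uniform(2 * np.pi / 200, 2 * np.pi / 20, size=10):
            design = np.column_stack([np.sin(omega * t), np.cos(omega * t)])
            coef, *_ = np.linalg.lstsq(design, d, rcond=None)
            rss = float(np.sum((d - design @ coef) ** 2))
            tss = float(d @ d)
            expected = (rss / tss) ** (0.5 * (spec.m - n))
            got = np.exp(log_posterior_at(ts, omega, spec))
            assert got == pytest.approx(expected, rel=1e-8)

    def test_perfect_fit_clamps_to_finite_maximum(self):
        t = np.linspace(0, 600, 50)
        omega0 = 2 * np.pi / 60
        ts = TimeSeries(t, np.sin(omega0 * t + 0.4))
        lp0 = log_posterior_at(ts, omega0, ModelSpec(0))
        assert np.isfinite(lp0)
        # argmax semantics survive the clamp
        assert lp0 > log_posterior_at(ts, omega0 * 1.05, ModelSpec(0))

    def test_model_too_large(self):
        t = np.linspace(0, 10, 5)
        ts = TimeSeries(t, np.sin(t) + 0.01 * t)
        with pytest.raises(ModelTooLargeError):
            log_posterior_at(ts, 1.0, ModelSpec(3))


class TestPosteriorSpectrum:
    def test_normalization(self, noisy_sinusoid, std_grid):
        ps = posterior_spectrum(noisy_sinusoid, std_grid, ModelSpec(0))
        assert np.trapezoid(ps.density, std_grid.omegas) == pytest.approx(1.0, abs=1e-6)
        assert np.all(ps.density >= 0)

    def test_mode_recovers_true_period(self, noisy_sinusoid, std_grid):
        ps = posterior_spectrum(noisy_sinusoid, std_grid, ModelSpec(0))
        mode = std_grid.omegas[np.argmax(ps.density)]
        assert abs(mode - 2 * np.pi / 60) <= std_grid.step

    @given(scale=st.floats(0.01, 100.0), offset=st.floats(-10.0, 10.0))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_affine_invariance(self, scale, offset):
        """With a constant in the model span the normalized spectrum must
        not change under d -> a*d + b (checked on unit-peak spectra, which
        makes the 1e-10 tolerance scale-free)."""
        gs = GenSpec(
            n_points=100,
            duration=600.0,
            components=(Sinusoid(1.0, 60.0, 0.3),),
            noise_sd=0.5,
            seed=1,
        )
        ts, _ = generate(gs)
        grid = FrequencyGrid.from_periods(20.0, 200.0, 60)
        spec = ModelSpec(1)
        base = posterior_spectrum(ts, grid, spec)
        shifted = TimeSeries(ts.times, scale * ts.values + offset)
        moved = posterior_spectrum(shifted, grid, spec)
        np.testing.assert_allclose(
            moved.density / moved.density.max(),
            base.density / base.density.max(),
            atol=1e-10,
        )

    def test_scale_invariance_without_background(self, noisy_sinusoid):
        grid = FrequencyGrid.from_periods(20.0, 200.0, 60)
        base = posterior_spectrum(noisy_sinusoid, grid, ModelSpec(0))
        doubled = TimeSeries(noisy_sinusoid.times, 2.0 * noisy_sinusoid.values)
        moved = posterior_spectrum(doubled, grid, ModelSpec(0))
        np.testing.assert_allclose(moved.density, base.density, atol=1e-10)

    def test_residual_monotone_in_background_order(self, noisy_sinusoid):
        """Nested model spaces: the residual N*d2bar - m*h2bar cannot grow
        when another background function is added."""
        t, d = noisy_sinusoid.times, noisy_sinusoid.values
        omega = 0.08
        prev = np.inf
        for k in range(5):
            basis = build_ortho_basis(omega, t, ModelSpec(k))
            h = basis.phi @ d
            resid = float(d @ d - h @ h)
            assert resid <= prev + 1e-9
            prev = resid

    def test_lomb_scargle_concordance(self):
        """Uniform sampling, no background: the posterior peak must sit on
        the Lomb-Scargle periodogram peak."""
        from scipy.signal import lombscargle

        grid = FrequencyGrid.from_periods(20.0, 200.0, 300)
        for seed in (0, 1, 2):
            gs = GenSpec(
                n_points=100,
                duration=600.0,
                components=(Sinusoid(1.0, 60.0, 0.3),),
                noise_sd=0.5,
                seed=seed,
            )
            ts, _ = generate(gs)
            ps = posterior_spectrum(ts, grid, ModelSpec(0))
            ls = lombscargle(ts.times, ts.values, grid.omegas)
            i_ps, i_ls = np.argmax(ps.density), np.argmax(ls)
            assert abs(i_ps - i_ls) <= 1


class TestPeriodTransform:
    def _uniform_spectrum(self):
        grid = FrequencyGrid(0.05, 0.25, 201)
        dens = np.full(201, 1.0 / (0.25 - 0.05))
        logp = np.zeros(201)
        return PosteriorSpectrum(grid, logp, dens, ModelSpec(0))

    def test_jacobian_closed_form(self):
        """A uniform omega-density maps to a density proportional to 1/T^2."""
        ps = self._uniform_spectrum()
        period = to_period_spectrum(ps)
        ratio = period.density * period.periods**2
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)
        assert np.all(np.diff(period.periods) > 0)

    def test_probability_conserved(self, noisy_sinusoid, std_grid):
        ps = posterior_spectrum(noisy_sinusoid, std_grid, ModelSpec(0))
        period = to_period_spectrum(ps)
        assert np.trapezoid(period.density, period.periods) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_mode_maps_to_reciprocal(self, noisy_sinusoid, std_grid):
        ps = posterior_spectrum(noisy_sinusoid, std_grid, ModelSpec(0))
        mode_omega = std_grid.omegas[np.argmax(ps.density)]
        period = to_period_spectrum(ps)
        mode_period = period.periods[np.argmax(period.density)]
        # Jacobian tilt can move the discrete mode by about a grid cell
        assert mode_period == pytest.approx(2 * np.pi / mode_omega, rel=0.02)


class TestSummarize:
    def test_uniform_density_interval_covers_95_percent(self):
        grid = FrequencyGrid(0.05, 0.25, 201)
        dens = np.full(201, 1.0 / 0.2)
        ps = PosteriorSpectrum(grid, np.zeros(201), dens, ModelSpec(0))
        s = summarize(ps)
        width = s.ci_omega_high - s.ci_omega_low
        assert width == pytest.approx(0.95 * 0.2, rel=0.02)

    def test_delta_peak_interval_is_one_step(self):
        grid = FrequencyGrid(0.05, 0.25, 201)
        dens = np.zeros(201)
        dens[100] = 1.0
        dens /= np.trapezoid(dens, grid.omegas)
        ps = PosteriorSpectrum(grid, np.zeros(201), dens, ModelSpec(0))
        s = summarize(ps)
        assert s.mode_omega == pytest.approx(grid.omegas[100])
        assert s.ci_omega_low >= grid.omegas[99] - 1e-12
        assert s.ci_omega_high <= grid.omegas[101] + 1e-12

    def test_true_frequency_inside_interval(self, noisy_sinusoid, std_grid):
        ps = posterior_spectrum(noisy_sinusoid, std_grid, ModelSpec(0))
        s = summarize(ps)
        assert s.ci_omega_low <= 2 * np.pi / 60 <= s.ci_omega_high
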