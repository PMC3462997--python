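# Methods

## Model and marginal frequency posterior

A single trace `d(t_1)…d(t_N)` on strictly increasing times (seconds,
possibly nonuniform) is modelled as signal + background + noise.  The
signal hypothesis is one harmonic pair at angular frequency ω; the
background is a set of Legendre polynomials of degree 0…`n_background−1`
evaluated on the sample times affinely mapped to [−1, 1] (so
`n_background = 1` is a constant offset, `2` adds a linear drift, and so
on).  The total function count is `m = 2 + n_background`.  Noise is
i.i.d. Gaussian with unknown level.

With a uniform prior on the amplitudes and a Jeffreys (1/σ) prior on the
noise level, both integrate out analytically and the posterior over ω is
proportional to `r(ω)^((m−N)/2)` with

    r(ω) = 1 − m h̄² / (N d̄²) = RSS(ω) / TSS,

the residual fraction of the least-squares fit of the m functions at ω.
The identity with RSS/TSS holds because the functions are orthonormalized
*on the discrete sample points*; harmonics are not orthogonal on an
arbitrary time grid, so the orthonormal set is rebuilt at every ω.  This
identity is also the backbone of the test suite: an ordinary
least-squares fit of the raw (un-orthonormalized) functions is the
independent oracle for the posterior statistic.

Consequences used as invariants:

- scale invariance — `d → a·d` leaves the normalized spectrum unchanged
  for every model;
- affine invariance — `d → a·d + b` leaves it unchanged whenever the
  constant is in the model span (`n_background ≥ 1`);
- residual monotonicity — RSS is non-increasing in `n_background` at
  fixed ω (nested model spaces);
- for uniform sampling and no background the argmax coincides with the
  Lomb–Scargle periodogram peak (both are monotone in the projected
  power).

## Numerical evaluation

Everything is computed in the log domain: `(m−N)/2` is large and negative
(−49 for a typical N = 100 series), so the density itself under/overflows
double precision.  Grid normalization subtracts the maximum log density
before exponentiating and divides by the trapezoid integral over ω.

- Orthonormalization: QR factorization of the N×m design matrix (stabler
  than classical Gram–Schmidt when `sin(ωt)` is nearly collinear with a
  low-order polynomial at small ω).  Rank guard: singular values below
  1e-10 of the largest raise a rank-deficiency error naming the offending
  ω.
- Hot path: repeated evaluation over a grid or inside the sampler uses
  the normal equations `Σh² = b'G⁻¹b` (`G = A'A`, `b = A'd`) with the
  ω-independent Legendre block precomputed — algebraically identical to
  the QR projection, about twice as fast; the rank guard becomes an
  eigenvalue ratio of G at (1e-10)².
- Perfect fits: `r` is floored at 1e-300 before the log, so a noise-free
  sinusoid at the true ω yields a finite, representable maximum and
  argmax semantics survive.
- Frequency grid: uniform in ω between `2π/stop` and `2π/start` for a
  user period range `[start, stop]` seconds.  Uniform-in-ω matches the
  uniform prior over ω and makes trapezoid normalization direct.  100–500
  grid samples is a good default range (the CLI advises when outside it);
  300 is the package default.
- Period domain: `density_T(T) = density_ω(2π/T)·2π/T²`, grid reversed to
  increasing T, then re-normalized on the period partition (the continuous
  integral is preserved exactly, but trapezoid sums on the two partitions
  differ at ~1e-4 on wide grids).
- Credible interval: the shortest contiguous grid span holding ≥ 95%
  trapezoid mass.  The underlying method outputs only the distribution;
  the interval is a convenience summary.

## Evidence and model comparison

The evidence `Z = P(D|H)` is the integral of the marginalized likelihood
over the uniform ω prior.  The proportionality constant dropped from the
posterior statistic is treated as model-independent, so log evidences are
comparable only across models on the same data and frequency range —
which is exactly how they are used: the posterior model ratio

    P(H_i|D) / P(H_j|D) = prior_odds × Z_i / Z_j

(H_i the model with fewer functions) cancels the shared constant.  A
ratio above one prefers the simpler model; exact ties go to the simpler
model.

Nested sampling follows the standard loop: `n_live` points from the
prior; at each iteration the worst point is removed with prior-mass
weight `X_{i−1} − X_i`, `X_i = exp(−i/n_live)`, and replaced by a clone
of a random survivor evolved by 20 bounded random-walk steps accepting
moves at or above the removed likelihood, with the step size started at
10% of the live spread and adapted toward ~50% acceptance.  Sampling
stops at an iteration cap (default 300; the model-comparison routines use
3000) or when the largest live likelihood times the remaining prior mass
falls below 1e-6 of the accumulated evidence; the remaining mass is then
credited to the live points, which makes the flat-likelihood case exact
and reduces truncation bias otherwise.  The standard error is
`sqrt(H/n_live)` with `H` the information.  Posterior ω samples are
importance-resampled from the dead+live pool.

Because the parameter space is one-dimensional, a dense trapezoid
quadrature of the same likelihood is a deterministic oracle; nested
sampling is validated against it (and against closed-form integrands)
rather than trusted on its own.

Model comparisons run both models' samplers from the *same* seed on the
same data and range (common random numbers): the prior-mass shrinkage
errors are strongly correlated and largely cancel in the log ratio.  A
model's evidence therefore depends only on (data, model, range, seed),
never on which comparison requested it — the automated scan caches and
reuses evidences, and antisymmetry under argument swap is exact.

`auto_select` scans k = 0, 1, 2, … comparing background order k against
k+1 and stops at the first k that defeats its extension — a greedy Occam
schedule that caps sampler cost; the cap (default `max_background = 6`,
returned with a warning flag if reached) exists because high Legendre
orders start absorbing oscillatory signal on short series.

## Time-resolved analysis

`local_spectrogram` slides a rectangular window (a taper would reweight
the data and break the uniform-noise assumption) and computes a full
normalized posterior on each window's points.  The Legendre background is
re-mapped to each window's own [−1, 1], so baseline drift is fitted
locally — a bleaching trend needs no pre-processing.  Defaults: window =
2× the longest period of interest (windows must cover at least one full
cycle of the longest sought period, which is enforced), step = window/8.
Windows with fewer than `m + 2` points are skipped and reported.  The
ridge is the per-window argmax in ω (with its period equivalent); the
validation battery additionally refines the peak by local quadratic
interpolation of the log density when measuring sub-grid ridge shifts,
since the raw argmax quantizes any shift to whole grid cells.

## Synthetic data

`bayespec.synth` generates the regimes the package targets:

- sinusoids (fixed period) and chirps whose *period* interpolates
  linearly over the record — matching how calcium oscillations slow down,
  and giving a closed-form instantaneous period for scoring ridge tests;
  the chirp phase is the exact integral of the instantaneous frequency;
- polynomial and decaying-exponential (bleaching) trends;
- Gaussian noise, or zero-mean uniform noise (half-width sd·√3) for
  bounded null data;
- uniform, jittered or fully random sampling, always strictly increasing.

Draw order is fixed (times, then noise), so two specs differing only in
deterministic parts — e.g. with and without a trend — share identical
times and noise at the same seed; "twin" comparisons isolate the trend's
effect exactly.

Presets: `cellcycle_like` (20 points over 5 h, period 150 min, noise sd
0.25 — a short sparse expression profile), `calcium_like` (300 points
over 30 min, period 60 → 110 s, bleaching trend of 3× the amplitude
decaying with a 20 min constant, noise sd 0.15), `null_noise` (100
uniform random values in [1, 2] — no signal).

## Study conditions in the validation battery

- Frequency recovery: period 60 s, amplitude 1, Gaussian sd 0.5 (SNR 2),
  N = 100 uniform over 600 s, grid of 300 samples over periods 20–200 s —
  a deliberately noisy detection problem; the posterior mode lands within
  one grid step of the truth in ≥ 95% of seeds.
- Background-order selection: same trace at sd 0.1 (SNR 10, a
  well-resolved reporter trace), alone and with a linear trend whose rise
  over the record is 5× the amplitude.  The selection experiments probe
  background structure, not detectability, hence the cleaner trace; at
  SNR 2 the order-selection question degenerates into the detection
  question.  Exact (quadrature) Bayes factors under these conditions
  prefer no background on 18/20 pure traces and order 2 on 20/20 trended
  ones, so the sampler is being tested against an attainable target.
- Ridge tracking: chirp 50 → 90 s over 600 s at sd 0.1, windows of 180 s
  every 30 s; and the `calcium_like` preset against its trend-free twin
  with a local constant+linear background.
- Null behaviour: the `null_noise` preset re-seeded 100 times, analysed
  with a constant background; a diffuse posterior (no grid point holding
  more than half the mass) is the expected outcome on signal-free data.

What passing these does *not* show: the generator's noise is exactly the
i.i.d. Gaussian the marginalization assumes (except the bounded-uniform
null), trends are exactly polynomial/exponential, and single components
dominate.  Real traces with heavy-tailed noise, multiple interacting
frequencies, or sharp transients are outside what the battery
demonstrates.

## Known limitations

- One frequency dimension; one harmonic pair per model.
- Amplitude and noise-level estimates are integrated out and not
  reported.
- Evidences are meaningful only in ratios between models on the same
  data and frequency range (shared dropped constant).
- Duplicate time stamps are rejected, not averaged; out-of-order rows
  are sorted with a warning.
- Fixed-length rectangular windows in the local analysis; no
  multi-resolution scheme.
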