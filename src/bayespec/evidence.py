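"""Evidence estimation by nested sampling, with a quadrature oracle.

The evidence ``Z = P(D | H)`` is the integral of the marginalized
likelihood over the uniform frequency prior on ``[omega_min, omega_max]``.
It is the normalizing constant of the frequency posterior and the quantity
ratioed for background-model comparison.

Nested sampling keeps ``n_live`` points drawn from the prior, repeatedly
removes the one with the worst log-likelihood — assigning it the prior-mass
shell ``w_i = X_{i-1} - X_i`` with ``X_i = exp(-i / n_live)`` — and replaces
it with a clone of a survivor evolved by a bounded random walk that only
accepts moves at or above the removed likelihood.  The accumulated sum
``Z = sum_i L_i w_i`` (plus the mean live likelihood times the remaining
mass) estimates the evidence; its standard error is ``sqrt(H / n_live)``
with ``H`` the information (KL divergence of posterior from prior).

The likelihood here is the exponential of the marginalized log posterior
with its proportionality constant treated as model-independent, so log
evidences are comparable only across models evaluated on the same data and
frequency range — exactly the use the model-ratio module makes of them,
where the shared constant cancels.

Because the search space is one-dimensional, a dense trapezoid quadrature
(:func:`quadrature_evidence`) provides a deterministic cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .basis import ModelSpec
from .spectrum import FrequencyGrid, _PosteriorEvaluator
from .timeseries import TimeSeries

__all__ = [
    "EvidenceResult",
    "nested_sampling",
    "nested_sampling_loglike",
    "quadrature_evidence",
    "log_trapezoid",
]


@dataclass
class EvidenceResult:
    """Nested-sampling evidence estimate with posterior samples.

    ``flat_likelihood`` flags the degenerate case in which every evaluated
    likelihood was identical (uniform posterior); the evidence then equals
    that constant exactly.
    """

    log_evidence: float
    log_evidence_sd: float
    posterior_samples: np.ndarray
    n_live: int
    n_iterations: int
    information: float
    flat_likelihood: bool = False

    def __post_init__(self) -> None:
        if not self.log_evidence_sd > 0:
            raise ValueError("log_evidence_sd must be positive")

    def as_dict(self) -> dict:
        """JSON-compatible scalar summary."""
        return {
            "log_evidence": float(self.log_evidence),
            "log_evidence_sd": float(self.log_evidence_sd),
            "n_live": int(self.n_live),
            "n_iterations": int(self.n_iterations),
            "information": float(self.information),
            "flat_likelihood": bool(self.flat_likelihood),
        }


def nested_sampling_loglike(
    loglike,
    omega_min: float,
    omega_max: float,
    *,
    n_live: int = 50,
    n_target_samples: int = 300,
    seed: int | None = None,
    n_posterior_samples: int = 1000,
    n_walk_steps: int = 20,
    rel_tail: float = 1e-6,
) -> EvidenceResult:
    """Nested sampling of an arbitrary 1-D log-likelihood over a uniform prior.

    Generic engine behind :func:`nested_sampling`; taking the log-likelihood
    as a callable lets closed-form integrands (constant, Gaussian bump)
    validate the sampler independently of any data model.

    Parameters
    ----------
    loglike
        Callable ``omega -> float`` log-likelihood.
    omega_min, omega_max
        Support of the uniform prior (rad/s).
    n_live
        Live-point count (>= 10).
    n_target_samples
        Iteration cap; sampling also stops earlier once the largest live
        likelihood times the remaining prior mass falls below ``rel_tail``
        of the accumulated evidence.
    seed
        Seed for all randomness; ``None`` draws one from OS entropy.
    n_walk_steps
        Random-walk steps used to regenerate each replacement point.  The
        step size starts at 10% of the live-point spread and adapts toward
        ~50% acceptance.
    """
    if n_live < 10:
        raise ValueError(f"n_live must be >= 10, got {n_live}")
    if not (0 < omega_min < omega_max):
        raise ValueError(f"invalid omega range [{omega_min}, {omega_max}]")
    rng = np.random.default_rng(seed)
    width = omega_max - omega_min

    live_om = rng.uniform(omega_min, omega_max, size=n_live)
    live_ll = np.array([loglike(o) for o in live_om], dtype=float)

    dead_om: list[float] = []
    dead_ll: list[float] = []
    dead_logw: list[float] = []
    log_z = -np.inf
    # log(X_{i-1} - X_i) = -(i-1)/n_live + log(1 - exp(-1/n_live))
    log_shell = math.log1p(-math.exp(-1.0 / n_live))
    step = 0.1 * width
    n_iter = 0

    for i in range(1, n_target_samples + 1):
        worst = int(np.argmin(live_ll))
        threshold = live_ll[worst]
        log_w = -(i - 1) / n_live + log_shell
        dead_om.append(float(live_om[worst]))
        dead_ll.append(float(threshold))
        dead_logw.append(log_w)
        log_z = np.logaddexp(log_z, threshold + log_w)

        # clone a survivor and walk it within the likelihood constraint
        if n_live > 1:
            start = worst
            while start == worst:
                start = int(rng.integers(n_live))
        else:  # pragma: no cover - n_live >= 10 enforced above
            start = worst
        cur_om = float(live_om[start])
        cur_ll = float(live_ll[start])
        spread = float(live_om.max() - live_om.min()) or width
        step = min(max(step, 1e-12 * width), width)
        n_acc = n_rej = 0
        for _ in range(n_walk_steps):
            prop = cur_om + step * rng.standard_normal()
            if not (omega_min <= prop <= omega_max):
                n_rej += 1
                continue
            pll = float(loglike(prop))
            if pll >= threshold:
                cur_om, cur_ll = prop, pll
                n_acc += 1
            else:
                n_rej += 1
        # Sivia-style adaptation toward ~50% acceptance
        if n_acc > n_rej:
            step *= math.exp(1.0 / max(n_acc, 1))
        elif n_rej > n_acc:
            step /= math.exp(1.0 / max(n_rej, 1))
        step = min(step, spread if spread > 0 else width)
        live_om[worst], live_ll[worst] = cur_om, cur_ll
        n_iter = i

        log_x = -i / n_live
        if float(live_ll.max()) + log_x <= log_z + math.log(rel_tail):
            break

    # remaining prior mass, spread evenly over the live points
    log_x_final = -n_iter / n_live
    for om, ll in zip(live_om, live_ll):
        lw = log_x_final - math.log(n_live)
        dead_om.append(float(om))
        dead_ll.append(float(ll))
        dead_logw.append(lw)
        log_z = np.logaddexp(log_z, ll + lw)

    ll_arr = np.array(dead_ll)
    logw_arr = np.array(dead_logw)
    om_arr = np.array(dead_om)
    log_p = ll_arr + logw_arr - log_z
    p = np.exp(log_p)
    p /= p.sum()
    info = float(np.sum(p * (ll_arr - log_z)))
    sd = math.sqrt(max(info, 0.0) / n_live)
    sd = max(sd, 1e-12)
    flat = bool(ll_arr.max() - ll_arr.min() < 1e-12)
    samples = rng.choice(om_arr, size=n_posterior_samples, p=p, replace=True)
    return EvidenceResult(
        log_evidence=float(log_z),
        log_evidence_sd=sd,
        posterior_samples=samples,
        n_live=n_live,
        n_iterations=n_iter,
        information=info,
        flat_likelihood=flat,
    )


def nested_sampling(
    ts: TimeSeries,
    omega_range: tuple[float, float],
    spec: ModelSpec,
    *,
    n_live: int = 50,
    n_target_samples: int = 300,
    seed: int | None = None,
    **kwargs,
) -> EvidenceResult:
    """Nested-sampling evidence for one background model on one series.

    The likelihood is ``exp`` of the marginalized log posterior statistic
    and the prior over omega is uniform on ``omega_range``; the prior
    density ``1 / (omega_max - omega_min)`` is folded into the weights so
    the result matches :func:`quadrature_evidence` directly.
    """
    omega_min, omega_max = float(omega_range[0]), float(omega_range[1])
    evaluator = _PosteriorEvaluator(ts.times, ts.values, spec)
    return nested_sampling_loglike(
        evaluator.loglike,
        omega_min,
        omega_max,
        n_live=n_live,
        n_target_samples=n_target_samples,
        seed=seed,
        **kwargs,
    )


def log_trapezoid(log_f: np.ndarray, x: np.ndarray) -> float:
    """log of the trapezoid integral of exp(log_f) over x, shift-stabilized."""
    log_f = np.asarray(log_f, dtype=float)
    shift = log_f.max()
    return float(np.log(np.trapezoid(np.exp(log_f - shift), x)) + shift)


def quadrature_evidence(
    ts: TimeSeries, grid: FrequencyGrid, spec: ModelSpec
) -> float:
    """Deterministic log evidence by dense trapezoid quadrature.

    Valid because the marginalized parameter space is one-dimensional;
    a grid of >= 1024 points is recommended for smooth likelihoods.
    Returns ``log( integral of L(omega) * prior(omega) d omega )`` with the
    uniform prior ``1 / (omega_max - omega_min)``.
    """
    evaluator = _PosteriorEvaluator(ts.times, ts.values, spec)
    logl = np.array([evaluator.loglike(omega) for omega in grid.omegas])
    log_prior = -math.log(grid.omega_max - grid.omega_min)
    return log_trapezoid(logl, grid.omegas) + log_prior
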