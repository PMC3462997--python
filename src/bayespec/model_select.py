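"""Background-model comparison via posterior model ratios.

Two hypotheses that differ only in their Legendre background order are
compared through the ratio of their evidences times the prior odds::

    P(H_i | D) / P(H_j | D) = [P(H_i) / P(H_j)] * [P(D | H_i) / P(D | H_j)]

with ``H_i`` the model with fewer functions.  A ratio above one (positive
log ratio) prefers the simpler model.  :func:`auto_select` automates the
scan: it compares background order ``k`` against ``k + 1`` for increasing
``k`` and stops at the first order that defeats its extension — a greedy
Occam schedule that caps the number of nested-sampling runs.

Every model's evidence is computed by nested sampling started from the
*same* seed on the same data and frequency range (common random numbers):
the prior-mass shrinkage errors of the two runs are then strongly
correlated and largely cancel in the ratio, and a model's evidence depends
only on (data, model, range, seed) — never on which comparison requested
it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import ModelSpec
from .evidence import EvidenceResult, nested_sampling
from .spectrum import FrequencyGrid, PosteriorSpectrum, posterior_spectrum
from .timeseries import TimeSeries

__all__ = ["ModelComparison", "AutoSelectResult", "model_ratio", "auto_select"]

DEFAULT_MAX_BACKGROUND = 6


@dataclass(frozen=True)
class ModelComparison:
    """Outcome of one simpler-vs-complex background comparison."""

    simpler: ModelSpec
    complex: ModelSpec
    log_ratio: float  # log prior odds + log Z_simpler - log Z_complex
    prior_odds: float
    decision: str  # "simpler" or "complex"
    evidence_simpler: EvidenceResult
    evidence_complex: EvidenceResult

    def as_dict(self) -> dict:
        """JSON-compatible comparison report."""
        return {
            "n_background_simpler": self.simpler.n_background,
            "n_background_complex": self.complex.n_background,
            "log_evidence_simpler": self.evidence_simpler.log_evidence,
            "log_evidence_simpler_sd": self.evidence_simpler.log_evidence_sd,
            "log_evidence_complex": self.evidence_complex.log_evidence,
            "log_evidence_complex_sd": self.evidence_complex.log_evidence_sd,
            "prior_odds": self.prior_odds,
            "log_ratio": self.log_ratio,
            "decision": self.decision,
        }


@dataclass(frozen=True)
class AutoSelectResult:
    """Selected background model with its spectrum and comparison trail."""

    spec: ModelSpec
    spectrum: PosteriorSpectrum
    comparisons: tuple[ModelComparison, ...] = ()
    capped: bool = False  # True if the scan hit max_background without a winner


def _model_seed(seed: int | None, spec: ModelSpec) -> int | None:
    """Seed for one model's evidence run: shared across models (common
    random numbers), so comparison noise largely cancels in the ratio."""
    return seed


def _compare(
    simpler: ModelSpec,
    complex_spec: ModelSpec,
    ev_s: EvidenceResult,
    ev_c: EvidenceResult,
    prior_odds: float,
) -> ModelComparison:
    log_ratio = float(
        np.log(prior_odds) + ev_s.log_evidence - ev_c.log_evidence
    )
    return ModelComparison(
        simpler=simpler,
        complex=complex_spec,
        log_ratio=log_ratio,
        prior_odds=float(prior_odds),
        # exact ties (identical models, identical seeds) go to the simpler
        # model — the Occam default
        decision="simpler" if log_ratio >= 0 else "complex",
        evidence_simpler=ev_s,
        evidence_complex=ev_c,
    )


def model_ratio(
    ts: TimeSeries,
    simpler: ModelSpec,
    complex: ModelSpec,
    grid: FrequencyGrid,
    *,
    prior_odds: float = 1.0,
    seed: int | None = None,
    n_live: int = 100,
    n_target_samples: int = 3000,
) -> ModelComparison:
    """Compare two background models on the same data and frequency range.

    Both evidences are computed by nested sampling over ``[grid.omega_min,
    grid.omega_max]``; the dropped likelihood constant is shared, so it
    cancels in the ratio.  ``decision`` is ``"simpler"`` exactly when the
    log ratio (including prior odds, default 1) is non-negative.
    """
    if simpler.m > complex.m:
        raise ValueError(
            f"simpler model (m={simpler.m}) must not have more functions "
            f"than complex (m={complex.m}); swap the arguments"
        )
    if complex.m >= ts.n:
        raise ValueError(
            f"complex model has m={complex.m} functions but the series has "
            f"N={ts.n} points"
        )
    if prior_odds <= 0:
        raise ValueError(f"prior_odds must be positive, got {prior_odds}")
    omega_range = (grid.omega_min, grid.omega_max)
    ev_s = nested_sampling(
        ts,
        omega_range,
        simpler,
        n_live=n_live,
        n_target_samples=n_target_samples,
        seed=_model_seed(seed, simpler),
    )
    ev_c = nested_sampling(
        ts,
        omega_range,
        complex,
        n_live=n_live,
        n_target_samples=n_target_samples,
        seed=_model_seed(seed, complex),
    )
    return _compare(simpler, complex, ev_s, ev_c, prior_odds)


def auto_select(
    ts: TimeSeries,
    grid: FrequencyGrid,
    *,
    max_background: int = DEFAULT_MAX_BACKGROUND,
    prior_odds: float = 1.0,
    seed: int | None = None,
    n_live: int = 100,
    n_target_samples: int = 3000,
) -> AutoSelectResult:
    """Choose the Legendre background order automatically.

    Scans ``k = 0, 1, 2, ...``: at each step the evidence of background
    order ``k`` is compared to order ``k + 1``; the first ``k`` whose ratio
    favours the simpler model is selected and its posterior spectrum
    returned.  If no order wins before ``max_background``, that cap is
    returned with ``capped=True``.  Evidences are cached, so a scan to
    order ``k`` costs ``k + 2`` nested-sampling runs.
    """
    if max_background < 0:
        raise ValueError(f"max_background must be >= 0, got {max_background}")
    if 2 + max_background >= ts.n:
        raise ValueError(
            f"max_background={max_background} implies m={2 + max_background} "
            f">= N={ts.n}"
        )
    omega_range = (grid.omega_min, grid.omega_max)
    cache: dict[int, EvidenceResult] = {}

    def evidence(k: int) -> EvidenceResult:
        if k not in cache:
            spec_k = ModelSpec(n_background=k)
            cache[k] = nested_sampling(
                ts,
                omega_range,
                spec_k,
                n_live=n_live,
                n_target_samples=n_target_samples,
                seed=_model_seed(seed, spec_k),
            )
        return cache[k]

    comparisons: list[ModelComparison] = []
    chosen = max_background
    capped = max_background > 0
    for k in range(max_background):
        cmp_k = _compare(
            ModelSpec(k), ModelSpec(k + 1), evidence(k), evidence(k + 1), prior_odds
        )
        comparisons.append(cmp_k)
        if cmp_k.decision == "simpler":
            chosen = k
            capped = False
            break
    selected = ModelSpec(n_background=chosen)
    return AutoSelectResult(
        spec=selected,
        spectrum=posterior_spectrum(ts, grid, selected),
        comparisons=tuple(comparisons),
        capped=capped,
    )
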