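"""Model-function construction and discrete orthonormalization.

The hypothesis for one angular frequency ``omega`` is a linear model with
``m = 2 + n_background`` functions of time: the harmonic pair ``sin(omega t)``,
``cos(omega t)`` plus ``n_background`` Legendre polynomials (degrees
``0 .. n_background - 1``) that absorb slow background trends without any
detrending of the data.  Legendre polynomials are evaluated on the sample
times mapped affinely onto [-1, 1].

The frequency posterior needs these functions orthonormalized *on the actual
sample points* — harmonics are not orthogonal on an arbitrary, possibly
nonuniform time grid, so the orthonormal set is rebuilt for every ``omega``.
A QR factorization (with an SVD rank guard) is used rather than classical
Gram–Schmidt: it is numerically stabler when ``sin(omega t)`` is nearly
collinear with a low-order polynomial at small ``omega``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = [
    "ModelSpec",
    "OrthoBasis",
    "RankDeficiencyError",
    "raw_basis",
    "build_ortho_basis",
    "RANK_RTOL",
]

#: Singular values below this fraction of the largest one mean the model
#: functions are numerically collinear on the given time points.
RANK_RTOL = 1e-10


class RankDeficiencyError(np.linalg.LinAlgError):
    """Model functions are numerically collinear at a given frequency."""

    def __init__(self, omega: float, detail: str = ""):
        self.omega = float(omega)
        msg = f"model functions are rank-deficient at omega={omega:.6g} rad/s"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


@dataclass(frozen=True)
class ModelSpec:
    """Model hypothesis: one harmonic pair plus Legendre background terms.

    ``n_background`` counts the Legendre polynomials (degree 0 upward), so
    ``n_background = 1`` adds a constant offset, ``2`` adds constant +
    linear drift, and so on.  The total number of model functions is
    ``m = 2 + n_background``.
    """

    n_background: int = 0

    def __post_init__(self) -> None:
        if int(self.n_background) != self.n_background or self.n_background < 0:
            raise ValueError(
                f"n_background must be a non-negative integer, got {self.n_background!r}"
            )
        object.__setattr__(self, "n_background", int(self.n_background))

    @property
    def m(self) -> int:
        """Total model-function count (harmonic pair + background)."""
        return 2 + self.n_background


@dataclass(frozen=True)
class OrthoBasis:
    """Orthonormalized model functions evaluated on the sample points.

    ``phi`` has shape ``(m, N)`` and satisfies
    ``sum_i phi[j, i] * phi[k, i] = delta_jk`` on the discrete time points
    the basis was built for.
    """

    omega: float
    phi: np.ndarray
    from_spec: ModelSpec

    @property
    def m(self) -> int:
        return self.phi.shape[0]

    @property
    def n(self) -> int:
        return self.phi.shape[1]


def raw_basis(omega: float, times: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Evaluate the un-orthonormalized model functions on ``times``.

    Rows 0–1 are ``sin(omega t)`` and ``cos(omega t)``; rows 2 onward are
    Legendre polynomials of degree 0, 1, ... evaluated at
    ``u = 2 (t - t_min) / (t_max - t_min) - 1``.

    Returns
    -------
    ndarray of shape ``(m, N)``.
    """
    if not omega > 0:
        raise ValueError(f"omega must be positive, got {omega}")
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("times must be a 1-D vector with at least 2 points")
    t_min, t_max = float(t[0]), float(t[-1])
    if t_max == t_min:
        raise ValueError("degenerate time vector: t_max == t_min")
    rows = [np.sin(omega * t), np.cos(omega * t)]
    if spec.n_background > 0:
        u = 2.0 * (t - t_min) / (t_max - t_min) - 1.0
        # legvander columns are P_0(u) .. P_{deg}(u)
        rows.append(npleg.legvander(u, spec.n_background - 1).T)
    return np.vstack(rows)


def build_ortho_basis(omega: float, times: np.ndarray, spec: ModelSpec) -> OrthoBasis:
    """Orthonormalize the raw model functions on the given sample points.

    The returned basis spans the same function space as :func:`raw_basis`
    (QR preserves column span), with Gram matrix equal to the identity to
    machine precision.

    Raises
    ------
    RankDeficiencyError
        If the raw functions are numerically collinear on ``times``
        (smallest singular value below ``RANK_RTOL`` times the largest).
    ValueError
        If ``m >= N`` — the posterior exponent ``(m - N)/2`` must be
        negative, so the model may never have as many functions as there
        are data points.
    """
    t = np.asarray(times, dtype=float)
    psi = raw_basis(omega, t, spec)
    m, n = psi.shape
    if m >= n:
        raise ValueError(
            f"model has m={m} functions but only N={n} points; m < N is required"
        )
    a = psi.T  # (N, m): columns are model functions
    sv = np.linalg.svd(a, compute_uv=False)
    if sv[-1] < RANK_RTOL * sv[0]:
        raise RankDeficiencyError(
            omega, f"singular value ratio {sv[-1] / sv[0]:.3g}"
        )
    q, _ = np.linalg.qr(a, mode="reduced")
    return OrthoBasis(omega=float(omega), phi=q.T, from_spec=spec)
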