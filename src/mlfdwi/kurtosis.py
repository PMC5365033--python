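"""Moments and excess kurtosis of the time-fractional subdiffusion propagator.

For time-fractional subdiffusion (order ``alpha`` in time, Gaussian jumps)
the propagator's even moments follow power laws in time,

    <x^2>(t) = 2 D t^alpha / Gamma(alpha + 1)
    <x^4>(t) = 24 D^2 t^(2 alpha) / Gamma(2 alpha + 1)

so the excess kurtosis K = <x^4>/<x^2>^2 - 3 is a pure function of alpha:

    K_MLF(alpha) = 6 Gamma(alpha+1)^2 / Gamma(2 alpha + 1) - 3,

strictly decreasing from 3 (alpha -> 0) to 0 (alpha = 1, the Gaussian
limit).  This closed form converts a fitted subdiffusion order directly
into a kurtosis value, with no restriction on the b-range sampled -- the
conceptual bridge between subdiffusion fitting and diffusional kurtosis
imaging.  The same Gamma-ratio, divided by 3, appears as a universal
scaling law for the ratio of a subdiffusing particle's mean squared
displacement to its squared mean drift (Goychuk's relation), which is
exposed here as :func:`goychuk_ratio`.

An independent finite-difference oracle recovers the moments by
differentiating the characteristic function at q = 0, tying the closed
forms to the Mittag-Leffler kernel they were derived from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import gammaln

from .exceptions import AccuracyError, DomainError
from .mlf import ALPHA_MIN
from .models import cf_subdiffusion

__all__ = [
    "MomentSet",
    "msd_subdiffusion",
    "fourth_moment_subdiffusion",
    "excess_kurtosis",
    "kurtosis_from_alpha",
    "alpha_from_kurtosis",
    "goychuk_ratio",
    "kurtosis_oracle_from_cf",
    "pdf_excess_kurtosis",
    "K_MLF_LIMIT",
]

#: Supremum of K_MLF over alpha in (0, 1], attained in the limit alpha -> 0.
K_MLF_LIMIT = 3.0


@dataclass(frozen=True)
class MomentSet:
    """Second and fourth moments of a propagator with its excess kurtosis.

    m2 : second moment <x^2> (mm2)
    m4 : fourth moment <x^4> (mm4)
    K_t : true excess kurtosis m4/m2^2 - 3 (dimensionless)
    """

    m2: float
    m4: float

    def __post_init__(self) -> None:
        if not (self.m2 > 0 and self.m4 > 0):
            raise DomainError("moments must be positive")
        if self.m4 < self.m2 ** 2 * (1.0 - 1e-12):
            raise DomainError("m4 >= m2^2 violated (Cauchy-Schwarz)")

    @property
    def K_t(self) -> float:
        return self.m4 / self.m2 ** 2 - 3.0


def _check_alpha(alpha: float) -> None:
    if not (0.0 < alpha <= 1.0):
        raise DomainError(f"alpha must be in (0, 1], got {alpha!r}")
    if alpha < ALPHA_MIN:
        raise DomainError(f"alpha below supported minimum {ALPHA_MIN}")


def msd_subdiffusion(D_a2: float, alpha: float, t: float) -> float:
    """Mean squared displacement 2 D_{a,2} t^alpha / Gamma(alpha+1)."""
    _check_alpha(alpha)
    if D_a2 <= 0 or t < 0:
        raise DomainError("D_a2 must be positive and t non-negative")
    if t == 0:
        return 0.0
    return 2.0 * D_a2 * t ** alpha * np.exp(-gammaln(alpha + 1.0))


def fourth_moment_subdiffusion(D_a2: float, alpha: float, t: float) -> float:
    """Fourth moment 24 D_{a,2}^2 t^(2 alpha) / Gamma(2 alpha + 1)."""
    _check_alpha(alpha)
    if D_a2 <= 0 or t < 0:
        raise DomainError("D_a2 must be positive and t non-negative")
    if t == 0:
        return 0.0
    return 24.0 * D_a2 ** 2 * t ** (2.0 * alpha) * np.exp(-gammaln(2.0 * alpha + 1.0))


def excess_kurtosis(moments: MomentSet) -> float:
    """Excess kurtosis m4 / m2^2 - 3 of a MomentSet."""
    return moments.K_t


def kurtosis_from_alpha(alpha: float) -> float:
    """Excess kurtosis of the subdiffusion propagator from its order alpha.

    K_MLF = 6 Gamma(alpha+1)^2 / Gamma(2 alpha + 1) - 3.  D and t cancel
    exactly, so this depends on alpha alone.  K_MLF(1) = 0;
    K_MLF -> 3 as alpha -> 0 (exposed as :data:`K_MLF_LIMIT`).
    """
    if not (0.0 < alpha <= 1.0):
        raise DomainError(f"alpha must be in (0, 1], got {alpha!r}")
    return 6.0 * np.exp(2.0 * gammaln(alpha + 1.0) - gammaln(2.0 * alpha + 1.0)) - 3.0


def alpha_from_kurtosis(K: float, tol: float = 1e-12) -> float:
    """Numerical inverse of :func:`kurtosis_from_alpha` on (0, 1].

    K_MLF is strictly decreasing in alpha, so the inverse is unique.
    Valid for K in [0, 3); K = 0 maps to alpha = 1.
    """
    if not (0.0 <= K < K_MLF_LIMIT):
        raise DomainError(f"K must be in [0, 3), got {K!r}")
    if K == 0.0:
        return 1.0
    lo = 1e-8  # kurtosis_from_alpha is continuous down to 0+
    if K >= kurtosis_from_alpha(lo):
        return lo
    return float(brentq(lambda a: kurtosis_from_alpha(a) - K, lo, 1.0,
                        xtol=tol, rtol=8.9e-16))


def goychuk_ratio(alpha: float) -> float:
    """Universal scaling ratio 2 Gamma(alpha+1)^2 / Gamma(2 alpha+1) - 1.

    The long-time ratio of a subdiffusing particle's MSD to its squared
    mean position under a constant force; algebraically equal to
    ``kurtosis_from_alpha(alpha) / 3``.
    """
    if not (0.0 < alpha <= 1.0):
        raise DomainError(f"alpha must be in (0, 1], got {alpha!r}")
    return 2.0 * np.exp(2.0 * gammaln(alpha + 1.0) - gammaln(2.0 * alpha + 1.0)) - 1.0


def kurtosis_oracle_from_cf(D_a2: float, alpha: float, t: float,
                            rel_step: float | None = None) -> MomentSet:
    """Moments recovered by finite differencing the characteristic function.

    m2 = -d^2 p/dq^2 at q = 0 (5-point stencil) and m4 = d^4 p/dq^4 at
    q = 0 (7-point stencil), with p(q, t) = E_alpha(-D q^2 t^alpha)
    evaluated by the Mittag-Leffler kernel.  Serves as an independent
    check of the closed-form moment laws.
    """
    _check_alpha(alpha)
    if D_a2 <= 0 or t <= 0:
        raise DomainError("D_a2 and t must be positive")
    # natural q scale: p decays on q ~ 1/sqrt(D t^alpha)
    q_scale = 1.0 / np.sqrt(D_a2 * t ** alpha)
    # h ~ tol^(1/order) balancing truncation vs roundoff of the stencils
    h2 = q_scale * (rel_step or 1e-16 ** (1.0 / 6.0))
    h4 = q_scale * (rel_step or 1e-16 ** (1.0 / 8.0))
    if h2 == 0.0 or h4 == 0.0:
        raise AccuracyError("finite-difference step underflowed")

    def p(q):
        return cf_subdiffusion(q, t, D_a2, alpha)

    k2 = np.arange(-2, 3)
    w2 = np.array([-1.0, 16.0, -30.0, 16.0, -1.0]) / 12.0
    d2 = np.dot(w2, p(k2 * h2)) / h2 ** 2
    k4 = np.arange(-3, 4)
    w4 = np.array([-1.0, 12.0, -39.0, 56.0, -39.0, 12.0, -1.0]) / 6.0
    d4 = np.dot(w4, p(k4 * h4)) / h4 ** 4
    return MomentSet(m2=float(-d2), m4=float(d4))


def pdf_excess_kurtosis(pdf, scale: float = 1.0, upper: float = 60.0,
                        tol: float = 1e-10) -> float:
    """Excess kurtosis of a symmetric pdf by numerical quadrature.

    Integrates x^2 pdf(x) and x^4 pdf(x) over [0, upper*scale] (doubled by
    symmetry) and returns m4/m2^2 - 3.  Used to validate reference values
    such as the Gaussian (0) and the hyperbolic secant (+2).
    """
    kw = dict(epsabs=1e-14, epsrel=tol, limit=400)
    m2 = 2.0 * quad(lambda x: x * x * pdf(x), 0.0, upper * scale, **kw)[0]
    m4 = 2.0 * quad(lambda x: x ** 4 * pdf(x), 0.0, upper * scale, **kw)[0]
    return m4 / m2 ** 2 - 3.0
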