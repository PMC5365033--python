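"""Closed-form diffusion-signal models and pulse-sequence arithmetic.

Normalized signal decay S/S0 as a function of the diffusion weighting b
(s/mm2), in four nested parameterizations:

* ``model_mono``  -- exp(-b D), the Gaussian/monoexponential ADC model;
* ``model_mlf2``  -- E_a(-b D), time-fractional subdiffusion (2 params);
* ``model_mlf3``  -- E_a(-(b D)**(beta/2)), time- and space-fractional
  (3 params; beta = 2 recovers the 2-parameter form, alpha = 1 with
  beta < 2 the stretched exponential);
* ``model_dki``   -- exp(-b D + b**2 D**2 K_app / 6), the kurtosis
  expansion, valid only up to its exponent apex b* = 3 / (D K_app).

Also here: Stejskal-Tanner two-pulse arithmetic (b, q, effective
diffusion time), the probe-length/displacement scales used to interpret a
protocol, and the unit conversion between the generalized diffusion
constant D_{a,b} (mm^beta / s^alpha) and the classical diffusivity
(mm2/s).

Unit conventions: b in s/mm2, D in mm2/s, times in seconds, q in 1/mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, InputError
from .mlf import DEFAULT_CONFIG, MLFEvalConfig, mittag_leffler

__all__ = [
    "AcquisitionProtocol",
    "DecayCurve",
    "AnomalousParams",
    "GeneralizedDiffusivity",
    "effective_diffusion_time",
    "q_value",
    "b_value",
    "probe_length_scale",
    "net_displacement",
    "model_mono",
    "model_mlf2",
    "model_mlf3",
    "model_dki",
    "cf_general",
    "cf_subdiffusion",
    "cf_superdiffusion",
    "generalized_to_classical",
]

#: gyromagnetic ratio of the proton, rad s^-1 T^-1
GAMMA_PROTON = 2.6752218744e8


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Two-pulse (Stejskal-Tanner spin-echo) gradient timing.

    gamma : gyromagnetic ratio (rad s^-1 T^-1)
    G     : diffusion gradient amplitude (T/mm)
    delta : gradient pulse duration (s)
    Delta : gradient pulse separation (s)
    """

    gamma: float = GAMMA_PROTON
    G: float = 0.0
    delta: float = 0.0
    Delta: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.delta < 0 or self.Delta < 0 or self.G < 0:
            raise DomainError("protocol parameters must be non-negative (gamma > 0)")
        if self.delta > self.Delta:
            raise DomainError("pulse duration delta must not exceed separation Delta")


@dataclass
class DecayCurve:
    """(b, signal) samples for one voxel or ROI.

    b values in s/mm2, signal magnitudes in arbitrary units.  Samples are
    sorted by b on construction; ``s0`` defaults to the measured signal at
    the smallest b (which must then be 0 for normalized fitting).
    """

    b: np.ndarray
    signal: np.ndarray
    s0: float | None = None

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if b.shape != s.shape or b.ndim != 1:
            raise InputError("b and signal must be 1-D arrays of equal length")
        if np.any(b < 0):
            raise InputError("b-values must be non-negative")
        order = np.argsort(b, kind="stable")
        b, s = b[order], s[order]
        if np.any(np.diff(b) <= 0):
            raise InputError("b-values must be distinct")
        if np.any(s <= 0):
            raise InputError("signal must be positive")
        self.b, self.signal = b, s
        if self.s0 is None:
            self.s0 = float(s[0]) if b[0] == 0 else None

    def __len__(self) -> int:
        return len(self.b)


@dataclass
class AnomalousParams:
    """Fitted parameters of one decay model.

    Fields unused by ``model`` are None.  ``alpha`` is the time-fractional
    order in (0, 1], ``beta`` the space-fractional order in (1, 2],
    ``K_app`` the apparent excess kurtosis of the kurtosis expansion.
    """

    model: str
    D: float
    alpha: float | None = None
    beta: float | None = None
    K_app: float | None = None

    def __post_init__(self) -> None:
        if self.model not in {"mono", "mlf2", "mlf3", "dki"}:
            raise DomainError(f"unknown model {self.model!r}")
        if not (self.D > 0 and np.isfinite(self.D)):
            raise DomainError("D must be positive and finite")
        if self.alpha is not None and not (0.0 < self.alpha <= 1.0):
            raise DomainError("alpha must be in (0, 1]")
        if self.beta is not None and not (1.0 < self.beta <= 2.0):
            raise DomainError("beta must be in (1, 2]")
        if self.K_app is not None and not np.isfinite(self.K_app):
            raise DomainError("K_app must be finite")


@dataclass(frozen=True)
class GeneralizedDiffusivity:
    """Generalized diffusion constant with its unit-preserving scales.

    D_ab : generalized diffusion constant (mm^beta / s^alpha)
    mu   : length-scale parameter (mm)
    tau  : time-scale parameter (s)
    """

    D_ab: float
    mu: float = 1.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.D_ab <= 0 or self.mu <= 0 or self.tau <= 0:
            raise DomainError("D_ab, mu and tau must be positive")


# ---------------------------------------------------------------------------
# pulse-sequence arithmetic


def effective_diffusion_time(protocol: AcquisitionProtocol) -> float:
    """Effective diffusion time t = Delta - delta/3 (s)."""
    return protocol.Delta - protocol.delta / 3.0


def q_value(protocol: AcquisitionProtocol) -> float:
    """Spatial-frequency weighting q = gamma G delta (1/mm)."""
    return protocol.gamma * protocol.G * protocol.delta


def b_value(protocol: AcquisitionProtocol) -> float:
    """Diffusion weighting b = (gamma G delta)^2 (Delta - delta/3) = q^2 t (s/mm2)."""
    q = q_value(protocol)
    return q * q * effective_diffusion_time(protocol)


def probe_length_scale(b: float, t: float) -> float:
    """Length scale probed by a measurement, 1/q with q = sqrt(b/t) (mm).

    Convention: reciprocal spatial frequency without a 2*pi factor.
    """
    if b <= 0:
        raise DomainError("length scale undefined at b = 0")
    if t <= 0:
        raise DomainError("diffusion time must be positive")
    return 1.0 / np.sqrt(b / t)


def net_displacement(D: float, t: float) -> float:
    """Root-mean-square net displacement sqrt(2 D t) (mm) in one dimension."""
    if D < 0 or t < 0:
        raise DomainError("D and t must be non-negative")
    return float(np.sqrt(2.0 * D * t))


# ---------------------------------------------------------------------------
# signal models (normalized S/S0 as a function of b)


def model_mono(b, D: float):
    """Monoexponential decay exp(-b D)."""
    return np.exp(-np.asarray(b, dtype=float) * D)


def model_mlf2(b, D: float, alpha: float, config: MLFEvalConfig = DEFAULT_CONFIG):
    """Two-parameter subdiffusion decay E_alpha(-b D)."""
    if D <= 0:
        raise DomainError("D must be positive")
    return mittag_leffler(alpha, -np.asarray(b, dtype=float) * D, config)


def model_mlf3(b, D: float, alpha: float, beta: float,
               config: MLFEvalConfig = DEFAULT_CONFIG):
    """Three-parameter decay E_alpha(-(b D)**(beta/2)).

    beta = 2 recovers :func:`model_mlf2`; alpha = 1 gives the stretched
    exponential exp(-(b D)**(beta/2)).
    """
    if D <= 0:
        raise DomainError("D must be positive")
    if not (1.0 < beta <= 2.0):
        raise DomainError("beta must be in (1, 2]")
    b_arr = np.asarray(b, dtype=float)
    # (bD)**(beta/2) via exp((beta/2) log(bD)); b = 0 short-circuits to 1
    arg = np.zeros_like(b_arr, dtype=float)
    nz = b_arr > 0
    arg[nz] = np.exp(0.5 * beta * np.log(b_arr[nz] * D))
    out = mittag_leffler(alpha, -arg, config)
    return out if b_arr.ndim else float(np.asarray(out))


def model_dki(b, D: float, K_app: float):
    """Kurtosis-expansion decay exp(-b D + (1/6) b^2 D^2 K_app).

    The formula is computed as written for any b; for K_app > 0 it stops
    decreasing at the exponent apex b* = 3/(D K_app).  Range policing is
    the fitting layer's job.
    """
    if D <= 0:
        raise DomainError("D must be positive")
    b_arr = np.asarray(b, dtype=float)
    return np.exp(-b_arr * D + (b_arr * D) ** 2 * K_app / 6.0)


def dki_apex(D: float, K_app: float) -> float:
    """b-value at which the kurtosis-expansion exponent turns around."""
    if K_app <= 0:
        return np.inf
    return 3.0 / (D * K_app)


# ---------------------------------------------------------------------------
# characteristic functions p(q, t) of the propagator


def cf_general(q, t: float, gd: GeneralizedDiffusivity, alpha: float, beta: float,
               config: MLFEvalConfig = DEFAULT_CONFIG):
    """General CTRW characteristic function E_alpha(-D_ab |q|^beta t^alpha)."""
    if not (1.0 < beta <= 2.0):
        raise DomainError("beta must be in (1, 2]")
    q_arr = np.abs(np.asarray(q, dtype=float))
    return mittag_leffler(alpha, -gd.D_ab * q_arr ** beta * t ** alpha, config)


def cf_subdiffusion(q, t: float, D_a2: float, alpha: float,
                    config: MLFEvalConfig = DEFAULT_CONFIG):
    """Time-fractional characteristic function E_alpha(-D_{a,2} q^2 t^alpha)."""
    if D_a2 <= 0:
        raise DomainError("D_a2 must be positive")
    q_arr = np.asarray(q, dtype=float)
    return mittag_leffler(alpha, -D_a2 * q_arr ** 2 * t ** alpha, config)


def cf_superdiffusion(q, t: float, D_1b: float, beta: float):
    """Space-fractional characteristic function exp(-D_{1,b} |q|^beta t)."""
    if D_1b <= 0:
        raise DomainError("D_1b must be positive")
    if not (1.0 < beta <= 2.0):
        raise DomainError("beta must be in (1, 2]")
    q_arr = np.abs(np.asarray(q, dtype=float))
    return np.exp(-D_1b * q_arr ** beta * t)


def generalized_to_classical(gd: GeneralizedDiffusivity, alpha: float, beta: float,
                             t: float) -> tuple[float, float]:
    """Convert D_{a,b} to the classical diffusivity at diffusion time t.

    Returns ``(D**(beta/2), D)`` with

        D**(beta/2) = D_12 * tau**(1-alpha) * mu**(2(1-beta/2)) * t**(alpha-beta/2)

    where D_12 = ``gd.D_ab`` read in classical units through the mu/tau
    scales.  At alpha = 1, beta = 2 the conversion is the identity
    D = D_12 for any mu, tau.
    """
    if not (0.0 < alpha <= 1.0):
        raise DomainError("alpha must be in (0, 1]")
    if not (1.0 < beta <= 2.0):
        raise DomainError("beta must be in (1, 2]")
    if t <= 0:
        raise DomainError("t must be positive")
    d_pow = (
        gd.D_ab
        * gd.tau ** (1.0 - alpha)
        * gd.mu ** (2.0 * (1.0 - beta / 2.0))
        * t ** (alpha - beta / 2.0)
    )
    return float(d_pow), float(d_pow ** (2.0 / beta))
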