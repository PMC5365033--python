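"""One-dimensional continuous-time random walk (CTRW) Monte Carlo.

A walker alternates waiting times and jumps.  Four regimes arise from
combining light- and heavy-tailed laws:

===========  ==========  =================================================
waiting law  jump law    regime
===========  ==========  =================================================
gaussian     gaussian    Brownian motion (MSD ~ t)
pareto(a)    gaussian    time-fractional subdiffusion (MSD ~ t^a, a < 1)
gaussian     pareto(b)   space-fractional superdiffusion (infinite-variance
                         jumps; plain MSD diverges)
pareto(a)    pareto(b)   combined time- and space-fractional diffusion
===========  ==========  =================================================

Heavy tails use the Pareto distribution with survival function
P(T > t) = (t/c)^-a for t >= c.  The exponent convention is the standard
one under which the waiting-time tail index equals the time-fractional
order ``alpha`` and the jump tail index the space-fractional order
``beta`` (so the subdiffusive MSD law recovers t^alpha); the literal
reciprocal reading of the tail exponents is available through
``exponent_convention="reciprocal"``.  "Gaussian waiting times" are
|N(0,1)| draws, so increments stay positive.

Jumps in the heavy-tailed case are made zero-mean either by a symmetric
random sign (default) or by subtracting the one-sided Pareto mean
c*beta/(beta-1).  For beta in (1, 2] the jump mean is finite but the
variance is not, so infinite-variance regimes are summarized by an
inter-quantile width of x(t) rather than by the (divergent) MSD.

Per-walker RNG substreams are spawned from the master seed, so enlarging
the ensemble does not reshuffle existing walkers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, DomainError, InputError

__all__ = [
    "WalkSpec",
    "WalkPath",
    "sample_waiting_times",
    "sample_jumps",
    "simulate_walks",
    "positions_at",
    "ensemble_msd",
    "ensemble_quantile_width",
    "msd_exponent",
]

_LAWS = {"gaussian", "pareto"}
_CONVENTIONS = {"standard", "reciprocal"}


@dataclass(frozen=True)
class WalkSpec:
    """Ensemble description for the CTRW Monte Carlo.

    alpha, beta : tail parameters of the waiting-time and jump laws
        (used only when the respective law is "pareto").
    c : Pareto scale constant (distribution minimum), default 1.
    n_steps, n_walkers : events per walk and ensemble size.
    seed : master RNG seed.
    time_law, jump_law : "gaussian" or "pareto".
    jump_centering : "symmetric" (random sign) or "mean" (subtract
        c*beta/(beta-1)).
    exponent_convention : "standard" tail indices (-alpha, -beta) or the
        "reciprocal" reading (-1/alpha, -1/beta).
    """

    alpha: float = 1.0
    beta: float = 2.0
    c: float = 1.0
    n_steps: int = 1000
    n_walkers: int = 1
    seed: int = 0
    time_law: str = "gaussian"
    jump_law: str = "gaussian"
    jump_centering: str = "symmetric"
    exponent_convention: str = "standard"

    def __post_init__(self) -> None:
        if self.time_law not in _LAWS or self.jump_law not in _LAWS:
            raise ConfigError(
                f"laws must be one of {sorted(_LAWS)}; got "
                f"{self.time_law!r}/{self.jump_law!r}"
            )
        if self.exponent_convention not in _CONVENTIONS:
            raise ConfigError(f"unknown exponent convention "
                              f"{self.exponent_convention!r}")
        if self.jump_centering not in {"symmetric", "mean"}:
            raise ConfigError(f"unknown jump centering {self.jump_centering!r}")
        if self.c <= 0:
            raise DomainError("c must be positive")
        if self.n_steps < 0 or self.n_walkers < 1:
            raise DomainError("n_steps must be >= 0 and n_walkers >= 1")
        if self.time_law == "pareto" and not (0.0 < self.alpha <= 1.0):
            raise DomainError("pareto waiting times need alpha in (0, 1]")
        if self.jump_law == "pareto" and not (1.0 < self.beta <= 2.0):
            raise DomainError("pareto jumps need beta in (1, 2] "
                              "(beta <= 1 has infinite mean)")


@dataclass
class WalkPath:
    """Event times and cumulative positions of one CTRW realization."""

    event_times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        x = np.asarray(self.positions, dtype=float)
        if t.shape != x.shape:
            raise InputError("event_times and positions must match in length")
        if len(t) and (t[0] < 0 or np.any(np.diff(t) < 0)):
            raise InputError("event_times must be non-decreasing and >= 0")
        self.event_times, self.positions = t, x


def _tail_exponent(value: float, spec: WalkSpec) -> float:
    return value if spec.exponent_convention == "standard" else 1.0 / value


def _pareto(rng: np.random.Generator, n: int, c: float, tail: float) -> np.ndarray:
    # inverse transform on the survival function: T = c * U**(-1/tail)
    u = rng.random(n)
    # U in [0,1); guard exact zeros to keep draws finite
    u = np.where(u == 0.0, np.nextafter(0.0, 1.0), u)
    return c * u ** (-1.0 / tail)


def sample_waiting_times(spec: WalkSpec, n: int,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw n i.i.d. positive waiting times under ``spec.time_law``."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.time_law == "pareto":
        return _pareto(rng, n, spec.c, _tail_exponent(spec.alpha, spec))
    return np.abs(rng.standard_normal(n))


def sample_jumps(spec: WalkSpec, n: int,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw n i.i.d. zero-mean jump lengths under ``spec.jump_law``."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.jump_law == "gaussian":
        return rng.standard_normal(n)
    mag = _pareto(rng, n, spec.c, _tail_exponent(spec.beta, spec))
    if spec.jump_centering == "symmetric":
        signs = rng.integers(0, 2, size=n) * 2 - 1
        return mag * signs
    tail = _tail_exponent(spec.beta, spec)
    if tail <= 1.0:
        raise DomainError("mean centering requires a finite jump mean (tail > 1)")
    return mag - spec.c * tail / (tail - 1.0)


def pareto_survival(t, c: float, tail: float):
    """Survival function (t/c)^-tail for t >= c (1 below c)."""
    t = np.asarray(t, dtype=float)
    return np.where(t < c, 1.0, (t / c) ** (-tail))


def simulate_walks(spec: WalkSpec) -> list[WalkPath]:
    """Simulate ``spec.n_walkers`` independent CTRW sample paths.

    Each path records cumulative event times and positions after each of
    ``spec.n_steps`` events (plus the origin at time 0).  Per-walker RNG
    substreams come from ``SeedSequence(spec.seed).spawn``.
    """
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_walkers)
    paths = []
    for ss in children:
        rng = np.random.Generator(np.random.PCG64(ss))
        waits = sample_waiting_times(spec, spec.n_steps, rng)
        jumps = sample_jumps(spec, spec.n_steps, rng)
        t = np.concatenate([[0.0], np.cumsum(waits)])
        x = np.concatenate([[0.0], np.cumsum(jumps)])
        paths.append(WalkPath(event_times=t, positions=x))
    return paths


def positions_at(paths: list[WalkPath], eval_times) -> np.ndarray:
    """Positions of all walkers at given times (right-continuous steps).

    The walker holds its position between events.  Raises when any
    evaluation time lies beyond the common simulated horizon (the
    smallest final event time in the ensemble).
    """
    eval_times = np.asarray(eval_times, dtype=float)
    horizon = min(p.event_times[-1] for p in paths)
    if np.any(eval_times > horizon):
        raise InputError(
            f"eval_times exceed the simulated horizon ({horizon:g})"
        )
    out = np.empty((len(paths), len(eval_times)))
    for i, p in enumerate(paths):
        idx = np.searchsorted(p.event_times, eval_times, side="right") - 1
        out[i] = p.positions[idx]
    return out


def ensemble_msd(paths: list[WalkPath], eval_times) -> np.ndarray:
    """Ensemble mean squared displacement <x(t)^2> at each evaluation time."""
    x = positions_at(paths, eval_times)
    return np.mean(x ** 2, axis=0)


def ensemble_quantile_width(paths: list[WalkPath], eval_times,
                            central: float = 0.9) -> np.ndarray:
    """Central inter-quantile width of x(t).

    The spread statistic of choice when jump variance is infinite and the
    plain MSD diverges: width of the central ``central`` probability mass.
    """
    if not (0.0 < central < 1.0):
        raise DomainError("central must be in (0, 1)")
    x = positions_at(paths, eval_times)
    lo = (1.0 - central) / 2.0
    return np.quantile(x, 1.0 - lo, axis=0) - np.quantile(x, lo, axis=0)


def msd_exponent(eval_times, msd_curve=None, paths: list[WalkPath] | None = None,
                 n_boot: int = 200, seed: int = 0,
                 ci_level: float = 0.95):
    """Power-law exponent of MSD(t) ~ t^H by log-log least squares.

    Either pass a precomputed ``msd_curve``, or ``paths`` (in which case
    the MSD is computed here and the confidence interval comes from a
    bootstrap over walkers; with only a curve, the CI comes from the
    regression's standard error).

    Returns ``(exponent, (ci_lo, ci_hi))``.
    """
    eval_times = np.asarray(eval_times, dtype=float)
    if np.any(eval_times <= 0):
        raise DomainError("eval_times must be positive for a log-log fit")
    log_t = np.log(eval_times)

    def slope(msd):
        ok = msd > 0  # walkers may all still sit at the origin at early t
        if ok.sum() < 2:
            raise InputError("fewer than 2 positive MSD values for log-log fit")
        A = np.vstack([log_t[ok], np.ones(int(ok.sum()))]).T
        coef, *_ = np.linalg.lstsq(A, np.log(msd[ok]), rcond=None)
        return coef[0]

    if paths is not None:
        x = positions_at(paths, eval_times)
        msd = np.mean(x ** 2, axis=0)
        est = slope(msd)
        rng = np.random.default_rng(seed)
        n = x.shape[0]
        boots = np.empty(n_boot)
        for i in range(n_boot):
            pick = rng.integers(0, n, size=n)
            boots[i] = slope(np.mean(x[pick] ** 2, axis=0))
        lo = (1.0 - ci_level) / 2.0
        return float(est), (float(np.quantile(boots, lo)),
                            float(np.quantile(boots, 1.0 - lo)))
    if msd_curve is None:
        raise InputError("need either msd_curve or paths")
    msd = np.asarray(msd_curve, dtype=float)
    ok = msd > 0
    if ok.sum() < 3:
        raise InputError("need at least 3 positive MSD values for a CI")
    lt = log_t[ok]
    A = np.vstack([lt, np.ones_like(lt)]).T
    coef, res_ss, *_ = np.linalg.lstsq(A, np.log(msd[ok]), rcond=None)
    est = coef[0]
    n = int(ok.sum())
    if n > 2 and len(res_ss):
        s2 = res_ss[0] / (n - 2)
        se = float(np.sqrt(s2 / np.sum((lt - lt.mean()) ** 2)))
    else:
        se = 0.0
    halfwidth = 1.96 * se
    return float(est), (float(est - halfwidth), float(est + halfwidth))
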