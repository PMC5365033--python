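"""Per-curve model fitting, Rician correction, and voxelwise parameter maps.

The pipeline mirrors standard multi-b-value diffusion MRI analysis:

1. magnitude signals are corrected for the Rician noise floor,
   S_rn = sqrt(S^2 - 2 sigma^2), with points at or below the floor set to
   zero, flagged, and excluded from fits;
2. each voxel's decay curve, normalized by its measured S(b=0), is fitted
   by bounded nonlinear least squares to one of the four signal models
   (mono, mlf2, mlf3, dki);
3. for the Mittag-Leffler models the fitted subdiffusion order alpha is
   converted to an excess kurtosis K_MLF through the closed-form
   Gamma-ratio, and a classical ADC is computed from the b = 0 and
   b = 1000 s/mm2 points for reference.

Bounds: D in (1e-5, 1e-1) mm2/s, alpha in [0.01, 1], beta in (1, 2],
K_app in [0, 10].  Optimization uses scipy's trust-region-reflective
least squares: the classical Levenberg-Marquardt step is unavailable with
box bounds, and TRF reduces to the same Gauss-Newton/LM behaviour in the
interior.  Non-convergence triggers up to five seeded, jittered restarts
and is reported through a flag rather than an exception.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import ConfigError, DomainError, InputError
from .kurtosis import kurtosis_from_alpha
from .mlf import ALPHA_MIN, DEFAULT_CONFIG, MLFEvalConfig
from .models import (
    AnomalousParams,
    DecayCurve,
    dki_apex,
    model_dki,
    model_mlf2,
    model_mlf3,
    model_mono,
)

__all__ = [
    "NoiseModel",
    "FitResult",
    "ParameterMaps",
    "rician_correct",
    "two_point_adc",
    "fit_curve",
    "fit_maps",
    "dki_validity_check",
    "estimate_sigma",
]

BOUNDS = {
    "D": (1e-5, 1e-1),
    "alpha": (ALPHA_MIN, 1.0),
    "beta": (1.0 + 1e-6, 2.0),
    "K_app": (0.0, 10.0),
}

_N_PARAMS = {"mono": 1, "mlf2": 2, "mlf3": 3, "dki": 2}
_MAX_RESTARTS = 5


@dataclass(frozen=True)
class NoiseModel:
    """Rician noise description.

    sigma : noise standard deviation, in signal units (scalar, or one
        value per b-sample).
    floor_multiplier : points with S < floor_multiplier * sigma are
        flagged as noise-floor.
    exclude_floor : drop flagged points from fits instead of keeping
        their floor-corrected values.  Off by default: excluding them
        discards the information that the decay has reached the floor and
        biases the fitted order low in fast-decaying voxels (CSF-like),
        whereas the corrected value (zero at the floor) is the least
        biased estimate available.
    """

    sigma: float | np.ndarray = 0.0
    floor_multiplier: float = 2.0
    exclude_floor: bool = False

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.sigma) < 0) or self.floor_multiplier < 0:
            raise DomainError("sigma and floor_multiplier must be >= 0")


NO_NOISE = NoiseModel(0.0)


@dataclass
class FitResult:
    """Outcome of one curve fit."""

    params: AnomalousParams
    residual_norm: float
    converged: bool
    derived_K_MLF: float | None = None
    adc: float | None = None
    n_restarts: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass
class ParameterMaps:
    """Voxelwise parameter maps on the input grid; NaN outside the mask."""

    alpha_map: np.ndarray
    D_map: np.ndarray
    K_MLF_map: np.ndarray
    K_app_map: np.ndarray
    ADC_map: np.ndarray
    mask: np.ndarray
    model: str
    affine: np.ndarray | None = None
    convergence_count: int = 0
    n_fitted: int = 0


def rician_correct(signal, noise: NoiseModel):
    """Rician noise-floor correction S_rn = sqrt(S^2 - 2 sigma^2).

    Where S^2 <= 2 sigma^2 the corrected signal is 0 and the point is
    flagged.  Returns ``(corrected, flagged)`` with ``flagged`` a boolean
    array.
    """
    s = np.asarray(signal, dtype=float)
    if np.any(s < 0):
        raise InputError("magnitude signal must be non-negative")
    sigma = np.broadcast_to(np.asarray(noise.sigma, dtype=float), s.shape)
    arg = s ** 2 - 2.0 * sigma ** 2
    flagged = arg <= 0
    corrected = np.sqrt(np.where(flagged, 0.0, arg))
    return corrected, flagged


def two_point_adc(curve: DecayCurve, b_ref: float = 1000.0) -> float:
    """Classical ADC from the b = 0 and b = b_ref samples, ln(S0/S)/b_ref.

    A negative result (signal increase with b) is returned as-is; callers
    may warn.
    """
    b, s = curve.b, curve.signal
    i0 = np.flatnonzero(b == 0)
    iref = np.flatnonzero(b == b_ref)
    if len(i0) == 0 or len(iref) == 0:
        raise InputError(f"curve must contain b = 0 and b = {b_ref} samples")
    return float(np.log(s[i0[0]] / s[iref[0]]) / b_ref)


def dki_validity_check(params: AnomalousParams, b_max_sampled: float) -> str | None:
    """Warn when sampled b exceeds the kurtosis-expansion apex 3/(D K_app).

    Returns a warning string, or None when the sampling is valid.
    """
    if params.model != "dki" or not params.K_app or params.K_app <= 0:
        return None
    apex = dki_apex(params.D, params.K_app)
    if b_max_sampled > apex:
        return (
            f"sampled b_max = {b_max_sampled:g} exceeds kurtosis-expansion "
            f"apex b* = {apex:g} s/mm2; the fitted decay is non-monotone "
            "inside the sampled range"
        )
    return None


def estimate_sigma(roi_signals) -> float:
    """Noise sigma from a user-drawn homogeneous ROI's signal spread.

    Uses the sample standard deviation of the ROI signal values; in a
    signal-free (air/ventricle-tail) region the magnitude is Rayleigh and
    this overestimates sigma by the fixed Rayleigh factor, which is
    corrected here.
    """
    vals = np.asarray(roi_signals, dtype=float).ravel()
    if vals.size < 2:
        raise InputError("ROI must contain at least 2 voxels")
    # Rayleigh std = sigma * sqrt(2 - pi/2)
    return float(np.std(vals, ddof=1) / np.sqrt(2.0 - np.pi / 2.0))


# ---------------------------------------------------------------------------
# curve fitting


def _predict(model: str, b, theta, config: MLFEvalConfig):
    if model == "mono":
        return model_mono(b, theta[0])
    if model == "mlf2":
        return model_mlf2(b, theta[0], theta[1], config)
    if model == "mlf3":
        return model_mlf3(b, theta[0], theta[1], theta[2], config)
    if model == "dki":
        return model_dki(b, theta[0], theta[1])
    raise ConfigError(f"unknown model {model!r}")


def _bounds_for(model: str):
    names = {
        "mono": ["D"],
        "mlf2": ["D", "alpha"],
        "mlf3": ["D", "alpha", "beta"],
        "dki": ["D", "K_app"],
    }[model]
    lo = np.array([BOUNDS[n][0] for n in names])
    hi = np.array([BOUNDS[n][1] for n in names])
    return names, lo, hi


def _initial_guess(model: str, b, y):
    """D0 from the two-point log slope at the smallest nonzero b."""
    nz = np.flatnonzero(b > 0)
    d0 = 1e-3
    if len(nz) and y[nz[0]] > 0 and y[nz[0]] < 1.0:
        d0 = float(np.clip(-np.log(y[nz[0]]) / b[nz[0]], 2e-5, 5e-2))
    return {
        "mono": [d0],
        "mlf2": [d0, 0.9],
        "mlf3": [d0, 0.9, 1.9],
        "dki": [d0, 0.5],
    }[model]


def fit_curve(curve: DecayCurve, model: str = "mlf2",
              noise: NoiseModel = NO_NOISE, seed: int | None = 0,
              mlf_config: MLFEvalConfig = DEFAULT_CONFIG) -> FitResult:
    """Bounded least-squares fit of one decay curve.

    The curve is Rician-corrected with ``noise``, normalized by its
    measured S(b=0), and fitted to ``model``.  Deterministic for a given
    (curve, model, seed): restarts draw their jitter from
    ``numpy.random.default_rng(seed)``.

    Raises
    ------
    InputError
        When fewer usable points remain than the model has parameters
        (plus the b = 0 anchor).
    """
    if model not in _N_PARAMS:
        raise ConfigError(f"unknown model {model!r}")
    warnings_list: list[str] = []
    b_all = curve.b
    s_all = curve.signal.astype(float)
    corrected, flagged_floor = rician_correct(s_all, noise)
    sigma_arr = np.broadcast_to(np.asarray(noise.sigma, float), s_all.shape)
    flagged = flagged_floor | (corrected < noise.floor_multiplier * sigma_arr)
    if np.any(flagged):
        action = "excluded" if noise.exclude_floor else "retained at corrected value"
        warnings_list.append(
            f"{int(flagged.sum())} point(s) at/below the noise floor ({action})"
        )
    if b_all[0] != 0:
        raise InputError("curve must include a b = 0 sample for normalization")
    s0 = corrected[0]
    if s0 <= 0 or flagged[0]:
        raise InputError("b = 0 signal is at the noise floor; cannot normalize")
    keep = ~flagged if noise.exclude_floor else np.ones_like(flagged)
    b = b_all[keep]
    y = corrected[keep] / s0
    n_par = _N_PARAMS[model]
    if len(b) < n_par + 1:
        raise InputError(
            f"model {model!r} needs at least {n_par + 1} usable points, "
            f"got {len(b)}"
        )

    names, lo, hi = _bounds_for(model)
    x0 = np.clip(_initial_guess(model, b, y), lo, hi)
    rng = np.random.default_rng(seed)

    def residuals(theta):
        return _predict(model, b, theta, mlf_config) - y

    best = None
    n_restarts = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for attempt in range(_MAX_RESTARTS + 1):
            res = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=400,
            )
            if best is None or res.cost < best.cost:
                best = res
            if res.status > 0:
                break
            n_restarts = attempt + 1
            # jitter the start multiplicatively inside the bounds
            x0 = np.clip(
                best.x * np.exp(rng.normal(0.0, 0.3, size=len(x0))), lo, hi
            )
    res = best
    converged = bool(res.status > 0)

    kwargs = dict(zip(names, res.x))
    params = AnomalousParams(model=model, **kwargs)
    k_mlf = None
    if model in ("mlf2", "mlf3"):
        k_mlf = float(kurtosis_from_alpha(params.alpha))
    adc = None
    if 0.0 in b_all and 1000.0 in b_all:
        adc_curve = DecayCurve(b=b_all, signal=np.maximum(corrected, 1e-30))
        try:
            adc = two_point_adc(adc_curve, 1000.0)
        except (InputError, FloatingPointError):
            adc = None
    if model == "dki":
        w = dki_validity_check(params, float(b.max()))
        if w:
            warnings_list.append(w)
    return FitResult(
        params=params,
        residual_norm=float(np.sqrt(2.0 * res.cost)),
        converged=converged,
        derived_K_MLF=k_mlf,
        adc=adc,
        n_restarts=n_restarts,
        warnings=warnings_list,
    )


def fit_maps(stack: np.ndarray, bvals, mask: np.ndarray | None = None,
             model: str = "mlf2", noise: NoiseModel = NO_NOISE,
             seed: int = 0, affine: np.ndarray | None = None,
             mlf_config: MLFEvalConfig = DEFAULT_CONFIG) -> ParameterMaps:
    """Voxelwise fit of a 4-D diffusion-weighted stack.

    ``stack`` is (X, Y, Z, N) with the 4th axis matching ``bvals``;
    ``mask`` is a 0/1 or boolean (X, Y, Z) array (all-ones when omitted).
    Per-voxel fits are independent and seeded reproducibly from ``seed``
    and the voxel's flat index.
    """
    stack = np.asarray(stack, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    if stack.ndim != 4:
        raise InputError("stack must be 4-D (X, Y, Z, volumes)")
    if stack.shape[3] != len(bvals):
        raise InputError(
            f"stack has {stack.shape[3]} volumes but {len(bvals)} b-values"
        )
    shape = stack.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != shape:
        raise InputError("mask shape must match the spatial grid")

    maps = {k: np.full(shape, np.nan) for k in
            ("alpha", "D", "K_MLF", "K_app", "ADC")}
    n_conv = 0
    n_fit = 0
    idx = np.flatnonzero(mask.ravel())
    for flat in idx:
        ijk = np.unravel_index(flat, shape)
        sig = stack[ijk]
        if np.any(~np.isfinite(sig)) or np.all(sig <= 0):
            continue
        voxel_seed = np.random.SeedSequence([int(seed), int(flat)]).generate_state(1)[0]
        try:
            curve = DecayCurve(b=bvals, signal=np.maximum(sig, 1e-12))
            fr = fit_curve(curve, model=model, noise=noise,
                           seed=int(voxel_seed), mlf_config=mlf_config)
        except (InputError, DomainError):
            continue
        n_fit += 1
        n_conv += int(fr.converged)
        p = fr.params
        maps["D"][ijk] = p.D
        if p.alpha is not None:
            maps["alpha"][ijk] = p.alpha
        if fr.derived_K_MLF is not None:
            maps["K_MLF"][ijk] = fr.derived_K_MLF
        if p.K_app is not None:
            maps["K_app"][ijk] = p.K_app
        if fr.adc is not None:
            maps["ADC"][ijk] = fr.adc
    return ParameterMaps(
        alpha_map=maps["alpha"], D_map=maps["D"], K_MLF_map=maps["K_MLF"],
        K_app_map=maps["K_app"], ADC_map=maps["ADC"], mask=mask,
        model=model, affine=affine, convergence_count=n_conv, n_fitted=n_fit,
    )
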