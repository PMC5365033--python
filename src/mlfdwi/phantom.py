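"""Synthetic multi-b-value brain phantom with Rician magnitude noise.

The phantom emulates a clinical multi-b-value acquisition: a 3-D grid is
partitioned into tissue-class blocks, each voxel's decay curve is
generated from a signal model with that class's parameters, and Rician
noise of chosen standard deviation is applied to the magnitudes.  The
default four classes carry subdiffusion parameters representative of
human brain at 3 T -- white matter (strongly subdiffusive, slow), gray
matter (moderately subdiffusive), necrotic/ischemic tissue and CSF (both
near-Gaussian and fast):

=====  =====  ============  ===========
class  alpha  D (mm2/s)     K_app
=====  =====  ============  ===========
WM     0.49   0.72e-3       0.99
GM     0.77   0.97e-3       0.58
IT     0.94   3.12e-3       0.35
CSF    0.97   3.27e-3       0.29
=====  =====  ============  ===========

Default b-values are {0, 500, 1000, 3000, 4000} s/mm2.  The companion
ground-truth maps make the phantom a full round-trip test bed for the
voxelwise fitting pipeline without any patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, DomainError
from .kurtosis import kurtosis_from_alpha
from .models import model_dki, model_mlf2, model_mono

__all__ = [
    "TissueClass",
    "PhantomSpec",
    "PhantomTruth",
    "DEFAULT_CLASSES",
    "DEFAULT_BVALS",
    "make_phantom",
    "add_rician_noise",
]

DEFAULT_BVALS = (0.0, 500.0, 1000.0, 3000.0, 4000.0)


@dataclass(frozen=True)
class TissueClass:
    """One phantom tissue class: label with its generative parameters."""

    label: str
    alpha: float
    D: float
    K_app: float | None = None
    fraction: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise DomainError(f"{self.label}: alpha must be in (0, 1]")
        if self.D <= 0:
            raise DomainError(f"{self.label}: D must be positive")
        if self.fraction <= 0:
            raise DomainError(f"{self.label}: fraction must be positive")


DEFAULT_CLASSES = (
    TissueClass("WM", alpha=0.49, D=0.72e-3, K_app=0.99),
    TissueClass("GM", alpha=0.77, D=0.97e-3, K_app=0.58),
    TissueClass("IT", alpha=0.94, D=3.12e-3, K_app=0.35),
    TissueClass("CSF", alpha=0.97, D=3.27e-3, K_app=0.29),
)


@dataclass
class PhantomSpec:
    """Generator settings for :func:`make_phantom`.

    classes : tissue classes laid out as consecutive blocks along x in
        proportion to their fractions.
    b_values : acquisition b-values (s/mm2); must include 0.
    shape : 3-D grid dimensions.
    s0 : baseline signal at b = 0.
    sigma : Rician noise standard deviation, same units as s0 (scalar or
        one value per b).
    seed : RNG seed for the noise.
    model : generator model, "mlf2" (alpha, D), "dki" (D, K_app) or
        "mono" (D only).
    """

    classes: tuple = DEFAULT_CLASSES
    b_values: tuple = DEFAULT_BVALS
    shape: tuple = (16, 16, 4)
    s0: float = 1000.0
    sigma: float = 0.0
    seed: int = 0
    model: str = "mlf2"

    def __post_init__(self) -> None:
        if self.model not in {"mlf2", "dki", "mono"}:
            raise ConfigError(f"unknown generator model {self.model!r}")
        if 0.0 not in tuple(self.b_values):
            raise ConfigError("b_values must include 0")
        if any(n <= 0 for n in self.shape) or len(self.shape) != 3:
            raise ConfigError("shape must be three positive dimensions")
        if self.s0 <= 0 or np.any(np.asarray(self.sigma) < 0):
            raise DomainError("s0 must be positive and sigma >= 0")
        if self.model == "dki" and any(c.K_app is None for c in self.classes):
            raise ConfigError("dki generator needs K_app for every class")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    label_map: np.ndarray       # integer class index per voxel
    labels: list[str]
    alpha_true: np.ndarray
    D_true: np.ndarray
    K_true: np.ndarray          # K_MLF(alpha) for mlf2/mono, K_app for dki


def _class_signal(cls: TissueClass, b: np.ndarray, model: str) -> np.ndarray:
    if model == "mlf2":
        return np.asarray(model_mlf2(b, cls.D, cls.alpha))
    if model == "dki":
        return np.asarray(model_dki(b, cls.D, cls.K_app))
    return np.asarray(model_mono(b, cls.D))


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Generate a (X, Y, Z, n_b) signal stack and its ground truth.

    Voxels are assigned to classes in consecutive x-slabs proportional to
    the class fractions; each voxel's noise-free curve is
    ``s0 * model(b; class params)`` and Rician noise is added when
    ``sigma > 0``.  Deterministic for a given seed.
    """
    b = np.asarray(spec.b_values, dtype=float)
    nx, ny, nz = spec.shape
    fracs = np.array([c.fraction for c in spec.classes], dtype=float)
    fracs = fracs / fracs.sum()
    edges = np.round(np.cumsum(np.concatenate([[0.0], fracs])) * nx).astype(int)
    edges[-1] = nx
    label_map = np.zeros(spec.shape, dtype=int)
    for i in range(len(spec.classes)):
        label_map[edges[i]:edges[i + 1]] = i

    stack = np.empty(spec.shape + (len(b),), dtype=float)
    alpha_true = np.empty(spec.shape)
    d_true = np.empty(spec.shape)
    k_true = np.empty(spec.shape)
    for i, cls in enumerate(spec.classes):
        sel = label_map == i
        stack[sel] = spec.s0 * _class_signal(cls, b, spec.model)
        alpha_true[sel] = cls.alpha
        d_true[sel] = cls.D
        if spec.model == "dki":
            k_true[sel] = cls.K_app
        else:
            k_true[sel] = kurtosis_from_alpha(cls.alpha)
    if np.any(np.asarray(spec.sigma) > 0):
        stack = add_rician_noise(stack, spec.sigma, spec.seed)
    truth = PhantomTruth(
        label_map=label_map,
        labels=[c.label for c in spec.classes],
        alpha_true=alpha_true,
        D_true=d_true,
        K_true=k_true,
    )
    return stack.astype(np.float32, copy=False).astype(float), truth


def add_rician_noise(signal, sigma, seed: int = 0) -> np.ndarray:
    """Rician magnitude noise: sqrt((S + n1)^2 + n2^2), n1, n2 ~ N(0, sigma^2).

    ``sigma`` may be scalar or broadcastable over the last axis (per-b
    noise levels).  ``sigma = 0`` returns the input unchanged.
    """
    s = np.asarray(signal, dtype=float)
    sigma_arr = np.asarray(sigma, dtype=float)
    if np.any(sigma_arr < 0):
        raise DomainError("sigma must be >= 0")
    if np.all(sigma_arr == 0):
        return s.copy()
    rng = np.random.default_rng(seed)
    n1 = rng.standard_normal(s.shape)
    n2 = rng.standard_normal(s.shape)
    return np.sqrt((s + sigma_arr * n1) ** 2 + (sigma_arr * n2) ** 2)
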