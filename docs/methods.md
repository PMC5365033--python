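# Methods

## The model

Water diffusion in brain tissue deviates from the Gaussian propagator that
underlies the classical apparent-diffusion-coefficient (ADC) picture.  The
continuous-time random walk (CTRW) framework describes this with two
fractional orders: `alpha` in (0, 1] for the waiting-time law (heavy-tailed
waiting produces *subdiffusion*) and `beta` in (1, 2] for the jump-length
law (heavy-tailed jumps produce *superdiffusion*).  The characteristic
function of the CTRW propagator is the one-parameter Mittag-Leffler
function (MLF)

    E_a(z) = sum_{k>=0} z^k / Gamma(a k + 1),

which reduces to the exponential at `alpha = 1`.  Expressed against the
experimental diffusion weighting `b` (s/mm2), the package implements four
nested signal models for the normalized decay S/S0:

| model | form                          | parameters       |
|-------|-------------------------------|------------------|
| mono  | exp(-bD)                      | D                |
| mlf2  | E_a(-bD)                      | D, alpha         |
| mlf3  | E_a(-(bD)^(beta/2))           | D, alpha, beta   |
| dki   | exp(-bD + (bD)^2 K_app / 6)   | D, K_app         |

`mlf3(beta=2) == mlf2`, `mlf2(alpha=1) == mono`, `dki(K_app=0) == mono`;
the kurtosis expansion (dki) additionally stops being monotone beyond its
exponent apex `b* = 3/(D K_app)`, which is why a b-range limit is inherent
to that model and not to the MLF forms.

For time-fractional subdiffusion the propagator's moments are

    <x^2> = 2 D t^a / Gamma(a+1),    <x^4> = 24 D^2 t^{2a} / Gamma(2a+1),

giving an excess kurtosis that depends on `alpha` alone:

    K_MLF(a) = 6 Gamma(a+1)^2 / Gamma(2a+1) - 3,

strictly decreasing from 3 (a -> 0) to 0 (a = 1).  This closed form is the
bridge between subdiffusion fitting and diffusional kurtosis imaging; the
same Gamma ratio divided by 3 is Goychuk's universal scaling ratio for
forced subdiffusion, exposed as `goychuk_ratio`.  The numerical inverse
`alpha_from_kurtosis` uses Brent root-finding on the strictly monotone
closed form.

## Mittag-Leffler numerics

`mittag_leffler(alpha, z)` targets 1e-10 relative accuracy on the real
axis (primarily z <= 0) with two schemes:

* **Guarded Taylor summation.** Kahan-compensated summation of the power
  series, accepted only when `max_term * eps / |sum|` stays below the
  tolerance.  The guard is evaluated at run time, so the usable radius
  adapts to the order instead of relying on a fixed cut.
* **Spectral (complete-monotonicity) integral.** For 0 < a < 1, x > 0,

      E_a(-x) = int_0^inf K_a(r) exp(-r x^{1/a}) dr,
      K_a(r) = (1/pi) sin(pi a) r^{a-1} / (r^{2a} + 2 r^a cos(pi a) + 1),

  integrated by adaptive QUADPACK quadrature with four numerically
  load-bearing choices:

  1. the `r^{a-1}` endpoint singularity is handled by the QAWS algebraic
     weight, or for `a < 0.35` by the substitution `v = u^a` (most of the
     weight mass then sits many decades below the interval scale, where a
     polynomial rule cannot follow the kernel);
  2. the kernel's Lorentzian peak at `r0 = (-cos(pi a))^{1/a}` (width
     shrinking like `(1-a)`) is flattened by the arctan substitution
     `u = peak + width * tan(theta)`;
  3. the Lorentzian's `1/(u-peak)^2` wings are integrated under log
     substitutions, making the power-law decay exponentially smooth;
  4. the denominator is evaluated as `(r^a - r0^a)^2 + sin^2(pi a)` via
     `expm1`/`log1p` — the direct polynomial form loses all significant
     digits once `sin(pi a) ~ sqrt(eps)` and biases the integral upward
     (1/Q is convex in the noise).

  Orders within 1e-13 of 1 route to `exp(z)` plus the optimally truncated
  algebraic tail `sum_k (-1)^{k+1} x^{-k}/Gamma(1-ak)`; `alpha = 1`
  exactly routes to `exp` (bit-stable identity).

Validation: against an arbitrary-precision summation oracle (mpmath,
adaptive working precision) where direct summation is feasible, and
against arbitrary-precision Talbot inversion of the Laplace transform
`s^{a-1}/(s^a + x)` elsewhere.  On the development grid
`alpha in [0.02, 1-1e-12] x x in [1e-3, 100]` the worst relative error is
2e-5 (at `alpha = 1 - 1e-12`, on 1e-14-scale values); everywhere with
`alpha <= 1 - 1e-8` the error is at or below ~5e-9.  Public entry points
reject `alpha < 0.01` (Gamma-pole region).  Evaluation costs ~70 us on
the series path and ~0.7 ms on the integral path.

The moment laws are cross-checked by an independent finite-difference
oracle: 5-point (second derivative) and 7-point (fourth derivative)
central stencils applied to the characteristic function at q = 0, with
steps `h ~ eps^{1/6}` and `eps^{1/8}` balancing truncation against
roundoff.

## Fitting pipeline

Signals are corrected for the Rician noise floor, `S_rn = sqrt(S^2 -
2 sigma^2)` (zero below the floor), normalized by the measured S(b=0),
and fitted by bounded trust-region-reflective least squares.  The
classical Levenberg-Marquardt step does not support box bounds; TRF
reduces to the same Gauss-Newton behaviour in the interior.  Bounds:
D in (1e-5, 1e-1) mm2/s, alpha in [0.01, 1], beta in (1, 2], K_app in
[0, 10].  Initialization takes D0 from the two-point log slope at the
smallest nonzero b, with alpha0 = 0.9, beta0 = 1.9, K0 = 0.5; up to five
seeded, jittered restarts run on non-convergence, and non-convergence is
reported via a flag, never an exception.  `sigma` is a user input
(scalar or per-b); `estimate_sigma` derives it from a homogeneous ROI's
signal spread with the Rayleigh correction factor.

**Noise-floor points are retained, not dropped.**  Points flagged below
`floor_multiplier * sigma` (default 2) keep their floor-corrected value
(zero at the floor).  Excluding them was measured to bias the fitted
order low by up to -0.35 in fast-decaying (CSF-like) voxels, because
exclusion discards the information that the decay has reached the floor;
retention keeps class-mean biases within ~0.04.
`NoiseModel(exclude_floor=True)` restores exclusion for users who want
it.

What recovery accuracy is attainable is set by information, not code:
for the 5-point clinical b-sampling at SNR 40 the Cramer-Rao bound gives
sd(alpha) ~ 0.087 for a gray-matter-like curve and ~ 0.17 for white
matter.  The test suite asserts the fitter sits within ~15% of these
bounds (it measures median |d alpha| of 0.058 and 0.105 respectively) —
per-voxel subdiffusion orders at this SNR are usable through ROI or
class averaging, not individually.  Near the `alpha = 1` bound the
class-mean estimate carries a truncation bias of about -0.03 to -0.04
(the sampling distribution cannot spill past 1), visible in the CSF and
necrotic-tissue phantom classes.

`fit_maps` runs `fit_curve` per voxel inside a mask, with per-voxel seeds
derived from `SeedSequence([seed, flat_index])`, so results are
reproducible and independent of mask shape.  A voxel fit takes ~30-45 ms
(the upper end when the MLF integral path dominates), i.e. ~40 s for the
default 16x16x4 phantom.

## CTRW simulator

Waiting times and jumps are sampled by inverse transform from the Pareto
law with survival `(t/c)^-tail` (t >= c), or from Gaussians ("Gaussian
waiting times" are |N(0,1)| so increments stay positive).  The tail
exponents follow the standard convention (waiting tail = alpha, jump
tail = beta), under which the subdiffusive MSD law `t^alpha` emerges;
`exponent_convention="reciprocal"` provides the literal reciprocal
reading for comparison.  Heavy-tailed jumps are made zero-mean by
symmetric random signs (default) or by subtracting the one-sided mean
`c beta/(beta-1)`.  `c` defaults to 1 so that distance ~ sqrt(time) is
directly visible in the Brownian regime.

Ensemble statistics evaluate walker positions as right-continuous step
functions.  The MSD exponent is the log-log least-squares slope over a
window excluding early times (renewal-theory corrections decay like the
inverse mean event count); its confidence interval is a bootstrap over
walkers.  Regimes with infinite jump variance report the central 90%
inter-quantile width of x(t) instead of the divergent MSD.  Per-walker
RNG substreams are spawned from the master seed, so enlarging the
ensemble never reshuffles existing walkers, and runs are bit-reproducible.

Acceptance-scale runs use 10^4 walkers x 10^3 steps per regime (a few
minutes total); unit tests use 2-4 x 10^3 walkers x 400 steps, where the
same laws hold with wider intervals.

## Synthetic phantom

The phantom emulates a multi-b-value brain acquisition at
b = {0, 500, 1000, 3000, 4000} s/mm2 with four tissue-class blocks:

| class | alpha | D (mm2/s) | K_app |
|-------|-------|-----------|-------|
| WM    | 0.49  | 0.72e-3   | 0.99  |
| GM    | 0.77  | 0.97e-3   | 0.58  |
| IT    | 0.94  | 3.12e-3   | 0.35  |
| CSF   | 0.97  | 3.27e-3   | 0.29  |

(representative fitted values for white matter, gray matter, necrosed
ischemic tissue and CSF in chronic-stroke brain at 3 T).  The generator
model is `mlf2` by default; a `dki` mode uses the (D, K_app) columns for
cross-model comparison.  S0 defaults to 1000 with Rician noise
`sqrt((S+n1)^2 + n2^2)`, `n1, n2 ~ N(0, sigma^2)`; the noisy-recovery
conditions use `sigma = S0/40`.  Geometry defaults to 16x16x4 (x-axis
class slabs); the acceptance suite enlarges to 16x16x16 so the class-mean
standard error (~0.005) resolves estimator bias against the recovery
band rather than measuring seed luck.

What the phantom does *not* emulate: anatomical geometry, partial-volume
mixing at class borders, spatially varying (multi-coil) noise,
direction-dependent diffusion, motion, or eddy currents.  Passing
recovery tests therefore demonstrate correctness of the estimator under
the stated noise model, not robustness to everything clinical data
contains.

## Protocol arithmetic conventions

Effective diffusion time `t = Delta - delta/3`; `q = gamma G delta`
(1/mm); `b = q^2 t`.  The probe length scale is reported as `1/q`
(reciprocal spatial frequency without a 2*pi factor) — the convention
under which the clinical protocol's b-range 500-4000 s/mm2 at t = 31 ms
probes 7.9 down to 2.8 um, matching the sqrt(2Dt) ~ 6-8 um net water
displacement.  b-values are carried in s/mm2 and D in mm2/s throughout;
unit conversion happens only at I/O boundaries.

## Known limitations

- Single-order isotropic analysis; no tensor/directional extension.
- The space-fractional (beta < 2) propagator has a divergent second
  moment; no moments or kurtosis are defined for it here, and the
  simulator reports quantile widths instead.
- The mu/tau unit-preserving scales of the generalized diffusivity are
  user inputs, not fitted.
- The Rician treatment assumes a known, spatially homogeneous sigma
  (scalar or per-b); multi-coil spatial noise fields are out of scope.
- MLF accuracy degrades gracefully (to ~1e-5 relative) only in the
  measure-zero sliver alpha in (1-1e-8, 1); `alpha = 1` itself is exact.
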