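"""Fit a single diffusion decay curve with the four signal models.

Builds a noise-free gray-matter-like curve at the clinical b-values,
fits it with the monoexponential, subdiffusion (Mittag-Leffler) and
kurtosis-expansion models, and prints what each recovers.
"""

import numpy as np

from mlfdwi import DecayCurve, fit_curve, model_mlf2

b = np.array([0.0, 500.0, 1000.0, 3000.0, 4000.0])  # s/mm2
true_D, true_alpha = 0.97e-3, 0.77                   # gray-matter-like
signal = 1000.0 * np.asarray(model_mlf2(b, true_D, true_alpha))
curve = DecayCurve(b=b, signal=signal)

print(f"generator: D = {true_D:.2e} mm2/s, alpha = {true_alpha}")
for model in ("mono", "mlf2", "mlf3", "dki"):
    fr = fit_curve(curve, model=model)
    p = fr.params
    parts = [f"D = {p.D:.3e}"]
    if p.alpha is not None:
        parts.append(f"alpha = {p.alpha:.4f}")
    if p.beta is not None:
        parts.append(f"beta = {p.beta:.4f}")
    if p.K_app is not None:
        parts.append(f"K_app = {p.K_app:.4f}")
    if fr.derived_K_MLF is not None:
        parts.append(f"K_MLF = {fr.derived_K_MLF:.4f}")
    print(f"  {model:5s}: " + ", ".join(parts)
          + f"  (residual {fr.residual_norm:.2e})")

# The mlf2 fit recovers the generator exactly; mono sees only an
# "apparent" diffusivity because the decay is not exponential; dki
# approximates the curvature with an apparent kurtosis K_app, smaller
# than the true propagator kurtosis K_MLF of the generator.
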