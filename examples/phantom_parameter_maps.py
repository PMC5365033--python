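"""Generate a four-tissue phantom, add Rician noise, fit voxelwise maps.

Shows the full pipeline on synthetic data: phantom -> noise -> voxelwise
subdiffusion fit -> class-mean parameter recovery.
"""

import numpy as np

from mlfdwi import NoiseModel, PhantomSpec, fit_maps, make_phantom

sigma = 25.0  # SNR 40 at b = 0
spec = PhantomSpec(shape=(8, 8, 2), sigma=sigma, s0=1000.0, seed=7)
stack, truth = make_phantom(spec)
maps = fit_maps(stack, spec.b_values, model="mlf2",
                noise=NoiseModel(sigma=sigma), seed=0)

print(f"phantom {spec.shape}, sigma = {sigma} (SNR {spec.s0 / sigma:.0f}), "
      f"{maps.n_fitted} voxels fitted, {maps.convergence_count} converged")
print(f"{'class':5s} {'alpha true':>10s} {'alpha fit':>10s} "
      f"{'D true':>10s} {'D fit':>10s} {'K_MLF fit':>10s}")
for i, cls in enumerate(spec.classes):
    sel = truth.label_map == i
    print(f"{cls.label:5s} {cls.alpha:10.2f} "
          f"{np.nanmean(maps.alpha_map[sel]):10.3f} "
          f"{cls.D:10.2e} {np.nanmean(maps.D_map[sel]):10.2e} "
          f"{np.nanmean(maps.K_MLF_map[sel]):10.3f}")

# White matter is strongly subdiffusive (low alpha, high kurtosis); CSF
# is nearly Gaussian (alpha ~ 1, kurtosis ~ 0). Class means recover the
# generator within the noise-limited uncertainty.
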