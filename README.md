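# mlfdwi

Anomalous-diffusion analysis of diffusion-weighted MRI: Mittag-Leffler
(continuous-time random walk) signal models, a closed-form
subdiffusion-to-kurtosis conversion, Rician noise handling, voxelwise
parameter mapping, a CTRW Monte Carlo simulator and a synthetic brain
phantom.

## Who this is for

Water diffusion in brain tissue is not Gaussian: multi-b-value decay
curves bend away from the monoexponential `exp(-bD)` that defines the
classical ADC.  Two practical descriptions of that bending are
diffusional kurtosis imaging (DKI), which fits the expansion
`S/S0 = exp(-bD + b²D²K_app/6)` but is only valid up to
`b* = 3/(D·K_app)`, and the continuous-time random walk model, whose
signal is the Mittag-Leffler function

    S/S0 = E_alpha(-bD),      E_alpha(z) = sum_k z^k / Gamma(alpha*k + 1),

a complete monotone decay valid at every b.  The time-fractional order
`alpha` in (0, 1] measures subdiffusion (1 = Gaussian), and converts to
an excess kurtosis in closed form:

    K_MLF = 6*Gamma(alpha+1)^2 / Gamma(2*alpha+1) - 3,

decreasing from 3 (alpha -> 0) to 0 (alpha = 1).  The package is for
researchers fitting these models to multi-b-value brain data (NIfTI
stacks or plain decay curves) and for anyone needing a careful
double-precision Mittag-Leffler evaluator on the real axis.

## Worked example

```python
import numpy as np
from mlfdwi import DecayCurve, fit_curve, model_mlf2

b = np.array([0., 500., 1000., 3000., 4000.])        # s/mm2
signal = 1000 * np.asarray(model_mlf2(b, 0.97e-3, 0.77))  # gray-matter-like
fit = fit_curve(DecayCurve(b=b, signal=signal), model="mlf2")
print(fit.params.D, fit.params.alpha, fit.derived_K_MLF)
```

prints

```
0.0009699999999999966 0.7700000000000029 0.7432767038122368
```

— the fitted diffusivity (mm2/s) and subdiffusion order recover the
generator exactly on noise-free data, and `alpha = 0.77` converts to an
excess kurtosis `K_MLF = 0.743`: moderately non-Gaussian, typical of
gray matter.  White matter sits near `alpha ~ 0.49, K_MLF ~ 1.8`
(strongly restricted), CSF near `alpha ~ 1, K_MLF ~ 0` (free water).

The `examples/` directory has one short script per capability
(single-curve fits, phantom parameter maps, random-walk regimes,
protocol length scales); each prints its numbers with a line on what
they mean.  A thin CLI covers the file-based workflows:

```bash
mlfdwi phantom --out ph/
mlfdwi fit --dwi ph/dwi.nii.gz --bvals ph/bvals.txt --model mlf2 --out maps/
mlfdwi protocol --delta 0.0306 --big-delta 0.0412 --bvals 0,500,1000,3000,4000
```

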