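import numpy as np
import pytest

from mlfdwi import DecayCurve, PhantomSpec, make_phantom, model_mlf2


@pytest.fixture(scope="session")
def gm_curve():
    """Noise-free gray-matter-like subdiffusive decay curve."""
    b = np.array([0.0, 500.0, 1000.0, 3000.0, 4000.0])
    sig = 1000.0 * np.asarray(model_mlf2(b, 0.97e-3, 0.77))
    return DecayCurve(b=b, signal=sig)


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free 4-class phantom on a small grid (fast round trips)."""
    spec = PhantomSpec(shape=(8, 4, 1), sigma=0.0, seed=11)
    stack, truth = make_phantom(spec)
    return spec, stack, truth
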