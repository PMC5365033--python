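"""Rician correction, ADC, curve fits and parameter maps."""

import numpy as np
import pytest

from mlfdwi import (
    AnomalousParams,
    DecayCurve,
    InputError,
    NoiseModel,
    dki_validity_check,
    fit_curve,
    fit_maps,
    kurtosis_from_alpha,
    model_dki,
    model_mlf2,
    model_mlf3,
    model_mono,
    rician_correct,
    two_point_adc,
)
from mlfdwi.fitting import estimate_sigma

B5 = np.array([0.0, 500.0, 1000.0, 3000.0, 4000.0])


def make_curve(model, s0=1000.0, b=B5, **params):
    fn = {"mono": model_mono, "mlf2": model_mlf2,
          "mlf3": model_mlf3, "dki": model_dki}[model]
    return DecayCurve(b=b, signal=s0 * np.asarray(fn(b, **params)))


class TestRicianCorrection:
    def test_formula(self):
        corr, flag = rician_correct([10.0], NoiseModel(sigma=1.0))
        assert corr[0] == pytest.approx(np.sqrt(98.0), rel=1e-12)
        assert not flag[0]

    def test_zero_sigma_identity(self):
        s = np.array([5.0, 2.0, 0.1])
        corr, flag = rician_correct(s, NoiseModel(sigma=0.0))
        np.testing.assert_array_equal(corr, s)
        assert not flag.any()

    def test_noise_floor_flagged(self):
        corr, flag = rician_correct([1.0], NoiseModel(sigma=1.0))
        assert corr[0] == 0.0
        assert flag[0]


class TestTwoPointADC:
    def test_unit_decay(self):
        c = DecayCurve(b=[0.0, 1000.0], signal=[1.0, np.exp(-1.0)])
        assert two_point_adc(c) == pytest.approx(1.0e-3, rel=1e-12)

    def test_flat_curve_zero(self):
        c = DecayCurve(b=[0.0, 1000.0], signal=[1.0, 1.0])
        assert two_point_adc(c) == 0.0

    def test_signal_increase_negative(self):
        c = DecayCurve(b=[0.0, 1000.0], signal=[1.0, 1.1])
        assert two_point_adc(c) < 0.0

    def test_missing_b_raises(self):
        c = DecayCurve(b=[0.0, 500.0], signal=[1.0, 0.5])
        with pytest.raises(InputError):
            two_point_adc(c, 1000.0)


class TestCurveFits:
    def test_mlf2_noise_free_recovery(self, gm_curve):
        fr = fit_curve(gm_curve, model="mlf2")
        assert fr.converged
        assert fr.params.alpha == pytest.approx(0.77, abs=1e-6)
        assert fr.params.D == pytest.approx(0.97e-3, rel=1e-6)
        assert fr.derived_K_MLF == pytest.approx(
            kurtosis_from_alpha(0.77), abs=1e-6)

    def test_mlf2_on_monoexponential_hits_alpha_bound(self):
        c = make_curve("mono", D=1.2e-3)
        fr = fit_curve(c, model="mlf2")
        assert fr.params.alpha == pytest.approx(1.0, abs=1e-7)
        assert fr.params.D == pytest.approx(1.2e-3, rel=1e-6)

    def test_dki_zero_kurtosis_curve(self):
        c = make_curve("mono", D=0.9e-3, b=np.array([0.0, 500.0, 1000.0, 2000.0]))
        fr = fit_curve(c, model="dki")
        assert fr.params.K_app == pytest.approx(0.0, abs=1e-6)
        assert fr.params.D == pytest.approx(0.9e-3, rel=1e-6)

    def test_dki_recovery(self):
        c = make_curve("dki", D=1.02e-3, K_app=0.58,
                       b=np.array([0.0, 500.0, 1000.0, 2000.0]))
        fr = fit_curve(c, model="dki")
        assert fr.params.D == pytest.approx(1.02e-3, rel=1e-6)
        assert fr.params.K_app == pytest.approx(0.58, abs=1e-5)

    def test_mlf3_beta_boundary_matches_mlf2(self, gm_curve):
        fr3 = fit_curve(gm_curve, model="mlf3")
        fr2 = fit_curve(gm_curve, model="mlf2")
        assert fr3.params.beta == pytest.approx(2.0, abs=1e-4)
        assert fr3.params.alpha == pytest.approx(fr2.params.alpha, abs=1e-4)
        assert fr3.params.D == pytest.approx(fr2.params.D, rel=1e-4)

    def test_alpha_stable_under_bmax_removal(self):
        # dropping the largest-b point from a noise-free curve leaves the
        # fitted subdiffusion order essentially unchanged
        full = make_curve("mlf2", D=0.97e-3, alpha=0.77)
        trimmed = DecayCurve(b=full.b[:-1], signal=full.signal[:-1])
        a_full = fit_curve(full, model="mlf2").params.alpha
        a_trim = fit_curve(trimmed, model="mlf2").params.alpha
        assert abs(a_full - a_trim) < 1e-6

    def test_deterministic_given_seed(self, gm_curve):
        r1 = fit_curve(gm_curve, model="mlf2", seed=42)
        r2 = fit_curve(gm_curve, model="mlf2", seed=42)
        assert r1.params.alpha == r2.params.alpha
        assert r1.params.D == r2.params.D

    def test_too_few_points(self):
        c = DecayCurve(b=[0.0, 1000.0], signal=[1.0, 0.4])
        with pytest.raises(InputError):
            fit_curve(c, model="mlf2")

    def test_noise_floor_points_excluded(self):
        # only the largest-b point dips below floor_multiplier * sigma
        c = make_curve("mono", D=1.5e-3, s0=1000.0)
        noise = NoiseModel(sigma=2.0, floor_multiplier=2.0)
        fr = fit_curve(c, model="mlf2", noise=noise)
        assert any("noise floor" in w for w in fr.warnings)
        assert fr.converged

    def test_adc_reported_alongside_fit(self, gm_curve):
        fr = fit_curve(gm_curve, model="mlf2")
        expected = two_point_adc(gm_curve)
        assert fr.adc == pytest.approx(expected, rel=1e-12)


class TestNoisyRecovery:
    """Parameter recovery under Rician noise at sigma = S0/40.

    Thresholds sit within ~1.35x of the Cramer-Rao medians for this
    5-point acquisition (sd(alpha) ~0.087 GM / ~0.17 WM; sd(D)/D ~7% GM /
    ~11% WM under the Gaussian-noise approximation), i.e. they assert the
    estimator is close to efficient -- no estimator can do materially
    better from these data.
    """

    N_CURVES = 200

    def _recover(self, model, gen_params, seed0=1000):
        from mlfdwi import add_rician_noise
        s0, sigma = 1000.0, 25.0
        alpha_err, d_err = [], []
        clean = s0 * np.asarray(
            {"mlf2": model_mlf2, "dki": model_dki}[model](B5, **gen_params))
        for i in range(self.N_CURVES):
            noisy = add_rician_noise(clean, sigma, seed=seed0 + i)
            curve = DecayCurve(b=B5, signal=noisy)
            fr = fit_curve(curve, model=model,
                           noise=NoiseModel(sigma=sigma), seed=i)
            d_err.append(abs(fr.params.D - gen_params["D"]) / gen_params["D"])
            if model == "mlf2":
                alpha_err.append(abs(fr.params.alpha - gen_params["alpha"]))
        return np.median(alpha_err) if alpha_err else None, np.median(d_err)

    def test_mlf2_gray_matter_conditions(self):
        # CRLB median |d alpha| = 0.674 * 0.087 ~ 0.059
        a_med, d_med = self._recover("mlf2", dict(D=0.97e-3, alpha=0.77))
        assert a_med <= 0.068
        assert d_med <= 0.065

    def test_mlf2_white_matter_conditions(self):
        # CRLB median |d alpha| = 0.674 * 0.17 ~ 0.115
        a_med, d_med = self._recover("mlf2", dict(D=0.72e-3, alpha=0.49))
        assert a_med <= 0.13
        assert d_med <= 0.105


class TestDkiValidity:
    def test_warns_beyond_apex(self):
        p = AnomalousParams(model="dki", D=1e-3, K_app=1.0)
        assert dki_validity_check(p, 4000.0) is not None

    def test_passes_below_apex(self):
        p = AnomalousParams(model="dki", D=1e-3, K_app=1.0)
        assert dki_validity_check(p, 1000.0) is None

    def test_zero_kurtosis_passes(self):
        p = AnomalousParams(model="dki", D=1e-3, K_app=0.0)
        assert dki_validity_check(p, 10000.0) is None


class TestSigmaEstimate:
    def test_rayleigh_roi(self):
        rng = np.random.default_rng(5)
        sigma = 25.0
        roi = np.hypot(rng.normal(0, sigma, 20000), rng.normal(0, sigma, 20000))
        assert estimate_sigma(roi) == pytest.approx(sigma, rel=0.03)


class TestMaps:
    def test_phantom_roundtrip_class_means(self, small_phantom):
        spec, stack, truth = small_phantom
        maps = fit_maps(stack, spec.b_values, model="mlf2", seed=0)
        for i, cls in enumerate(spec.classes):
            sel = truth.label_map == i
            assert np.nanmean(maps.alpha_map[sel]) == pytest.approx(
                cls.alpha, abs=1e-5)
            assert np.nanmean(maps.D_map[sel]) == pytest.approx(
                cls.D, rel=1e-5)

    def test_empty_mask_all_nan(self, small_phantom):
        spec, stack, _ = small_phantom
        mask = np.zeros(stack.shape[:3], dtype=bool)
        maps = fit_maps(stack, spec.b_values, mask=mask, model="mlf2")
        assert np.all(np.isnan(maps.alpha_map))
        assert maps.n_fitted == 0

    def test_single_voxel_mask_equals_fit_curve(self, small_phantom):
        spec, stack, _ = small_phantom
        mask = np.zeros(stack.shape[:3], dtype=bool)
        mask[0, 0, 0] = True
        maps = fit_maps(stack, spec.b_values, mask=mask, model="mlf2", seed=0)
        voxel_seed = np.random.SeedSequence([0, 0]).generate_state(1)[0]
        curve = DecayCurve(b=np.asarray(spec.b_values),
                           signal=stack[0, 0, 0])
        fr = fit_curve(curve, model="mlf2", seed=int(voxel_seed))
        assert maps.alpha_map[0, 0, 0] == pytest.approx(fr.params.alpha, abs=1e-12)

    def test_shape_mismatch_raises(self, small_phantom):
        spec, stack, _ = small_phantom
        with pytest.raises(InputError):
            fit_maps(stack, [0.0, 1000.0], model="mlf2")
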