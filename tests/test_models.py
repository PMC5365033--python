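"""Signal models, pulse-sequence arithmetic and unit conversions."""

import numpy as np
import pytest

from mlfdwi import (
    AcquisitionProtocol,
    DecayCurve,
    DomainError,
    GeneralizedDiffusivity,
    InputError,
    b_value,
    cf_general,
    cf_subdiffusion,
    cf_superdiffusion,
    effective_diffusion_time,
    generalized_to_classical,
    model_dki,
    model_mlf2,
    model_mlf3,
    model_mono,
    net_displacement,
    probe_length_scale,
    q_value,
)
from mlfdwi.models import dki_apex

B_GRID = np.linspace(0.0, 1e4, 41)


class TestProtocolArithmetic:
    def test_effective_diffusion_time_clinical(self):
        p = AcquisitionProtocol(G=30e-6, delta=30.6e-3, Delta=41.2e-3)
        assert effective_diffusion_time(p) == pytest.approx(31.0e-3, rel=1e-12)

    def test_short_pulse_limit(self):
        p = AcquisitionProtocol(G=1e-5, delta=1e-9, Delta=0.05)
        assert effective_diffusion_time(p) == pytest.approx(0.05, rel=1e-6)
        p2 = AcquisitionProtocol(G=1e-5, delta=30e-3, Delta=30e-3)
        assert effective_diffusion_time(p2) == pytest.approx(20e-3, rel=1e-12)

    def test_b_equals_q_squared_t(self):
        p = AcquisitionProtocol(G=43.6e-6, delta=30.6e-3, Delta=41.2e-3)
        q = q_value(p)
        t = effective_diffusion_time(p)
        assert b_value(p) == pytest.approx(q * q * t, rel=1e-12)

    def test_q_for_b4000(self):
        # q = sqrt(b/t): 4000 s/mm2 at t = 31 ms -> ~359 /mm
        q = np.sqrt(4000.0 / 0.031)
        assert q == pytest.approx(359.21, abs=0.05)
        assert q * q * 0.031 == pytest.approx(4000.0, rel=1e-12)

    def test_zero_gradient(self):
        p = AcquisitionProtocol(G=0.0, delta=30e-3, Delta=40e-3)
        assert q_value(p) == 0.0
        assert b_value(p) == 0.0

    def test_b_scales_with_gradient_squared(self):
        p1 = AcquisitionProtocol(G=20e-6, delta=30e-3, Delta=40e-3)
        p2 = AcquisitionProtocol(G=40e-6, delta=30e-3, Delta=40e-3)
        assert b_value(p2) == pytest.approx(4.0 * b_value(p1), rel=1e-12)

    def test_invalid_protocol(self):
        with pytest.raises(DomainError):
            AcquisitionProtocol(G=1e-5, delta=50e-3, Delta=40e-3)


class TestLengthScales:
    def test_probe_lengths_of_clinical_protocol(self):
        # b range 500-4000 s/mm2 at t = 31 ms probes ~2.8-7.9 um
        assert probe_length_scale(4000.0, 0.031) * 1e3 == pytest.approx(2.8, abs=0.05)
        assert probe_length_scale(500.0, 0.031) * 1e3 == pytest.approx(7.9, abs=0.05)

    def test_quadrupling_b_halves_length(self):
        l1 = probe_length_scale(1000.0, 0.031)
        l4 = probe_length_scale(4000.0, 0.031)
        assert l4 == pytest.approx(l1 / 2.0, rel=1e-12)

    def test_undefined_at_b_zero(self):
        with pytest.raises(DomainError):
            probe_length_scale(0.0, 0.031)

    def test_net_displacement_brain_range(self):
        # D ~ 0.6-1.0e-3 mm2/s over 31 ms displaces ~6-8 um
        assert net_displacement(1.0e-3, 0.031) * 1e3 == pytest.approx(7.9, abs=0.1)
        assert net_displacement(0.6e-3, 0.031) * 1e3 == pytest.approx(6.1, abs=0.1)
        assert net_displacement(1e-3, 0.0) == 0.0


class TestSignalModels:
    def test_mono_values(self):
        assert model_mono(0.0, 1e-3) == 1.0
        assert model_mono(1000.0, 1e-3) == pytest.approx(np.exp(-1.0), rel=1e-14)
        assert model_mono(3000.0, 3.12e-3) == pytest.approx(np.exp(-9.36), rel=1e-12)

    def test_reduction_chain(self):
        # mlf3(beta=2) == mlf2; mlf2(alpha=1) == mono; dki(K=0) == mono
        b = B_GRID
        D = 0.97e-3
        np.testing.assert_allclose(
            model_mlf3(b, D, 0.75, 2.0), model_mlf2(b, D, 0.75), rtol=1e-12)
        np.testing.assert_allclose(
            model_mlf2(b, D, 1.0), model_mono(b, D), rtol=1e-12)
        np.testing.assert_allclose(
            model_dki(b, D, 0.0), model_mono(b, D), rtol=1e-12)

    def test_mlf3_stretched_exponential_limit(self):
        # alpha = 1, beta < 2: exp(-(bD)^(beta/2))
        b, D, beta = 2000.0, 1e-3, 1.5
        expected = np.exp(-((b * D) ** (beta / 2.0)))
        assert model_mlf3(b, D, 1.0, beta) == pytest.approx(expected, rel=1e-12)
        # (bD)^(beta/2) = 1 whenever bD = 1
        assert model_mlf3(1000.0, 1e-3, 1.0, 1.5) == pytest.approx(
            np.exp(-1.0), rel=1e-12)

    def test_mlf2_closed_form_half_order(self):
        from scipy.special import erfcx
        assert model_mlf2(1000.0, 1e-3, 0.5) == pytest.approx(
            erfcx(1.0), rel=1e-10)

    def test_all_models_start_at_one_and_decrease(self):
        D = 1e-3
        for vals in (
            model_mono(B_GRID, D),
            model_mlf2(B_GRID, D, 0.6),
            model_mlf3(B_GRID, D, 0.8, 1.7),
        ):
            assert vals[0] == pytest.approx(1.0, abs=1e-14)
            assert np.all(np.diff(vals) < 0.0)

    def test_dki_apex_and_nonmonotonicity(self):
        D, K = 1e-3, 1.0
        assert dki_apex(D, K) == pytest.approx(3000.0, rel=1e-12)
        vals = model_dki(B_GRID, D, K)
        below = B_GRID < 3000.0
        assert np.all(np.diff(vals[below]) < 0.0)
        assert vals[-1] > vals[np.argmin(np.abs(B_GRID - 3000.0))]

    def test_dki_value(self):
        assert model_dki(1000.0, 1e-3, 1.0) == pytest.approx(
            np.exp(-5.0 / 6.0), rel=1e-12)


class TestCharacteristicFunctions:
    def test_unity_at_q_zero(self):
        gd = GeneralizedDiffusivity(D_ab=1e-3)
        assert cf_general(0.0, 0.031, gd, 0.8, 1.5) == 1.0
        assert cf_subdiffusion(0.0, 0.031, 1e-3, 0.8) == 1.0
        assert cf_superdiffusion(0.0, 0.031, 1e-3, 1.5) == 1.0

    def test_gaussian_limit_coincides(self):
        q, t, D = 100.0, 0.031, 1e-3
        expected = np.exp(-D * q * q * t)
        gd = GeneralizedDiffusivity(D_ab=D)
        assert cf_general(q, t, gd, 1.0, 2.0) == pytest.approx(expected, rel=1e-12)
        assert cf_subdiffusion(q, t, D, 1.0) == pytest.approx(expected, rel=1e-12)
        assert cf_superdiffusion(q, t, D, 2.0) == pytest.approx(expected, rel=1e-12)

    def test_subdiffusion_closed_form(self):
        # D q^2 t^alpha = 1 at alpha = 1/2 -> erfcx(1)
        from scipy.special import erfcx
        t = 0.25
        q = np.sqrt(1.0 / (1.0 * t ** 0.5))
        assert cf_subdiffusion(q, t, 1.0, 0.5) == pytest.approx(
            erfcx(1.0), rel=1e-10)


class TestGeneralizedDiffusivity:
    def test_identity_at_gaussian_orders(self):
        gd = GeneralizedDiffusivity(D_ab=0.97e-3, mu=3.3, tau=0.7)
        _, D = generalized_to_classical(gd, 1.0, 2.0, t=0.031)
        assert D == pytest.approx(0.97e-3, rel=1e-12)

    def test_unit_scales_identity(self):
        gd = GeneralizedDiffusivity(D_ab=2e-3, mu=1.0, tau=1.0)
        d_pow, D = generalized_to_classical(gd, 1.0, 2.0, t=5.0)
        assert d_pow == pytest.approx(2e-3, rel=1e-12)
        assert D == pytest.approx(2e-3, rel=1e-12)

    def test_beta2_tau_equals_t_matches_two_parameter_form(self):
        # with beta = 2 and tau = t the 3- and 2-parameter arguments agree:
        # D q^2 tau^(1-a) t^a = D q^2 t -> b D
        D12, t, alpha = 0.97e-3, 0.031, 0.75
        gd = GeneralizedDiffusivity(D_ab=D12, mu=1.0, tau=t)
        d_pow, D = generalized_to_classical(gd, alpha, 2.0, t=t)
        assert D == pytest.approx(D12, rel=1e-12)

    def test_positive_invariants(self):
        with pytest.raises(DomainError):
            GeneralizedDiffusivity(D_ab=-1.0)


class TestDecayCurve:
    def test_sorting_and_s0(self):
        c = DecayCurve(b=[1000.0, 0.0, 500.0], signal=[3.0, 10.0, 5.0])
        assert list(c.b) == [0.0, 500.0, 1000.0]
        assert c.s0 == 10.0

    def test_rejects_bad_input(self):
        with pytest.raises(InputError):
            DecayCurve(b=[0.0, 500.0], signal=[1.0])
        with pytest.raises(InputError):
            DecayCurve(b=[0.0, 0.0], signal=[1.0, 1.0])
        with pytest.raises(InputError):
            DecayCurve(b=[0.0, 500.0], signal=[1.0, -1.0])
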