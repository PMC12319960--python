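import numpy as np
import pytest

from chisep.acquisition import AcquisitionParams
from chisep.separation import (
    FitOptions,
    composite_maps,
    decay_kernel,
    fit_three_pool,
    fit_volume,
    model_signal,
    signal_fractions,
    synthesize_signal,
)


@pytest.fixture(scope="module")
def a(params):
    return decay_kernel(params.B0, params.gamma)


class TestDecayKernel:
    def test_value_at_11p7T(self):
        # 1.26 kHz/ppm at 11.7 T
        a = decay_kernel(11.7, 2.6752e8)
        assert a / 1e3 == pytest.approx(1.26, abs=0.005)

    def test_closed_form(self):
        a = decay_kernel(11.7, 2.6752e8)
        assert a == pytest.approx(2 * np.pi * 2.6752e8 * 11.7 / (9 * np.sqrt(3)) * 1e-6)

    def test_rejects_nonpositive_b0(self):
        with pytest.raises(ValueError):
            decay_kernel(0.0, 2.6752e8)

    def test_linear_in_b0(self):
        a3, a117 = decay_kernel(3.0, 2.6752e8), decay_kernel(11.7, 2.6752e8)
        assert a3 / a117 == pytest.approx(3.0 / 11.7)
        assert a3 / 1e3 == pytest.approx(0.323, abs=0.001)


class TestSynthesizeSignal:
    def test_zero_chi_gives_real_signal(self, params, rng):
        mag = rng.uniform(0.5, 1.5, size=(3, 3, 3, 8))
        y = synthesize_signal(mag, np.zeros_like(mag), params)
        assert np.allclose(y, mag)

    def test_scalar_phase(self):
        params = AcquisitionParams(echo_times=(0.01,), B0=11.7, gamma=2.6752e8)
        y = synthesize_signal(np.ones((1, 1, 1, 1)), np.full((1, 1, 1, 1), 0.1), params)
        assert np.angle(y).ravel()[0] == pytest.approx(2.0866559999999996, rel=1e-9)

    def test_conjugation_symmetry(self, params, rng):
        mag = rng.uniform(0.5, 1.5, size=(2, 2, 2, 8))
        chi = rng.normal(scale=0.02, size=mag.shape)
        assert np.allclose(synthesize_signal(mag, -chi, params), np.conj(synthesize_signal(mag, chi, params)))

    def test_mismatched_lengths(self, params):
        with pytest.raises(ValueError):
            synthesize_signal(np.ones((2, 2, 2, 7)), np.zeros((2, 2, 2, 7)), params)


class TestModelSignal:
    def test_t0_sums_amplitudes(self, params, a):
        s = model_signal(0.3, 0.4, 0.3, 50.0, 0.02, -0.03, np.array([0.0]), a, params)
        assert s[0] == pytest.approx(1.0)

    def test_one_pool_limit(self, params, a):
        t = params.echo_times_array
        s = model_signal(1.0, 0.0, 0.0, 60.0, 0.05, -0.05, t, a, params)
        assert np.allclose(s, np.exp(-60.0 * t))
        assert np.allclose(s.imag, 0.0)

    def test_symmetric_pools_give_real_signal(self, params, a):
        # equal amplitudes, mirrored chi: phases cancel pairwise
        t = params.echo_times_array
        s = model_signal(0.0, 0.5, 0.5, 50.0, 0.05, -0.05, t, a, params)
        assert np.allclose(s.imag, 0.0, atol=1e-15)
        # both pools decay at R2*0 + a*0.05, phases combine to a cosine
        assert np.allclose(s.real, np.exp(-(50.0 + a * 0.05) * t) * np.cos(
            (2 / 3) * 0.05e-6 * params.gamma * params.B0 * t))


class TestFitThreePool:
    def test_noiseless_one_pool(self, params, a):
        t = params.echo_times_array
        y = model_signal(1.0, 0.0, 0.0, 60.0, 0.0, 0.0, t, a, params)
        fit = fit_three_pool(y, params)
        assert fit.alpha0 == pytest.approx(1.0, rel=0.01)
        assert fit.r2star0 == pytest.approx(60.0, rel=0.01)
        assert fit.fractions[0] >= 0.99

    def test_noiseless_two_pool(self, params, a):
        t = params.echo_times_array
        y = model_signal(0.6, 0.4, 0.0, 50.0, 0.03, 0.0, t, a, params)
        fit = fit_three_pool(y, params)
        assert fit.chi_plus == pytest.approx(0.03, rel=0.10)
        assert fit.fractions[1] == pytest.approx(0.4, abs=0.05)

    def test_fixed_point_at_optimum(self, params, a):
        t = params.echo_times_array
        y = model_signal(0.5, 0.3, 0.2, 45.0, 0.02, -0.015, t, a, params)
        first = fit_three_pool(y, params)
        refit_input = model_signal(
            first.alpha0, first.alpha_plus, first.alpha_minus,
            first.r2star0, first.chi_plus, first.chi_minus, t, a, params,
        )
        second = fit_three_pool(refit_input, params)
        assert second.chi_plus == pytest.approx(first.chi_plus, abs=1e-4)
        assert second.chi_minus == pytest.approx(first.chi_minus, abs=1e-4)
        assert second.r2star0 == pytest.approx(first.r2star0, rel=1e-3)

    def test_objective_monotone_noisy(self, params, rng):
        a = decay_kernel(params.B0, params.gamma)
        t = params.echo_times_array
        for _ in range(20):
            y = model_signal(0.4, 0.35, 0.25, rng.uniform(15, 60), rng.uniform(0.005, 0.05),
                             -rng.uniform(0.005, 0.05), t, a, params)
            y = y + rng.normal(0, 0.02, t.size) + 1j * rng.normal(0, 0.02, t.size)
            fit = fit_three_pool(y, params)
            trace = np.asarray(fit.objective_trace)
            assert np.all(np.diff(trace) <= 1e-12)

    def test_constraints_respected(self, params, rng):
        a = decay_kernel(params.B0, params.gamma)
        t = params.echo_times_array
        for _ in range(10):
            y = model_signal(0.3, 0.4, 0.3, rng.uniform(15, 60), rng.uniform(0.005, 0.05),
                             -rng.uniform(0.005, 0.05), t, a, params)
            y = y + rng.normal(0, 0.03, t.size) + 1j * rng.normal(0, 0.03, t.size)
            fit = fit_three_pool(y, params)
            assert fit.alpha0 >= 0 and fit.alpha_plus >= 0 and fit.alpha_minus >= 0
            assert fit.r2star0 > 0
            assert 0 <= fit.chi_plus < 0.1
            assert -0.1 < fit.chi_minus <= 0

    def test_rejects_zero_signal(self, params):
        with pytest.raises(ValueError):
            fit_three_pool(np.zeros(8, dtype=complex), params)

    def test_rejects_nan(self, params):
        y = np.ones(8, dtype=complex)
        y[3] = np.nan
        with pytest.raises(ValueError):
            fit_three_pool(y, params)

    def test_needs_six_echoes(self):
        p = AcquisitionParams(echo_times=(4e-3, 8e-3, 12e-3, 16e-3))
        with pytest.raises(ValueError, match="6 echoes"):
            fit_three_pool(np.ones(4, dtype=complex), p)


class TestFitVolume:
    def test_order_invariance_and_floor(self, params, a, rng):
        # two voxels with distinct parameters plus one sub-floor voxel
        t = params.echo_times_array
        shape = (3, 1, 1)
        y = np.zeros(shape + (8,), dtype=complex)
        y[0, 0, 0] = model_signal(0.6, 0.4, 0.0, 40.0, 0.03, 0.0, t, a, params)
        y[1, 0, 0] = model_signal(0.6, 0.0, 0.4, 40.0, 0.0, -0.03, t, a, params)
        y[2, 0, 0] = 1e-6 * model_signal(1.0, 0.0, 0.0, 40.0, 0.0, 0.0, t, a, params)
        mask = np.ones(shape, dtype=bool)
        maps = fit_volume(y, mask, params)
        assert maps["fitted_mask"][0, 0, 0] and maps["fitted_mask"][1, 0, 0]
        assert not maps["fitted_mask"][2, 0, 0]  # magnitude floor exclusion
        assert maps["chi_plus"][0, 0, 0] == pytest.approx(0.03, rel=0.05)
        assert maps["chi_minus"][1, 0, 0] == pytest.approx(-0.03, rel=0.05)
        # independence of processing order: refit a sub-volume, same result
        sub = fit_volume(y[:2], mask[:2], params)
        assert sub["chi_plus"][0, 0, 0] == maps["chi_plus"][0, 0, 0]
        assert sub["chi_minus"][1, 0, 0] == maps["chi_minus"][1, 0, 0]


class TestFractions:
    def test_simple_normalization(self):
        out = signal_fractions(np.array([[[1.0]]]), np.array([[[1.0]]]), np.array([[[2.0]]]))
        assert out["C0"][0, 0, 0] == pytest.approx(0.25)
        assert out["C_plus"][0, 0, 0] == pytest.approx(0.25)
        assert out["C_minus"][0, 0, 0] == pytest.approx(0.5)

    def test_single_pool(self):
        out = signal_fractions(np.array([[[2.0]]]), np.zeros((1, 1, 1)), np.zeros((1, 1, 1)))
        assert out["C0"][0, 0, 0] == 1.0 and out["C_plus"][0, 0, 0] == 0.0

    def test_zero_total_flagged(self):
        out = signal_fractions(np.zeros((1, 1, 1)), np.zeros((1, 1, 1)), np.zeros((1, 1, 1)))
        assert not out["valid"][0, 0, 0]
        assert out["C0"][0, 0, 0] == 0.0

    def test_sum_to_one_in_valid(self, rng):
        a0, ap, am = rng.uniform(0, 1, (3, 4, 4, 4))
        out = signal_fractions(a0, ap, am)
        total = out["C0"] + out["C_plus"] + out["C_minus"]
        assert np.allclose(total[out["valid"]], 1.0, atol=1e-9)


class TestCompositeMaps:
    def test_definition(self):
        fracs = {"C_plus": np.array([[[0.5]]]), "C_minus": np.array([[[0.2]]])}
        out = composite_maps(fracs, np.array([[[0.02]]]), np.array([[[-0.01]]]))
        assert out["PCS"][0, 0, 0] == pytest.approx(0.01)
        assert out["DCS"][0, 0, 0] == pytest.approx(-0.002)

    def test_ppb_boundary(self):
        fracs = {"C_plus": np.array([[[0.5]]]), "C_minus": np.array([[[0.0]]])}
        out = composite_maps(fracs, np.array([[[0.02]]]), np.array([[[-0.05]]]), ppb=True)
        assert out["PCS"][0, 0, 0] == pytest.approx(10.0)
        assert out["DCS"][0, 0, 0] == 0.0

    def test_neutral_voxel(self):
        fracs = {"C_plus": np.array([[[0.0]]]), "C_minus": np.array([[[0.0]]])}
        out = composite_maps(fracs, np.array([[[0.09]]]), np.array([[[-0.09]]]))
        assert out["PCS"][0, 0, 0] == 0.0 and out["DCS"][0, 0, 0] == 0.0

    def test_signs(self, rng):
        cp = rng.uniform(0, 1, (4, 4, 4))
        cm = rng.uniform(0, 1, (4, 4, 4))
        chip = rng.uniform(0, 0.1, (4, 4, 4))
        chim = -rng.uniform(0, 0.1, (4, 4, 4))
        out = composite_maps({"C_plus": cp, "C_minus": cm}, chip, chim)
        assert np.all(out["PCS"] >= 0) and np.all(out["DCS"] <= 0)
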