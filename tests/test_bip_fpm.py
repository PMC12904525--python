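"""Stage-I reconstruction: loss arithmetic, operator identities, training."""

import numpy as np
import pytest

from conftest import make_bench, pearson
from ptystain import autodiff as ad
from ptystain.bip_fpm import (
    BipFpmLossWeights,
    BipFpmReconstructor,
    BipFpmTrainConfig,
    minmax_normalize,
    raised_cosine_weights,
    synthetic_aperture_fuse,
    wiener_deconvolve,
)
from ptystain.optics import IlluminationSet, OpticalSystem, make_pupil
from ptystain.simulator import ComplexField, FPMStack, PhantomSpec, make_phantom, simulate_stack


@pytest.fixture(scope="module")
def bench():
    return make_bench(size=64, leds=5)


@pytest.fixture(scope="module")
def recon(bench):
    obj, system, pupil, illum, stack = bench
    return BipFpmReconstructor(system, illum,
                               BipFpmTrainConfig(epochs=20, freeze_epochs=2, seed=0,
                                                 base_width=8, n_res_blocks=2))


class TestForwardProject:
    def test_ground_truth_prediction_gives_zero_physics_loss(self, bench, recon):
        obj, system, pupil, illum, stack = bench
        sim = recon.forward_project((obj.amplitude, obj.phase, pupil.array, 1.0))
        l_phys = ((sim.numpy() - stack.images) ** 2).mean()
        assert l_phys < 1e-20

    def test_agreement_with_simulator_on_random_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            obj, system, pupil, illum, stack = make_bench(
                size=32, leds=3, phantom="texture", seed=int(rng.integers(1000)))
            rec = BipFpmReconstructor(system, illum,
                                      BipFpmTrainConfig(epochs=2, freeze_epochs=1,
                                                        base_width=4, n_res_blocks=1))
            sim = rec.forward_project((obj.amplitude, obj.phase, pupil.array, 1.0))
            assert np.abs(sim.numpy() - stack.images).max() < 1e-6

    def test_gain_linearity(self, bench, recon):
        obj, system, pupil, illum, stack = bench
        s1 = recon.forward_project((obj.amplitude, obj.phase, pupil.array, 1.0)).numpy()
        s3 = recon.forward_project((obj.amplitude, obj.phase, pupil.array, 3.0)).numpy()
        np.testing.assert_allclose(s3, 3.0 * s1, rtol=1e-12)


class TestPredictContract:
    def test_output_shapes_positivity_and_determinism(self, bench, recon):
        obj, system, pupil, illum, stack = bench
        p1 = recon.predict(stack)
        p2 = recon.predict(stack)
        assert p1.amplitude.shape == tuple(system.hr_shape)
        assert p1.phase.shape == tuple(system.hr_shape)
        assert np.all(p1.amplitude >= 0)
        assert np.all((p1.phase > -np.pi) & (p1.phase <= np.pi))
        np.testing.assert_array_equal(p1.amplitude, p2.amplitude)
        np.testing.assert_array_equal(p1.phase, p2.phase)

    def test_led_count_mismatch_raises(self, bench, recon):
        obj, system, pupil, illum, stack = bench
        bad = FPMStack(stack.images[:3], IlluminationSet(illum.wavevectors[:3]))
        with pytest.raises(ValueError):
            recon.predict(bad)


class TestComputeLosses:
    def test_two_led_toy_physics_loss_arithmetic(self):
        # 2 LEDs, 2x2 images, uniform per-pixel error 0.1 -> L_phys = 0.01
        system = OpticalSystem(wavelength=520e-9, objective_na=0.3, magnification=10.0,
                               camera_pixel_size=3e-6, hr_shape=(4, 4), upsample_factor=2)
        illum = IlluminationSet(np.zeros((2, 2)))
        rec = BipFpmReconstructor(system, illum,
                                  BipFpmTrainConfig(epochs=2, freeze_epochs=1,
                                                    base_width=4, n_res_blocks=1),
                                  BipFpmLossWeights(lambda_d=0.0))
        amp = ad.Tensor(np.ones((4, 4)))
        phase = ad.Tensor(np.zeros((4, 4)))
        pupil = ad.Tensor(np.ones((4, 4), dtype=complex))
        gain = ad.Tensor(np.array(1.0))
        sim = rec.forward_project((amp, phase, pupil, gain))
        stack = FPMStack(sim.numpy() + 0.1, illum)
        _, report = rec.compute_losses(stack, (amp, phase, pupil, gain))
        assert report["l_phys"] == pytest.approx(0.01, abs=1e-12)

    def test_constant_maps_have_zero_tv_and_zero_pupil_penalty(self, bench, recon):
        obj, system, pupil, illum, stack = bench
        amp = ad.Tensor(np.full(system.hr_shape, 0.7))
        phase = ad.Tensor(np.zeros(system.hr_shape))
        gain = ad.Tensor(np.array(1.0))
        _, report = recon.compute_losses(stack, (amp, phase, recon.pupil_tensor(), gain))
        assert report["l_tv"] == 0.0
        assert report["r_pupil"] == 0.0  # zero coefficients, even real pupil
        assert report["r_gain"] == 0.0

    def test_total_equals_weighted_sum_of_terms(self, bench, recon):
        obj, system, pupil, illum, stack = bench
        total, report = recon.compute_losses(stack)
        recomposed = sum(report.weighted(k) for k in report.terms)
        assert total.item() == pytest.approx(recomposed, rel=1e-12)

    def test_all_terms_nonnegative(self, bench, recon):
        obj, system, pupil, illum, stack = bench
        _, report = recon.compute_losses(stack)
        assert all(v >= 0 for v in report.terms.values())

    def test_gradient_flows_to_every_learnable(self, bench):
        obj, system, pupil, illum, stack = bench
        rec = BipFpmReconstructor(system, illum,
                                  BipFpmTrainConfig(epochs=2, freeze_epochs=1,
                                                    base_width=8, n_res_blocks=2))
        amp, phase, _ = rec._predict_tensors(stack)
        sim = rec.forward_project((amp, phase, rec.pupil_tensor(), rec.gain_tensor()))
        l_phys = ad.abs2(sim - ad.Tensor(stack.images)).mean()
        l_phys.backward()
        assert np.abs(rec.net.amp_head.weight.grad).max() > 0
        assert np.abs(rec.net.phase_head.weight.grad).max() > 0
        assert np.abs(rec.coeffs.grad[1:]).max() > 0  # non-piston modes
        assert abs(rec.log_gain.grad) > 0


class TestWienerDeconvolve:
    def test_identity_filter(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0.1, 1.0, (16, 16))
        out = wiener_deconvolve(img, np.ones((16, 16), dtype=complex), 0.0)
        np.testing.assert_allclose(out.real, img, atol=1e-12)

    def test_large_alpha_shrinks_monotonically(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0.1, 1.0, (16, 16))
        h = np.ones((16, 16), dtype=complex)
        norms = [np.linalg.norm(np.abs(wiener_deconvolve(img, h, a)))
                 for a in (0.0, 1.0, 1e3, 1e6)]
        assert all(b < a for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-5 * norms[0]

    def test_restoration_gain_on_blurred_phantom(self):
        from scipy.ndimage import gaussian_filter
        bars = make_phantom(PhantomSpec(kind="bars", size=64, seed=0)).amplitude
        # matched transfer function of a Gaussian blur, built in the same
        # DC-centered convention as the deconvolution
        sigma = 2.0
        psf = np.zeros((64, 64))
        psf[32, 32] = 1.0
        psf = gaussian_filter(psf, sigma)
        h = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(psf)))
        blurred = gaussian_filter(bars, sigma)
        restored = np.abs(wiener_deconvolve(blurred, h, 1e-3))
        assert pearson(restored, bars) > pearson(blurred, bars)

    def test_zero_alpha_with_otf_zeros_rejected(self):
        h = np.ones((8, 8), dtype=complex)
        h[0, 0] = 0.0
        with pytest.raises(ZeroDivisionError):
            wiener_deconvolve(np.ones((8, 8)), h, 0.0)


class TestSyntheticAperture:
    def test_identity_configuration(self):
        system = OpticalSystem(wavelength=520e-9, objective_na=0.25, magnification=10.0,
                               camera_pixel_size=6.5e-6, hr_shape=(32, 32), upsample_factor=2)
        rng = np.random.default_rng(0)
        fld = ComplexField(rng.uniform(0.1, 1, (32, 32)), rng.uniform(-1, 1, (32, 32)), 1e-6)
        illum = IlluminationSet(np.zeros((1, 2)))
        allpass = make_pupil(system)
        allpass.array[:] = 1.0
        weights = np.ones((1, 32, 32))
        fused = synthetic_aperture_fuse(fld, illum, system, pupil=allpass, weights=weights)
        np.testing.assert_allclose(fused.amplitude, fld.amplitude, atol=1e-10)

    def test_spectrum_zero_outside_shifted_supports(self, bench):
        obj, system, pupil, illum, stack = bench
        fused = synthetic_aperture_fuse(obj, illum, system)
        weights, covered = raised_cosine_weights(illum, system)
        spec = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(fused.as_complex()), norm="ortho"))
        assert np.abs(spec[~covered]).max() < 1e-9 * np.abs(spec).max()

    def test_flat_weights_preserve_inband_spectrum_up_to_scalar(self):
        obj, system, pupil, illum, stack = make_bench(size=64, leds=5)
        weights, covered = raised_cosine_weights(illum, system)
        flat = (weights > 0).astype(float)
        cover_count = flat.sum(axis=0)
        flat[:, cover_count > 0] /= cover_count[cover_count > 0]
        fused = synthetic_aperture_fuse(obj, illum, system, weights=flat)
        spec_in = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(obj.as_complex()), norm="ortho"))
        spec_out = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(fused.as_complex()), norm="ortho"))
        n = len(illum)
        interior = covered & (np.abs(spec_in) > 1e-3 * np.abs(spec_in).max())
        rel = np.abs(spec_out[interior] * n - spec_in[interior]) / np.abs(spec_in[interior])
        assert rel.max() < 1e-3

    def test_weight_partition_of_unity(self, bench):
        obj, system, pupil, illum, stack = bench
        weights, covered = raised_cosine_weights(illum, system)
        assert np.all(weights >= 0)
        np.testing.assert_allclose(weights.sum(axis=0)[covered], 1.0, atol=1e-12)


@pytest.fixture(scope="module")
def short_run():
    obj, system, pupil, illum, stack = make_bench(size=64, leds=5, seed=3)
    rec = BipFpmReconstructor(system, illum,
                              BipFpmTrainConfig(epochs=40, freeze_epochs=5, seed=0,
                                                base_width=8, n_res_blocks=3))
    pred, history = rec.train(stack)
    return obj, rec, pred, history


class TestTraining:

    def test_loss_decreases_after_freeze(self, short_run):
        obj, rec, pred, history = short_run
        assert history[-1].total <= history[5].total

    def test_optical_params_frozen_early(self, short_run):
        obj, rec, pred, history = short_run
        # during freeze epochs the coefficients stay exactly zero
        assert history[0].terms["r_pupil"] == 0.0

    def test_best_prediction_is_finite_and_positive(self, short_run):
        obj, rec, pred, history = short_run
        assert np.all(np.isfinite(pred.amplitude))
        assert np.all(pred.amplitude >= 0)
        assert pred.gain > 0

    def test_same_seed_reproduces_training(self):
        obj, system, pupil, illum, stack = make_bench(size=32, leds=3, seed=1)
        results = []
        for _ in range(2):
            rec = BipFpmReconstructor(system, illum,
                                      BipFpmTrainConfig(epochs=8, freeze_epochs=2, seed=7,
                                                        base_width=4, n_res_blocks=1))
            pred, hist = rec.train(stack)
            results.append((pred.amplitude, [h.total for h in hist]))
        np.testing.assert_array_equal(results[0][0], results[1][0])
        assert results[0][1] == results[1][1]


class TestExportInterface:
    def test_interface_range_and_idempotence(self, bench, recon):
        obj, system, pupil, illum, stack = bench
        pred = recon.predict(stack)
        i_int, feats = recon.export_interface(pred)
        assert i_int.min() >= 0.0 and i_int.max() <= 1.0
        np.testing.assert_array_equal(minmax_normalize(i_int), i_int)
        assert len(feats) == 3

    def test_constant_amplitude_maps_to_zeros(self):
        assert np.all(minmax_normalize(np.full((8, 8), 3.3)) == 0.0)

    def test_phase_and_optics_not_exported(self, bench, recon):
        obj, system, pupil, illum, stack = bench
        out = recon.export_interface(recon.predict(stack))
        assert len(out) == 2  # interface image and features only
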