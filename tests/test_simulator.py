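"""FPM stack simulation: forward model exactness, noise protocol, phantoms."""

import numpy as np
import pytest

from ptystain import autodiff as ad
from ptystain.optics import (
    InvalidConfiguration,
    LEDArrayGeometry,
    OpticalSystem,
    PupilFunction,
    led_wavevectors,
    make_pupil,
    zernike_basis,
)
from ptystain.simulator import (
    ComplexField,
    FPMStack,
    PhantomSpec,
    add_noise,
    baboon_protocol,
    forward_intensities,
    make_phantom,
    simulate_stack,
)


@pytest.fixture
def system():
    return OpticalSystem(wavelength=520e-9, objective_na=0.25, magnification=10.0,
                         camera_pixel_size=6.5e-6, hr_shape=(64, 64), upsample_factor=2)


@pytest.fixture
def geom():
    return LEDArrayGeometry(rows=5, cols=5, pitch=4e-3, distance=40e-3)


@pytest.fixture
def illum(system, geom):
    return led_wavevectors(geom, system)


def _allpass_pupil(system):
    return PupilFunction(cutoff=np.inf, zernike_coeffs=np.zeros(15),
                         array=np.ones(system.hr_shape, dtype=complex),
                         freq_step=system.freq_step)


def _bandlimited_field(system, rng, frac=0.6):
    """Random complex object whose spectrum lies well inside the pupil disk."""
    n = system.hr_shape[0]
    spec = np.zeros((n, n), dtype=complex)
    r = int(system.pupil_radius_px * frac)
    c = n // 2
    block = rng.normal(size=(2 * r + 1, 2 * r + 1)) + 1j * rng.normal(size=(2 * r + 1, 2 * r + 1))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    block[yy ** 2 + xx ** 2 > r * r] = 0
    spec[c - r:c + r + 1, c - r:c + r + 1] = block
    u = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(spec), norm="ortho"))
    u = u / np.abs(u).max() * 0.8 + 1.0  # keep amplitude positive
    return ComplexField(np.abs(u), np.angle(u), system.hr_pixel_size)


class TestForwardModel:
    def test_flat_object_allpass_gives_unit_intensity(self, system, illum):
        obj = ComplexField(np.ones(system.hr_shape), np.zeros(system.hr_shape),
                           system.hr_pixel_size)
        # single oblique LED within the grid budget
        one = type(illum)(illum.wavevectors[7:8])
        stack = simulate_stack(obj, system, _allpass_pupil(system), one, gain=1.0)
        np.testing.assert_allclose(stack.images, 1.0, atol=1e-10)

    def test_gain_linearity(self, system, illum):
        obj = make_phantom(PhantomSpec(kind="texture", size=64, seed=1))
        pupil = make_pupil(system)
        s1 = simulate_stack(obj, system, pupil, illum, gain=1.0)
        s2 = simulate_stack(obj, system, pupil, illum, gain=2.0)
        np.testing.assert_allclose(s2.images, 2.0 * s1.images, rtol=1e-12)

    def test_bandlimited_object_central_led_matches_fft_crop_oracle(self, system):
        rng = np.random.default_rng(3)
        obj = _bandlimited_field(system, rng)
        pupil = make_pupil(system)
        central = type(led_wavevectors(LEDArrayGeometry(1, 1, 1e-3, 40e-3), system))(
            np.zeros((1, 2)))
        stack = simulate_stack(obj, system, pupil, central)
        # independent oracle: ideal FFT-crop downsampling of the complex field
        u = obj.as_complex()
        n, m = system.hr_shape[0], system.lr_shape[0]
        spec = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(u), norm="ortho"))
        crop = spec[(n - m) // 2:(n + m) // 2, (n - m) // 2:(n + m) // 2] * (m / n)
        o_ds = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(crop), norm="ortho"))
        assert np.abs(stack.images[0] - np.abs(o_ds) ** 2).max() < 1e-6

    def test_shift_consistency_with_premodulated_object(self, system, illum):
        # LED n equals the central LED on the object times exp(j k_n . r),
        # with k_n rounded to the frequency grid (the simulator's convention)
        rng = np.random.default_rng(5)
        obj = make_phantom(PhantomSpec(kind="disks", size=64, seed=2))
        pupil = make_pupil(system)
        shifts, _ = illum.pixel_shifts(system)
        idx = 3  # an oblique LED
        one = type(illum)(illum.wavevectors[idx:idx + 1])
        direct = simulate_stack(obj, system, pupil, one)
        n = system.hr_shape[0]
        coords = np.arange(n) - n // 2
        yy, xx = np.meshgrid(coords, coords, indexing="ij")
        sy, sx = shifts[idx]
        ramp = np.exp(2j * np.pi * (sy * yy + sx * xx) / n)
        u = obj.as_complex() * ramp
        premod = ComplexField(np.abs(u), np.angle(u), system.hr_pixel_size)
        central = type(illum)(np.zeros((1, 2)))
        via_center = simulate_stack(premod, system, pupil, central)
        np.testing.assert_allclose(direct.images, via_center.images, atol=1e-8)

    def test_energy_monotone_in_pupil_cutoff(self, system, illum):
        obj = make_phantom(PhantomSpec(kind="texture", size=64, seed=4))
        fy, fx = system.frequency_grid()
        rho = np.hypot(fy, fx)
        energies = []
        for frac in (1.0, 0.8, 0.6, 0.4):
            cut = system.cutoff_frequency * frac
            pupil = PupilFunction(cut, np.zeros(15), np.where(rho <= cut, 1.0 + 0j, 0.0),
                                  system.freq_step)
            stack = simulate_stack(obj, system, pupil, illum)
            energies.append(stack.images.sum(axis=(1, 2)))
        for bigger, smaller in zip(energies, energies[1:]):
            assert np.all(smaller <= bigger + 1e-12)

    def test_gradient_wrt_defocus_matches_finite_differences(self):
        sysm = OpticalSystem(wavelength=520e-9, objective_na=0.25, magnification=10.0,
                             camera_pixel_size=6.5e-6, hr_shape=(32, 32), upsample_factor=2)
        geom = LEDArrayGeometry(rows=3, cols=3, pitch=4e-3, distance=40e-3)
        illum = led_wavevectors(geom, sysm)
        shifts, _ = illum.pixel_shifts(sysm)
        obj = make_phantom(PhantomSpec(kind="texture", size=32, seed=6))
        fy, fx = sysm.frequency_grid()
        mask = (np.hypot(fy, fx) <= sysm.cutoff_frequency).astype(float)
        z4 = zernike_basis(4, fy, fx, sysm.cutoff_frequency)[3]
        # reference stack at a4 = 0; the data-consistency residual has a
        # nonzero defocus gradient (total intensity alone is phase-blind
        # by Parseval, so a residual loss is the meaningful probe)
        with ad.no_grad():
            ref = forward_intensities(obj.amplitude, obj.phase,
                                      mask.astype(complex), shifts, sysm).numpy()

        def value(a4):
            pupn = mask * np.exp(1j * a4 * z4)
            with ad.no_grad():
                out = forward_intensities(obj.amplitude, obj.phase, pupn, shifts, sysm).numpy()
            return ((out - ref) ** 2).sum()

        coeff = ad.Tensor(np.array(0.3), requires_grad=True)
        pup = ad.polar(ad.Tensor(mask), ad.Tensor(z4) * coeff)
        out = forward_intensities(obj.amplitude, obj.phase, pup, shifts, sysm)
        ((out - ad.Tensor(ref)) ** 2).sum().backward()
        eps = 1e-5
        numeric = (value(0.3 + eps) - value(0.3 - eps)) / (2 * eps)
        assert abs(coeff.grad - numeric) / abs(numeric) < 1e-4

    def test_shape_and_gain_errors(self, system, illum):
        obj = make_phantom(PhantomSpec(kind="texture", size=32, seed=0))
        with pytest.raises(ValueError):
            simulate_stack(obj, system, make_pupil(system), illum)
        obj64 = make_phantom(PhantomSpec(kind="texture", size=64, seed=0))
        with pytest.raises(InvalidConfiguration):
            simulate_stack(obj64, system, make_pupil(system), illum, gain=-1.0)


class TestNoise:
    @pytest.fixture
    def stack(self, system, illum):
        obj = make_phantom(PhantomSpec(kind="texture", size=64, seed=7))
        return simulate_stack(obj, system, make_pupil(system), illum)

    def test_zero_sd_is_bit_identical(self, stack):
        out = add_noise(stack, 0.0, seed=1)
        np.testing.assert_array_equal(out.images, stack.images)

    def test_empirical_sd_matches_request(self, stack):
        sd = 1e-4
        out = add_noise(stack, sd, seed=2)
        resid = out.images - stack.images
        # clipping at zero affects only pixels within ~sd of zero; measure on the rest
        unclipped = stack.images > 10 * sd * stack.images.max()
        measured = resid[unclipped].std()
        assert abs(measured - sd * stack.images.max()) / (sd * stack.images.max()) < 0.05

    def test_seeded_determinism(self, stack):
        a = add_noise(stack, 5e-5, seed=3)
        b = add_noise(stack, 5e-5, seed=3)
        np.testing.assert_array_equal(a.images, b.images)

    def test_negative_sd_rejected(self, stack):
        with pytest.raises(ValueError):
            add_noise(stack, -1e-5, seed=0)


class TestPhantoms:
    def test_bars_metadata_matches_construction(self):
        fld = make_phantom(PhantomSpec(kind="bars", size=128, seed=0))
        groups = fld.meta["groups"]
        assert groups, "bars phantom must contain at least one group"
        for g in groups:
            assert g["pitch_px"] == 2 * g["bar_width_px"]
        assert fld.meta["finest_pitch_px"] == groups[-1]["pitch_px"]

    @pytest.mark.parametrize("kind", ["bars", "disks", "texture"])
    def test_amplitude_normalized(self, kind):
        fld = make_phantom(PhantomSpec(kind=kind, size=64, seed=1))
        assert fld.amplitude.min() >= 0.0
        assert fld.amplitude.max() <= 1.0

    @pytest.mark.parametrize("kind", ["bars", "disks", "texture"])
    def test_seeded_reproducibility(self, kind):
        a = make_phantom(PhantomSpec(kind=kind, size=64, seed=9))
        b = make_phantom(PhantomSpec(kind=kind, size=64, seed=9))
        np.testing.assert_array_equal(a.amplitude, b.amplitude)
        np.testing.assert_array_equal(a.phase, b.phase)

    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError):
            make_phantom(PhantomSpec(kind="voronoi"))

    def test_phase_amplitude_coupling(self):
        fld = make_phantom(PhantomSpec(kind="texture", size=64, seed=1))
        np.testing.assert_allclose(fld.phase, np.pi * fld.amplitude)


@pytest.fixture(scope="module")
def protocol():
    img = make_phantom(PhantomSpec(kind="texture", size=64, seed=11)).amplitude
    with pytest.warns(UserWarning):
        return baboon_protocol(img, seed=0)


class TestBaboonProtocol:
    def test_each_stack_has_169_images(self, protocol):
        stacks, _, _ = protocol
        assert len(stacks) == 6
        assert all(len(s) == 13 * 13 for s in stacks)

    def test_zero_noise_stack_equals_clean_simulation(self, protocol):
        stacks, system, obj = protocol
        from ptystain.optics import led_wavevectors as lwv
        geom = LEDArrayGeometry(rows=13, cols=13, pitch=8e-3, distance=98e-3)
        clean = simulate_stack(obj, system, make_pupil(system), lwv(geom, system))
        np.testing.assert_array_equal(stacks[0].images, clean.images)

    def test_cutoff_frequency_in_metadata(self, protocol):
        stacks, _, _ = protocol
        assert np.isclose(stacks[0].meta["cutoff_frequency"], 0.13 / 505e-9, rtol=1e-12)
        assert np.isclose(stacks[0].meta["cutoff_frequency"], 2.574e5, rtol=1e-3)

    def test_noise_levels_are_the_printed_grid(self, protocol):
        stacks, _, _ = protocol
        np.testing.assert_allclose([s.noise_sd for s in stacks],
                                   np.array([0, 0.2, 0.4, 0.6, 0.8, 1.0]) * 1e-4)


def test_stack_validation():
    illum = led_wavevectors(LEDArrayGeometry(2, 2, 4e-3, 40e-3),
                            OpticalSystem(wavelength=520e-9, objective_na=0.25,
                                          magnification=10, camera_pixel_size=6.5e-6,
                                          hr_shape=(32, 32)))
    with pytest.raises(ValueError):
        FPMStack(np.ones((3, 8, 8)), illum)  # 3 images, 4 LEDs
    with pytest.raises(ValueError):
        FPMStack(np.full((4, 8, 8), np.nan), illum)
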