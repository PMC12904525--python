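"""Differentiable multi-LED FPM simulator and procedural test phantoms.

The coherent forward model (per LED n, gain s):

    I_n = s * | invFT( P(f) * U(f - k_n) ) |^2   downsampled to the LR grid

with U = FT(A * exp(j*phi)).  Downsampling is a Fourier-domain central crop
(ideal band-limited sampling), scaled so a unit-amplitude plane wave through
an all-pass system yields unit intensity.  The same code path serves both
stack synthesis and the reconstruction network's forward projection, and is
differentiable with respect to amplitude, phase, Zernike coefficients and
gain through :mod:`ptystain.autodiff`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .optics import (
    IlluminationSet,
    InvalidConfiguration,
    LEDArrayGeometry,
    OpticalSystem,
    PupilFunction,
    led_wavevectors,
    make_pupil,
)

__all__ = [
    "ComplexField",
    "FPMStack",
    "PhantomSpec",
    "forward_intensities",
    "simulate_stack",
    "add_noise",
    "make_phantom",
    "baboon_protocol",
    "BABOON_NOISE_LEVELS",
]

# noise SD grid of the printed robustness protocol (relative to unit maximum)
BABOON_NOISE_LEVELS = tuple(np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0]) * 1e-4)


@dataclass
class ComplexField:
    """High-resolution object field A(x,y) * exp(j*phi(x,y))."""

    amplitude: np.ndarray
    phase: np.ndarray
    pixel_size: float

    def __post_init__(self):
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase grids must share a shape")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be nonnegative")

    @property
    def shape(self):
        return self.amplitude.shape

    def as_complex(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)


@dataclass
class FPMStack:
    """N low-resolution intensity images plus illumination metadata."""

    images: np.ndarray  # (N, h, w)
    illumination: IlluminationSet
    gain: float = 1.0
    noise_sd: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("stack images must be (N, h, w)")
        if self.images.shape[0] != len(self.illumination):
            raise ValueError(
                f"{self.images.shape[0]} images but {len(self.illumination)} LEDs")
        if not np.all(np.isfinite(self.images)):
            raise ValueError("stack contains non-finite intensities")

    def __len__(self):
        return self.images.shape[0]

    @property
    def lr_shape(self):
        return self.images.shape[1:]


# ---------------------------------------------------------------------------
# differentiable forward model
# ---------------------------------------------------------------------------

def forward_intensities(amplitude, phase, pupil, shifts, system: OpticalSystem,
                        gain=1.0):
    """Differentiable core of the imaging model; returns a Tensor (N, h, w).

    Parameters may be :class:`~ptystain.autodiff.Tensor` (to participate in a
    gradient graph) or plain arrays.  ``pupil`` is the complex pupil sampled
    on the HR frequency lattice; ``shifts`` are integer (dy, dx) spectrum
    shifts per LED (nearest-bin rounding of k_n).
    """
    amp = ad.astensor(amplitude)
    ph = ad.astensor(phase)
    pup = ad.astensor(pupil)
    g = ad.astensor(gain)
    if amp.shape != tuple(system.hr_shape):
        raise ValueError(f"object grid {amp.shape} != HR grid {tuple(system.hr_shape)}")
    if pup.shape != tuple(system.hr_shape):
        raise ValueError(f"pupil grid {pup.shape} != HR grid {tuple(system.hr_shape)}")
    if np.any(g.data <= 0):
        raise InvalidConfiguration("gain s must be positive")
    mlr, nhr = system.lr_shape[0], system.hr_shape[0]
    scale = mlr / nhr  # unit plane wave -> unit intensity under ortho FFTs
    spectrum = ad.fft2c(ad.polar(amp, ph))
    outs = []
    for dy, dx in shifts:
        shifted = ad.roll2d(spectrum, int(dy), int(dx))
        banded = shifted * pup
        lr_spec = ad.crop_center(banded, *system.lr_shape) * scale
        outs.append(ad.abs2(ad.ifft2c(lr_spec)))
    return ad.stack(outs, axis=0) * g


def simulate_stack(obj: ComplexField, system: OpticalSystem, pupil: PupilFunction,
                   illum: IlluminationSet, gain: float = 1.0,
                   meta: dict | None = None) -> FPMStack:
    """Synthesize the noiseless multi-LED stack for a known object."""
    if obj.shape != tuple(system.hr_shape):
        raise ValueError(f"object grid {obj.shape} != HR grid {tuple(system.hr_shape)}")
    shifts, residual = illum.pixel_shifts(system)
    with ad.no_grad():
        images = forward_intensities(obj.amplitude, obj.phase, pupil.array,
                                     shifts, system, gain).numpy()
    info = {
        "cutoff_frequency": system.cutoff_frequency,
        "pixel_shifts": shifts,
        "subpixel_residual": residual,
    }
    if meta:
        info.update(meta)
    return FPMStack(images, illum, gain=gain, noise_sd=0.0, meta=info)


def add_noise(stack: FPMStack, sd: float, seed: int) -> FPMStack:
    """Additive zero-mean Gaussian noise, SD relative to the stack maximum.

    Intensities are interpreted on a scale where the noiseless global
    maximum is 1, so ``sd`` matches the printed noise protocol; values are
    clipped at zero (intensities are nonnegative).  ``sd = 0`` returns a
    bit-identical copy.
    """
    if sd < 0:
        raise ValueError("noise SD must be nonnegative")
    if sd == 0:
        noisy = stack.images.copy()
    else:
        rng = np.random.default_rng(seed)
        scale = stack.images.max()
        noisy = stack.images + sd * scale * rng.standard_normal(stack.images.shape)
        np.clip(noisy, 0.0, None, out=noisy)
    meta = dict(stack.meta)
    meta["noise_seed"] = seed
    return FPMStack(noisy, stack.illumination, gain=stack.gain, noise_sd=sd, meta=meta)


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Seeded procedural phantom description (bit-reproducible)."""

    kind: str = "bars"
    size: int = 128
    seed: int = 0
    contrast: float = 0.9       # amplitude swing above background
    background: float = 0.1
    phase_scale: float = np.pi  # phi = phase_scale * A (amplitude-coupled phase)
    n_disks: int = 12


def _bars_phantom(spec: PhantomSpec):
    """USAF-style resolution groups: vertical 5-bar blocks at known pitches."""
    size = spec.size
    amp = np.full((size, size), spec.background)
    widths = [max(1, size // s) for s in (16, 24, 32, 48, 64)]
    groups = []
    x = size // 12
    for w in widths:
        n_bars = 5
        span = n_bars * 2 * w - w
        if x + span >= size - size // 12:
            break
        y0, y1 = size // 8, size - size // 8
        centers = []
        for b in range(n_bars):
            x0 = x + b * 2 * w
            amp[y0:y1, x0:x0 + w] = spec.background + spec.contrast
            centers.append(x0 + w / 2)
        groups.append({"pitch_px": 2 * w, "bar_width_px": w, "bar_centers_x": centers,
                       "rows": (y0, y1), "n_bars": n_bars})
        x += span + 3 * w
    return amp, {"groups": groups, "finest_pitch_px": groups[-1]["pitch_px"] if groups else None}


def _disks_phantom(spec: PhantomSpec, rng: np.random.Generator):
    size = spec.size
    amp = np.full((size, size), spec.background)
    yy, xx = np.mgrid[0:size, 0:size]
    placed = []
    tries = 0
    while len(placed) < spec.n_disks and tries < 200 * spec.n_disks:
        tries += 1
        r = rng.uniform(size / 24, size / 8)
        cy, cx = rng.uniform(r, size - r, size=2)
        if all((cy - py) ** 2 + (cx - px) ** 2 > (r + pr) ** 2 for py, px, pr in placed):
            placed.append((cy, cx, r))
            amp[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = spec.background + spec.contrast
    return amp, {"disks": placed}


def _texture_phantom(spec: PhantomSpec, rng: np.random.Generator):
    size = spec.size
    rough = rng.standard_normal((size, size))
    smooth = ndimage.gaussian_filter(rough, sigma=size / 48.0)
    smooth = (smooth - smooth.min()) / (smooth.max() - smooth.min() + 1e-12)
    amp = spec.background + spec.contrast * smooth
    return amp, {}


def make_phantom(spec: PhantomSpec) -> ComplexField:
    """Build a seeded phantom; amplitude in [0, 1], phase = phase_scale * A."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "bars":
        amp, meta = _bars_phantom(spec)
    elif spec.kind == "disks":
        amp, meta = _disks_phantom(spec, rng)
    elif spec.kind == "texture":
        amp, meta = _texture_phantom(spec, rng)
    elif spec.kind == "stain-tissue":
        from .tissue import TissuePhantomSpec, generate_bundle
        bundle, geo = generate_bundle(TissuePhantomSpec(size=spec.size, seed=spec.seed))
        amp = spec.background + spec.contrast * bundle.interface
        meta = {"tissue": geo}
    else:
        raise ValueError(f"unknown phantom kind: {spec.kind!r}")
    amp = np.clip(amp, 0.0, 1.0)
    fld = ComplexField(amp, spec.phase_scale * amp, pixel_size=np.nan)
    fld.meta = meta  # attached, not part of the dataclass contract
    fld.meta["spec"] = spec
    return fld


# ---------------------------------------------------------------------------
# printed noise protocol
# ---------------------------------------------------------------------------

def baboon_protocol(image: np.ndarray, noise_levels=BABOON_NOISE_LEVELS,
                    upsample_factor: int = 4, seed: int = 0,
                    phase_scale: float = 0.0):
    """Simulate the printed noise-robustness protocol on a grayscale image.

    Optics: 4x magnification, NA 0.13, 6.5 um camera pixels, 505 nm light,
    a 13 x 13 LED array 98 mm below the specimen with 8 mm pitch.  One stack
    is emitted per noise SD, sharing a single noise realization scaled by SD
    (common-random-numbers design) so noise sweeps are directly comparable.

    Returns ``(stacks, system, ground_truth_field)``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("protocol expects a square grayscale image")
    lo, hi = image.min(), image.max()
    amp = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)
    system = OpticalSystem(wavelength=505e-9, objective_na=0.13, magnification=4.0,
                           camera_pixel_size=6.5e-6, hr_shape=image.shape,
                           upsample_factor=upsample_factor)
    geom = LEDArrayGeometry(rows=13, cols=13, pitch=8e-3, distance=98e-3)
    illum = led_wavevectors(geom, system)
    shifts, _ = illum.pixel_shifts(system)
    radial = np.hypot(shifts[:, 0], shifts[:, 1])
    if (radial + system.pupil_radius_px).max() > system.hr_shape[0] / 2:
        n_alias = int(np.sum(radial + system.pupil_radius_px > system.hr_shape[0] / 2))
        warnings.warn(
            f"{n_alias} oblique LEDs exceed the HR frequency grid and wrap "
            "(printed geometry at this grid size); increase upsample_factor "
            "for a strictly alias-free simulation", stacklevel=2)
    obj = ComplexField(amp, phase_scale * amp, pixel_size=system.hr_pixel_size)
    pupil = make_pupil(system)
    clean = simulate_stack(obj, system, pupil, illum, meta={"protocol": "baboon-noise-sweep"})
    stacks = [add_noise(clean, sd, seed) for sd in noise_levels]
    return stacks, system, obj
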