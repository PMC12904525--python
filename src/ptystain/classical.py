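"""Classical FPM reconstruction: alternating projections with embedded
pupil recovery (AP + EPRY).

Sequential Gerchberg-Saxton-style projections: for each LED the modulus of
the low-resolution field is replaced by the measured sqrt-intensity, the
corresponding shifted patch of the high-resolution spectrum is updated with
the standard PIE-type step, and the pupil receives the EPRY gradient step.
LEDs are processed spiralling outward from the center (low to high spatial
frequency), the standard ordering when none is prescribed.

This module is intentionally network-free; it is the published baseline and
doubles as an independent oracle for the learned reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .optics import OpticalSystem, PupilFunction, make_pupil
from .simulator import ComplexField, FPMStack

__all__ = ["APConfig", "ap_epry_reconstruct", "ReconstructionDiverged"]


class ReconstructionDiverged(ArithmeticError):
    """Raised when the data-consistency residual becomes non-finite."""


@dataclass
class APConfig:
    n_iterations: int = 20
    object_step: float = 1.0
    pupil_step: float = 0.1
    initialization: str = "upsampled-mean"  # or "flat"
    update_pupil: bool = True
    init_field: np.ndarray = None  # explicit complex init (overrides initialization)

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.object_step <= 0 or self.pupil_step < 0:
            raise ValueError("step sizes must be positive")
        if self.initialization not in ("upsampled-mean", "flat"):
            raise ValueError(f"unknown initialization {self.initialization!r}")


def _fft2c(x):
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x), norm="ortho"))


def _ifft2c(x):
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(x), norm="ortho"))


def ap_epry_reconstruct(stack: FPMStack, system: OpticalSystem,
                        config: APConfig | None = None,
                        pupil_init: PupilFunction | None = None):
    """Reconstruct (field, pupil, residual history) from a multi-LED stack.

    The residual logged per iteration is the mean over LEDs of the per-image
    mean squared amplitude mismatch before that iteration's updates.
    """
    config = config or APConfig()
    n = system.hr_shape[0]
    m = system.lr_shape[0]
    scale = m / n  # spectral-crop sampling convention shared with the simulator
    shifts, _ = stack.illumination.pixel_shifts(system)
    amps = np.sqrt(np.clip(stack.images / stack.gain, 0.0, None))

    # --- initialization ----------------------------------------------------
    if config.init_field is not None:
        field0 = np.asarray(config.init_field, dtype=complex)
        if field0.shape != tuple(system.hr_shape):
            raise ValueError("init_field must live on the HR grid")
    elif config.initialization == "upsampled-mean":
        mean_amp = np.sqrt(np.clip(stack.images.mean(axis=0) / stack.gain, 0.0, None))
        field0 = resize(mean_amp, system.hr_shape, order=3, anti_aliasing=False).astype(complex)
    else:
        field0 = np.ones(system.hr_shape, dtype=complex)
    spectrum = _fft2c(field0)

    base = make_pupil(system)
    support_lr = PupilFunction(base.cutoff, base.zernike_coeffs, base.array,
                               base.freq_step, support=base.support).lr_crop(system.lr_shape)
    mask = np.abs(support_lr.array) > 0
    if pupil_init is not None:
        pupil = pupil_init.array
        if pupil.shape == tuple(system.hr_shape):
            c0 = (n - m) // 2
            pupil = pupil[c0:c0 + m, c0:c0 + m].copy()
    else:
        pupil = support_lr.array.copy()

    order = np.argsort(np.hypot(shifts[:, 0], shifts[:, 1]), kind="stable")
    c0 = (n - m) // 2
    residuals = []

    for it in range(config.n_iterations):
        resid = 0.0
        for idx in order:
            sy, sx = int(shifts[idx, 0]), int(shifts[idx, 1])
            rolled = np.roll(spectrum, (sy, sx), axis=(0, 1))
            patch = rolled[c0:c0 + m, c0:c0 + m]
            psi = pupil * patch
            u = _ifft2c(psi) * scale
            model_amp = np.abs(u)
            resid += float(((model_amp - amps[idx]) ** 2).mean())
            u_new = amps[idx] * u / np.maximum(model_amp, 1e-12)
            dpsi = _fft2c(u_new) / scale - psi
            patch_new = patch + config.object_step * np.conj(pupil) / (np.abs(pupil).max() ** 2 + 1e-12) * dpsi
            if config.update_pupil and config.pupil_step > 0:
                pupil = pupil + config.pupil_step * np.conj(patch) / (np.abs(patch).max() ** 2 + 1e-12) * dpsi
                pupil *= mask
            rolled[c0:c0 + m, c0:c0 + m] = patch_new
            spectrum = np.roll(rolled, (-sy, -sx), axis=(0, 1))
        resid /= len(order)
        if not np.isfinite(resid):
            raise ReconstructionDiverged(f"residual became non-finite at iteration {it}")
        residuals.append(resid)

    field = _ifft2c(spectrum)
    recon = ComplexField(np.abs(field), np.angle(field), system.hr_pixel_size)
    pupil_hr = np.zeros(system.hr_shape, dtype=complex)
    pupil_hr[c0:c0 + m, c0:c0 + m] = pupil
    pupil_out = PupilFunction(system.cutoff_frequency, np.zeros(15), pupil_hr,
                              system.freq_step)
    return recon, pupil_out, residuals
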