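"""Fourier-optics primitives: system geometry, LED illumination wave vectors,
Zernike pupil aberrations and transfer functions.

All spatial frequencies are cycles/m unless a name says otherwise; LED wave
vectors follow the angular-frequency convention k = 2*pi*sin(theta)/lambda
(rad/m).  Image arrays are (row=y, col=x) with a DC-centered frequency grid
matching the package-wide unitary FFT convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalSystem",
    "LEDArrayGeometry",
    "IlluminationSet",
    "PupilFunction",
    "led_positions",
    "led_wavevectors",
    "illumination_na",
    "synthetic_na",
    "zernike_basis",
    "make_pupil",
    "intensity_otf",
    "InvalidConfiguration",
]

N_ZERNIKE_DEFAULT = 15


class InvalidConfiguration(ValueError):
    """Raised for physically impossible optical configurations."""


@dataclass(frozen=True)
class OpticalSystem:
    """Imaging geometry of the microscope.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength in meters.
    objective_na : float
        Numerical aperture of the objective, in (0, 1).
    magnification : float
        Lateral magnification onto the camera.
    camera_pixel_size : float
        Physical camera pixel pitch in meters.
    hr_shape : tuple
        (height, width) of the high-resolution reconstruction grid.
    upsample_factor : int
        Integer ratio between the HR grid and the recorded low-resolution grid.
    """

    wavelength: float
    objective_na: float
    magnification: float
    camera_pixel_size: float
    hr_shape: tuple
    upsample_factor: int = 2

    def __post_init__(self):
        if self.wavelength <= 0:
            raise InvalidConfiguration("wavelength must be positive")
        if not 0 < self.objective_na < 1:
            raise InvalidConfiguration("objective NA must lie in (0, 1)")
        if self.magnification <= 0 or self.camera_pixel_size <= 0:
            raise InvalidConfiguration("magnification and pixel size must be positive")
        if self.upsample_factor < 1:
            raise InvalidConfiguration("upsample_factor must be >= 1")
        h, w = self.hr_shape
        if h != w:
            raise InvalidConfiguration("hr_shape must be square (single frequency step)")
        if h % self.upsample_factor or w % self.upsample_factor:
            raise InvalidConfiguration("hr_shape must be divisible by upsample_factor")
        if self.cutoff_frequency >= self.hr_nyquist:
            raise InvalidConfiguration(
                f"coherent cutoff {self.cutoff_frequency:.3e} 1/m exceeds the HR grid "
                f"Nyquist {self.hr_nyquist:.3e} 1/m")

    @property
    def lr_shape(self) -> tuple:
        return (self.hr_shape[0] // self.upsample_factor,
                self.hr_shape[1] // self.upsample_factor)

    @property
    def hr_pixel_size(self) -> float:
        """Object-plane sampling of the HR grid (m)."""
        return self.camera_pixel_size / self.magnification / self.upsample_factor

    @property
    def lr_pixel_size(self) -> float:
        return self.camera_pixel_size / self.magnification

    @property
    def cutoff_frequency(self) -> float:
        """Coherent cutoff f_c = NA / lambda (cycles/m)."""
        return self.objective_na / self.wavelength

    @property
    def freq_step(self) -> float:
        """Frequency-bin width of the HR (and LR) grid, 1/(N*dx) (cycles/m)."""
        return 1.0 / (self.hr_shape[0] * self.hr_pixel_size)

    @property
    def hr_nyquist(self) -> float:
        return 0.5 / self.hr_pixel_size

    @property
    def pupil_radius_px(self) -> float:
        """Pupil support radius in frequency-grid pixels."""
        return self.cutoff_frequency / self.freq_step

    def frequency_grid(self, shape=None):
        """Centered (f_y, f_x) lattices in cycles/m for ``shape`` (default HR)."""
        h, w = shape if shape is not None else self.hr_shape
        fy = (np.arange(h) - h // 2) * self.freq_step
        fx = (np.arange(w) - w // 2) * self.freq_step
        return np.meshgrid(fy, fx, indexing="ij")


@dataclass(frozen=True)
class LEDArrayGeometry:
    """Planar LED matrix centered under the specimen."""

    rows: int
    cols: int
    pitch: float
    distance: float
    center_offset: tuple = (0.0, 0.0)

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise InvalidConfiguration("LED array needs at least one LED")
        if self.pitch <= 0 or self.distance <= 0:
            raise InvalidConfiguration("pitch and distance must be positive")


@dataclass
class IlluminationSet:
    """Per-LED illumination wave vectors (k_x, k_y) in rad/m, row-major order."""

    wavevectors: np.ndarray  # (N, 2) -> (k_x, k_y)

    def __post_init__(self):
        self.wavevectors = np.asarray(self.wavevectors, dtype=float).reshape(-1, 2)

    def __len__(self):
        return self.wavevectors.shape[0]

    def pixel_shifts(self, system: OpticalSystem):
        """Round each k to the nearest HR frequency bin.

        Returns integer (shift_y, shift_x) per LED plus the sub-bin residual
        in bin units (recorded, not applied — classical FPM convention).
        """
        f = self.wavevectors / (2 * np.pi)  # cycles/m, (f_x, f_y)
        bins = f / system.freq_step
        ints = np.rint(bins).astype(int)
        residual = bins - ints
        shifts = ints[:, ::-1]  # (shift_y, shift_x)
        return shifts, residual[:, ::-1]

    def max_na(self, wavelength: float) -> float:
        knorm = np.hypot(self.wavevectors[:, 0], self.wavevectors[:, 1])
        return float(knorm.max() * wavelength / (2 * np.pi))


def led_positions(geom: LEDArrayGeometry) -> np.ndarray:
    """Lateral LED offsets (d_x, d_y) in meters, row-major (N, 2)."""
    iy, ix = np.meshgrid(np.arange(geom.rows), np.arange(geom.cols), indexing="ij")
    dx = (ix - (geom.cols - 1) / 2.0) * geom.pitch + geom.center_offset[0]
    dy = (iy - (geom.rows - 1) / 2.0) * geom.pitch + geom.center_offset[1]
    return np.stack([dx.ravel(), dy.ravel()], axis=1)


def led_wavevectors(geom: LEDArrayGeometry, system: OpticalSystem) -> IlluminationSet:
    """Illumination wave vectors k = 2*pi*(d_x, d_y) / (lambda*sqrt(d^2 + h^2)).

    The LED at lateral offset (d_x, d_y) a distance h below the specimen
    illuminates at sin(theta) = d / sqrt(d^2 + h^2) along each axis.
    """
    pos = led_positions(geom)
    h = geom.distance
    r = np.sqrt(pos[:, 0] ** 2 + pos[:, 1] ** 2 + h ** 2)
    k = 2 * np.pi * pos / (system.wavelength * r[:, None])
    return IlluminationSet(k)


def illumination_na(geom: LEDArrayGeometry) -> float:
    """NA of the most oblique LED (corner of the array)."""
    pos = led_positions(geom)
    d = np.hypot(pos[:, 0], pos[:, 1]).max()
    return float(d / np.hypot(d, geom.distance))


def synthetic_na(objective_na: float, illum_na: float) -> float:
    """Synthetic aperture NA: objective NA plus peak illumination NA."""
    return objective_na + illum_na


# ---------------------------------------------------------------------------
# Zernike pupil
# ---------------------------------------------------------------------------

def _zernike_noll(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Noll-indexed, Noll-normalized Zernike polynomial j in 1..15."""
    r2 = rho * rho
    table = {
        1: lambda: np.ones_like(rho),
        2: lambda: 2 * rho * np.cos(theta),
        3: lambda: 2 * rho * np.sin(theta),
        4: lambda: np.sqrt(3) * (2 * r2 - 1),
        5: lambda: np.sqrt(6) * r2 * np.sin(2 * theta),
        6: lambda: np.sqrt(6) * r2 * np.cos(2 * theta),
        7: lambda: np.sqrt(8) * (3 * rho * r2 - 2 * rho) * np.sin(theta),
        8: lambda: np.sqrt(8) * (3 * rho * r2 - 2 * rho) * np.cos(theta),
        9: lambda: np.sqrt(8) * rho * r2 * np.sin(3 * theta),
        10: lambda: np.sqrt(8) * rho * r2 * np.cos(3 * theta),
        11: lambda: np.sqrt(5) * (6 * r2 * r2 - 6 * r2 + 1),
        12: lambda: np.sqrt(10) * (4 * r2 * r2 - 3 * r2) * np.cos(2 * theta),
        13: lambda: np.sqrt(10) * (4 * r2 * r2 - 3 * r2) * np.sin(2 * theta),
        14: lambda: np.sqrt(10) * r2 * r2 * np.cos(4 * theta),
        15: lambda: np.sqrt(10) * r2 * r2 * np.sin(4 * theta),
    }
    if j not in table:
        raise ValueError(f"Noll index {j} outside the implemented range 1..15")
    return table[j]()


# Spatial parity of each Noll mode under f -> -f (True = even).  Modes with
# even azimuthal order m (piston, defocus, astigmatism, spherical, quadrafoil)
# have even phase and therefore break Hermitian pupil symmetry when present.
NOLL_EVEN_PARITY = {1: True, 2: False, 3: False, 4: True, 5: True, 6: True,
                    7: False, 8: False, 9: False, 10: False, 11: True,
                    12: True, 13: True, 14: True, 15: True}


def zernike_basis(n_modes: int, fy: np.ndarray, fx: np.ndarray, cutoff: float) -> np.ndarray:
    """Stack of Zernike modes Z_1..Z_n sampled on a frequency lattice.

    rho = |f| / cutoff, theta = atan2(f_y, f_x); modes are zero outside the
    unit disk.  Returns an array of shape (n_modes, H, W).
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    rho = np.hypot(fy, fx) / cutoff
    theta = np.arctan2(fy, fx)
    disk = rho <= 1.0
    basis = np.zeros((n_modes,) + rho.shape)
    for j in range(1, n_modes + 1):
        basis[j - 1] = np.where(disk, _zernike_noll(j, rho, theta), 0.0)
    return basis


@dataclass
class PupilFunction:
    """Band-limited complex pupil P(f) = circ(|f|/f_c) * exp(j sum a_i Z_i)."""

    cutoff: float
    zernike_coeffs: np.ndarray
    array: np.ndarray  # complex samples on the HR frequency lattice
    freq_step: float
    support: np.ndarray = field(default=None)  # boolean disk mask

    def __post_init__(self):
        self.zernike_coeffs = np.asarray(self.zernike_coeffs, dtype=float)
        if self.support is None:
            self.support = np.abs(self.array) > 0

    @property
    def shape(self):
        return self.array.shape

    def lr_crop(self, lr_shape) -> "PupilFunction":
        """Central crop to the LR frequency grid (same frequency step)."""
        h, w = self.array.shape
        oh, ow = lr_shape
        y0, x0 = (h - oh) // 2, (w - ow) // 2
        return PupilFunction(self.cutoff, self.zernike_coeffs,
                             self.array[y0:y0 + oh, x0:x0 + ow].copy(), self.freq_step)


def make_pupil(system: OpticalSystem, coeffs=None, n_modes: int = N_ZERNIKE_DEFAULT) -> PupilFunction:
    """Construct the Zernike-aberrated pupil on the HR frequency lattice.

    With all-zero coefficients this is the binary circular aperture; any
    coefficients only modulate the phase, so |P| <= 1 everywhere and
    |P| = 0 outside the cutoff.
    """
    if coeffs is None:
        coeffs = np.zeros(n_modes)
    coeffs = np.asarray(coeffs, dtype=float)
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("Zernike coefficients must be finite")
    fy, fx = system.frequency_grid()
    fc = system.cutoff_frequency
    disk = np.hypot(fy, fx) <= fc
    basis = zernike_basis(len(coeffs), fy, fx, fc)
    phase = np.tensordot(coeffs, basis, axes=(0, 0))
    array = np.where(disk, np.exp(1j * phase), 0.0)
    return PupilFunction(fc, coeffs, array, system.freq_step, support=disk)


def intensity_otf(pupil: PupilFunction, alpha_mode: str = "incoherent") -> np.ndarray:
    """Transfer function H(f) consistent with the pupil.

    ``coherent`` returns P itself.  ``incoherent`` (the default, appropriate
    for deconvolving an intensity average) returns the normalized pupil
    autocorrelation with H(0) = 1; its support radius is twice the coherent
    cutoff.
    """
    if not np.any(pupil.support):
        raise ValueError("pupil has empty support")
    if alpha_mode == "coherent":
        return pupil.array.copy()
    if alpha_mode != "incoherent":
        raise ValueError(f"unknown transfer-function mode: {alpha_mode!r}")
    p = pupil.array
    # autocorrelation via FFT on a zero-padded grid to avoid circular wrap
    h, w = p.shape
    pad = np.zeros((2 * h, 2 * w), dtype=complex)
    pad[h // 2:h // 2 + h, w // 2:w // 2 + w] = p
    spec = np.fft.fft2(np.fft.ifftshift(pad))
    acorr = np.fft.fftshift(np.fft.ifft2(np.abs(spec) ** 2))
    acorr = acorr[h // 2:h // 2 + h, w // 2:w // 2 + w]
    center = acorr[h // 2, w // 2]
    return acorr / center
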