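"""Procedural tissue phantoms with biologically consistent stain channels.

Each phantom is built from explicit geometry so the cross-channel relations
hold by construction rather than by training:

* DAPI marks nucleus interiors (random non-overlapping disks);
* LAP2 marks the nuclear envelope (an annulus hugging each disk edge);
* panCK marks the epithelial region, excluded from nuclei and envelopes
  with a one-pixel guard gap, so LAP2 and panCK supports are exactly
  disjoint;
* H&E is a stain-intensity map that equals DAPI inside nuclear regions and
  a lighter cytoplasm texture elsewhere, so nuclear consistency between
  DAPI and H&E holds to the anti-aliasing tolerance.

Edges are smoothed with a compact (1-pixel) ramp so sigmoid-output networks
can fit the targets; hard binary targets are a config option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["TissuePhantomSpec", "StainBundle", "generate_bundle", "degrade_bundle",
           "PackingError", "STAIN_CHANNELS"]

STAIN_CHANNELS = ("lap2", "dapi", "panck", "he")


class PackingError(RuntimeError):
    """Raised when the requested cell count cannot be placed."""


@dataclass
class TissuePhantomSpec:
    size: int = 96
    n_cells: int = 10
    nucleus_radius: tuple = (5.0, 9.0)
    envelope_thickness: float = 2.0
    epithelial_fraction: float = 0.45
    texture_noise: float = 0.05
    soft_edges: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.nucleus_radius[0] <= self.envelope_thickness or self.envelope_thickness < 1.0:
            raise ValueError("need radius > envelope thickness >= 1 px")
        if not 0.0 <= self.epithelial_fraction <= 1.0:
            raise ValueError("epithelial_fraction must lie in [0, 1]")


@dataclass
class StainBundle:
    """Co-registered grayscale interface image and four stain maps in [0, 1]."""

    interface: np.ndarray
    lap2: np.ndarray
    dapi: np.ndarray
    panck: np.ndarray
    he: np.ndarray

    def __post_init__(self):
        shapes = {c.shape for c in (self.interface, self.lap2, self.dapi, self.panck, self.he)}
        if len(shapes) != 1:
            raise ValueError("all channels must be co-registered (same shape)")
        for name in ("interface",) + STAIN_CHANNELS:
            arr = getattr(self, name)
            if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
                raise ValueError(f"channel {name} outside [0, 1]")

    @property
    def channels(self) -> np.ndarray:
        """Stacked (4, H, W) target in the canonical LAP2/DAPI/panCK/H&E order."""
        return np.stack([self.lap2, self.dapi, self.panck, self.he], axis=0)

    def he_rgb(self) -> np.ndarray:
        """Display-only two-color render (hematoxylin-/eosin-like tints)."""
        nuc = self.he[..., None] * np.array([0.35, 0.16, 0.55])
        background = (1.0 - self.he[..., None]) * np.array([0.94, 0.75, 0.85])
        return np.clip(nuc + background, 0, 1)


def _ramp(dist: np.ndarray, soft: bool) -> np.ndarray:
    """1 inside (dist<=0), 0 outside (dist>=1), linear ramp between."""
    if not soft:
        return (dist <= 0.0).astype(float)
    return np.clip(1.0 - dist, 0.0, 1.0)


def generate_bundle(spec: TissuePhantomSpec):
    """Build one phantom; returns (StainBundle, geometry metadata)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    yy, xx = np.mgrid[0:n, 0:n].astype(float)

    # epithelial region: thresholded smooth noise occupying ~ the requested fraction
    rough = ndimage.gaussian_filter(rng.standard_normal((n, n)), sigma=n / 8.0)
    if spec.epithelial_fraction >= 1.0:
        epi = np.ones((n, n), bool)
    elif spec.epithelial_fraction <= 0.0:
        epi = np.zeros((n, n), bool)
    else:
        epi = rough >= np.quantile(rough, 1.0 - spec.epithelial_fraction)

    # non-overlapping nuclei; rejection sampling can dead-end (an early
    # central placement may block the rest), so restart a bounded number
    # of times before declaring the packing infeasible
    r_lo, r_hi = spec.nucleus_radius
    margin = spec.envelope_thickness + 2.0
    cells = []
    for restart in range(25):
        cells, tries = [], 0
        while len(cells) < spec.n_cells and tries < 200 * max(spec.n_cells, 1):
            tries += 1
            r = rng.uniform(r_lo, r_hi)
            cy, cx = rng.uniform(r + margin, n - r - margin, size=2)
            if all((cy - oy) ** 2 + (cx - ox) ** 2 >= (r + orad + 2 * margin) ** 2
                   for oy, ox, orad in cells):
                cells.append((cy, cx, r))
        if len(cells) == spec.n_cells:
            break
    else:
        raise PackingError(
            f"could not place {spec.n_cells} nuclei of radius {spec.nucleus_radius} "
            f"in a {n}x{n} field after 25 restarts")

    dapi = np.zeros((n, n))
    lap2 = np.zeros((n, n))
    nucleus_region = np.zeros((n, n), bool)  # nuclei + envelopes + guard
    t = spec.envelope_thickness
    for cy, cx, r in cells:
        d = np.hypot(yy - cy, xx - cx)
        dapi = np.maximum(dapi, _ramp(d - r, spec.soft_edges))
        ring = np.minimum(_ramp(r - d, spec.soft_edges), _ramp(d - (r + t), spec.soft_edges))
        lap2 = np.maximum(lap2, ring)
        nucleus_region |= d <= r + t + 1.0  # one-pixel guard beyond the envelope ramp

    # panCK: epithelium with an exact-zero guard around every envelope
    panck_shape = _ramp(1.0 - ndimage.gaussian_filter(epi.astype(float), 1.0) * 2.0,
                        spec.soft_edges) if spec.soft_edges else epi.astype(float)
    panck = np.where(nucleus_region, 0.0, panck_shape)

    # H&E stain-intensity map: equals DAPI in nuclear regions, lighter
    # cytoplasm texture elsewhere (so Eq-style nuclear consistency holds)
    cyto = 0.25 + 0.15 * epi + spec.texture_noise * rng.standard_normal((n, n))
    cyto = np.clip(ndimage.gaussian_filter(cyto, 1.0), 0.0, 0.45)
    he = np.where(dapi > 0, dapi, cyto)

    interface = (0.30 + 0.40 * dapi + 0.12 * lap2 + 0.10 * panck_shape
                 + spec.texture_noise * ndimage.gaussian_filter(rng.standard_normal((n, n)), 1.0))
    interface = np.clip(interface, 0.0, 1.0)

    bundle = StainBundle(interface=interface, lap2=np.clip(lap2, 0, 1),
                         dapi=np.clip(dapi, 0, 1), panck=np.clip(panck, 0, 1),
                         he=np.clip(he, 0, 1))
    meta = {"cells": cells, "epithelial_fraction": float(epi.mean()), "seed": spec.seed,
            "n_cells": len(cells)}
    return bundle, meta


def degrade_bundle(bundle: StainBundle, system, illum, pupil=None, noise_sd: float = 0.0,
                   seed: int = 0, phase_scale: float = np.pi):
    """FPM-degrade the interface image; stain targets pass through untouched.

    Returns (FPMStack, bundle).  The interface image serves as the HR
    amplitude with the simulator's default amplitude-coupled phase.
    """
    from .optics import make_pupil
    from .simulator import ComplexField, add_noise, simulate_stack

    if bundle.interface.shape != tuple(system.hr_shape):
        raise ValueError(f"interface {bundle.interface.shape} != HR grid {tuple(system.hr_shape)}")
    obj = ComplexField(bundle.interface, phase_scale * bundle.interface,
                       system.hr_pixel_size)
    pupil = pupil if pupil is not None else make_pupil(system)
    stack = simulate_stack(obj, system, pupil, illum, meta={"source": "tissue-phantom"})
    if noise_sd > 0:
        stack = add_noise(stack, noise_sd, seed)
    return stack, bundle
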