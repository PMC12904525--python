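"""Shared fixtures: a small, well-overlapped FPM test bench.

The bench uses a 0.25-NA, 10x system with an LED array whose pupil overlaps
are ~85% (comfortably above the classical 35% recoverability threshold), so
both the iterative and the learned reconstructions are well-posed at test
sizes.
"""

import numpy as np
import pytest

from ptystain.optics import LEDArrayGeometry, OpticalSystem, led_wavevectors, make_pupil
from ptystain.simulator import PhantomSpec, make_phantom, simulate_stack


def make_bench(size=64, leds=5, upsample=2, pitch=3e-3, distance=45e-3,
               phantom="texture", seed=0, coeffs=None, gain=1.0, phase_scale=np.pi):
    """Build (object, system, pupil, illumination, stack) at test scale."""
    system = OpticalSystem(wavelength=520e-9, objective_na=0.25, magnification=10.0,
                           camera_pixel_size=6.5e-6, hr_shape=(size, size),
                           upsample_factor=upsample)
    geom = LEDArrayGeometry(rows=leds, cols=leds, pitch=pitch, distance=distance)
    illum = led_wavevectors(geom, system)
    obj = make_phantom(PhantomSpec(kind=phantom, size=size, seed=seed,
                                   phase_scale=phase_scale))
    obj.pixel_size = system.hr_pixel_size
    pupil = make_pupil(system, coeffs)
    stack = simulate_stack(obj, system, pupil, illum, gain=gain)
    return obj, system, pupil, illum, stack


@pytest.fixture
def bench64():
    return make_bench(size=64, leds=5)


def pearson(a, b):
    a, b = np.ravel(a), np.ravel(b)
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))
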