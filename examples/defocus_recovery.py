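"""Recover an unknown pupil aberration from intensity data alone.

A 0.5-radian defocus (Noll Z4) is injected into the simulated pupil; the
self-supervised reconstruction then has to explain the measured stack with
its own Zernike-parameterized pupil.  The printed coefficient should land
within ~0.1 rad of the injected value, and the gain near 1.
"""

import numpy as np

from ptystain.bip_fpm import BipFpmReconstructor, BipFpmTrainConfig
from ptystain.optics import LEDArrayGeometry, OpticalSystem, led_wavevectors, make_pupil
from ptystain.simulator import PhantomSpec, make_phantom, simulate_stack

system = OpticalSystem(wavelength=520e-9, objective_na=0.25, magnification=10.0,
                       camera_pixel_size=6.5e-6, hr_shape=(96, 96), upsample_factor=2)
illum = led_wavevectors(LEDArrayGeometry(7, 7, 3e-3, 45e-3), system)

coeffs = np.zeros(15)
coeffs[3] = 0.5  # Noll Z4 defocus, radians of pupil phase
phantom = make_phantom(PhantomSpec(kind="texture", size=96, seed=4))
stack = simulate_stack(phantom, system, make_pupil(system, coeffs), illum)

rec = BipFpmReconstructor(system, illum,
                          BipFpmTrainConfig(epochs=300, freeze_epochs=10, seed=0))
pred, _ = rec.train(stack)
print(f"injected defocus  a4 = {coeffs[3]:+.3f} rad")
print(f"recovered defocus a4 = {pred.zernike_coeffs[3]:+.3f} rad")
print(f"recovered gain    s  = {pred.gain:.3f}  (true 1.0)")
print(f"largest spurious coefficient: "
      f"{np.abs(np.delete(pred.zernike_coeffs, 3)).max():.3f} rad")
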