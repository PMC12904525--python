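"""The full pipeline: FPM degradation -> reconstruction -> virtual staining.

A tissue phantom's grayscale render is pushed through the simulated
microscope (multi-LED low-resolution stack), reconstructed by the
self-supervised Stage I, normalized into the interface image, and finally
stained by a generator trained on paired phantoms.  A short joint
fine-tuning pass then optimizes both stages together under the warm-up
weighted combined objective.
"""

import numpy as np

from ptystain.bip_fpm import BipFpmReconstructor, BipFpmTrainConfig, minmax_normalize
from ptystain.evalkit import psnr
from ptystain.optics import LEDArrayGeometry, OpticalSystem, led_wavevectors
from ptystain.stain_net import GeneratorConfig, JointTrainer, StainTrainer
from ptystain.tissue import TissuePhantomSpec, degrade_bundle, generate_bundle

system = OpticalSystem(wavelength=520e-9, objective_na=0.25, magnification=10.0,
                       camera_pixel_size=6.5e-6, hr_shape=(64, 64), upsample_factor=2)
illum = led_wavevectors(LEDArrayGeometry(5, 5, 3e-3, 45e-3), system)

bundles, stacks = [], []
for s in range(4):
    b, _ = generate_bundle(TissuePhantomSpec(size=64, n_cells=6, seed=s))
    stack, _ = degrade_bundle(b, system, illum, noise_sd=5e-5, seed=s)
    bundles.append(b)
    stacks.append(stack)
print(f"degraded {len(bundles)} phantoms into {len(stacks[0])}-LED stacks "
      f"at {stacks[0].lr_shape} pixels")

# Stage I on the first specimen
stage1 = BipFpmReconstructor(system, illum,
                             BipFpmTrainConfig(epochs=80, freeze_epochs=10, seed=0))
pred, _ = stage1.train(stacks[0])
i_int, feats = stage1.export_interface(pred)
print(f"stage I amplitude PSNR vs phantom render: "
      f"{psnr(np.clip(pred.amplitude, 0, 2), bundles[0].interface):5.2f} dB")

# Stage II pre-trained decoupled, then a short joint pass
stain = StainTrainer(GeneratorConfig(base_width=8, seed=0), seed=0, batch_size=4)
stain.fit(bundles, epochs=3)
joint = JointTrainer(stage1, stain)
history = joint.fit(stacks, bundles, epochs=3)
print(f"joint fine-tuning: lambda_s warm-up {history[0].extras['lambda_s']:.2f} -> "
      f"{history[-1].extras['lambda_s']:.2f}")

out = stain.generator.generate(i_int)
print(f"predicted stains from the reconstructed interface image: "
      f"DAPI MAE {np.abs(out.dapi - bundles[0].dapi).mean():.3f}, "
      f"LAP2*panCK overlap {(out.lap2 * out.panck).mean():.4f}")
print("the overlap should be near zero (the two markers are biologically exclusive)")
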