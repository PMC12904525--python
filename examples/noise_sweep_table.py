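"""Noise-robustness table: method x noise-SD grid on the darkfield bench.

The sweep shares one noise realization per phantom scaled by the SD, so
each method's curve is directly comparable across levels.  The classical
solver is the noise-sensitive row (it fits the corrupted darkfield images
exactly); the learned and inverse-filter rows move far less.
"""

from ptystain.evalkit import noise_sweep

result = noise_sweep(methods=("bicubic", "ap-epry", "bip-fpm-psf-only"),
                     noise_levels=(0.0, 0.5e-4, 1.0e-4),
                     n_patches=2, size=48, seed=0)
print(f"{'method':22s}" + "".join(f"  sd={lvl:.1e}" for lvl in result.noise_levels))
for method in result.methods:
    cells = []
    for lvl in result.noise_levels:
        mean, sd = result.stats(method, lvl, "psnr")
        cells.append(f"{mean:5.2f}+-{sd:4.2f}")
    print(f"{method:22s}  " + "  ".join(cells))
print("values are amplitude PSNR (dB) against ground truth, mean +- SD "
      "over the phantom battery")
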