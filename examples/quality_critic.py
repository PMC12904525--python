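"""Train the difference-perception quality critic on synthetic distortions.

Phantom images are blurred, noised and quantized with known severities;
the critic learns an absolute quality score q in [0, 1] and a symmetric
perceptual dissimilarity d >= 0.  The held-out Spearman correlation between
labels and predictions is the headline number (1.0 = perfect ranking).
"""

from ptystain.dp_iqa import train_on_synthetic_distortions, _distort
from ptystain.simulator import PhantomSpec, make_phantom

import numpy as np

corpus = [make_phantom(PhantomSpec(kind=k, size=48, seed=s)).amplitude
          for s in range(30) for k in ("texture", "disks")]
critic, metrics = train_on_synthetic_distortions(corpus, seed=0, epochs=40)
print(f"held-out Spearman(q_label, q_pred) = {metrics['val_spearman_q']:.3f} "
      f"over {metrics['n_val']} images")

img = corpus[0]
rng = np.random.default_rng(1)
for strength in (0.0, 0.4, 0.8):
    distorted = _distort(img, "blur", strength, rng) if strength else img
    qa = critic.assess(distorted, img)
    print(f"blur strength {strength:.1f}: q_main={qa.q_main:.3f}  d_hat={qa.d_hat:.3f}")
print("quality should fall and dissimilarity rise as the blur strengthens")
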