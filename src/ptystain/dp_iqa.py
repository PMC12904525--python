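"""Difference-perception image-quality critic.

Two branches: a main convolutional regression branch producing an absolute
quality score q_main in [0, 1], and a wavelet difference branch that
decomposes both inputs with a two-level Haar DWT, extracts subband-conv
features, fuses the per-scale |feature difference| maps with a multi-scale
asymmetric attention module (MS-AFFM), and regresses a perceptual
dissimilarity d_hat >= 0.  The difference representation is also injected
into the main branch to refine q_main.  Symmetry d(I1, I2) = d(I2, I1)
holds by construction (only absolute feature differences are used).

No opinion-score corpus ships with the package; the critic is trained on
synthetic distortions (blur, noise, quantization) with quality labels
q = 1 - normalized distortion strength, and validated by rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from . import autodiff as ad
from . import nn
from .report import LossReport

__all__ = [
    "QualityAssessment",
    "DPIQAConfig",
    "DPIQACritic",
    "MSAFFM",
    "dpiqa_loss",
    "make_distortion_set",
    "train_on_synthetic_distortions",
]


@dataclass
class QualityAssessment:
    q_main: float
    q_aux: float
    d_hat: float
    f_diff: np.ndarray = None

    def __post_init__(self):
        if not (np.isfinite(self.q_main) and np.isfinite(self.q_aux) and np.isfinite(self.d_hat)):
            raise ValueError("quality scores must be finite")
        if self.d_hat < 0:
            raise ValueError("perceptual dissimilarity must be nonnegative")


@dataclass
class DPIQAConfig:
    lambda1: float = 0.5   # auxiliary-score weight
    lambda2: float = 0.5   # difference-regression weight
    wavelet_levels: int = 2
    width: int = 8         # narrow residual-style encoder (desk preset)
    seed: int = 0

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be nonnegative")


class MSAFFM(nn.Module):
    """Multi-scale asymmetric feature fusion.

    Per scale s: a scalar-vector gate alpha_s = sigmoid(W2 relu(W1 GAP(F_s)))
    in (0, 1) weights the (spatially aligned) features; the fused map is
    sum_s alpha_s * F_s plus a residual of the finest scale.
    """

    def __init__(self, channels: int, n_scales: int, rng: np.random.Generator):
        hidden = max(channels // 2, 2)
        self.gates = [(nn.Linear(channels, hidden, rng), nn.Linear(hidden, channels, rng))
                      for _ in range(n_scales)]

    def forward(self, feats):
        target = feats[0].shape[-2:]  # finest scale
        fused = None
        for (fc1, fc2), f in zip(self.gates, feats):
            while f.shape[-2] < target[0]:
                f = ad.upsample2x(f)
            gap = f.mean(axis=(2, 3))
            gate = ad.sigmoid(fc2(ad.relu(fc1(gap))))
            weighted = f * gate.reshape((f.shape[0], f.shape[1], 1, 1))
            fused = weighted if fused is None else fused + weighted
        return fused + feats[0]


class DPIQACritic(nn.Module):
    """Quality critic; ``assess`` for scoring, ``distance`` as a frozen
    perceptual loss inside the staining objective."""

    def __init__(self, config: DPIQAConfig | None = None):
        cfg = config or DPIQAConfig()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        w = cfg.width
        # main branch
        self.m1 = nn.Conv2d(1, w, 3, stride=2, rng=rng)
        self.m2 = nn.Conv2d(w, 2 * w, 3, stride=2, rng=rng)
        self.m3 = nn.Conv2d(2 * w, 2 * w, 3, rng=rng)
        self.q_head = nn.Linear(4 * w, 1, rng)   # GAP features + injected diff vector
        # difference branch: subband convs per DWT level
        self.wt1 = nn.Conv2d(4, 2 * w, 3, rng=rng)
        self.wt2 = nn.Conv2d(4, 2 * w, 3, rng=rng)
        self.affm = MSAFFM(2 * w, cfg.wavelet_levels, rng)
        self.d_head = nn.Linear(2 * w, 1, rng)
        self.aux_head = nn.Linear(2 * w, 1, rng)

    # -- feature pipelines --------------------------------------------------
    def _wavelet_feats(self, x):
        ll1, lh1, hl1, hh1 = ad.haar_dwt2(x)
        level1 = ad.concat([ll1, lh1, hl1, hh1], axis=1)
        ll2, lh2, hl2, hh2 = ad.haar_dwt2(ll1)
        level2 = ad.concat([ll2, lh2, hl2, hh2], axis=1)
        return [ad.relu(self.wt1(level1)), ad.relu(self.wt2(level2))]

    def _difference_vector(self, x1, x2):
        f1 = self._wavelet_feats(x1)
        f2 = self._wavelet_feats(x2)
        diffs = [ad.tabs(a - b) for a, b in zip(f1, f2)]
        fused = self.affm(diffs)
        return fused.mean(axis=(2, 3)), fused  # (b, 2w), map

    def _main_vector(self, x):
        h = ad.relu(self.m1(x))
        h = ad.relu(self.m2(h))
        h = ad.relu(self.m3(h))
        return h.mean(axis=(2, 3))  # (b, 2w)

    # -- scoring ------------------------------------------------------------
    def forward(self, x1, x2):
        """Tensor pipeline; returns (q_main, q_aux, d_hat, f_diff)."""
        x1, x2 = ad.astensor(x1), ad.astensor(x2)
        if x1.shape != x2.shape:
            raise ValueError(f"inputs disagree: {x1.shape} vs {x2.shape}")
        dvec, dmap = self._difference_vector(x1, x2)
        mvec = self._main_vector(x1)
        q_main = ad.sigmoid(self.q_head(ad.concat([mvec, dvec], axis=1)))
        q_aux = ad.sigmoid(self.aux_head(dvec))
        d_hat = ad.softplus(self.d_head(dvec))
        return q_main, q_aux, d_hat, dmap

    def assess(self, i1: np.ndarray, i2: np.ndarray) -> QualityAssessment:
        a1 = np.asarray(i1, dtype=np.float32)
        a2 = np.asarray(i2, dtype=np.float32)
        if a1.ndim == 2:
            a1, a2 = a1[None, None], a2[None, None]
        with ad.no_grad():
            q_main, q_aux, d_hat, dmap = self.forward(a1, a2)
        return QualityAssessment(float(q_main.data.ravel()[0]),
                                 float(q_aux.data.ravel()[0]),
                                 float(d_hat.data.ravel()[0]),
                                 f_diff=dmap.numpy())

    def distance(self, pred, target):
        """Frozen-critic perceptual distance: d_hat averaged over 3 dyadic
        scales (critic parameters receive no gradient)."""
        pred = ad.astensor(pred)
        target = ad.astensor(target)
        total = None
        p, t = pred, target
        for scale in range(3):
            _, _, d_hat, _ = self.forward(p, t)
            d = d_hat.mean()
            total = d if total is None else total + d
            if scale < 2 and p.shape[-1] >= 16:
                p, t = ad.avg_pool2x(p), ad.avg_pool2x(t)
        return total * (1.0 / 3.0)


def dpiqa_loss(predictions, labels, config: DPIQAConfig | None = None) -> LossReport:
    """L_IQA = L_main + lambda1 L_aux + lambda2 L_diff (all L1 terms).

    ``predictions``: (q_main, q_aux, d_hat) tensors for a batch of pairs;
    ``labels``: dict with ``q1`` (quality of the first image) and ``q2``.
    """
    cfg = config or DPIQAConfig()
    if "q1" not in labels or "q2" not in labels:
        raise KeyError("labels must provide q1 and q2")
    q_main, q_aux, d_hat = predictions
    q1 = np.asarray(labels["q1"], dtype=float).reshape(-1, 1)
    q2 = np.asarray(labels["q2"], dtype=float).reshape(-1, 1)
    l_main = ad.tabs(q_main - ad.Tensor(q1)).mean()
    l_aux = ad.tabs(q_aux - ad.Tensor(q1)).mean()
    l_diff = ad.tabs(d_hat - ad.Tensor(np.abs(q1 - q2))).mean()
    total = l_main + cfg.lambda1 * l_aux + cfg.lambda2 * l_diff
    report = LossReport()
    report.add("l_main", l_main.item(), 1.0)
    report.add("l_aux", l_aux.item(), cfg.lambda1)
    report.add("l_diff", l_diff.item(), cfg.lambda2)
    report.extras["total_tensor"] = total
    return report


# ---------------------------------------------------------------------------
# synthetic distortion corpus
# ---------------------------------------------------------------------------

def _distort(img: np.ndarray, kind: str, strength: float, rng: np.random.Generator):
    """strength in [0, 1]; quality label is 1 - strength.

    Parameter maps are calibrated so equal strength produces comparable RMS
    impact across families (otherwise cross-family quality ranks are
    ill-posed): blur sigma up to ~1.2, noise SD up to 0.1, quantization
    down to a handful of gray levels.
    """
    if kind == "blur":
        return ndimage.gaussian_filter(img, sigma=1.2 * strength ** 2)
    if kind == "noise":
        return np.clip(img + 0.1 * strength * rng.standard_normal(img.shape), 0, 1)
    if kind == "quantize":
        levels = max(2, int(round(2.0 ** (8.0 - 7.0 * strength))))
        return np.round(img * (levels - 1)) / (levels - 1)
    raise ValueError(f"unknown distortion {kind!r}")


def make_distortion_set(corpus, seed: int, n_strengths: int = 3):
    """Distorted variants with labels q = 1 - normalized strength.

    Strengths are drawn uniformly (seeded) rather than gridded, giving
    continuous quality labels and tie-free rank statistics.
    """
    rng = np.random.default_rng(seed)
    samples = []  # (image, q)
    for img in corpus:
        img = np.asarray(img, dtype=np.float32)
        samples.append((img, 1.0))
        for kind in ("blur", "noise", "quantize"):
            for strength in sorted(rng.uniform(0.1, 1.0, n_strengths)):
                samples.append((_distort(img, kind, float(strength), rng).astype(np.float32),
                                1.0 - float(strength)))
    return samples


def train_on_synthetic_distortions(corpus, seed: int = 0, epochs: int = 40,
                                   batch_size: int = 16, lr: float = 3e-3,
                                   config: DPIQAConfig | None = None):
    """Train the critic on a grayscale corpus; returns (critic, metrics).

    Pairs are (distorted, pristine) views of the same base image, so d_hat
    learns |q1 - q2| = distortion strength.  Validation reports the held-out
    Spearman rank correlation between labels and q_main.
    """
    corpus = [np.asarray(c, dtype=np.float32) for c in corpus]
    if len(corpus) < 50:
        raise ValueError(f"corpus too small: {len(corpus)} images (need >= 50)")
    cfg = config or DPIQAConfig(seed=seed)
    rng = np.random.default_rng(seed)
    n_val = max(len(corpus) // 5, 5)
    order = rng.permutation(len(corpus))
    val_base = [corpus[i] for i in order[:n_val]]
    train_base = [corpus[i] for i in order[n_val:]]
    train_set = make_distortion_set(train_base, seed + 1)
    val_set = make_distortion_set(val_base, seed + 2)
    critic = DPIQACritic(cfg)
    opt = nn.Adam(critic.parameters(), lr=lr)

    imgs = np.stack([s[0] for s in train_set])[:, None]
    qs = np.array([s[1] for s in train_set])
    n_per = 1 + 3 * 3  # variants per base image
    base_idx = np.arange(len(train_set)) // n_per * n_per  # pristine partner
    for epoch in range(epochs):
        perm = rng.permutation(len(train_set))
        for start in range(0, len(perm), batch_size):
            idx = perm[start:start + batch_size]
            x1 = ad.Tensor(imgs[idx])
            x2 = ad.Tensor(imgs[base_idx[idx]])
            opt.zero_grad()
            q_main, q_aux, d_hat, _ = critic.forward(x1, x2)
            rep = dpiqa_loss((q_main, q_aux, d_hat),
                             {"q1": qs[idx], "q2": qs[base_idx[idx]]}, cfg)
            rep.extras["total_tensor"].backward()
            opt.step()

    # held-out monotonicity
    vi = np.stack([s[0] for s in val_set])[:, None]
    vq = np.array([s[1] for s in val_set])
    vbase = np.arange(len(val_set)) // n_per * n_per
    with ad.no_grad():
        q_pred, _, _, _ = critic.forward(ad.Tensor(vi), ad.Tensor(vi[vbase]))
    rho = stats.spearmanr(vq, q_pred.data.ravel()).statistic
    metrics = {"val_spearman_q": float(rho), "n_train": len(train_set), "n_val": len(val_set)}
    return critic, metrics
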