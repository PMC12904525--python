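"""Multi-task virtual staining (Stage II).

A shared encoder-fusion-decoder generator maps the Stage-I interface image
to four stain channels (LAP2, DAPI, panCK, H&E).  The encoder runs a
spatial branch (its own features, or projected Stage-I encoder features)
next to a wavelet-subband convolution branch; the two are merged by a
difference-aware fusion block that is an exact identity at initialization.
The decoder upsamples with squeeze-excitation gating and skip connections.
Each channel has an independent 70x70 PatchGAN discriminator trained with
the least-squares GAN objective; cross-task structural constraints couple
the channels (nuclear DAPI/H&E consistency, LAP2/panCK exclusivity, and a
DAPI-anchored attention alignment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .report import LossReport
from .tissue import STAIN_CHANNELS, StainBundle  # canonical channel order

__all__ = [
    "StainBundle",
    "STAIN_CHANNELS",
    "CrossTaskWeights",
    "StainObjectiveWeights",
    "GeneratorConfig",
    "MultiStainGenerator",
    "PatchDiscriminator",
    "FSFF",
    "adversarial_losses",
    "cross_task_losses",
    "stain_objective",
    "lambda_s_schedule",
    "soft_attention_pool",
    "StainTrainer",
    "JointTrainer",
]


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

@dataclass
class CrossTaskWeights:
    alpha: float = 1.0   # nuclear DAPI/H&E consistency
    beta: float = 0.5    # LAP2/panCK exclusivity
    gamma: float = 0.2   # relative attention alignment
    tau: float = 0.5     # nuclear-mask threshold on predicted DAPI

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("cross-task weights must be nonnegative")
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")


@dataclass
class StainObjectiveWeights:
    lambda1: float = 10.0   # per-channel L1
    lambda2: float = 0.2    # per-channel perceptual critic
    lambda3: float = 1.0    # cross-task constraint
    lambda_s: float = 0.5   # staining weight in the joint objective
    warmup_start: float = 0.1
    warmup_epochs: int = 10

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda3, self.lambda_s) < 0:
            raise ValueError("objective weights must be nonnegative")
        if self.warmup_start > self.lambda_s:
            raise ValueError("warm-up must start at or below lambda_s")


def lambda_s_schedule(epoch: int, weights: StainObjectiveWeights | None = None) -> float:
    """Linear warm-up of the staining weight over the first warmup_epochs."""
    w = weights or StainObjectiveWeights()
    if w.warmup_epochs == 0:
        return w.lambda_s
    frac = min(max(epoch, 0) / w.warmup_epochs, 1.0)
    return w.warmup_start + (w.lambda_s - w.warmup_start) * frac


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class FSFF(nn.Module):
    """Frequency-spatial feature fusion via difference-aware attention.

    F_out = Conv3x3( DA(|F_s - F_f|) ) + F_s, with the final convolution
    zero-initialized so the block is the identity mapping at initialization.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        self.gate1 = nn.Conv2d(channels, channels, 1, rng=rng)
        self.gate2 = nn.Conv2d(channels, channels, 1, rng=rng)
        self.out = nn.Conv2d(channels, channels, 3, zero_init=True)

    def forward(self, f_s, f_f):
        if f_s.shape != f_f.shape:
            raise ValueError(f"FS-FF inputs disagree: {f_s.shape} vs {f_f.shape}")
        diff = ad.tabs(f_s - f_f)
        attended = diff * ad.sigmoid(self.gate2(ad.relu(self.gate1(diff))))
        return self.out(attended) + f_s


class PatchDiscriminator(nn.Module):
    """70x70-receptive-field PatchGAN over (input, candidate) pairs.

    Four stride-2/stride-1 4x4 convolutions produce a patch map; each unit
    sees a 70x70 window of the input (standard conv arithmetic).
    """

    def __init__(self, c_in: int, rng: np.random.Generator, width: int = 16,
                 use_norm: bool = True):
        w = width
        self.c1 = nn.Conv2d(c_in, w, 4, stride=2, padding=1, rng=rng)
        self.c2 = nn.Conv2d(w, 2 * w, 4, stride=2, padding=1, rng=rng, bias=False)
        self.n2 = nn.InstanceNorm2d(2 * w) if use_norm else None
        self.c3 = nn.Conv2d(2 * w, 4 * w, 4, stride=2, padding=1, rng=rng, bias=False)
        self.n3 = nn.InstanceNorm2d(4 * w) if use_norm else None
        self.c4 = nn.Conv2d(4 * w, 8 * w, 4, stride=1, padding=1, rng=rng, bias=False)
        self.n4 = nn.InstanceNorm2d(8 * w) if use_norm else None
        self.head = nn.Conv2d(8 * w, 1, 4, stride=1, padding=1, rng=rng)

    def forward(self, x):
        norm = lambda n, t: n(t) if n is not None else t  # noqa: E731
        h = ad.leaky_relu(self.c1(x), 0.2)
        h = ad.leaky_relu(norm(self.n2, self.c2(h)), 0.2)
        h = ad.leaky_relu(norm(self.n3, self.c3(h)), 0.2)
        h = ad.leaky_relu(norm(self.n4, self.c4(h)), 0.2)
        return self.head(h)


@dataclass
class GeneratorConfig:
    base_width: int = 16
    use_bip_features: bool = False
    use_wtconv: bool = True       # off -> plain conv branch (w/o WTConv ablation)
    use_fsff: bool = True         # off -> spatial features pass straight through
    use_se: bool = True           # off -> no channel recalibration
    n_channels_out: int = 4
    seed: int = 0


class MultiStainGenerator(nn.Module):
    """Shared-encoder multi-stain generator with dual-branch bottleneck."""

    def __init__(self, config: GeneratorConfig | None = None,
                 feature_channels: tuple | None = None):
        cfg = config or GeneratorConfig()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        w = cfg.base_width
        self.stem = nn.Conv2d(1, w, 3, rng=rng)
        self.down1 = nn.Conv2d(w, 2 * w, 3, stride=2, rng=rng, bias=False)
        self.nd1 = nn.InstanceNorm2d(2 * w)
        self.down2 = nn.Conv2d(2 * w, 4 * w, 3, stride=2, rng=rng, bias=False)
        self.nd2 = nn.InstanceNorm2d(4 * w)
        if cfg.use_wtconv:
            self.freq = nn.WTConvBlock(4 * w, rng)
        else:
            self.freq = nn.Conv2d(4 * w, 4 * w, 3, rng=rng)
        if cfg.use_bip_features:
            if feature_channels is None:
                raise ValueError("feature_channels required when the Stage-I branch is enabled")
            self.proj = [nn.Conv2d(c, 4 * w, 1, rng=rng) for c in feature_channels]
        self.fuse = FSFF(4 * w, rng) if cfg.use_fsff else None
        self.up1 = nn.ConvTranspose2d(4 * w, 2 * w, rng)
        self.se1 = nn.SEBlock(2 * w, rng, reduction=np.gcd(8, 2 * w)) if cfg.use_se else None
        self.dec1 = nn.Conv2d(4 * w, 2 * w, 3, rng=rng)
        self.up2 = nn.ConvTranspose2d(2 * w, w, rng)
        self.se2 = nn.SEBlock(w, rng, reduction=np.gcd(8, w)) if cfg.use_se else None
        self.dec2 = nn.Conv2d(2 * w, w, 3, rng=rng)
        self.head = nn.Conv2d(w, cfg.n_channels_out, 3, rng=rng)

    def _spatial_branch(self, bottleneck, features):
        if not self.config.use_bip_features:
            return bottleneck
        if features is None:
            raise ValueError("generator configured with the Stage-I feature branch "
                             "but no features were provided")
        target_h = bottleneck.shape[-2]
        projected = None
        for proj, feat in zip(self.proj, features):
            if isinstance(feat, ad.Tensor):
                f = feat  # live Stage-I graph (joint training)
            else:
                f = ad.Tensor(np.asarray(feat, dtype=np.float32))
            if f.ndim == 3:
                f = f.reshape((1,) + tuple(f.shape))
            while f.shape[-2] > target_h:
                f = ad.avg_pool2x(f)
            while f.shape[-2] < target_h:
                f = ad.upsample2x(f)
            p = proj(f)
            projected = p if projected is None else projected + p
        return projected + bottleneck

    def forward(self, i_int, features=None):
        x = ad.astensor(i_int)
        if x.ndim == 2:
            x = x.reshape((1, 1) + tuple(x.shape))
        f1 = ad.relu(self.stem(x))
        f2 = ad.leaky_relu(self.nd1(self.down1(f1)), 0.2)
        h = ad.leaky_relu(self.nd2(self.down2(f2)), 0.2)
        spatial = self._spatial_branch(h, features)
        freq = self.freq(h)
        if self.fuse is not None:
            h = self.fuse(spatial, freq)
        else:
            h = spatial
        u = ad.relu(self.up1(h))
        if self.se1 is not None:
            u = self.se1(u)
        u = ad.relu(self.dec1(ad.concat([u, f2], axis=1)))
        u = ad.relu(self.up2(u))
        if self.se2 is not None:
            u = self.se2(u)
        u = ad.relu(self.dec2(ad.concat([u, f1], axis=1)))
        return ad.sigmoid(self.head(u))

    def generate(self, i_int: np.ndarray, features=None) -> StainBundle:
        """Predict a StainBundle from an interface image in [0, 1]."""
        with ad.no_grad():
            out = self.forward(i_int.astype(np.float32), features).numpy()[0]
        return StainBundle(interface=np.asarray(i_int, dtype=float),
                           lap2=out[0].astype(float), dapi=out[1].astype(float),
                           panck=out[2].astype(float), he=out[3].astype(float))


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def adversarial_losses(d_fake, d_real=None):
    """LSGAN terms from discriminator patch maps (labels: real 1, fake 0).

    Returns a LossReport with ``g_gan`` (generator side, D(fake) vs 1) and,
    when ``d_real`` is given, ``d_loss`` = 0.5 [ (D(real)-1)^2 + D(fake)^2 ].
    """
    report = LossReport()
    g = ad.abs2(d_fake - 1.0).mean()
    report.add("g_gan", g.item())
    report.extras["g_gan_tensor"] = g
    if d_real is not None:
        d = (ad.abs2(d_real - 1.0).mean() + ad.abs2(d_fake).mean()) * 0.5
        report.add("d_loss", d.item())
        report.extras["d_loss_tensor"] = d
    return report


def soft_attention_pool(x):
    """Per-map attention: |values| normalized to sum 1 (deterministic)."""
    mag = ad.tabs(x)
    total = mag.sum()
    denom = float(total.data) if isinstance(total, ad.Tensor) else float(total)
    if denom < 1e-12:
        return mag * 0.0
    return mag * (1.0 / denom)


def cross_task_losses(pred, weights: CrossTaskWeights | None = None) -> LossReport:
    """Biological structure constraints across predicted channels.

    ``pred``: dict name -> Tensor/array in [0, 1] (keys: lap2, dapi, panck, he).
    """
    w = weights or CrossTaskWeights()
    t = {k: ad.astensor(v) for k, v in pred.items()}
    dapi, he, lap2, panck = t["dapi"], t["he"], t["lap2"], t["panck"]

    mask = (dapi.data > w.tau).astype(float)  # constant: no gradient through the threshold
    n_nuc = mask.sum()
    if n_nuc == 0:
        warnings.warn("empty nuclear mask: consistency loss defined as 0", stacklevel=2)
        l_cons = ad.Tensor(np.array(0.0))
    else:
        l_cons = (ad.abs2(dapi - he) * ad.Tensor(mask)).sum() * (1.0 / n_nuc)

    l_excl = (lap2 * panck).mean()

    l_rel_terms = []
    anchor = soft_attention_pool(dapi)
    for target in (lap2, panck):
        l_rel_terms.append(ad.tabs(anchor - soft_attention_pool(target)).sum())
    l_rel = (l_rel_terms[0] + l_rel_terms[1]) * 0.5

    total = w.alpha * l_cons + w.beta * l_excl + w.gamma * l_rel
    report = LossReport()
    report.add("consistency", l_cons.item(), w.alpha)
    report.add("exclusive", l_excl.item(), w.beta)
    report.add("relative", l_rel.item(), w.gamma)
    report.extras["total_tensor"] = total
    return report


def stain_objective(per_channel: dict, cross_report: LossReport,
                    weights: StainObjectiveWeights | None = None) -> LossReport:
    """Full staining objective.

    ``per_channel``: name -> dict with keys ``gan``, ``l1`` and optionally
    ``iqa`` (floats or scalar Tensors).  Missing terms raise, naming the
    channel.  Total = sum_c (gan + lambda1 l1 + lambda2 iqa) + lambda3 cross.
    """
    w = weights or StainObjectiveWeights()
    report = LossReport()
    tensors = []

    def val(x):
        return x if isinstance(x, ad.Tensor) else ad.Tensor(np.array(float(x)))

    for name in STAIN_CHANNELS:
        if name not in per_channel:
            raise KeyError(f"missing loss components for channel {name!r}")
        comp = per_channel[name]
        for key in ("gan", "l1"):
            if key not in comp:
                raise KeyError(f"missing {key!r} loss for channel {name!r}")
        gan, l1 = val(comp["gan"]), val(comp["l1"])
        iqa = val(comp.get("iqa", 0.0))
        report.add(f"{name}_gan", gan.item(), 1.0)
        report.add(f"{name}_l1", l1.item(), w.lambda1)
        report.add(f"{name}_iqa", iqa.item(), w.lambda2)
        tensors.append(gan + w.lambda1 * l1 + w.lambda2 * iqa)
    cross_total = cross_report.extras.get("total_tensor")
    if cross_total is None:
        cross_total = ad.Tensor(np.array(cross_report.total))
    report.add("cross_task", cross_report.total, w.lambda3)
    total = tensors[0]
    for t in tensors[1:]:
        total = total + t
    total = total + w.lambda3 * cross_total
    report.extras["total_tensor"] = total
    report.extras["cross_report"] = cross_report
    return report


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _augment(x: np.ndarray, targets: np.ndarray, rng: np.random.Generator):
    """Random flips, 90-degree rotations, brightness jitter (input only)."""
    k = rng.integers(4)
    if k:
        x = np.rot90(x, k, axes=(-2, -1))
        targets = np.rot90(targets, k, axes=(-2, -1))
    if rng.random() < 0.5:
        x = x[..., ::-1]
        targets = targets[..., ::-1]
    if rng.random() < 0.5:
        x = x[..., ::-1, :]
        targets = targets[..., ::-1, :]
    x = np.clip(x * rng.uniform(0.9, 1.1) + rng.uniform(-0.05, 0.05), 0.0, 1.0)
    return np.ascontiguousarray(x), np.ascontiguousarray(targets)


class StainTrainer:
    """Paired-supervised GAN training of the staining generator.

    ``critic`` is an optional frozen perceptual critic exposing
    ``distance(pred, target) -> Tensor`` (see :mod:`ptystain.dp_iqa`);
    without it the perceptual term is zero ("w/o DP Net" configuration).
    """

    def __init__(self, gen_config: GeneratorConfig | None = None,
                 objective: StainObjectiveWeights | None = None,
                 cross: CrossTaskWeights | None = None,
                 critic=None, lr: float = 1e-4, batch_size: int = 8,
                 disc_width: int = 8, seed: int = 0,
                 feature_channels: tuple | None = None):
        self.gen_config = gen_config or GeneratorConfig(seed=seed)
        self.objective = objective or StainObjectiveWeights()
        self.cross = cross or CrossTaskWeights()
        self.critic = critic
        self.batch_size = batch_size
        self.rng = np.random.default_rng(seed)
        self.generator = MultiStainGenerator(self.gen_config, feature_channels)
        drng = np.random.default_rng(seed + 1)
        self.discriminators = {name: PatchDiscriminator(2, drng, width=disc_width)
                               for name in STAIN_CHANNELS}
        self.g_opt = nn.Adam(self.generator.parameters(), lr=lr)
        self.d_opts = {name: nn.Adam(d.parameters(), lr=lr)
                       for name, d in self.discriminators.items()}

    # -- one optimization step on a batch ----------------------------------
    def step(self, inputs: np.ndarray, targets: np.ndarray, augment: bool = True):
        """inputs (B,1,H,W), targets (B,4,H,W); returns a LossReport."""
        if augment:
            inputs, targets = _augment(inputs, targets, self.rng)
        x = ad.Tensor(inputs.astype(np.float32))
        y = targets.astype(np.float32)

        # one generator forward serves the discriminator updates (detached)
        # and the generator update (through the freshly updated critics)
        fake = self.generator.forward(x)
        fake_const = fake.data
        for ci, name in enumerate(STAIN_CHANNELS):
            d = self.discriminators[name]
            self.d_opts[name].zero_grad()
            pair_real = np.concatenate([inputs.astype(np.float32), y[:, ci:ci + 1]], axis=1)
            pair_fake = np.concatenate([inputs.astype(np.float32), fake_const[:, ci:ci + 1]], axis=1)
            rep = adversarial_losses(d(ad.Tensor(pair_fake)), d(ad.Tensor(pair_real)))
            rep.extras["d_loss_tensor"].backward()
            self.d_opts[name].step()

        # generator update
        self.g_opt.zero_grad()
        per_channel = {}
        pred_maps = {}
        for ci, name in enumerate(STAIN_CHANNELS):
            pf = fake[:, ci:ci + 1]
            pred_maps[name] = pf
            pair = ad.concat([x, pf], axis=1)
            g_gan = ad.abs2(self.discriminators[name](pair) - 1.0).mean()
            l1 = ad.tabs(pf - ad.Tensor(y[:, ci:ci + 1])).mean()
            comp = {"gan": g_gan, "l1": l1}
            if self.critic is not None:
                comp["iqa"] = self.critic.distance(pf, ad.Tensor(y[:, ci:ci + 1]))
            per_channel[name] = comp
        cross = cross_task_losses(pred_maps, self.cross)
        report = stain_objective(per_channel, cross, self.objective)
        report.extras["total_tensor"].backward()
        self.g_opt.step()
        return report

    def fit(self, bundles: list, epochs: int = 30, augment: bool = True,
            log_every: int = 0):
        """Train on a list of StainBundle; returns per-epoch mean totals."""
        inputs = np.stack([b.interface for b in bundles])[:, None]
        targets = np.stack([b.channels for b in bundles])
        n = len(bundles)
        history = []
        for epoch in range(epochs):
            order = self.rng.permutation(n)
            totals = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                rep = self.step(inputs[idx], targets[idx], augment=augment)
                totals.append(rep.total)
            history.append(float(np.mean(totals)))
        return history


class JointTrainer:
    """End-to-end optimization of Stage I + Stage II on paired data.

    One shared reconstruction network amortizes over the FPM stacks; the
    staining generator consumes the differentiable interface image (and,
    when configured, live Stage-I encoder features).  The total objective
    is L_stage1 + lambda_s(t) * L_stain with the linear lambda_s warm-up;
    the staining part here uses the pixel, perceptual and cross-task terms
    (the adversarial critics train in the decoupled phase).
    """

    def __init__(self, stage1, stain: StainTrainer,
                 objective: StainObjectiveWeights | None = None):
        from . import nn as _nn
        self.stage1 = stage1
        self.stain = stain
        self.objective = objective or stain.objective
        cfg = stage1.config
        self.s1_opt = _nn.Adam(stage1.net.parameters(), lr=cfg.learning_rate)
        self.s1_optical = _nn.Adam([stage1.coeffs, stage1.log_gain], lr=cfg.optical_lr)

    def fit(self, stacks: list, bundles: list, epochs: int = 5):
        """Returns per-epoch LossReport list; raises on unpaired samples."""
        from .bip_fpm import minmax_normalize
        if len(stacks) != len(bundles):
            raise ValueError(f"paired mode needs matching counts: "
                             f"{len(stacks)} stacks vs {len(bundles)} bundles")
        gen = self.stain.generator
        history = []
        for epoch in range(epochs):
            lam = lambda_s_schedule(epoch, self.objective)
            epoch_report = LossReport()
            for stack, bundle in zip(stacks, bundles):
                self.s1_opt.zero_grad()
                self.s1_optical.zero_grad()
                self.stain.g_opt.zero_grad()
                amp, phase, feats = self.stage1._predict_tensors(stack)
                total1, rep1 = self.stage1.compute_losses(
                    stack, (amp, phase, self.stage1.pupil_tensor(), self.stage1.gain_tensor()))
                i_int = minmax_normalize(amp).reshape((1, 1) + tuple(amp.shape))
                fake = gen.forward(i_int, feats if gen.config.use_bip_features else None)
                target = ad.Tensor(bundle.channels[None].astype(np.float32))
                l1 = ad.tabs(fake - target).mean()
                pred_maps = {name: fake[:, ci:ci + 1]
                             for ci, name in enumerate(STAIN_CHANNELS)}
                cross = cross_task_losses(pred_maps, self.stain.cross)
                l_stain = self.objective.lambda1 * l1 \
                    + self.objective.lambda3 * cross.extras["total_tensor"]
                if self.stain.critic is not None:
                    l_stain = l_stain + self.objective.lambda2 * self.stain.critic.distance(
                        fake, target)
                total = total1 + lam * l_stain
                total.backward()
                if self.stage1.coeffs.grad is not None:
                    self.stage1.coeffs.grad = self.stage1.coeffs.grad * self.stage1._piston_mask
                self.s1_opt.step()
                self.s1_optical.step()
                self.stain.g_opt.step()
                epoch_report.add(f"sample_{len(epoch_report.terms)}", total.item())
            epoch_report.extras["lambda_s"] = lam
            history.append(epoch_report)
        return history
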