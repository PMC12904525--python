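"""Evaluation: image metrics, the noise-robustness sweep, line profiles and
the staining ablation harness.

Metric conventions: MAE is the plain mean absolute difference; PSNR is
10 log10(range^2 / MSE), capped at 99 dB for exact matches; SSIM uses the
standard 11x11 Gaussian window (sigma 1.5) with K1 = 0.01, K2 = 0.03.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage.transform import resize

from .bip_fpm import BipFpmLossWeights, BipFpmReconstructor, BipFpmTrainConfig, wiener_deconvolve
from .classical import APConfig, ap_epry_reconstruct
from .optics import LEDArrayGeometry, OpticalSystem, intensity_otf, led_wavevectors, make_pupil
from .simulator import BABOON_NOISE_LEVELS, PhantomSpec, add_noise, make_phantom, simulate_stack
from .stain_net import GeneratorConfig, MultiStainGenerator, StainTrainer
from .tissue import STAIN_CHANNELS

__all__ = [
    "image_metrics",
    "ssim",
    "psnr",
    "SweepResult",
    "noise_sweep",
    "SWEEP_METHODS",
    "line_profile",
    "ablation_harness",
    "ABLATION_VARIANTS",
]

PSNR_CAP = 99.0


def psnr(x: np.ndarray, y: np.ndarray, data_range: float = 1.0) -> float:
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    mse = ((x - y) ** 2).mean()
    if mse == 0:
        return PSNR_CAP
    return min(10.0 * np.log10(data_range ** 2 / mse), PSNR_CAP)


def ssim(x: np.ndarray, y: np.ndarray, data_range: float = 1.0,
         sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity with a Gaussian window (truncate 3.5)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    blur = lambda a: ndimage.gaussian_filter(a, sigma, truncate=3.5)  # noqa: E731
    mx, my = blur(x), blur(y)
    mxx, myy, mxy = blur(x * x), blur(y * y), blur(x * y)
    vx = mxx - mx * mx
    vy = myy - my * my
    cxy = mxy - mx * my
    num = (2 * mx * my + c1) * (2 * cxy + c2)
    den = (mx * mx + my * my + c1) * (vx + vy + c2)
    # crop the filter-radius boundary, as the reference implementation does
    pad = int(3.5 * sigma + 0.5)
    return float((num / den)[pad:-pad, pad:-pad].mean())


def image_metrics(x: np.ndarray, y: np.ndarray, data_range: float = 1.0) -> dict:
    """(MAE, PSNR, SSIM) of a prediction x against a reference y."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return {
        "mae": float(np.abs(x - y).mean()),
        "psnr": psnr(x, y, data_range),
        "ssim": ssim(x, y, data_range),
    }


# ---------------------------------------------------------------------------
# noise sweep
# ---------------------------------------------------------------------------

SWEEP_METHODS = ("bicubic", "ap-epry", "bip-fpm", "bip-fpm-psf-only", "bip-fpm-pbnn-only")


@dataclass
class SweepResult:
    """Per (method, noise level): mean +- SD over the phantom battery."""

    noise_levels: tuple
    methods: tuple
    values: dict = field(default_factory=dict)   # (method, level) -> {metric: [per-patch]}
    n: int = 0
    seeds: tuple = ()

    def stats(self, method: str, level: float, metric: str):
        vals = np.asarray(self.values[(method, level)][metric])
        return float(vals.mean()), float(vals.std(ddof=1))

    def mean_curve(self, method: str, metric: str):
        return [self.stats(method, level, metric)[0] for level in self.noise_levels]

    def as_table(self, metric: str = "psnr") -> dict:
        return {m: {lvl: self.stats(m, lvl, metric) for lvl in self.noise_levels}
                for m in self.methods}


def _sweep_bench(size: int, seed: int):
    """Darkfield-heavy bench echoing the printed protocol's character:
    illumination NA extends well beyond the objective NA, so the printed
    noise SDs measurably corrupt the dim darkfield images."""
    system = OpticalSystem(wavelength=520e-9, objective_na=0.25, magnification=10.0,
                           camera_pixel_size=6.5e-6, hr_shape=(size, size), upsample_factor=2)
    geom = LEDArrayGeometry(rows=5, cols=5, pitch=10e-3, distance=45e-3)
    illum = led_wavevectors(geom, system)
    obj = make_phantom(PhantomSpec(kind="texture", size=size, seed=seed))
    pupil = make_pupil(system)
    stack = simulate_stack(obj, system, pupil, illum)
    return obj, system, illum, stack


def _reconstruct(method: str, noisy, system, illum, epochs: int, width: int, seed: int):
    if method == "bicubic":
        return resize(np.sqrt(noisy.images.mean(axis=0)), system.hr_shape, order=3,
                      anti_aliasing=False)
    if method == "ap-epry":
        recon, _, _ = ap_epry_reconstruct(noisy, system, APConfig(n_iterations=20))
        return np.clip(recon.amplitude, 0, None)
    if method == "bip-fpm-psf-only":
        h = intensity_otf(make_pupil(system), "incoherent")
        i_avg = resize(noisy.images.mean(axis=0), system.hr_shape, order=3,
                       anti_aliasing=False)
        u = wiener_deconvolve(i_avg, h, 1e-3)
        return np.sqrt(np.clip(np.abs(u), 0, None))
    if method in ("bip-fpm", "bip-fpm-pbnn-only"):
        weights = BipFpmLossWeights() if method == "bip-fpm" else BipFpmLossWeights(lambda_d=0.0)
        rec = BipFpmReconstructor(
            system, illum,
            BipFpmTrainConfig(epochs=epochs, freeze_epochs=min(10, epochs - 1),
                              seed=seed, base_width=width),
            weights)
        pred, _ = rec.train(noisy)
        return np.clip(pred.amplitude, 0, None)
    raise ValueError(f"unknown method {method!r}")


def noise_sweep(methods=SWEEP_METHODS, noise_levels=BABOON_NOISE_LEVELS,
                n_patches: int = 3, size: int = 64, epochs: int = 120,
                width: int = 16, seed: int = 0) -> SweepResult:
    """Reconstruction quality of each method across the printed noise grid.

    Each phantom shares one noise realization scaled by the SD
    (common random numbers), so curves are directly comparable across
    levels.  ``n_patches`` >= 2 is required for a defined SD.
    """
    if n_patches < 2:
        raise ValueError("n_patches must be >= 2 for a defined standard deviation")
    for m in methods:
        if m not in SWEEP_METHODS:
            raise ValueError(f"unknown method {m!r}")
    result = SweepResult(noise_levels=tuple(noise_levels), methods=tuple(methods),
                         n=n_patches, seeds=tuple(seed + i for i in range(n_patches)))
    for i in range(n_patches):
        obj, system, illum, clean = _sweep_bench(size, seed + i)
        for level in noise_levels:
            noisy = add_noise(clean, float(level), seed=seed + 1000 + i)
            for method in methods:
                amp = _reconstruct(method, noisy, system, illum, epochs, width, seed)
                metrics = image_metrics(np.clip(amp, 0, 1), obj.amplitude)
                slot = result.values.setdefault((method, level),
                                                {k: [] for k in ("mae", "psnr", "ssim")})
                for k, v in metrics.items():
                    slot[k].append(v)
    return result


# ---------------------------------------------------------------------------
# line profiles
# ---------------------------------------------------------------------------

def line_profile(image: np.ndarray, axis: str, index: int, span=None,
                 prominence: float = 0.1):
    """Intensity profile along a row (axis='x') or column (axis='y').

    Returns (profile, peak_positions); peaks via local-maxima detection
    with the given prominence.
    """
    image = np.asarray(image, dtype=float)
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' (along a row) or 'y' (along a column)")
    n_lines = image.shape[0] if axis == "x" else image.shape[1]
    if not 0 <= index < n_lines:
        raise IndexError(f"index {index} out of bounds for {n_lines} lines")
    line = image[index, :] if axis == "x" else image[:, index]
    if span is not None:
        start, stop = span
        line = line[start:stop]
    peaks, _ = signal.find_peaks(line, prominence=prominence)
    return line, peaks


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

ABLATION_VARIANTS = (
    "Full",
    "w/o WTConv",
    "w/o FS-FF",
    "w/o SE block",
    "w/o DP Net",
    "Single-task (4x)",
    "w/o Joint Training",
    "w/o BiP-FPM-Feat",
    "BiP-FPM-Feat (ours)",
)


def _variant_config(variant: str, seed: int) -> dict:
    base = dict(gen=GeneratorConfig(seed=seed), use_critic=True, single_task=False,
                joint=True, bip_features=False)
    if variant == "Full":
        return base
    if variant == "w/o WTConv":
        base["gen"] = GeneratorConfig(use_wtconv=False, seed=seed)
    elif variant == "w/o FS-FF":
        base["gen"] = GeneratorConfig(use_fsff=False, seed=seed)
    elif variant == "w/o SE block":
        base["gen"] = GeneratorConfig(use_se=False, seed=seed)
    elif variant == "w/o DP Net":
        base["use_critic"] = False
    elif variant == "Single-task (4x)":
        base["single_task"] = True
    elif variant == "w/o Joint Training":
        base["joint"] = False
    elif variant == "w/o BiP-FPM-Feat":
        base["bip_features"] = False
        base["joint"] = False
    elif variant == "BiP-FPM-Feat (ours)":
        base["bip_features"] = True
        base["joint"] = False
    else:
        raise ValueError(f"unknown ablation variant {variant!r}")
    return base


def _channel_scores(pred_channels: np.ndarray, bundles) -> tuple:
    """Per-channel mean MAE and SSIM over the battery."""
    maes, ssims = {}, {}
    for ci, name in enumerate(STAIN_CHANNELS):
        maes[name] = float(np.mean([np.abs(pred_channels[bi, ci] - getattr(b, name)).mean()
                                    for bi, b in enumerate(bundles)]))
        ssims[name] = float(np.mean([ssim(pred_channels[bi, ci], getattr(b, name))
                                     for bi, b in enumerate(bundles)]))
    return maes, ssims


def _fit_l1(generator, opt, inputs: np.ndarray, targets: np.ndarray, epochs: int,
            features=None):
    """Plain L1 fitting loop used by the single-task and feature rows."""
    from . import autodiff as ad
    for _ in range(epochs):
        opt.zero_grad()
        fake = generator.forward(ad.Tensor(inputs.astype(np.float32)), features)
        ad.tabs(fake - ad.Tensor(targets.astype(np.float32))).mean().backward()
        opt.step()


def ablation_harness(bundles, variants=ABLATION_VARIANTS, epochs: int = 5,
                     seed: int = 0, base_width: int = 8, critic=None,
                     features_fn=None, joint_context=None) -> dict:
    """Train each staining variant on a bundle battery; report per-channel
    SSIM and MAE on the training battery (synthetic-battery numbers).

    ``features_fn(bundle) -> features`` supplies Stage-I encoder features
    for the feature-fusion row (without it that row falls back to the
    generator's own branch, recorded as ``features_used=False``).
    ``joint_context = (stage1_factory, stacks)`` enables a joint Stage I +
    Stage II fine-tuning pass for the rows whose configuration asks for it;
    otherwise all rows train decoupled (recorded as ``joint_used=False``).
    """
    from . import nn as pnn
    from .stain_net import JointTrainer

    rows = {}
    for variant in variants:
        cfg = _variant_config(variant, seed)
        row = {"variant": variant, "config": {k: v for k, v in cfg.items() if k != "gen"}}
        if cfg["single_task"]:
            # four independent generators, no shared trunk, no cross-task ties
            preds = np.zeros((len(bundles), 4) + bundles[0].interface.shape)
            inputs = np.stack([b.interface for b in bundles])[:, None]
            n_gens = 0
            for ci, name in enumerate(STAIN_CHANNELS):
                gen = MultiStainGenerator(GeneratorConfig(base_width=base_width,
                                                          n_channels_out=1, seed=seed + ci))
                opt = pnn.Adam(gen.parameters(), lr=1e-3)
                targets = np.stack([b.channels[ci:ci + 1] for b in bundles])
                _fit_l1(gen, opt, inputs, targets, epochs)
                from . import autodiff as ad
                with ad.no_grad():
                    preds[:, ci] = gen.forward(
                        ad.Tensor(inputs.astype(np.float32))).numpy()[:, 0]
                n_gens += 1
            row["n_generators"] = n_gens
        else:
            use_feats = cfg["bip_features"] and features_fn is not None
            g_cfg = GeneratorConfig(base_width=base_width,
                                    use_wtconv=cfg["gen"].use_wtconv,
                                    use_fsff=cfg["gen"].use_fsff,
                                    use_se=cfg["gen"].use_se,
                                    use_bip_features=use_feats,
                                    seed=seed)
            feats = [features_fn(b) for b in bundles] if use_feats else None
            feat_ch = tuple(np.asarray(f).shape[0] for f in feats[0]) if use_feats else None
            tr = StainTrainer(g_cfg, critic=critic if cfg["use_critic"] else None,
                              seed=seed, batch_size=min(4, len(bundles)),
                              feature_channels=feat_ch)
            if use_feats:
                inputs = np.stack([b.interface for b in bundles])[:, None]
                targets = np.stack([b.channels for b in bundles])
                for bi, (b, f) in enumerate(zip(bundles, feats)):
                    _fit_l1(tr.generator, tr.g_opt, inputs[bi:bi + 1],
                            targets[bi:bi + 1], epochs, features=f)
            else:
                tr.fit(bundles, epochs=epochs)
            joint_used = False
            if cfg["joint"] and joint_context is not None:
                stage1_factory, stacks = joint_context
                joint = JointTrainer(stage1_factory(), tr)
                joint.fit(stacks, bundles, epochs=max(epochs // 2, 1))
                joint_used = True
            from . import autodiff as ad
            preds = np.zeros((len(bundles), 4) + bundles[0].interface.shape)
            with ad.no_grad():
                for bi, b in enumerate(bundles):
                    f = feats[bi] if use_feats else None
                    preds[bi] = tr.generator.forward(
                        ad.Tensor(b.interface[None, None].astype(np.float32)), f).numpy()[0]
            row["n_generators"] = 1
            row["features_used"] = use_feats
            row["joint_used"] = joint_used
        row["mae"], row["ssim"] = _channel_scores(preds, bundles)
        rows[variant] = row
    return rows
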