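"""Self-supervised physics-guided FPM reconstruction (Stage I).

A compact ResNet U-Net maps the multi-LED intensity stack (plus per-LED
wave-vector embedding channels) to a high-resolution amplitude and phase;
fourteen Zernike coefficients (piston frozen) and a log-gain are trained
alongside as standalone optical parameters.  Supervision is bidirectional
physics consistency:

* forward: the differentiable coherent model re-renders every LED image
  from the prediction and penalizes the intensity mismatch;
* inverse: a Wiener deconvolution of the mean intensity through the same
  optical transfer function must agree with the predicted amplitude.

Total-variation and pupil regularizers (coefficient energy plus Hermitian
asymmetry) complete the objective.  All squared norms are per-pixel means,
making the printed loss weights resolution-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from . import autodiff as ad
from . import nn
from .optics import IlluminationSet, OpticalSystem, PupilFunction, make_pupil, zernike_basis
from .report import LossReport
from .simulator import ComplexField, FPMStack, forward_intensities

__all__ = [
    "BipFpmPrediction",
    "BipFpmLossWeights",
    "BipFpmTrainConfig",
    "BipFpmReconstructor",
    "wiener_deconvolve",
    "synthetic_aperture_fuse",
    "raised_cosine_weights",
    "minmax_normalize",
]

N_ZERNIKE = 15


# ---------------------------------------------------------------------------
# configuration and result types
# ---------------------------------------------------------------------------

@dataclass
class BipFpmLossWeights:
    """Weights of the Stage-I objective (printed defaults)."""

    lambda_d: float = 0.1       # deconvolution-consistency weight
    lambda_tv: float = 1e-4     # total-variation weight
    lambda_p: float = 1e-3      # pupil-regularizer weight
    eta1: float = 1.0           # Zernike coefficient energy
    eta2: float = 1.0           # Hermitian-asymmetry penalty
    alpha_wiener: float = 1e-3  # Wiener stabilizer
    band_threshold: float = 0.1  # |H| level above which the inverse path is trusted
    # gauge fixing: s|U|^2 is invariant under (A, s) -> (A/c, c^2 s), so a
    # weak prior pins the gain near 1 (intensities are max-normalized)
    lambda_gain: float = 0.1

    def __post_init__(self):
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class BipFpmTrainConfig:
    epochs: int = 200
    learning_rate: float = 2e-4
    optical_lr: float = 1e-2    # Zernike coefficients and log-gain step size
    freeze_epochs: int = 10     # epochs with (P, s) frozen
    seed: int = 0
    base_width: int = 16        # channel width of the reconstruction net
    n_res_blocks: int = 9
    otf_mode: str = "incoherent"

    def __post_init__(self):
        if self.freeze_epochs >= self.epochs:
            raise ValueError("freeze_epochs must be smaller than epochs")


@dataclass
class BipFpmPrediction:
    """Physically interpretable Stage-I outputs on the HR grid."""

    amplitude: np.ndarray
    phase: np.ndarray
    zernike_coeffs: np.ndarray
    gain: float
    features: list = field(default_factory=list)  # multi-scale encoder features

    @property
    def field(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)


# ---------------------------------------------------------------------------
# free operations
# ---------------------------------------------------------------------------

def minmax_normalize(x):
    """Deterministic per-field min-max map into [0, 1]; constants map to 0.

    Idempotent: N(N(x)) = N(x).  Works on arrays and on autodiff tensors
    (the bounds are treated as constants in the gradient).
    """
    if isinstance(x, ad.Tensor):
        lo = float(x.data.min())
        hi = float(x.data.max())
        if hi - lo < 1e-12:
            return x * 0.0
        return (x - lo) * (1.0 / (hi - lo))
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def wiener_deconvolve(i_avg, h, alpha: float):
    """Regularized inverse filtering: invFT( conj(H) FT(I) / (|H|^2 + alpha) ).

    With ``H == 1`` and ``alpha == 0`` this is the identity.  ``alpha = 0``
    is rejected unless H is strictly nonzero everywhere.
    """
    if alpha < 0:
        raise ValueError("Wiener stabilizer alpha must be nonnegative")
    tensor_in = isinstance(i_avg, ad.Tensor) or isinstance(h, ad.Tensor)
    it = ad.astensor(i_avg)
    ht = ad.astensor(h)
    if alpha == 0 and np.abs(ht.data).min() < 1e-12:
        raise ZeroDivisionError("alpha = 0 requires a strictly nonzero transfer function")
    spec = ad.fft2c(it)
    denom = ad.abs2(ht) + alpha
    out = ad.ifft2c(ad.conj(ht) * spec * ad.power(denom, -1.0))
    if tensor_in:
        return out
    with ad.no_grad():
        return out.numpy()


def raised_cosine_weights(illum: IlluminationSet, system: OpticalSystem):
    """LED-dependent frequency masks W_n with smooth transitions.

    Each mask is a raised-cosine taper over that LED's shifted pupil disk,
    renormalized so that sum_n W_n = 1 on every covered frequency.
    Returns (weights (N, H, W), covered boolean mask).
    """
    n = system.hr_shape[0]
    shifts, _ = illum.pixel_shifts(system)
    r = system.pupil_radius_px
    yy, xx = np.mgrid[-(n // 2):n - n // 2, -(n // 2):n - n // 2]
    weights = np.zeros((len(illum), n, n))
    for i, (sy, sx) in enumerate(shifts):
        # LED n's windowed sub-spectrum sits around -shift_n on the true
        # frequency axes (spectrum-roll convention of the forward model)
        rho = np.hypot(yy + sy, xx + sx) / r
        weights[i] = np.where(rho <= 1.0, 0.5 * (1 + np.cos(np.pi * np.clip(rho, 0, 1))), 0.0)
    cover = weights.sum(axis=0)
    covered = cover > 1e-12
    weights[:, covered] /= cover[covered]
    return weights, covered


def synthetic_aperture_fuse(pred, illum: IlluminationSet, system: OpticalSystem,
                            pupil: PupilFunction | None = None,
                            weights: np.ndarray | None = None) -> ComplexField:
    """Stitch per-LED band-limited sub-spectra into the synthetic aperture.

    Each LED's windowed sub-spectrum P(f) U(f - k_n) is un-shifted back to
    its true frequencies before weighting, so the fused spectrum has support
    inside the union of the shifted pupil disks; the result is the inverse
    transform of the (1/N)-scaled weighted sum.
    """
    if isinstance(pred, BipFpmPrediction):
        field = pred.field
    elif isinstance(pred, ComplexField):
        field = pred.as_complex()
    else:
        field = np.asarray(pred, dtype=complex)
    if pupil is None:
        pupil = make_pupil(system)
    if weights is None:
        weights, covered = raised_cosine_weights(illum, system)
    else:
        covered = weights.sum(axis=0) > 1e-12
    shifts, _ = illum.pixel_shifts(system)
    spectrum = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(field), norm="ortho"))
    fused = np.zeros_like(spectrum)
    for i, (sy, sx) in enumerate(shifts):
        sub = pupil.array * np.roll(spectrum, (sy, sx), axis=(0, 1))
        fused += weights[i] * np.roll(sub, (-sy, -sx), axis=(0, 1))
    fused /= len(illum)
    if not np.all(np.abs(fused[~covered]) < 1e-9 * max(np.abs(fused).max(), 1e-30)):
        import warnings
        warnings.warn("nonzero fused spectrum outside the covered aperture", stacklevel=2)
    out = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(fused), norm="ortho"))
    return ComplexField(np.abs(out), np.angle(out), system.hr_pixel_size)


def _tv(x) -> ad.Tensor:
    """Anisotropic L1 total variation, per-pixel mean normalization."""
    dy = ad.tabs(x[1:, :] - x[:-1, :]).mean()
    dx = ad.tabs(x[:, 1:] - x[:, :-1]).mean()
    return dy + dx


# ---------------------------------------------------------------------------
# reconstruction network
# ---------------------------------------------------------------------------

def _inv_softplus(y: np.ndarray) -> np.ndarray:
    y = np.clip(y, 1e-4, None)
    return y + np.log1p(-np.exp(-y))


class _ReconNet(nn.Module):
    """ResNet U-Net over the LED stack; amplitude is a residual correction
    on the bicubic baseline through a softplus positivity map."""

    def __init__(self, n_leds: int, upsample: int, width: int, n_blocks: int,
                 rng: np.random.Generator):
        if upsample & (upsample - 1):
            raise ValueError("upsample_factor must be a power of two for the network")
        w = width
        c_in = 3 * n_leds  # intensity + (k_x, k_y) embedding channels per LED
        self.stem = nn.Conv2d(c_in, w, 3, rng=rng)
        self.down1 = nn.Conv2d(w, 2 * w, 3, stride=2, rng=rng)
        self.down2 = nn.Conv2d(2 * w, 4 * w, 3, stride=2, rng=rng)
        self.blocks = [nn.ResidualBlock(4 * w, rng) for _ in range(n_blocks)]
        self.up1 = nn.ConvTranspose2d(4 * w, 2 * w, rng)
        self.fuse1 = nn.Conv2d(4 * w, 2 * w, 3, rng=rng)
        self.up2 = nn.ConvTranspose2d(2 * w, w, rng)
        self.fuse2 = nn.Conv2d(2 * w, w, 3, rng=rng)
        self.super = [nn.ConvTranspose2d(w, w, rng)
                      for _ in range(int(np.log2(upsample)))]
        self.amp_head = nn.Conv2d(w, 1, 3, zero_init=True)
        self.phase_head = nn.Conv2d(w, 1, 3, zero_init=True)

    def forward(self, x, amp_base_logit):
        f1 = ad.relu(self.stem(x))
        f2 = ad.relu(self.down1(f1))
        h = ad.relu(self.down2(f2))
        for blk in self.blocks:
            h = blk(h)
        f3 = h
        u = ad.relu(self.up1(h))
        u = ad.relu(self.fuse1(ad.concat([u, f2], axis=1)))
        u = ad.relu(self.up2(u))
        u = ad.relu(self.fuse2(ad.concat([u, f1], axis=1)))
        for layer in self.super:
            u = ad.relu(layer(u))
        amp = ad.softplus(self.amp_head(u) + amp_base_logit)
        phase = ad.tanh(self.phase_head(u)) * np.pi
        return amp, phase, [f1, f2, f3]


# ---------------------------------------------------------------------------
# the reconstructor
# ---------------------------------------------------------------------------

class BipFpmReconstructor:
    """Per-specimen self-supervised reconstruction of (A, phi, P, s)."""

    def __init__(self, system: OpticalSystem, illum: IlluminationSet,
                 config: BipFpmTrainConfig | None = None,
                 weights: BipFpmLossWeights | None = None):
        self.system = system
        self.illum = illum
        self.config = config or BipFpmTrainConfig()
        self.weights = weights or BipFpmLossWeights()
        self.shifts, _ = illum.pixel_shifts(system)
        rng = np.random.default_rng(self.config.seed)
        self.net = _ReconNet(len(illum), system.upsample_factor,
                             self.config.base_width, self.config.n_res_blocks, rng)
        fy, fx = system.frequency_grid()
        self.pupil_mask = (np.hypot(fy, fx) <= system.cutoff_frequency).astype(float)
        self.zernike = zernike_basis(N_ZERNIKE, fy, fx, system.cutoff_frequency)
        # optical parameters: a single stack determines one pupil and gain,
        # so these are standalone trainables; piston (a_1) stays frozen
        self.coeffs = ad.Parameter(np.zeros(N_ZERNIKE))
        self.log_gain = ad.Parameter(np.array(0.0))
        self._piston_mask = np.ones(N_ZERNIKE)
        self._piston_mask[0] = 0.0

    # -- pieces -------------------------------------------------------------
    def _net_input(self, stack: FPMStack):
        if len(stack) != len(self.illum):
            raise ValueError(f"stack has {len(stack)} images, configured for {len(self.illum)} LEDs")
        imgs = stack.images.astype(np.float32)
        scale = max(imgs.max(), 1e-12)
        imgs = imgs / scale
        k = self.illum.wavevectors
        kn = k / (np.abs(k).max() + 1e-30)
        n, h, w = imgs.shape
        emb = np.repeat(kn[:, :, None, None], h, axis=2).repeat(w, axis=3)
        channels = np.concatenate([imgs[:, None], emb.reshape(n, 2, h, w)[:, 0:1],
                                   emb.reshape(n, 2, h, w)[:, 1:2]], axis=1)
        x = channels.reshape(1, 3 * n, h, w).astype(np.float32)
        base = resize(np.sqrt(np.clip(stack.images.mean(axis=0), 0, None)),
                      self.system.hr_shape, order=3, anti_aliasing=False)
        base_logit = _inv_softplus(np.clip(base, 1e-3, None)).astype(np.float32)
        return ad.Tensor(x), ad.Tensor(base_logit[None, None]), base

    def pupil_tensor(self) -> ad.Tensor:
        masked = self.coeffs * ad.Tensor(self._piston_mask)
        phase = (masked.reshape((N_ZERNIKE, 1, 1)) * ad.Tensor(self.zernike)).sum(axis=0)
        return ad.polar(ad.Tensor(self.pupil_mask), phase)

    def gain_tensor(self) -> ad.Tensor:
        return ad.texp(self.log_gain)

    def _predict_tensors(self, stack: FPMStack):
        x, base_logit, _ = self._net_input(stack)
        amp, phase, feats = self.net(x, base_logit)
        n = self.system.hr_shape[0]
        return amp.reshape((n, n)), phase.reshape((n, n)), feats

    def predict(self, stack: FPMStack) -> BipFpmPrediction:
        with ad.no_grad():
            amp, phase, feats = self._predict_tensors(stack)
            return BipFpmPrediction(
                amplitude=amp.numpy().astype(float),
                phase=phase.numpy().astype(float),
                zernike_coeffs=(self.coeffs.data * self._piston_mask).copy(),
                gain=float(np.exp(self.log_gain.data)),
                features=[f.numpy().astype(float) for f in feats],
            )

    def forward_project(self, pred: BipFpmPrediction | tuple):
        """Simulate the stack implied by a prediction (shared physics path)."""
        if isinstance(pred, BipFpmPrediction):
            amp, phase = pred.amplitude, pred.phase
            pupil = self.pupil_mask * np.exp(
                1j * np.tensordot(pred.zernike_coeffs, self.zernike, axes=(0, 0)))
            gain = pred.gain
        else:
            amp, phase, pupil, gain = pred
        return forward_intensities(amp, phase, pupil, self.shifts, self.system, gain)

    def otf_tensor(self, pupil: ad.Tensor) -> ad.Tensor:
        """Transfer function for the inverse (deconvolution) path."""
        if self.config.otf_mode == "coherent":
            return pupil
        n = self.system.hr_shape[0]
        padded = ad.pad_center(pupil, 2 * n, 2 * n)
        acorr = ad.ifft2c(ad.abs2(ad.fft2c(padded))) * (2 * n)
        acorr = ad.crop_center(acorr, n, n)
        dc = float(np.abs(acorr.data[n // 2, n // 2]))
        return acorr * (1.0 / max(dc, 1e-12))

    def compute_losses(self, stack: FPMStack, tensors=None) -> tuple:
        """Return (total loss Tensor, LossReport with every term)."""
        w = self.weights
        if tensors is None:
            amp, phase, _ = self._predict_tensors(stack)
            pupil = self.pupil_tensor()
            gain = self.gain_tensor()
        else:
            amp, phase, pupil, gain = tensors
        sim = forward_intensities(amp, phase, pupil, self.shifts, self.system, gain)
        meas = ad.Tensor(stack.images)
        l_phys = ad.abs2(sim - meas).mean(axis=(1, 2)).mean()

        # the mean intensity is upsampled to the HR lattice (constant w.r.t.
        # the parameters) and deconvolved through the pupil-consistent OTF
        i_avg_hr = resize(stack.images.mean(axis=0), self.system.hr_shape,
                          order=3, anti_aliasing=False)
        # The inverse path is evaluated with the *current* pupil but treated
        # as a per-epoch target (no gradient through the near-singular
        # inverse filter, which otherwise destabilizes the Zernike
        # coefficients); its pull acts on the amplitude.  The deconvolved
        # mean intensity is mapped to amplitude scale via a square root:
        # comparing an intensity-domain map to A directly would push A
        # toward its own square.
        with ad.no_grad():
            otf_const = self.otf_tensor(ad.Tensor(pupil.data))
            band_np = (np.abs(otf_const.data) > w.band_threshold).astype(float)
            u_dec = wiener_deconvolve(ad.Tensor(i_avg_hr), otf_const, w.alpha_wiener)
            # keep only the trusted band: below |H| ~ band_threshold the
            # Wiener inverse mostly amplifies model mismatch and ringing
            u_spec = ad.fft2c(u_dec) * ad.Tensor(band_np)
            u_dec_int = ad.tabs(ad.ifft2c(u_spec))
            u_dec_amp = ad.tsqrt(u_dec_int + 1e-12)
        # compare within the same band; the target is affine-matched to the
        # current amplitude (detached least-squares fit), so the term pulls
        # shape, not scale — normalizing both sides instead invites
        # outlier-driven scale games
        band = ad.Tensor(band_np)
        amp_band = ad.real(ad.ifft2c(ad.fft2c(amp) * band))
        t = u_dec_amp.data.ravel()
        a_cur = amp_band.data.ravel()
        design = np.stack([t, np.ones_like(t)], axis=1)
        coef, *_ = np.linalg.lstsq(design, a_cur, rcond=None)
        target = coef[0] * u_dec_amp.data + coef[1]
        l_dec = ad.abs2(amp_band - ad.Tensor(target)).mean()

        l_tv = _tv(amp) + _tv(phase)

        masked = self.coeffs * ad.Tensor(self._piston_mask)
        sym = pupil - ad.roll2d(ad.flip2d(ad.conj(pupil)), 1, 1)
        r_pupil = w.eta1 * ad.abs2(masked).sum() + w.eta2 * ad.abs2(sym).mean()
        r_gain = ad.abs2(ad.tlog(gain))

        total = (l_phys + w.lambda_d * l_dec + w.lambda_tv * l_tv
                 + w.lambda_p * r_pupil + w.lambda_gain * r_gain)
        for name, t in (("l_phys", l_phys), ("l_deconv", l_dec),
                        ("l_tv", l_tv), ("r_pupil", r_pupil), ("total", total)):
            if not np.isfinite(t.data):
                raise ArithmeticError(f"non-finite loss term {name}")
        report = LossReport()
        report.add("l_phys", l_phys.item(), 1.0)
        report.add("l_deconv", l_dec.item(), w.lambda_d)
        report.add("l_tv", l_tv.item(), w.lambda_tv)
        report.add("r_pupil", r_pupil.item(), w.lambda_p)
        report.add("r_gain", r_gain.item(), w.lambda_gain)
        report.extras["i_rec_forward"] = sim.data  # Zernike-pupil re-rendering
        report.extras["i_rec_deconv"] = u_dec_int.data  # deconvolved intensity map
        return total, report

    # -- training -----------------------------------------------------------
    def train(self, stack: FPMStack, epochs: int | None = None, log_every: int = 1):
        """Optimize the network and optical parameters on one stack.

        Returns (best prediction, list of per-epoch LossReport).
        """
        cfg = self.config
        epochs = epochs if epochs is not None else cfg.epochs
        opt = nn.Adam(self.net.parameters(), lr=cfg.learning_rate)
        opt_optical = nn.Adam([self.coeffs, self.log_gain], lr=cfg.optical_lr)
        history = []
        best = (np.inf, None)
        x, base_logit, _ = self._net_input(stack)
        for epoch in range(epochs):
            opt.zero_grad()
            amp, phase, feats = self.net(x, base_logit)
            n = self.system.hr_shape[0]
            amp2, phase2 = amp.reshape((n, n)), phase.reshape((n, n))
            pupil = self.pupil_tensor()
            gain = self.gain_tensor()
            try:
                total, report = self.compute_losses(stack, (amp2, phase2, pupil, gain))
            except ArithmeticError as err:
                raise ArithmeticError(
                    f"aborting at epoch {epoch}: {err}; last report: "
                    f"{history[-1].as_dict() if history else 'none'}") from err
            total.backward()
            if self.coeffs.grad is not None:
                self.coeffs.grad = self.coeffs.grad * self._piston_mask
            if epoch < cfg.freeze_epochs:
                self.coeffs.grad = None
                self.log_gain.grad = None
            opt.step()
            opt_optical.step()
            opt_optical.zero_grad()
            history.append(report)
            if report.total < best[0]:
                with ad.no_grad():
                    best = (report.total, BipFpmPrediction(
                        amplitude=np.asarray(amp2.data, dtype=float).copy(),
                        phase=np.asarray(phase2.data, dtype=float).copy(),
                        zernike_coeffs=(self.coeffs.data * self._piston_mask).copy(),
                        gain=float(np.exp(self.log_gain.data)),
                        features=[np.asarray(f.data, dtype=float).copy() for f in feats]))
        return best[1], history

    # -- interface to Stage II ---------------------------------------------
    def export_interface(self, pred: BipFpmPrediction):
        """Interface image I_int = minmax(A) plus raw multi-scale features.

        Phase, pupil and gain are deliberately not exported; the staining
        stage sees only the normalized amplitude and encoder features.
        """
        return minmax_normalize(pred.amplitude), list(pred.features)
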