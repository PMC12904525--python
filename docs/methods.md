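# Methods

## Imaging model and conventions

A thin specimen with transmission `A(x,y) · exp(jφ(x,y))` is illuminated by
oblique plane waves from a planar LED array. The LED at lateral offset
`(d_x, d_y)` a distance `h` below the specimen contributes the wave vector
`k = 2π (d_x, d_y) / (λ √(d_x² + d_y² + h²))` (rad/m); in the frequency
domain this shifts the object spectrum by `k`, the objective pupil
band-limits it at the coherent cutoff `f_c = NA/λ`, and the camera records
the squared modulus scaled by an illumination gain `s`.

Conventions used throughout:

* arrays are `(row=y, col=x)`, origin top-left; spectra are DC-centered;
  all FFTs are orthonormal, so Parseval holds exactly;
* LED wave vectors are rounded to the nearest high-resolution frequency
  bin (the classical FPM convention); the sub-bin residual is recorded in
  the stack metadata but not applied;
* downsampling to the camera grid is a Fourier-domain central crop scaled
  by the grid ratio, so a unit-amplitude plane wave through an all-pass
  system yields unit intensity. Spectral cropping makes the forward model
  exactly band-limited, which keeps the classical solver an exact oracle;
* pupil aberrations use Noll-indexed, Noll-normalized Zernike modes 1–15.
  Piston is represented but frozen at zero during learning (a constant
  pupil phase is unobservable in intensity). Hermitian pupil symmetry
  `P(f) = conj(P(−f))` holds exactly when all even-azimuthal-order modes
  vanish; the even modes (defocus, astigmatism, spherical, quadrafoil)
  break it, which is precisely what the pupil-asymmetry penalty measures.

## Differentiation

No deep-learning framework is used. A compact reverse-mode autodiff engine
over NumPy (`ptystain.autodiff`) provides the complex arithmetic, centered
FFTs, convolutions (channels-last shift-and-add kernels backed by BLAS) and
pointwise ops the package needs; every derivative rule is validated against
central finite differences in the test suite, including the Wirtinger-style
rules for complex tensors (gradients stored as steepest-ascent vectors).

## Stage I: self-supervised reconstruction

A ResNet U-Net (stem → two stride-2 stages → residual blocks → mirrored
decoder with skips, then learned upsampling to the HR grid) maps the LED
stack — each image accompanied by two constant channels carrying its
normalized `(k_x, k_y)` — to amplitude and phase. The amplitude head is a
zero-initialized residual on the bicubic-upsampled root-mean intensity
through a softplus map (positive by construction, sensible at
initialization); the phase head is `π·tanh`, zero-initialized. The Zernike
coefficients `a_2..a_15` and the log-gain are standalone trainable
parameters rather than network outputs: one self-supervised stack
determines exactly one pupil, so a constant head is the identifiable
parameterization. They get their own Adam at `optical_lr = 1e-2` (the
network uses the published `2e-4`); shared across both, scalar optical
parameters would otherwise crawl. Both are frozen for the first
`freeze_epochs = 10` epochs.

The objective is

```
L = L_phys + λ_d·L_deconv + λ_tv·(TV(A)+TV(φ)) + λ_P·R(P) + λ_gain·(log s)²
```

with `λ_d = 0.1`, `λ_tv = 1e-4`, `λ_P = 1e-3`,
`R(P) = η₁ Σ aᵢ² + η₂ ‖P(f) − conj(P(−f))‖²` (η₁ = η₂ = 1). All squared
norms are per-pixel means so the weights are resolution-independent.
Two numerical choices deserve emphasis:

* **Gauge fixing.** `s|U|²` is invariant under `(A, s) → (A/c, c²s)`, so a
  weak prior `λ_gain (log s)² = 0.1·(log s)²` pins the gain near 1 (the
  natural anchor on max-normalized intensities). Without it the flat
  direction drifts and the amplitude scale decouples from the data.
* **The inverse path.** The mean intensity is bicubic-upsampled and Wiener
  deconvolved through the incoherent OTF (the pupil autocorrelation;
  stabilizer `α = 1e-3`). Deconvolving an intensity yields an
  intensity-domain map, so its square root is the amplitude-scale target;
  comparing the raw map to `A` would push the amplitude toward its own
  square. The comparison is restricted to the trusted band
  (`|H| > 0.1`, below which the inverse filter mostly amplifies model
  mismatch), the target is affine-matched to the current amplitude by a
  detached least-squares fit (a shape pull, not a scale pull — normalizing
  both sides invites outlier-driven scale games), and the whole inverse
  branch is treated as a per-epoch target (no gradient through the
  near-singular filter, which otherwise destabilizes the Zernike
  coefficients). These choices came out of failure analysis on the
  synthetic bench; the naive readings each collapsed reconstruction
  quality by 20+ dB.

Synthetic-aperture fusion stitches the per-LED windowed sub-spectra back
at their true frequencies under raised-cosine weights renormalized to a
partition of unity over the covered band; it is exposed as an operation
and verified to preserve in-band spectra up to the documented `1/N` scalar.

## Stage II: multi-task staining

The generator is encoder–fusion–decoder: a 3×3 stem plus two stride-2
blocks; at the bottleneck a wavelet branch (orthonormal Haar DWT →
per-subband depthwise convolutions → inverse DWT; an exact identity at
identity initialization) runs next to the spatial branch (the generator's
own features, or 1×1-projected, rescaled Stage-I encoder features when the
feature-fusion variant is enabled); difference-aware fusion
`F_out = Conv3×3(DA(|F_s − F_f|)) + F_s` with the output convolution
zero-initialized (identity at init); the decoder upsamples with
squeeze-excitation gating (reduction 8, clamped to divide narrow widths)
and additive skips; a sigmoid head emits the four channels. H&E is one
grayscale stain-intensity map (nuclei bright), keeping the printed
four-channel layout; a fixed two-color render exists for display only.

Each channel has an independent two-input (input, candidate) PatchGAN with
the canonical 70×70 receptive field, trained with the least-squares
objective. The full loss is

```
L_stain = Σ_c (L_GAN^c + 10.0·L1^c + 0.2·L_DP-IQA^c) + 1.0·L_cross
L_cross = 1.0·L_consistency + 0.5·L_exclusive + 0.2·L_relative
```

with the nuclear mask thresholded at `τ = 0.5` on predicted DAPI (treated
as a constant — no gradient through the threshold; an empty mask defines
the consistency term as 0 with a warning), and the relative term using
soft attention pooling (per-map absolute values normalized to sum 1,
compared in summed L1 — a scale-free distribution distance). Joint training
optimizes `L_stageI + λ_s(t)·L_stain` with `λ_s` warmed up linearly from
0.1 to 0.5 over the first 10 epochs; one shared reconstruction network
amortizes over the stacks, and the generator can consume the live Stage-I
graph. The adversarial critics train in the decoupled phase; the joint
pass uses the pixel, perceptual and cross-task terms.

## Quality critic

The critic has a small convolutional main branch (absolute quality
`q_main ∈ [0,1]` via sigmoid) and a wavelet difference branch: two-level
Haar pyramids of both inputs, subband-conv features, per-scale absolute
feature differences fused by multi-scale asymmetric attention
(`α_s = σ(W₂ δ(W₁ GAP(F_s)))`), regressing a dissimilarity
`d ≥ 0` (softplus) that is symmetric by construction. Training data are
synthetic distortions of phantom images — blur, additive noise, gray-level
quantization — with quality labels `q = 1 − strength`. The parameter maps
are calibrated so equal strength has comparable RMS impact across families
(blur σ = 1.2·s², noise SD = 0.1·s, levels = 2^(8−7s)); without this
calibration cross-family quality ranks are ill-posed and no scorer can
order them. Used as a perceptual loss, the frozen critic's `d` is averaged
over three dyadic scales. Loss weights `λ₁ = λ₂ = 0.5` for the auxiliary
and difference terms are package defaults (nothing published to anchor
them).

## Synthetic data

The tissue generator draws non-overlapping nuclei (bounded-restart
rejection sampling; an infeasible packing raises after 25 restarts) inside
a smoothly thresholded epithelial region. DAPI is the disk interiors, LAP2
a compact annulus at each disk edge, panCK the epithelium minus
nuclei-plus-envelopes with a one-pixel exact-zero guard (so
`mean(LAP2·panCK) = 0` holds exactly, soft edges included), and H&E equals
DAPI inside nuclear regions over a lighter cytoplasm texture. Edges use
compact one-pixel ramps so sigmoid networks can fit them; hard-binary
targets are a flag. The FPM degradation reuses the simulator with the
interface image as amplitude and the default amplitude-coupled phase
`φ = π·A`.

What the phantoms do not emulate: real chromatin texture, stain variability
and bleed-through, registration error, shot noise, LED non-uniformity, or
out-of-focus structure. Passing tests therefore demonstrate correctness of
the mechanisms (physics consistency, constraint satisfaction,
learnability), not clinical staining fidelity.

## Study conditions and problem sizes

Everything runs on one CPU. The benchmark bench is a 0.25-NA, 10×, 520 nm
system with 6.5 µm camera pixels at upsample factor 2:

* forward consistency: twenty 32²/3×3-LED stacks with random defocus and gain;
* baseline vs learned: 128², 9×9 LEDs (~85% pupil overlap), AP+EPRY at 20
  iterations vs 150 self-supervised epochs at base width 16;
* defocus recovery / super-resolution gain: 96², 7×7 LEDs, 300 epochs;
* noise sweep: 64² with a 10 mm-pitch array whose corner LEDs are deeply
  darkfield (illumination NA up to 0.53), two phantoms, SDs
  {0, 0.5, 1}×10⁻⁴ sharing one noise realization per phantom
  (common random numbers), 120 epochs per cell;
* staining learnability: 200 phantom pairs at 96², 30 epochs, batch 8,
  generator base width 16, discriminator width 8, evaluated on 30 held-out
  pairs;
* critic: 60 phantom images (48²), 40 epochs, 20% held out.

The printed optical protocol (4×, NA 0.13, 505 nm, 13×13 LEDs at 98 mm
with 8 mm pitch, noise SD 0–1×10⁻⁴) is implemented as a stack factory; at
default grid sizes a ring of corner LEDs exceeds the HR frequency grid and
wraps, which the factory reports as a warning (increase the upsample factor
for a strictly alias-free simulation).

## Known limitations

* At SDs ≤ 1×10⁻⁴ the learned reconstruction's optimization floor
  (amplitude MSE ~10⁻³ at these training budgets) exceeds the noise-induced
  data perturbation by several orders of magnitude, so its PSNR-vs-noise
  curve is flat to within optimization jitter; the classical solver, which
  fits the data to machine precision, is the noise-resolving row of the
  sweep. Making the learned curve resolve these SDs would require
  convergence to ~10⁻⁸ residuals, far beyond CPU-scale budgets.
* On noiseless, well-overlapped data the deconvolution-consistency term is
  a biased prior: its Wiener target carries irreducible coherent-imaging
  model error (a single intensity OTF cannot represent a sum of coherent
  band-passes), so with `λ_d = 0.1` the full objective converges ~1–3 dB
  below its own `λ_d = 0` ablation on the synthetic battery. The term's
  intended value is robustness, not noiseless accuracy; the package keeps
  the published weight and reports both variants in the sweep.
* The classical solver leaves out-of-band spectrum at its initialization
  value; with the default bicubic initialization this caps single-LED
  fixed-point accuracy (flat initialization reaches the in-band fixed
  point exactly).
* Self-supervised training is per-specimen (one stack, one model);
  amortized inference across specimens exists only in the joint-training
  mode and is exercised at smoke-test scale.
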