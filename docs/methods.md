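# Methods

## Image formation model

A thin sample with complex transmission o(r) is illuminated by a planar LED
array (default 13 × 13 LEDs, 4 mm pitch, 100 mm below the sample, wavelength
λ = 505 nm). Each LED approximates a tilted plane wave, so in the Fourier
domain the objective — a binary circular pupil of radius NA/λ (NA = 0.13) —
selects a disc of the object spectrum centered at the LED's spatial-frequency
offset

    k = (sin θx, sin θy) / λ,    sin θx = x / √(x² + y² + h²),

where (x, y) is the LED's in-plane position and h the array height. The
camera (6.5 µm pixels, magnification 4×) records the intensity of the
low-resolution field. On the discrete grid the capture for LED i is

    I_i = | F⁻¹{ P · Ô[k_i] } |²,

where Ô is the centered high-resolution spectrum, Ô[k_i] the LR-sized crop
around k_i (nearest-pixel rounding; sub-pixel shifts are not modelled), and
P the pupil. Crops are scaled by (lr/hr)² so a constant object of amplitude
c produces intensity |c|² and mean LR intensity equals mean low-passed HR
intensity. The forward implementation is verified against a brute-force
explicit-DFT oracle to < 1e−10 on 32 × 32 grids.

Default sampling: HR grid 192 px at 0.40625 µm/px, downsample factor 4
(LR 48 px at 1.625 µm/px, which satisfies Nyquist for the coherent cutoff
NA/λ = 0.257 cycles/µm). Magnification, LED pitch and downsample factor are
not uniquely determined by the physical parameters above; the defaults are
chosen to represent a typical 4× / 0.13-NA configuration and give an
adjacent-pupil spectral overlap of 0.80, comfortably above the ≈ 0.6
practitioners consider necessary for stable phase retrieval
(`spectral_overlap` reports this; `build_dataset` refuses geometries below
0.5).

Acquisition noise: capture intensities are normalized to a stack-wide peak
of 1, then i.i.d. Gaussian noise with σ = 3 × 10⁻⁴ (default; 1 × 10⁻⁴ as the
low-noise condition) is added and negative values are clipped at zero. The σ
is dimensionless because it applies to the peak-normalized intensities; the
noise protocol is validated by measuring the empirical sd on bright pixels,
where the zero-clip is inactive.

## Phase retrieval

`gs_reconstruct` is plain sequential spectrum stitching: initialize the HR
spectrum from the Fourier-upsampled center-LED amplitude with zero phase;
then, sweeping LEDs center-outward (spiral order, ties clockwise from +x),
replace the modulus of each LED's low-resolution field by the measured
√intensity and write the updated sub-spectrum back inside the pupil support.
The per-sweep data-fidelity error is

    E = Σ_i Σ_px ( √I_est − √I_meas )² / Σ_i Σ_px I_meas .

`as_reconstruct` applies the same update damped by a step size α (spectrum ←
spectrum + α·Δ), with α₀ = 1 halved whenever a sweep improves E by less than
1%. Per-sweep (rather than per-LED) adaptation was chosen; on noisy stacks
the damping suppresses the noise-floor oscillation of the plain update and
empirically yields a lower final E. One naming caveat: the literature this
follows uses "GS" for the plain replacement update and "AS" for the
adaptive-step variant, and this package fixes that convention.

No pupil estimation, LED-position or intensity correction is performed:
those are deliberately out of scope, and the simulator generates data with
an ideal binary pupil.

Two identifiability facts shape the tests:

* **Global phase gauge.** All captures are invariant to o → o·exp(iφ₀), so
  phase quality is measured after `align_global_phase` (rotation by the
  phase of the inner product with the reference).
* **Synthetic aperture.** Only frequencies inside the union of the shifted
  pupils (objective NA extended by the maximum illumination NA) are observed
  at all. Recovery tests therefore use objects projected onto that passband
  (`bandlimit_field`); on such 64 × 64 objects 50 GS sweeps recover
  amplitude and phase with SSIM ≈ 1.0 and drive E down by > 20 orders of
  magnitude. Quality against a *full-band* object is bounded by the missing
  spectral content, not by the solver.

`one_iteration_init` (a single GS sweep, channel-encoded) is the network's
input representation: channel 0 is intensity |o|² normalized to peak 1,
channel 1 is phase mapped linearly from [−π, π] to [0, 1]. "Intensity" means
the squared modulus; with the paired encoder/decoder this choice is
self-consistent end to end.

## Reconstruction network

RHAN maps the 2-channel one-sweep reconstruction to the 2-channel HR target:
a 3 × 3 shallow convolution to C channels; n_hags hybrid attention groups
(each n_rhabs residual hybrid attention blocks in series plus a trailing
3 × 3 convolution and a group residual); a long skip adding the shallow
features; and a reconstruction head of sub-pixel convolution (3 × 3 conv to
C·s² channels + pixel shuffle, s = 1 by default since input and target share
the 192 px size) followed by two 3 × 3 convolutions (Leaky ReLU between
them) down to 2 channels.

Each block computes

    y = SA(x) + CA(conv₂(LeakyReLU(conv₁(x)))),

i.e. the identity shortcut is replaced by spatial attention while channel
attention reweights the residual branch. SA runs parallel 3 × 3 convolutions
at dilations {1, 2} (receptive fields 3 × 3 and 5 × 5 without extra
parameters), concatenates the branches, fuses them back to C channels with a
1 × 1 convolution, and multiplies by a sigmoid spatial map produced from the
concatenation by a second 1 × 1 convolution. Gating the *fused features*
(rather than the block input) is one of two defensible wirings; it is fixed
here and exercised by tests. CA is squeeze-and-excitation with Leaky ReLU
(slope 0.2) in the bottleneck: global average pool → 1 × 1 conv to C/r →
Leaky ReLU → 1 × 1 conv to C → sigmoid. Ablations: RCN removes SA (identity
shortcut restored), RSN removes CA.

Depth and width are not pinned down by the architecture description, so the
defaults follow residual channel-attention super-resolution practice and are
all configuration-exposed: C = 64, 5 HAGs × 4 RHABs, CA reduction 16,
leaky slope 0.2.

Numerical choices that matter:

* **Initialization.** Conv weights are Kaiming-uniform with a = √5 (bound
  1/√fan_in) — the convention this family of residual networks is tuned
  around. A gain-√2-style init compounds through the ~20 stacked residual
  blocks and saturates float32 within a few groups. The final conv starts
  with 0.1-scaled weights and bias 0.5, so the initial prediction is flat
  mid-gray: this conditions the SSIM luminance term and removes an observed
  failure mode where some seeds collapse to dark outputs. All initialization
  is seeded; two builds with the same seed are bit-identical.
* **Engine.** The network runs on a compact reverse-mode autodiff engine
  (numpy, float32 for training), with convolution as im2col + GEMM. Every
  primitive's backward rule, and the whole network with its SSIM loss, are
  gradient-checked against central finite differences in float64.

## Training and evaluation

The loss is 1 − mean SSIM (Gaussian window 11, σ = 1.5, C₁ = (0.01·R)²,
C₂ = (0.03·R)², R = 1 on the pre-normalized channels, population
covariances, fully valid windows). The differentiable loss and the reported
SSIM metric share one implementation of the window, so
ssim_loss(x, y) = 1 − mean SSIM holds exactly; the metric is additionally
checked against scikit-image's implementation to 1e−6. PSNR is
10·log₁₀(R²/MSE), capped at 100 dB for identical images.

Optimizers: AdamW (β = (0.9, 0.999), ε = 1e−8, decoupled weight decay 0.01)
and Adagrad for the optimizer-comparison harness. The full-scale protocol is
AdamW, lr 1e−4, batch 64, 200 epochs, on 25,600 pairs of 192 × 192 images —
provided as the `full` preset but far beyond a single-CPU budget.

**Desk scale.** All tests and the acceptance script run a scaled-down
protocol chosen once as this package's own benchmark sizes: 32 × 32 HR
patches (LR 8 px; the 13 × 13 array and all other optics unchanged), 64
training pairs + 4 validation + 4 test, the tiny configuration (C = 16,
1 HAG × 2 RHABs, CA reduction 4), AdamW at lr 1e−4, batch 2, 40 epochs.
Under these conditions the trained network beats the one-sweep input
baseline on held-out intensity PSNR by ≈ +1.4 to +2 dB in 10/10 seeds while
reducing held-out SSIM loss from ≈ 0.89 to ≈ 0.49. Batch 2 rather than 64 is
deliberate: with Adam-family updates the per-step movement is ≈ lr, so at
lr = 1e−4 a small dataset needs many steps, not large batches.

## Synthetic data

Three procedural styles supply HR intensity/phase pairs with controllable
spectra: Gaussian-bump "blobs" with fine smoothed texture (sparse cell-like
objects), 1/f^β "fbm_texture" (tissue-like broadband texture), and a
period-4 "checker" blended with a smooth ramp (worst-case square-wave
harmonics). Intensity lies in [0.1, 1] — a non-zero background keeps phase
observable — and phase spans the full [0, 1] ↔ [−π, π] to exercise wrapping.
Every style carries ≥ 5% of its mean-removed spectral energy beyond the
coherent cutoff, so the LR input genuinely loses information. Intensity and
phase are independent draws; datasets are pure functions of their manifest
(byte-identical on rebuild), and `degrade_with_noise_level` re-simulates the
same HR content at a different σ for paired noise comparisons.

What the generator does *not* emulate: natural-image statistics, correlated
intensity/phase structure of real tissue, pupil aberrations, LED intensity
miscalibration, partial coherence, or camera-specific noise (shot noise,
fixed-pattern noise). Passing tests therefore demonstrate that the pipeline
is correct and trainable under the stated forward model, not that the
trained weights transfer to a physical microscope.

## Known limitations

* CPU-only numpy training: full-scale (192 px, C = 64, 25,600 pairs) is
  provided as configuration but is GPU-scale work.
* Nearest-pixel spectrum cropping limits LED-position fidelity to half a
  frequency pixel; fine for the default geometry, coarse for very small
  grids.
* The published PSNR/SSIM tables for this method depend on a non-deposited
  dataset and undisclosed hyperparameters; this package reproduces the
  method and its qualitative orderings (e.g. AdamW over Adagrad, hybrid
  attention over single-attention ablations at scale), not those numbers.
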