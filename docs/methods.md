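# Methods

## Problem and model

Coherent fiber bundles relay an endomicroscopic image through ~5,000-30,000
light-guiding cores. Under contact imaging each core integrates the tissue
intensity over its footprint and acts as a single-pixel detector, while the
non-guiding cladding between cores transmits nothing; the result is a mosaic
of constant-intensity core discs on a dark hexagonal lattice (the honeycomb
effect), with lateral resolution set by the core size (3-4 µm) rather than by
diffraction.

The method implemented here restores the underlying tissue from *multiple*
honeycomb frames taken under small bundle rotations. Rotating the bundle by
-10° to +10° in 2° steps (11 angles) moves the core lattice over the tissue,
so pixels hidden under cladding in one frame are sampled in another; across
the default synthetic bundle the union of the 11 core footprints covers ~95%
of the field versus ~80% for a single frame. The 11 frames (aligned to the
tissue, i.e. the mask rotates and no de-rotation is applied) are stacked as
input channels of a convolutional autoencoder that emits a single restored
grayscale image.

### Restoration network

Encoder: repeated [3×3 conv, "same" padding, ReLU] stages separated by 2×2
max-pooling; decoder: mirrored stages with 2× nearest-neighbour up-sampling;
head: 3×3 conv to one channel with a sigmoid, guaranteeing outputs in [0, 1]
(the output activation is a package choice). The multi-frame network (MFAE) takes 11 input channels; the
single-image variant (SIAE) is identical with one channel.

Stage widths and depth are free parameters. The package default is
(32, 64, 128). The scaled-down study uses (8, 16, 32, 64) — three pooling
stages — selected by validation loss among half a dozen variants on a
100-150-tile pilot under the same fixed optimization budget; depth (hence
receptive field, ~40 px versus the ~10 px core pitch) mattered more than
width.

The network, its layers and Adam are implemented in numpy with hand-written
backpropagation (`fibersr.nn`); convolutions are evaluated as im2col matrix
products. Everything is seeded: identical seeds and data reproduce parameters
and loss curves bit-for-bit on the same BLAS.

### Loss

    L = 0.001·MAE + 1.0·MSE + 0.001·(1 − SSIM)

MAE and MSE are plain pixel means. The SSIM term uses the single-window
(whole-image statistics) form of the similarity index, for which the analytic
gradient is implemented and verified against finite differences. Writing the
term as +w·(1−SSIM) makes the loss zero exactly at identity; a literal plain
sum of the three terms (+w·SSIM) would reward dissimilarity, and is
available behind a `literal_ssim_sign` flag for comparison. Weights,
optimizer (Adam, learning rate 1e-4, conventional moments) and the stopping
rule follow the published settings.

### Early stopping

Training stops when the validation loss fails to improve by `min_delta`
(1e-5 loss units; the tolerance for "does not change" is a package choice)
for 5 consecutive epochs; the parameters of the best validation epoch are
restored. The baseline validation loss is evaluated once before the first
epoch, so a perfectly flat validation curve stops after exactly 5 epochs.
Validation (not training) loss is monitored.

## Synthetic data

### Bundle geometry

Core centers are laid on a hexagonal lattice of pitch 3.3 µm, jittered by
isotropic Gaussian noise (σ 0.3 µm) and clipped to the field; radii are drawn
uniformly from 1.5-2.0 µm, so the mean core diameter is 3.5 µm, matching a
30,000-core, ~650 µm bundle imaged at 0.316 µm/px. Rotation is applied to
core-center coordinates analytically about the field center and the mask is
re-rasterized per angle, avoiding raster-resampling artifacts. A pixel
belongs to the nearest core whose radius covers its center; cladding is 0.
With these defaults cores may touch or slightly overlap (nearest center
wins), leaving a cladding fraction around 15-20%.

### Tissue phantoms

Ground-truth tiles emulate grayscale H&E histology: a bright stroma-like
background (0.65-0.90) with smooth low-frequency variation plus mild
fine-scale texture, and dark (0.08-0.30) non-overlapping ellipses for nuclei
with axis diameters drawn from 4.5-9.6 µm, the scale of prostate cell
nuclei. The bands are chosen so a grey-level threshold of 100/255 separates
nuclei from background unambiguously, which the diameter measurement relies
on. Nucleus positions and axes are recorded as ground truth.

What the phantoms do *not* model: H&E color (tiles are grayscale directly),
optical blur (contact imaging is assumed), staining variability, out-of-focus
regions, core-to-core crosstalk and transmission-coefficient dynamics.
Passing tests therefore demonstrate the pipeline's behaviour under ideal
aligned, noise-free conditions — they do not certify performance on real
fiber images, which are known to be substantially harder.

### Test patterns

Sinewave targets are horizontal full-contrast sinusoids (mean 0.5, Michelson
1.0); periods below 2 px are rejected as aliased. USAF-style three-bar
targets follow the 1951 chart formula, resolution = 2^(group+(element−1)/6)
line pairs/mm, line width = 500/resolution µm; group 4 element 1 gives
31.25 µm, which over a measured 99 px yields the 0.316 µm/px calibration
used throughout.

## Baselines

Gaussian blurring (σ = half the core pitch in pixels by default; no value is
published) and single-frame linear interpolation: per-core mean intensities
at core-footprint centroids are Delaunay-triangulated and interpolated with
barycentric (linear-precision) weights; pixels outside the convex hull are
left at 0, reproducing the dark seams reported when interpolated tiles are
stitched. The interpolation baseline operates on the 0° frame.

## Metrics and analyses

* **PSNR**: 10·log10(255²/MSE) on the 0-255 scale. The printed formula
  20·log10(255/MSE) is dimensionally inconsistent and only available behind
  a `literal_formula` flag.
* **SSIM**: windowed, 11×11 Gaussian window (σ 1.5), K1=0.01, K2=0.03,
  population statistics (delegated to scikit-image); a global single-window
  option matches the loss term. Summary tables report mean/max/min and the
  *population* standard deviation. The headline SSIM ratio between two
  methods is truncated (not rounded) to two decimals, so 0.83/0.42 → 1.97.
* **Nuclei diameters**: a line profile across the nucleus (bilinear, unit
  steps); the diameter is the longest run of samples strictly below
  threshold 100, times the pixel size. Longest-run (rather than total count)
  keeps isolated dark specks from inflating diameters; equality with the
  threshold counts as background.
* **MTF probe**: sinewave targets of decreasing period are forward-simulated
  through the bundle, reconstructed, and a sinusoid of the known period with
  free amplitude/phase/offset is least-squares fitted over the central
  quarter of rows; modulation = fitted amplitude/offset. Scanning stops at
  the first period whose modulation drops below 0.1 Michelson (the numeric
  criterion standing in for "visibly reconstructed"); the resolution limit
  is the smallest period of the initial passing run. Stopping at the first
  failure is deliberate: triangulated reconstructions show spurious
  above-criterion modulation at deeply aliased periods which a global
  minimum rule would mistake for resolution. Cycles/mm conversion uses
  1000/(period·pixel size).

## The scaled-down study

The canonical experiment (`fibersr.experiments.run_study`, also what
`scripts/acceptance.py` re-runs) uses 250 phantom tiles of 128×128 px at
0.316 µm/px, the default bundle, 11 angles, a 0.64/0.16/0.20
train/validation/test split (floor-rounded, remainder to training — the same
proportions as the published 1343/336/420), batch size 1, Adam 1e-4, at most
30 epochs with patience-5 early stopping. These sizes are the package's
choice of a CPU-scale stand-in for the published 1680-tile, 256-px, GPU
setup: 128 px keeps the 11×11 SSIM window's border band a small fraction of
the tile, and per-sample updates give the fixed learning rate enough
optimizer steps inside the epoch cap.

At this scale the study reproduces the qualitative claims: mean held-out
SSIM ordering MFAE > linear interpolation > raw frame, MFAE mean SSIM in the
~0.8 regime, and nuclei diameters better preserved by the MFAE than by
interpolation. One quantitative claim does not carry over: the full-scale
work reports the model resolving 9 px/cycle sinewaves versus 19 px/cycle for
interpolation, while the scaled-down model's limit lands near 14-15 px/cycle
— slightly *above* the interpolation baseline's ~13 px/cycle under the 0.1
fitted-modulation criterion. Two effects drive this: (i) 9 px/cycle lies at
the first zero of the averaging MTF of a 3.5 µm (11 px) core, so almost no
coherent modulation survives core averaging there, and (ii) the fitted
criterion credits the triangulation baseline for residual coherent energy
that a human "visibly reconstructed" judgment would likely reject. The
discrepancy is reported as measured rather than tuned away.

Two further published inconsistencies are preserved rather than resolved:
the source's tile-count arithmetic (1680 vs 2100 vs 1343+336+420 = 2099) —
tile count is a free parameter here — and its cycles/mm conversions (356 and
169 cycles/mm for 9 and 19 px at 0.316 µm/px; the stated pixel size actually
gives 351.6 and 166.6).

## Numerical and degenerate-input choices

* Overlapping core claims resolve to the nearest center; cores clipped at
  the field edge are kept while their centers are inside.
* Fewer than 3 or collinear core samples raise a degenerate-geometry error;
  an empty layout after clipping raises a degenerate-field error.
* Identical images flag PSNR as infinite rather than raising.
* The sinusoid fit returns modulation 0 when the fitted offset is ≤ 1e-9.
* Phantom packing aborts after 1000 rejection-sampling attempts.
* All randomness flows from `numpy.random.default_rng` seeds; derived seeds
  are drawn below 2^31.
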