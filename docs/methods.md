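# Methods

## Problem and pipeline

The package stages liver fibrosis (METAVIR F0–F4) from frames of
ultrasound-backscattered radiofrequency (RF) signals: 1247 axial samples ×
256 scan lines per frame, 3 MHz pulse center frequency, 12 MHz sampling.
The method is two-step: a 2D encoder–decoder network segments the liver
region of interest (ROI) from reconstructed B-mode images, then a 1D CNN
classifies per-line frequency spectra of the ROI-masked signals, with a
whole-frame majority vote over the 256 line predictions. Because clinical
RF data are not distributable, a phantom simulator generates labeled
frames with ground-truth masks; every empirical number the tests and
`scripts/acceptance.py` report is computed on those phantoms at run time.

## B-mode reconstruction

Envelope detection is the magnitude of the per-line analytic signal
(Hilbert transform); log compression maps envelope e to
`clip((20·log10(e/e_max) + DR)/DR, 0, 1)` with dynamic range DR = 40 dB by
default, so the frame maximum is white and signals DR below it are black.
No scan conversion is performed: images live on the sample × line grid.
Images are resized (bicubic) to 192 × 256 for training — or smaller
shapes in the desk-scale experiments — and masks are re-binarized at 0.5
after any interpolating resize.

## Dataset handling

Splits are participant-level: identifiers are shuffled by a seeded
generator; train and validation take `floor(r·N)` items and the test part
the remainder — the only rounding consistent with 613 → 367/122/124 at
60:20:20. Augmentation appends exactly one transformed copy per training
or validation image: a rotation drawn from {0°, 90°, 180°, 270°} (rotated
non-square results are resized back so batches stay rectangular), a
random 80–100%-area crop-and-resize, and ±10% brightness/contrast(/
saturation for 3-channel input) jitter applied to the image only.
Geometric transforms are applied identically to image and mask.

## Spectra and ROI spectrum signals

Per line, the spectrum is the full 1247-point two-sided FFT without
windowing or zero padding; amplitude = |S_F|, phase = angle(S_F) with
angle(0) := 0, power = |S_F|²/N, in standard FFT bin order. The binary
liver mask multiplies the spectrum frame elementwise on the shared
1247 × 256 grid — note the mask rows index depth while spectrum rows
index frequency; the product is taken literally, which is how the
upstream method is defined, not a physically motivated filter. The masked
frame is min–max normalized as a whole (masked zeros participate in
min/max), then gated: per line, the longest contiguous mask run is used;
a run of L ≥ 768 samples yields `floor((L−768)/20)+1` gate placements
("≥" so that an exactly fitting gate yields one segment; a strict-
inequality mode is available). Gated columns concatenate in line-then-
offset order into a 768 × L_lateral array; a 768 × 256 window slides
laterally in steps of `max(1, floor((L_lateral−256)/n_aug))`, start
positions clipped, emitting exactly n_aug windows. Balancing: frames are
split by participant first, then only minority-class *training* frames
receive n_aug = round(N_major/N_minor) windows (validation and test
frames one each). Splitting before windowing prevents near-duplicate
windows of one participant straddling parts; this deliberately reorders
the published augment-then-split sequence in favour of leakage safety.
Frames whose ROI holds no full gate cannot produce samples; the pipeline
drops them with a warning. On cohorts too small for every split part to
contain both classes (fewer frames of a class than parts), the pipeline
falls back to requiring mixed classes in train and test only, retrying
deterministically derived split seeds.

## Networks and training

Both networks run on a small NumPy engine (`rfpipe.nn`): convolutions are
im2col + GEMM in float32, pooling and activations are vectorized, and
every backward pass is finite-difference checked in the test suite. Adam
uses lr 2·10⁻⁴ and betas (0.9, 0.999) by default, the published training
setting; batch sizes default to 2 (segmentation) and 256 lines
(classification); the best-validation-loss parameters are retained.

*Segmentation.* Encoder levels are (3×3 conv + batch norm + ReLU)×2 with
2×2 max pooling; the decoder up-samples by 2×2 transpose convolution and
concatenates skip features; the attention variant gates each skip tensor
with additive attention (1×1 maps of gating and skip features, ReLU, 1×1
conv + sigmoid) before concatenation; a 1×1 convolution yields the
sigmoid logit map. Grayscale input is replicated to 3 channels. Default
widths are (32, 64, 128, 256, 512); the desk-scale experiments use
(8, 16, 32, 64) at 96 × 128, which train in minutes on one CPU. Because
batch 2 makes EMA batch-norm statistics noisy, training ends with a
batch-norm recalibration pass (exact pooled statistics over the training
set under the kept weights); without it, inference on homogeneous
low-stage livers fragments. Predicted masks may optionally be cleaned by
binary closing, hole filling, and largest-component selection
(`segnet.clean_mask`) — the pipeline does this before gating, since
speckle-sized holes would break the contiguous runs gating relies on.

*Classification.* Four (1D conv + tanh + max pool) stages then four
fully-connected layers ending in 2 logits; every one of a gated sample's
256 lines is an independent training instance with the sample's label.
Default channels are (8, 16, 32, 32) with kernels (7, 5, 5, 3), pools of
2, and fully-connected widths (256, 64, 16, 2) — layer sizes are not
fixed by the published method; these defaults are sized so a 30-epoch
training run of the reference experiment takes a few minutes on one CPU
core. At test time the frame is correct only when the fraction of
agreeing lines strictly exceeds 0.5; a 128–128 tie therefore counts as
incorrect, and the reported predicted class at a tie is the one opposite
the true label, consistent with that strict rule. The continuous frame
score for ROC analysis is the mean positive-class probability over the
256 lines (the published method reports AUC without defining a frame
score; the mean probability is the natural choice).

## Metrics

Segmentation: Jaccard, Dice, accuracy, sensitivity, precision,
specificity from pixel counts; two identical empty masks score 1 and are
flagged. Cohort values are per-image means by default (macro); pooled-
pixel (micro) mode is available, since the published cohort averages do
not state which was used. Classification: accuracy, sensitivity,
specificity from frame-level confusion counts; ROC/AUC by threshold sweep
over unique scores with trapezoidal area (scikit-learn's curve routine),
which the tests verify equals the tie-aware Mann–Whitney statistic.

## Phantom simulator

Each scan line is an impulse train convolved with a unit-peak
Gaussian-enveloped cosine (3 MHz at 12 MHz sampling, fractional −6 dB
bandwidth 0.6 by default; the resolution cell is the −6 dB envelope
length, ≈ 5.9 samples). The liver band lies between two cosine-perturbed
boundary curves; the top base is drawn from [150, 350] samples and the
bottom jointly from [max(900, top + 768 + 2·wobble + 10), 1200] so every
frame keeps lines eligible for the 768-point gate. Outside the band, a
brighter wall stands in for the abdominal wall and sub-hepatic
interfaces (relative echogenicity 4.0, density 12 per cell) — strongly
echogenic interfaces versus parenchyma, as in vivo, and the contrast cue
the segmentation networks learn.

Stage dependence: diffuse scatterer density 10·(1 + 0.4·s) per
resolution cell and amplitude coefficient of variation 0.3·(1 + 0.3·s)
make the mean liver envelope monotone in stage; additionally, fibrotic
stages gain sparse bright discrete scatterers (septa-like; Poisson rate
1.5·s per line at amplitude 2× the diffuse per-bin spectral RMS). The
discrete component is essential: by the central limit theorem, diffuse
density and amplitude-spread changes leave the *normalized* spectra
statistically almost unchanged (the spectrum tends to a circular Gaussian
whose overall scale the min–max normalization removes), whereas a few
strong coherent scatterers alter the local phase and amplitude statistics
of every bin — the classical coherent-scattering signature of fibrotic
structure, and what makes phase-spectrum classification work here. A
single `effect_scale` knob scales the stage maps for
sensitivity/ablation studies. Envelope statistics reach the Rayleigh
limit (SNR → 1.91) as density grows, which the tests verify by Monte
Carlo.

What the simulator does **not** model: lateral point-spread coupling
(each line is independent), attenuation and dispersion, nonlinear
propagation, scan geometry, and any claim that the stage→parameter maps
match clinical effect sizes. Passing tests therefore demonstrate that the
pipeline's machinery — reconstruction, segmentation, spectral features,
augmentation, training, voting, metrics — behaves correctly and can
recover a known class structure; they do not certify clinical staging
performance.

## Desk-scale experiment sizes

`experiments.classifier_recovery`: 40 frames (20 each of F0 and F4,
effect_scale 2.0), ground-truth masks, phase spectra, 80:10:10 split,
default 1D CNN, 30 epochs — a few minutes on one CPU
(`scripts/acceptance.py` runs it at 15 epochs; the validation loss is
flat well before that).
`experiments.segmentation_recovery`: 60 frames (stages cycling 0–4),
96 × 128 inputs, widths (8, 16, 32, 64), 20 epochs for both U-Net and
Attention U-Net — about three minutes. This experiment trains at lr 10⁻³
rather than the standard protocol's 2·10⁻⁴: with 5× fewer epochs than
the standard 100, proportionally larger steps converge far more reliably;
residual seed-to-seed variance (occasional hard boundary geometries in a
12-frame test part) remains and is visible in the reported Dice. The end-to-end pipeline smoke
config uses 10 frames with a 20-epoch segmentation net and a micro
classifier. These sizes are the package's reference conditions for its
own validation; all are configurable.

## Numerical choices and degenerate inputs

angle(0) := 0; all-zero envelopes are rejected in log compression (no
reference maximum); constant ROI frames are rejected by normalization;
min–max normalization is idempotent. Mask binarization after bicubic
resize uses 0.5. Ties in the 2×2/1×2 max-pool fast paths resolve to the
earlier element, matching argmax semantics. Window steps are floored with
a minimum of 1 and start positions clipped so windows always fit; frames
narrower than 256 gated columns are an error unless lateral
reflect-padding is explicitly enabled. Seeds: one master seed; per-frame
and per-stage seeds derive from it by a counter-based SHA-256 hash, so
datasets are order-independent and every stage of the pipeline is
bit-reproducible on CPU.
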