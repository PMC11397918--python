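# rfpipe

Quantitative-ultrasound analysis of backscattered radiofrequency (RF)
signals for liver fibrosis staging, with a synthetic RF phantom simulator
so the whole pipeline is trainable and testable without clinical data.

## The method

An acquisition is a frame of 1247 samples × 256 scan lines recorded at a
12 MHz sampling rate with a 3 MHz pulse. The pipeline stages a liver in
two steps:

1. **Liver-ROI segmentation.** B-mode images are reconstructed on the raw
   grid (Hilbert-transform envelope per line, logarithmic compression to a
   40 dB dynamic range, no scan conversion), resized to 192 × 256, and fed
   to a 2D encoder–decoder network — U-Net or Attention U-Net, i.e.
   (3×3 conv + batch norm + ReLU)×2 and 2×2 max pooling per encoder level,
   transpose-convolution up-sampling with (optionally attention-gated) skip
   connections, trained with binary cross-entropy and Adam
   (lr 2·10⁻⁴, betas 0.9/0.999, batch 2). The predicted mask is resized
   back to 1247 × 256 (bicubic, re-binarized at 0.5).

2. **Spectral classification.** Each scan line s yields a full-length
   two-sided FFT, S_F = fft(s), from which three spectra are formed:
   amplitude |S_F|, phase angle(S_F), and power |S_F|²/N. The spectrum
   frame is multiplied elementwise by the binary liver mask, min–max
   normalized over the frame, R′ = (R − R_min)/(R_max − R_min), and cut
   into classifier inputs: a 768-point axial gate slides down each
   eligible line (liver run ≥ 768) in steps of 20, the gated columns are
   concatenated, and a 768 × 256 lateral window slides across them in
   steps of (L_lateral − 256)/N_aug, where N_aug = round(N_major/N_minor)
   balances the classes (training portion only). A 1D CNN — four
   (conv + tanh + max-pool) stages and four fully-connected layers —
   classifies each of a frame's 256 lines; the frame counts as correctly
   staged when the fraction of agreeing lines p = n_c/(n_c + n_w) strictly
   exceeds 0.5. Four binary tasks are evaluated: ≥F1, ≥F2, ≥F3, ≥F4 on the
   METAVIR scale.

Both networks run on a compact NumPy engine (`rfpipe.nn`: im2col + GEMM
convolutions, manual backprop, Adam) validated by finite-difference
gradient checks, so the package has no deep-learning framework dependency
and is exactly reproducible from a seed on CPU.

The phantom simulator (`rfpipe.sim`) draws per-line scatterer impulse
trains convolved with a Gaussian-enveloped 3 MHz pulse: a liver band
between smooth boundary curves with stage-dependent diffuse scatterer
density and amplitude variability plus stage-dependent sparse bright
(septa-like) scatterers, and brighter wall-like bands outside. Envelope
statistics reach the Rayleigh speckle limit (SNR → 1.91) at high density.

## Worked example

```python
import numpy as np
from rfpipe import experiments

res = experiments.classifier_recovery(seed=1)
print({k: round(v, 3) if isinstance(v, float) else v for k, v in res.items()})
```

prints (exact numbers are seed-reproducible):

```
{'frame_accuracy': 1.0, 'vote_accuracy': 1.0, 'auc': 1.0,
 'n_test_frames': 4, 'final_val_loss': 0.001}
```

i.e. with a strong simulated stage effect, the 1D CNN trained for 30
epochs on normalized ROI **phase** spectra of 40 phantoms separates
no-fibrosis from cirrhotic frames perfectly on the held-out frames:
every per-line vote fraction p exceeds 0.5 for the true class, and the
frame scores (mean positive-class probability over the 256 lines) rank
all positives above all negatives (AUC 1.0).

The same end-to-end flow, starting from raw simulated RF and including
the trained segmentation masks, is driven by a declarative YAML config:

```sh
rfpipe run --config examples/pipeline.yaml --seed 7
```

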