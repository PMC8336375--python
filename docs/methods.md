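# Methods

This document specifies the algorithms and protocols implemented in
`pathospeech`, and records the desk-scale choices made so the full
pipeline runs on a single CPU in minutes.

## 1. Audio front-end

Clips are decoded from WAV (PCM 8/16/32-bit or float), averaged to
mono, scaled to [-1, 1] and resampled to 44.1 kHz with a polyphase
filter (`pathospeech.audio`).

Spectrograms are short-time Fourier transforms with `n_fft` 2048, hop
512 and a Hann window. Magnitudes are converted to dB referenced to the
per-clip spectral peak and floored 80 dB below it, so digital silence
stays finite. The network input is the dB matrix resized bilinearly to
128 frequency rows × 256 time columns and standardized per image to
zero mean, unit variance (`pathospeech.spectrogram`). The mapping from
image row to center frequency (`net_input_row_freqs`) follows the pixel
centers of the bilinear resize and is used by the band statistics of
the activation maps.

## 2. Detector architecture

`SkipAttentionNet` (`pathospeech.model`) consists of:

- Four double-convolution blocks (3×3 kernels, Conv→BatchNorm→ReLU
  twice, then 2×2 max pooling) with 64/128/256/512 filters at full
  width, taking the 128×256×1 image down to an 8×16×512 map.
- Skip connections: the outputs of blocks 1–3 are average-pooled to
  8×16 (strides 8/4/2), projected by per-tap 3×3 convolutions to 512
  channels each, and concatenated with the backbone output into a
  2048-channel merged map.
- A convolutional block attention module (CBAM): channel gating by a
  shared two-layer MLP (reduction 16) over the spatial average- and
  max-pooled descriptors, followed by spatial gating by a 7×7
  convolution over the channel mean and max; both gates are sigmoids.
- A 512-filter 3×3 fusion convolution, global average pooling, and a
  512→2 fully connected head with softmax output. The patient class is
  class 1.

The main path therefore has exactly 12 convolution layers (8 backbone +
3 skip projections + 1 fusion); at full width the model has 16,982,053
parameters. `width_scale` multiplies every filter/unit count (the
2-way output is fixed) so the same architecture runs at desk scale.
Ablation variants: `backbone` (neither skips nor CBAM), `backbone_sc`
(skips only), `backbone_cbam` (CBAM only), `full`.

The network and its gradients run on a small reverse-mode array engine
(`pathospeech.nn`): channels-last layout, explicit backward closures per
operation, finite-difference-checked in the test suite.

## 3. Training and evaluation protocol

Training (`pathospeech.training`) uses Adam at 3e-4, batch size 16,
softmax cross-entropy, and a step schedule dividing the learning rate
by 10 after 25 epochs; default 50 epochs. Shuffling, initialization and
therefore the entire run are determined by the config seeds.

Augmentation (`pathospeech.augment`) offers pad-and-crop (8 px),
rotation (±5°), rescaling (0.9–1.1), additive Gaussian noise (5 % of
image sd) and frequency/time masking (up to 16 rows / 32 columns),
applied to training batches only.

Cross-validation (`pathospeech.crossval`) is repeated stratified k-fold:
by default 30 iterations of 10-fold CV, each iteration reseeded, with
metrics computed once per iteration on the pooled out-of-fold scores.
Subject-disjoint folds (`StratifiedGroupKFold`) are used whenever
subject identifiers exist. Reports carry per-iteration values and 95 %
normal-approximation confidence intervals (mean ± 1.96·sd/√n; exactly
zero-width for constant iterations).

Seven metrics are reported (`pathospeech.metrics`): accuracy,
precision, recall, F1, sensitivity (= recall of the patient class),
specificity, and rank-statistic AUC with half-credit for ties.
Zero-denominator ratios report 0 with a warning; one-class AUC is NaN
with a warning.

Hold-out experiments (`pathospeech.experiments.train_holdout`) carve
one stratified, subject-disjoint fold (test fraction 0.25 by default,
clamped to the number of available subjects) and report held-out
metrics.

## 4. Class activation maps

`pathospeech.gradcam` computes gradient-weighted class activation maps
at the last convolution (the fusion conv, post BN+ReLU): the target
logit's gradient is spatially averaged per channel, the weighted
activation sum is rectified and bilinearly upsampled to 128×256. Because
the gradient is taken on the pre-softmax logit, the map is invariant to
shifting all logits. `band_energy_share` reports the fraction of heat
mass above a cutoff frequency via the row→frequency mapping;
`band_share_study` compares the above-5 kHz share between classes with
a one-sided Mann-Whitney rank test (control > patient).

## 5. Acoustic features

All features use 25 ms frames with a 10 ms hop (Hamming window where
windowing applies).

- **Short-term energy**: windowed frame energies summarized by mean,
  sd, max, min, skewness, excess kurtosis (6 values).
- **Pitch**: normalized autocorrelation peak in the 75–500 Hz lag band;
  frames are voiced at peak ≥ 0.3. Summary: voiced mean, sd, range,
  voiced fraction (4 values).
- **Voice activity / fluency**: frames below −35 dB relative to the
  loudest frame are silent; pauses shorter than 0.15 s are absorbed,
  then speech bursts shorter than 0.1 s are discarded. Pauses are
  reported as the full extent of the all-silent frames; speech is the
  complement, which recovers constructed segmentations within one hop.
  Syllable nuclei are energy peaks (≥3 dB prominence, ≥0.1 s apart)
  inside voiced segments. Fluency vector: total time, voiced time,
  voiced ratio, max pause, mean syllable length (5 values).
- **LTAS**: time-mean of the dB spectrogram averaged into 128 bands.
- **MFCC**: 26 triangular mel filters, 13 orthonormal DCT-II
  coefficients; per-clip summary is mean and sd of each (26 values).
- **GTCC**: like MFCC but 64 gammatone magnitude responses, ERB-rate
  spaced on [50 Hz, Nyquist] with ERB(f) = 24.7·(4.37 f/1000 + 1),
  4th-order peak-normalized filters (26 values).
- **Linear prediction family**, order 38, coefficients averaged over
  frames (38 values each):
  - plain LP — biased autocorrelation, Toeplitz solve;
  - WLP — weighted covariance equations with the short-time-energy
    weight w(n) = Σ_{i=1..38} x²(n−i);
  - SWLP — stabilized weight built from a clamped square-root energy
    recursion, plus reflection of any remaining pole into the unit
    circle, so the model is always stable;
  - XLP — per-lag weighting z_k(n) = w_k(n)·x(n−k) with
    w_k(n) = (|x(n)| + |x(n−k)|)/2.
  Singular normal equations fall back to a small ridge with a warning.

## 6. Classic-classifier benchmark

`pathospeech.baselines` evaluates random forest (500 trees), k-NN
(k = 5, Euclidean), RBF SVM (C = 1, gamma = 1/n_features) and LDA over
any selection of feature sets. Every fold fits a fresh pipeline of
zero-variance-column dropping, z-scoring and the classifier, so no
statistic leaks from the test folds. Results form the classifier ×
feature-set accuracy grid.

## 7. Synthetic two-class data

`pathospeech.synth` generates clips from a source-filter model: voiced
segments are impulse trains at an Ornstein-Uhlenbeck-wandering F0
(mean 120 Hz) with a −12 dB/octave source tilt through a four-formant
resonator cascade; consonants are high-passed (3 kHz) noise; pauses are
near-silence with a −60 dB noise floor; all segments get 10 ms fades,
a class low-pass and peak normalization.

Default class parameters plant the contrasts the pipeline should find:

| parameter | control (0) | patient (1) |
|---|---|---|
| F0 sd (Hz) | 30 | 4 |
| low-pass cutoff (kHz) | 16 | 5 |
| pause rate (/s) | 0.2 | 0.6 |
| pause duration (s) | 0.3–0.6 | 0.6–1.2 |
| devoiced-consonant probability | 0 | 0.6 |

Every clip carries exact segment annotations and its true F0 contour;
per-clip seeds derive deterministically from the master seed. Subject
identifiers group four consecutive clips per synthetic speaker, so
subject-disjoint protocols are exercised realistically.

## 8. Desk-scale study conditions

The end-to-end checks and `scripts/acceptance.py` run the pipeline at
sizes chosen for single-CPU wall-clock budgets; these are the package's
own choices:

- quarter-width network (`width_scale` 0.25), 240 clips (120 per class,
  5 s) in the test suite, 10 training epochs, subject-disjoint hold-out
  with test fraction 0.25;
- the ablation runner trains all four variants under one shared,
  shorter protocol (2 epochs) on the same data and split procedure —
  the point of the table is the like-for-like comparison, not each
  variant's ceiling;
- augmentation is disabled in these short runs (it slows convergence
  at this scale and the synthetic contrasts do not require it);
- the classic-feature baseline uses a single CV iteration
  (10 folds) instead of the full 30-iteration protocol;
- `scripts/acceptance.py` uses 80 clips and 6 epochs to stay well
  inside its budget.

All randomness flows from explicit seeds; reruns with the same
configuration reproduce identical numbers.
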