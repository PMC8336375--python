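# pathospeech

Detection of pathological speech from spectrograms with a skip-attention
convolutional network, plus the classical acoustic-feature toolkit to
benchmark it against — all in pure scientific Python (NumPy/SciPy/
scikit-learn; the network and its training run on a small built-in
reverse-mode array engine, no deep-learning framework required).

The package contains:

- **Audio front-end** — WAV decoding to mono float, log-magnitude STFT
  spectrograms, and the fixed 128×256 standardized network input image
  (`pathospeech.audio`, `pathospeech.spectrogram`).
- **Detector** — a VGG-style backbone with skip connections into a
  2048-channel merge, a convolutional block attention module (CBAM) and
  a 512→2 softmax head; 12 convolution layers and ~17 M parameters at
  full width, proportionally thinner via `width_scale`
  (`pathospeech.model`).
- **Training & evaluation** — Adam with a step learning-rate schedule,
  repeated stratified (optionally subject-disjoint) k-fold
  cross-validation, and seven metrics with normal-approximation
  confidence intervals (`pathospeech.training`, `pathospeech.crossval`,
  `pathospeech.metrics`).
- **Explanations** — gradient-weighted class activation maps taken at
  the last convolution, with per-band heat-share statistics and overlay
  rendering (`pathospeech.gradcam`).
- **Acoustic features** — short-term energy, autocorrelation pitch,
  voice-activity detection and fluency statistics, LTAS, MFCC, GTCC
  (ERB-spaced gammatone bank), and the order-38 linear-prediction
  family LP / WLP / SWLP / XLP (`pathospeech.features`).
- **Baselines** — random forest, k-NN, RBF SVM and LDA over any feature
  set under one leakage-free cross-validation protocol
  (`pathospeech.baselines`).
- **Synthetic data** — a source-filter speech generator producing two
  classes with planted, annotated contrasts (band limitation, flattened
  pitch, longer pauses), so every stage can be validated end to end
  without clinical recordings (`pathospeech.synth`).

## Command-line quickstart

```sh
# 1. generate a 100-clip synthetic dataset with truth annotations
pathospeech synth data/ --n-per-class 50 --seed 0

# 2. cache the 128x256 network inputs
pathospeech prepare data/manifest.csv

# 3. train the detector on a subject-disjoint split
pathospeech train data/manifest.csv --config my_run.yaml

# 4. ablation table (backbone / +skips / +attention / full)
pathospeech ablate data/manifest.csv --config my_run.yaml

# 5. classic-classifier benchmark grid
pathospeech baseline data/manifest.csv --config my_run.yaml

# 6. class activation maps and band statistics for a trained model
pathospeech gradcam data/manifest.csv runs/train_*/model.npz
```

Every command writes an immutable `config.yaml` plus a `run_log.json`
(config hash, seeds, library versions) into a fresh run directory.
`my_run.yaml` may override any field of
`pathospeech.config.RunConfig`; missing fields keep their defaults.

## Library quickstart

```python
import numpy as np
from pathospeech.datasets import images_from_clips
from pathospeech.experiments import train_holdout
from pathospeech.model import NetConfig
from pathospeech.synth import generate_clips, subject_ids
from pathospeech.training import TrainConfig

clips = generate_clips(n_per_class=40, duration_s=5.0, seed=0)
labels = np.array([c.label for c in clips])
run = train_holdout(images_from_clips(clips), labels, subject_ids(clips),
                    NetConfig(width_scale=0.25), TrainConfig(epochs=6))
print(run.metrics.values())
```

## Testing

```sh
pytest tests/
```

The suite includes fast unit tests and a desk-scale end-to-end check
(synthesize → train → evaluate → explain) that takes several minutes on
one CPU.  A standalone end-to-end run with a JSON summary:

```sh
python scripts/acceptance.py --seed 1 --out results.json
```

See `docs/methods.md` for the full description of the architecture,
protocols, feature definitions and the synthetic data generator.
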