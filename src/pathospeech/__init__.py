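"""Pathological-speech detection from spectrograms.

A skip-attention convolutional detector over log-magnitude STFT images,
the training/cross-validation/metric protocol around it, gradient-based
class activation maps, a bank of classic acoustic features with four
baseline classifiers, and a synthetic two-class speech generator for
end-to-end testing without clinical data.
"""

__version__ = "0.1.0"

from .audio import AudioClip, load_audio, save_wav
from .model import NetConfig, SkipAttentionNet, build_model
from .spectrogram import (NET_INPUT_SHAPE, NetInputImage, SpectrogramMatrix,
                          clip_to_net_input, compute_spectrogram, to_net_input)
from .training import TrainConfig, train_model
from .crossval import CVProtocol, CVReport, cross_validate
from .metrics import ConfusionCounts, MetricRecord, compute_metrics

__all__ = [
    "__version__", "AudioClip", "load_audio", "save_wav",
    "NetConfig", "SkipAttentionNet", "build_model",
    "NET_INPUT_SHAPE", "NetInputImage", "SpectrogramMatrix",
    "clip_to_net_input", "compute_spectrogram", "to_net_input",
    "TrainConfig", "train_model", "CVProtocol", "CVReport", "cross_validate",
    "ConfusionCounts", "MetricRecord", "compute_metrics",
]
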