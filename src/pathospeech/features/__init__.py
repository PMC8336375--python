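"""Per-clip acoustic feature bank for the classic-classifier benchmark.

Ten named feature sets, each mapping a clip to a fixed-length vector:
``ste`` (6), ``pitch`` (4), ``fluency`` (5), ``ltas`` (128),
``spectrogram`` (512, an 8x mean-pooled network input image), ``mfcc``
(26), ``gtcc`` (26) and the order-38 linear-prediction family ``lp`` /
``swlp`` / ``xlp`` (38 each, coefficients averaged over frames).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..audio import AudioClip
from ..spectrogram import clip_to_net_input, compute_spectrogram
from .lpc import LPModel, lp_family
from .prosody import (FLUENCY_NAMES, FrameSpec, VADSegmentation, fluency_features,
                      frame_signal, pitch_track, short_term_energy, syllable_nuclei,
                      vad_segment)
from .spectral import gtcc, ltas, mfcc

FEATURE_SETS = ("ste", "pitch", "fluency", "ltas", "spectrogram",
                "mfcc", "gtcc", "lp", "swlp", "xlp")

__all__ = ["FEATURE_SETS", "ClipFeatures", "extract_feature_set", "feature_length",
           "FrameSpec", "VADSegmentation", "LPModel", "lp_family",
           "short_term_energy", "pitch_track", "vad_segment", "fluency_features",
           "syllable_nuclei", "ltas", "mfcc", "gtcc", "frame_signal"]


@dataclass
class ClipFeatures:
    feature_set_name: str
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self):
        if len(self.values) != len(self.names):
            raise ValueError("values and names disagree in length")
        if not np.isfinite(self.values).all():
            raise ValueError(f"non-finite values in feature set {self.feature_set_name}")


def _lp_set(clip: AudioClip, weighting: str, order: int, fs: FrameSpec) -> np.ndarray:
    frames = frame_signal(clip.samples, fs.frame_len(clip.sample_rate),
                          fs.hop(clip.sample_rate))
    if frames.shape[1] <= 2 * order:
        raise ValueError("frames too short for the LP order")
    coeffs = [lp_family(f, order=order, weighting=weighting).coefficients
              for f in frames]
    return np.mean(coeffs, axis=0)


def _pooled_spectrogram(clip: AudioClip, pool: int = 8) -> np.ndarray:
    img = clip_to_net_input(clip).pixels
    h, w = img.shape
    return img.reshape(h // pool, pool, w // pool, pool).mean(axis=(1, 3)).ravel()


def extract_feature_set(clip: AudioClip, set_name: str,
                        fs: FrameSpec = FrameSpec(), lp_order: int = 38
                        ) -> ClipFeatures:
    """Compute one named feature set for a clip (deterministic)."""
    if set_name not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {set_name!r}; valid: {FEATURE_SETS}")
    if set_name == "ste":
        _, values = short_term_energy(clip, fs)
        names = ("mean", "sd", "max", "min", "skewness", "kurtosis")
    elif set_name == "pitch":
        _, values = pitch_track(clip, fs)
        names = ("f0_mean", "f0_sd", "f0_range", "voiced_fraction")
    elif set_name == "fluency":
        seg = vad_segment(clip, fs=fs)
        values = fluency_features(seg, syllable_nuclei(clip, seg, fs))
        names = FLUENCY_NAMES
    elif set_name == "ltas":
        values = ltas(compute_spectrogram(clip))
        names = tuple(f"band_{i:03d}" for i in range(len(values)))
    elif set_name == "spectrogram":
        values = _pooled_spectrogram(clip)
        names = tuple(f"px_{i:03d}" for i in range(len(values)))
    elif set_name == "mfcc":
        _, values = mfcc(clip, fs)
        n = len(values) // 2
        names = tuple(f"c{i}_mean" for i in range(n)) + tuple(f"c{i}_sd" for i in range(n))
    elif set_name == "gtcc":
        _, values = gtcc(clip, fs)
        n = len(values) // 2
        names = tuple(f"g{i}_mean" for i in range(n)) + tuple(f"g{i}_sd" for i in range(n))
    else:  # lp / swlp / xlp
        weighting = "none" if set_name == "lp" else set_name
        values = _lp_set(clip, weighting, lp_order, fs)
        names = tuple(f"a{i + 1}" for i in range(len(values)))
    return ClipFeatures(feature_set_name=set_name,
                        values=np.asarray(values, dtype=float), names=names)


def feature_length(set_name: str, lp_order: int = 38) -> int:
    fixed = {"ste": 6, "pitch": 4, "fluency": 5, "ltas": 128,
             "spectrogram": 512, "mfcc": 26, "gtcc": 26}
    if set_name in fixed:
        return fixed[set_name]
    if set_name in ("lp", "swlp", "xlp"):
        return lp_order
    raise ValueError(f"unknown feature set {set_name!r}; valid: {FEATURE_SETS}")
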