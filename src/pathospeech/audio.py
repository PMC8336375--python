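"""WAV decoding and the universal in-memory audio record.

Clips are always reduced to mono float samples in [-1, 1].  Stereo
recordings are averaged across channels; integer PCM is rescaled by the
type's full-scale value.  Resampling uses a polyphase filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly


class AudioDecodeError(RuntimeError):
    pass


class EmptyAudioError(ValueError):
    pass


@dataclass
class AudioClip:
    """Mono waveform with its sample rate.

    samples are float in [-1, 1]; ``duration_s`` is derived.
    """

    samples: np.ndarray
    sample_rate: int
    n_channels: int = 1  # channel count of the source, before mixdown
    source: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip stores mono samples (1-D array)")
        if self.samples.size == 0:
            raise EmptyAudioError("zero-length audio")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be a positive integer")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate


_PCM_SCALE = {np.dtype(np.int16): 32768.0,
              np.dtype(np.int32): 2147483648.0,
              np.dtype(np.uint8): 128.0}


def load_audio(path: str | Path, target_rate: int = 44100) -> AudioClip:
    """Decode a WAV file to a mono ``AudioClip`` at ``target_rate``.

    PCM 16-bit (and 32-bit/8-bit/float) WAV is accepted; stereo is
    averaged to mono; amplitudes are scaled to [-1, 1].
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / non-WAV payloads
        raise AudioDecodeError(f"cannot decode WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise EmptyAudioError(f"zero-length audio in {path}")
    n_channels = 1 if data.ndim == 1 else data.shape[1]
    x = data.astype(np.float64)
    if data.dtype in _PCM_SCALE:
        x = x / _PCM_SCALE[data.dtype]
        if data.dtype == np.dtype(np.uint8):  # unsigned 8-bit is offset binary
            x = x - 1.0
    if x.ndim == 2:
        x = x.mean(axis=1)
    if rate != target_rate:
        g = math.gcd(int(target_rate), int(rate))
        x = resample_poly(x, target_rate // g, rate // g)
    np.clip(x, -1.0, 1.0, out=x)
    return AudioClip(samples=x, sample_rate=int(target_rate),
                     n_channels=n_channels, source=str(path))


def save_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV."""
    pcm = np.clip(np.round(clip.samples * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(Path(path), clip.sample_rate, pcm)
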