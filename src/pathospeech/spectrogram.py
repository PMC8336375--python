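"""Log-magnitude STFT spectrograms and the fixed network input image.

The network consumes a linear-frequency STFT image resized bilinearly
to 128 rows (frequency, low to high) x 256 columns (time) and then
standardized per image to zero mean / unit variance.  Defaults follow
standard wideband speech analysis at 44.1 kHz: n_fft 2048, hop 512,
Hann window, dB magnitudes floored 80 dB below the per-clip maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window, stft as _scipy_stft
from skimage.transform import resize as _resize

from .audio import AudioClip

NET_INPUT_SHAPE = (128, 256)
DB_FLOOR_RANGE = 80.0


class ClipTooShortError(ValueError):
    pass


@dataclass
class SpectrogramMatrix:
    """dB magnitudes, rows = frequency bins (row 0 = DC), cols = frames."""

    values: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    n_fft: int
    hop_length: int
    window_name: str
    sample_rate: int

    @property
    def n_freq_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class NetInputImage:
    """128x256 standardized image (zero mean, unit variance per image)."""

    pixels: np.ndarray
    provenance: str = ""
    sample_rate: int = 44100
    n_fft: int = 2048


def compute_spectrogram(clip: AudioClip, n_fft: int = 2048, hop_length: int = 512,
                        window_name: str = "hann") -> SpectrogramMatrix:
    """Log-magnitude STFT of a clip.

    The dB matrix is floored at (max - 80 dB) so values stay finite on
    digital silence.
    """
    if n_fft < 256 or (n_fft & (n_fft - 1)) != 0:
        raise ValueError("n_fft must be a power of two >= 256")
    if hop_length < 1:
        raise ValueError("hop_length must be >= 1")
    if clip.samples.size < n_fft:
        raise ClipTooShortError(
            f"clip has {clip.samples.size} samples but one frame needs {n_fft}")
    win = get_window(window_name, n_fft, fftbins=True)
    freqs, times, z = _scipy_stft(clip.samples, fs=clip.sample_rate, window=win,
                                  nperseg=n_fft, noverlap=n_fft - hop_length,
                                  boundary=None, padded=False, scaling="spectrum")
    mag = np.abs(z)
    peak = mag.max()
    if peak <= 0.0:
        db = np.full_like(mag, -DB_FLOOR_RANGE)
    else:
        floor = peak * 10.0 ** (-DB_FLOOR_RANGE / 20.0)
        db = 20.0 * np.log10(np.maximum(mag, floor))
        db -= 20.0 * np.log10(peak)  # 0 dB at the clip's spectral peak
    return SpectrogramMatrix(values=db, freq_axis=freqs, time_axis=times,
                             n_fft=n_fft, hop_length=hop_length,
                             window_name=window_name, sample_rate=clip.sample_rate)


def standardize(img: np.ndarray) -> np.ndarray:
    """Per-image z-scoring; a constant image maps to all zeros."""
    sd = img.std()
    if sd < 1e-12:
        return np.zeros_like(img)
    return (img - img.mean()) / sd


def to_net_input(spec: SpectrogramMatrix, provenance: str = "") -> NetInputImage:
    """Bilinear resize of the dB matrix to 128x256, then standardize."""
    if spec.values.size == 0:
        raise ValueError("empty spectrogram")
    resized = _resize(spec.values, NET_INPUT_SHAPE, order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)
    return NetInputImage(pixels=standardize(resized).astype(np.float64),
                         provenance=provenance, sample_rate=spec.sample_rate,
                         n_fft=spec.n_fft)


def net_input_row_freqs(sample_rate: int = 44100, n_fft: int = 2048,
                        n_rows: int = NET_INPUT_SHAPE[0]) -> np.ndarray:
    """Center frequency (Hz) of each row of the 128-row network image.

    Rows arise from a bilinear resize of the n_fft/2+1 STFT bins; pixel
    centers map linearly between the two grids.
    """
    n_bins = n_fft // 2 + 1
    bin_coord = (np.arange(n_rows) + 0.5) * n_bins / n_rows - 0.5
    return np.clip(bin_coord, 0, n_bins - 1) * sample_rate / n_fft


def clip_to_net_input(clip: AudioClip, n_fft: int = 2048, hop_length: int = 512,
                      window_name: str = "hann", provenance: str = "") -> NetInputImage:
    return to_net_input(compute_spectrogram(clip, n_fft, hop_length, window_name),
                        provenance=provenance)
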