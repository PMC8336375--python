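"""FFT-based and auditory spectral features: LTAS, MFCC, GTCC.

MFCC uses 26 triangular mel filters and 13 DCT-II (orthonormal)
coefficients; GTCC replaces the mel bank with 64 gammatone magnitude
responses whose center frequencies are ERB-rate spaced on [50 Hz,
Nyquist], ERB(f) = 24.7 * (4.37 f / 1000 + 1).
"""

from __future__ import annotations

import numpy as np
from scipy.fft import dct
from scipy.signal import get_window

from ..audio import AudioClip
from ..spectrogram import SpectrogramMatrix
from .prosody import FrameSpec, frame_signal

_LOG_FLOOR = 1e-10


def ltas(spec: SpectrogramMatrix, n_bins_out: int = 128) -> np.ndarray:
    """Long-term average spectrum: time-mean of the dB spectrogram,
    averaged down to ``n_bins_out`` frequency bands."""
    if spec.n_frames < 1:
        raise ValueError("spectrogram has no frames")
    if n_bins_out < 1 or n_bins_out > spec.n_freq_bins:
        raise ValueError("n_bins_out must be in [1, n_freq_bins]")
    mean_db = spec.values.mean(axis=1)
    bands = np.array_split(mean_db, n_bins_out)
    return np.array([b.mean() for b in bands])


def ltas_band_freqs(spec: SpectrogramMatrix, n_bins_out: int = 128) -> np.ndarray:
    """Center frequency of each LTAS band (mean of member bin frequencies)."""
    bands = np.array_split(spec.freq_axis, n_bins_out)
    return np.array([b.mean() for b in bands])


def _power_frames(clip: AudioClip, fs: FrameSpec, n_fft: int | None
                  ) -> tuple[np.ndarray, int]:
    flen = fs.frame_len(clip.sample_rate)
    frames = frame_signal(clip.samples, flen, fs.hop(clip.sample_rate))
    win = get_window(fs.window_name, flen, fftbins=False)
    if n_fft is None:
        n_fft = int(2 ** np.ceil(np.log2(flen)))
    if n_fft < flen:
        raise ValueError("n_fft shorter than the frame length")
    power = np.abs(np.fft.rfft(frames * win, n=n_fft, axis=1)) ** 2
    return power, n_fft


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, n_fft: int, sample_rate: int) -> np.ndarray:
    """(n_filters, n_fft//2+1) triangular filters on the mel scale."""
    edges_mel = np.linspace(hz_to_mel(0.0), hz_to_mel(sample_rate / 2), n_filters + 2)
    edges_hz = mel_to_hz(edges_mel)
    bin_freqs = np.arange(n_fft // 2 + 1) * sample_rate / n_fft
    bank = np.zeros((n_filters, bin_freqs.size))
    for k in range(n_filters):
        lo, mid, hi = edges_hz[k], edges_hz[k + 1], edges_hz[k + 2]
        up = (bin_freqs - lo) / (mid - lo)
        down = (hi - bin_freqs) / (hi - mid)
        bank[k] = np.maximum(0.0, np.minimum(up, down))
    return bank


def dct_matrix(n_coeffs: int, n_filters: int) -> np.ndarray:
    """Orthonormal DCT-II rows (n_coeffs, n_filters)."""
    eye = np.eye(n_filters)
    return dct(eye, type=2, norm="ortho", axis=0)[:n_coeffs]


def mfcc(clip: AudioClip, fs: FrameSpec = FrameSpec(), n_filters: int = 26,
         n_coeffs: int = 13, n_fft: int | None = None
         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame MFCCs and the (mean, sd) summary of each coefficient."""
    power, n_fft = _power_frames(clip, fs, n_fft)
    bank = mel_filterbank(n_filters, n_fft, clip.sample_rate)
    logmel = np.log(np.maximum(power @ bank.T, _LOG_FLOOR))
    coeffs = logmel @ dct_matrix(n_coeffs, n_filters).T
    summary = np.concatenate([coeffs.mean(axis=0), coeffs.std(axis=0)])
    return coeffs, summary


def erb_bandwidth(f_hz):
    """Equivalent rectangular bandwidth at ``f_hz`` (Glasberg & Moore)."""
    return 24.7 * (4.37 * np.asarray(f_hz, dtype=float) / 1000.0 + 1.0)


_ERB_Q = 1000.0 / (24.7 * 4.37)   # ~9.265


def hz_to_erb_rate(f):
    return _ERB_Q * np.log(1.0 + np.asarray(f, dtype=float) * 4.37 / 1000.0)


def erb_rate_to_hz(e):
    return (np.exp(np.asarray(e, dtype=float) / _ERB_Q) - 1.0) * 1000.0 / 4.37


def gammatone_center_freqs(n_filters: int, f_lo: float, f_hi: float) -> np.ndarray:
    """ERB-rate-spaced center frequencies on [f_lo, f_hi], increasing."""
    return erb_rate_to_hz(np.linspace(hz_to_erb_rate(f_lo), hz_to_erb_rate(f_hi),
                                      n_filters))


def gammatone_filterbank(n_filters: int, n_fft: int, sample_rate: int,
                         f_lo: float = 50.0) -> tuple[np.ndarray, np.ndarray]:
    """Peak-normalized 4th-order gammatone magnitude responses.

    Returns (bank, center_freqs); bank is (n_filters, n_fft//2+1).
    """
    centers = gammatone_center_freqs(n_filters, f_lo, sample_rate / 2)
    bin_freqs = np.arange(n_fft // 2 + 1) * sample_rate / n_fft
    b = 1.019 * erb_bandwidth(centers)
    resp = (1.0 + ((bin_freqs[None, :] - centers[:, None]) / b[:, None]) ** 2) ** -2.0
    resp /= resp.max(axis=1, keepdims=True)
    return resp, centers


def gtcc(clip: AudioClip, fs: FrameSpec = FrameSpec(), n_filters: int = 64,
         n_coeffs: int = 13, n_fft: int | None = None
         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame gammatone cepstral coefficients and (mean, sd) summary."""
    power, n_fft = _power_frames(clip, fs, n_fft)
    bank, _ = gammatone_filterbank(n_filters, n_fft, clip.sample_rate)
    logg = np.log(np.maximum(power @ (bank ** 2).T, _LOG_FLOOR))
    coeffs = logg @ dct_matrix(n_coeffs, n_filters).T
    summary = np.concatenate([coeffs.mean(axis=0), coeffs.std(axis=0)])
    return coeffs, summary
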