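"""Time-domain prosodic features: energy, pitch, voice activity, fluency.

Framing defaults to 25 ms windows with a 10 ms hop.  The voice-activity
detector thresholds frame energy at -35 dB relative to the loudest
frame, applies duration-based morphology (short pauses are absorbed,
short speech bursts discarded) and reports pauses as the full extent of
the all-silent frames with speech as the complement, which recovers
constructed segmentations to within one hop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, get_window

from ..audio import AudioClip


@dataclass
class FrameSpec:
    frame_length_s: float = 0.025
    hop_s: float = 0.010
    window_name: str = "hamming"

    def __post_init__(self):
        if self.frame_length_s <= 0 or self.hop_s <= 0:
            raise ValueError("frame length and hop must be positive")
        if self.hop_s > self.frame_length_s:
            raise ValueError("hop must not exceed the frame length")

    def frame_len(self, sample_rate: int) -> int:
        return max(1, round(self.frame_length_s * sample_rate))

    def hop(self, sample_rate: int) -> int:
        return max(1, round(self.hop_s * sample_rate))


def frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """(n_frames, frame_len) view of ``x``; at least one (padded) frame."""
    if x.size < frame_len:
        out = np.zeros(frame_len, dtype=x.dtype)
        out[:x.size] = x
        return out[None, :]
    return np.lib.stride_tricks.sliding_window_view(x, frame_len)[::hop]


def _moments(v: np.ndarray) -> tuple[float, float]:
    """(skewness, excess kurtosis); zeros for a constant sequence."""
    sd = v.std()
    # ptp guards constant sequences whose mean carries summation rounding
    if sd < 1e-30 or np.ptp(v) == 0.0:
        return 0.0, 0.0
    z = (v - v.mean()) / sd
    return float(np.mean(z ** 3)), float(np.mean(z ** 4) - 3.0)


def short_term_energy(clip: AudioClip, fs: FrameSpec = FrameSpec()
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame windowed energy and its 6-number summary.

    E_t = sum((w * x_t)^2); summary = (mean, sd, max, min, skewness,
    excess kurtosis) over frames.
    """
    flen = fs.frame_len(clip.sample_rate)
    frames = frame_signal(clip.samples, flen, fs.hop(clip.sample_rate))
    win = get_window(fs.window_name, flen, fftbins=False)
    energies = ((frames * win) ** 2).sum(axis=1)
    skew, kurt = _moments(energies)
    summary = np.array([energies.mean(), energies.std(), energies.max(),
                        energies.min(), skew, kurt])
    return energies, summary


def pitch_track(clip: AudioClip, fs: FrameSpec = FrameSpec(),
                f0_range: tuple[float, float] = (75.0, 500.0),
                voicing_threshold: float = 0.3) -> tuple[np.ndarray, np.ndarray]:
    """Autocorrelation pitch track (0 = unvoiced) and a 4-number summary.

    A frame is voiced when the peak of its normalized autocorrelation in
    the F0 lag band reaches the voicing threshold.  Summary = (mean, sd,
    range, voiced fraction) over voiced frames; an all-unvoiced clip
    yields zeros with a warning.
    """
    lo, hi = f0_range
    sr = clip.sample_rate
    if not (0 < lo < hi <= sr / 2):
        raise ValueError("f0_range must satisfy 0 < lo < hi <= Nyquist")
    flen = fs.frame_len(sr)
    lag_min = max(1, int(np.floor(sr / hi)))
    lag_max = int(np.ceil(sr / lo))
    if lag_max >= flen:
        raise ValueError("frame too short for the lowest F0 in f0_range")
    frames = frame_signal(clip.samples, flen, fs.hop(sr)).astype(np.float64)
    frames = frames - frames.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * flen)))
    spec = np.fft.rfft(frames, n=nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=1)[:, :flen]
    r0 = ac[:, 0]
    band = ac[:, lag_min:lag_max + 1]
    best = band.argmax(axis=1)
    peak = band[np.arange(len(best)), best]
    # frames whose energy is at rounding-noise level are never voiced
    with np.errstate(divide="ignore", invalid="ignore"):
        norm_peak = np.where(r0 > 1e-20, peak / r0, 0.0)
    voiced = norm_peak >= voicing_threshold
    f0 = np.where(voiced, sr / (best + lag_min), 0.0)
    vf = float(voiced.mean())
    if not voiced.any():
        warnings.warn("no voiced frames found; pitch summary is all zeros")
        return f0, np.zeros(4)
    v = f0[voiced]
    summary = np.array([v.mean(), v.std(), v.max() - v.min(), vf])
    return f0, summary


@dataclass
class VADSegmentation:
    voiced_segments: list[tuple[float, float]]
    pauses: list[tuple[float, float]]
    threshold_db: float
    min_segment_s: float
    min_pause_s: float
    duration_s: float

    def total_voiced_s(self) -> float:
        return float(sum(e - s for s, e in self.voiced_segments))

    def max_pause_s(self) -> float:
        return float(max((e - s for s, e in self.pauses), default=0.0))


def vad_segment(clip: AudioClip, threshold_db: float = -35.0,
                min_segment_s: float = 0.1, min_pause_s: float = 0.15,
                fs: FrameSpec = FrameSpec()) -> VADSegmentation:
    """Energy-threshold voice-activity detection with duration morphology."""
    sr = clip.sample_rate
    flen, hop = fs.frame_len(sr), fs.hop(sr)
    frames = frame_signal(clip.samples, flen, hop)
    energies = (frames ** 2).sum(axis=1)
    e_max = energies.max()
    if e_max <= 0:
        speech = np.zeros(len(energies), dtype=bool)
    else:
        with np.errstate(divide="ignore"):
            e_db = 10.0 * np.log10(np.maximum(energies, 1e-300) / e_max)
        speech = e_db > threshold_db

    min_pause_f = max(1, round(min_pause_s / fs.hop_s))
    min_seg_f = max(1, round(min_segment_s / fs.hop_s))
    speech = _absorb_short_runs(speech, value=False, min_len=min_pause_f)
    speech = _absorb_short_runs(speech, value=True, min_len=min_seg_f)

    duration = clip.duration_s
    pauses = []
    for i0, i1 in _runs(~speech):
        start = i0 * fs.hop_s
        end = min((i1 - 1) * fs.hop_s + fs.frame_length_s, duration)
        pauses.append((start, end))
    if not speech.any():
        pauses = [(0.0, duration)]
    voiced = _complement(pauses, duration)
    return VADSegmentation(voiced_segments=voiced, pauses=pauses,
                           threshold_db=threshold_db, min_segment_s=min_segment_s,
                           min_pause_s=min_pause_s, duration_s=duration)


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of the True runs."""
    if not flags.any():
        return []
    padded = np.concatenate([[False], flags, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _absorb_short_runs(flags: np.ndarray, value: bool, min_len: int) -> np.ndarray:
    out = flags.copy()
    for i0, i1 in _runs(flags == value):
        if i1 - i0 < min_len:
            out[i0:i1] = not value
    return out


def _complement(intervals: list[tuple[float, float]], duration: float
                ) -> list[tuple[float, float]]:
    out, cursor = [], 0.0
    for s, e in intervals:
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < duration:
        out.append((cursor, duration))
    return out


def syllable_nuclei(clip: AudioClip, seg: VADSegmentation,
                    fs: FrameSpec = FrameSpec(), min_prominence_db: float = 3.0,
                    min_distance_s: float = 0.1) -> int:
    """Count energy peaks (syllable nuclei) inside the voiced segments."""
    sr = clip.sample_rate
    frames = frame_signal(clip.samples, fs.frame_len(sr), fs.hop(sr))
    energies = (frames ** 2).sum(axis=1)
    e_db = 10.0 * np.log10(np.maximum(energies, 1e-300))
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(e_db, kernel, mode="same")
    peaks, _ = find_peaks(smooth, prominence=min_prominence_db,
                          distance=max(1, round(min_distance_s / fs.hop_s)))
    times = peaks * fs.hop_s
    count = 0
    for s, e in seg.voiced_segments:
        count += int(((times >= s) & (times < e)).sum())
    return count


def fluency_features(seg: VADSegmentation, nuclei_count: int) -> np.ndarray:
    """(total time, voiced time, voiced ratio, max pause, mean syllable length)."""
    total = seg.duration_s
    voiced = seg.total_voiced_s()
    ratio = voiced / total if total > 0 else 0.0
    if nuclei_count > 0:
        mean_syllable = voiced / nuclei_count
    else:
        if voiced > 0:
            warnings.warn("no syllable nuclei found; mean syllable length set to 0")
        mean_syllable = 0.0
    return np.array([total, voiced, ratio, seg.max_pause_s(), mean_syllable])


FLUENCY_NAMES = ("total_time_s", "voiced_time_s", "voiced_ratio",
                 "max_pause_s", "mean_syllable_s")
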