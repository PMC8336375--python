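"""Source-filter synthesis of two-class clips with ground-truth labels.

Clips alternate voiced segments (impulse train at an Ornstein-Uhlenbeck
wandering F0, -12 dB/octave source tilt, formant resonator cascade),
unvoiced consonants (high-passed noise) and pauses (near-silence floored
at -60 dB), with per-segment fades, a class-specific low-pass and peak
normalization.  The two default parameter sets plant the contrasts the
detection pipeline is meant to find: the patient class has its energy
confined below 5 kHz, a much flatter F0, more and longer pauses, and
devoiced consonants; the control class keeps a wide band up to 16 kHz
and a lively F0.  Every clip carries exact segment annotations and its
true F0 contour, so downstream features can be tested against truth.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import butter, lfilter, sosfilt

from .audio import AudioClip, save_wav

PAUSE_FLOOR_DB = -60.0
SAMPLE_RATE = 44100


@dataclass
class ClassParams:
    f0_mean_hz: float = 120.0
    f0_sd_hz: float = 30.0
    formants: tuple[tuple[float, float], ...] = (
        (700.0, 130.0), (1220.0, 170.0), (2600.0, 250.0), (3500.0, 300.0))
    lowpass_cutoff_hz: float = 16000.0
    pause_rate_per_s: float = 0.2
    pause_dur_range_s: tuple[float, float] = (0.3, 0.6)
    devoice_prob: float = 0.0
    segment_dur_range_s: tuple[float, float] = (0.4, 0.9)
    voiced_prob: float = 0.7
    snr_db: float = PAUSE_FLOOR_DB

    def __post_init__(self):
        if not 0.0 <= self.devoice_prob <= 1.0:
            raise ValueError("devoice_prob must be in [0, 1]")
        if not 0.0 <= self.voiced_prob <= 1.0:
            raise ValueError("voiced_prob must be in [0, 1]")
        if self.lowpass_cutoff_hz >= SAMPLE_RATE / 2 or self.lowpass_cutoff_hz <= 0:
            raise ValueError("lowpass cutoff must lie in (0, Nyquist)")
        for lo, hi in (self.pause_dur_range_s, self.segment_dur_range_s):
            if not 0 < lo <= hi:
                raise ValueError("duration ranges must be positive with lo <= hi")

    def to_dict(self) -> dict:
        return asdict(self)


def default_class_params(label: int) -> ClassParams:
    """Canonical parameter sets for control (0) and patient (1) clips."""
    if label == 0:
        return ClassParams()
    if label == 1:
        return ClassParams(f0_sd_hz=4.0, lowpass_cutoff_hz=5000.0,
                           pause_rate_per_s=0.6, pause_dur_range_s=(0.6, 1.2),
                           devoice_prob=0.6)
    raise ValueError(f"label must be 0 or 1, got {label}")


@dataclass
class SegmentTruth:
    start_s: float
    end_s: float
    kind: str            # "voiced" | "consonant" | "pause"
    devoiced: bool = False


@dataclass
class ClipTruth:
    segments: list[SegmentTruth]
    f0_times_s: np.ndarray
    f0_hz: np.ndarray    # true contour, 0 where not genuinely voiced

    def pauses(self) -> list[tuple[float, float]]:
        return [(s.start_s, s.end_s) for s in self.segments if s.kind == "pause"]

    def max_pause_s(self) -> float:
        return max((e - s for s, e in self.pauses()), default=0.0)

    def voiced_f0_sd(self) -> float:
        v = self.f0_hz[self.f0_hz > 0]
        return float(v.std()) if v.size else 0.0

    def to_dict(self) -> dict:
        return {"segments": [asdict(s) for s in self.segments],
                "f0_times_s": self.f0_times_s.tolist(),
                "f0_hz": self.f0_hz.tolist()}


@dataclass
class SynthClip:
    clip: AudioClip
    label: int
    truth: ClipTruth
    seed: int
    params: ClassParams


def _ou_f0(n: int, sr: int, mean: float, sd: float, rng: np.random.Generator,
           theta: float = 1.5) -> np.ndarray:
    """Ornstein-Uhlenbeck F0 contour with stationary sd ``sd``."""
    hop = sr // 100                      # update every 10 ms
    steps = n // hop + 2
    dt = hop / sr
    sigma = sd * np.sqrt(2.0 * theta)
    f = np.empty(steps)
    f[0] = rng.normal(mean, sd)
    eps = rng.standard_normal(steps - 1)
    for i in range(1, steps):
        f[i] = f[i - 1] + theta * (mean - f[i - 1]) * dt + sigma * np.sqrt(dt) * eps[i - 1]
    coarse = np.clip(f, 40.0, 400.0)
    return np.interp(np.arange(n), np.arange(steps) * hop, coarse)


def _voiced_excitation(f0: np.ndarray, sr: int) -> np.ndarray:
    phase = np.cumsum(f0 / sr)
    pulses = np.zeros(f0.size)
    pulses[np.flatnonzero(np.diff(np.floor(phase)) > 0)] = 1.0
    # -12 dB/octave source tilt: two leaky integrators
    tilt = lfilter([1.0], [1.0, -0.98], lfilter([1.0], [1.0, -0.98], pulses))
    return tilt


def _formant_cascade(x: np.ndarray, formants, sr: int) -> np.ndarray:
    y = x
    for fc, bw in formants:
        r = np.exp(-np.pi * bw / sr)
        theta = 2.0 * np.pi * fc / sr
        a = [1.0, -2.0 * r * np.cos(theta), r * r]
        b0 = (1.0 - r) * np.sqrt(1.0 - 2.0 * r * np.cos(2.0 * theta) + r * r)
        y = lfilter([b0], a, y)
    return y


def _consonant_noise(n: int, sr: int, rng: np.random.Generator) -> np.ndarray:
    sos = butter(4, 3000.0, btype="highpass", fs=sr, output="sos")
    return sosfilt(sos, rng.standard_normal(n))


def _fade(x: np.ndarray, sr: int, fade_s: float = 0.010) -> np.ndarray:
    k = min(int(fade_s * sr), x.size // 2)
    if k > 0:
        ramp = 0.5 - 0.5 * np.cos(np.linspace(0.0, np.pi, k))
        x[:k] *= ramp
        x[-k:] *= ramp[::-1]
    return x


def synthesize_clip(params: ClassParams, duration_s: float, seed: int,
                    label: int = 0, sample_rate: int = SAMPLE_RATE) -> SynthClip:
    """One deterministic clip with exact truth annotations."""
    if duration_s < 1.0:
        raise ValueError("duration must be at least 1 s")
    rng = np.random.default_rng(seed)
    sr = sample_rate
    total = int(round(duration_s * sr))
    pieces: list[np.ndarray] = []
    segments: list[SegmentTruth] = []
    f0_chunks: list[tuple[int, np.ndarray]] = []
    pos = 0
    while pos < total:
        seg_len = int(rng.uniform(*params.segment_dur_range_s) * sr)
        seg_len = min(seg_len, total - pos)
        if seg_len <= 0:
            break
        voiced = rng.random() < params.voiced_prob
        devoiced = False
        if voiced:
            f0 = _ou_f0(seg_len, sr, params.f0_mean_hz, params.f0_sd_hz, rng)
            x = _formant_cascade(_voiced_excitation(f0, sr), params.formants, sr)
            kind = "voiced"
            f0_chunks.append((pos, f0))
        else:
            devoiced = rng.random() < params.devoice_prob
            if devoiced:
                # pathological trait: the consonant comes out voiced
                f0 = _ou_f0(seg_len, sr, params.f0_mean_hz, params.f0_sd_hz, rng)
                x = _formant_cascade(_voiced_excitation(f0, sr), params.formants, sr)
            else:
                x = _consonant_noise(seg_len, sr, rng)
            x = x * 0.4
            kind = "consonant"
        rms = np.sqrt(np.mean(x ** 2))
        if rms > 0:
            x = x / rms * 0.2
        pieces.append(_fade(x, sr))
        segments.append(SegmentTruth(pos / sr, (pos + seg_len) / sr, kind, devoiced))
        pos += seg_len
        if pos >= total:
            break
        seg_dur = seg_len / sr
        if rng.random() < min(1.0, params.pause_rate_per_s * seg_dur):
            p_len = int(rng.uniform(*params.pause_dur_range_s) * sr)
            p_len = min(p_len, total - pos)
            if p_len > 0:
                pieces.append(np.zeros(p_len))
                segments.append(SegmentTruth(pos / sr, (pos + p_len) / sr, "pause"))
                pos += p_len

    x = np.concatenate(pieces)
    sos = butter(10, params.lowpass_cutoff_hz, btype="lowpass", fs=sr, output="sos")
    x = sosfilt(sos, x)
    peak = np.abs(x).max()
    if peak > 0:
        x = x / peak * 0.9
    # pauses get a broadband noise floor instead of digital zero
    floor = 0.9 * 10.0 ** (params.snr_db / 20.0)
    for s in segments:
        if s.kind == "pause":
            i0, i1 = int(s.start_s * sr), int(s.end_s * sr)
            x[i0:i1] += rng.normal(0.0, floor, i1 - i0)
    x = np.clip(x, -1.0, 1.0)

    hop = sr // 100
    f0_full = np.zeros(x.size)
    for start, f0 in f0_chunks:
        f0_full[start:start + f0.size] = f0
    times = np.arange(0, x.size, hop) / sr
    truth = ClipTruth(segments=segments, f0_times_s=times,
                      f0_hz=f0_full[::hop][:times.size])
    return SynthClip(clip=AudioClip(samples=x, sample_rate=sr), label=label,
                     truth=truth, seed=seed, params=params)


def generate_clips(n_per_class: int, duration_s: float = 5.0, seed: int = 0,
                   params_by_label: dict[int, ClassParams] | None = None
                   ) -> list[SynthClip]:
    """Balanced in-memory dataset; per-clip seeds derive from the master seed."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out = []
    for label in (0, 1):
        params = (params_by_label or {}).get(label, default_class_params(label))
        for i in range(n_per_class):
            clip_seed = int(np.random.SeedSequence((seed, label, i)).generate_state(1)[0])
            out.append(synthesize_clip(params, duration_s, clip_seed, label=label))
    return out


def subject_ids(clips: list[SynthClip], clips_per_subject: int = 4) -> np.ndarray:
    """Deterministic synthetic speaker ids (~4 clips per speaker per class)."""
    counters: dict[int, int] = {}
    ids = []
    for c in clips:
        k = counters.get(c.label, 0)
        ids.append(f"s{c.label}_{k // clips_per_subject:03d}")
        counters[c.label] = k + 1
    return np.array(ids)


def generate_dataset(out_dir: str | Path, n_per_class: int, duration_s: float = 5.0,
                     seed: int = 0) -> Path:
    """Write WAVs, a clip_path,label,subject_id manifest and truth JSON.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clips = generate_clips(n_per_class, duration_s, seed)
    subjects = subject_ids(clips)
    manifest = out_dir / "manifest.csv"
    truth: dict[str, dict] = {}
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["clip_path", "label", "subject_id"])
        for i, (sc, subj) in enumerate(zip(clips, subjects)):
            name = f"clip_{i:04d}_label{sc.label}.wav"
            save_wav(out_dir / name, sc.clip)
            writer.writerow([name, sc.label, subj])
            truth[name] = {"label": sc.label, "seed": sc.seed,
                           **sc.truth.to_dict()}
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh)
    return manifest
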