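"""Synthetic speech generator: determinism, truth annotations, contrasts."""

from __future__ import annotations

import json

import numpy as np
import pytest

from pathospeech.features.prosody import pitch_track, vad_segment
from pathospeech.spectrogram import compute_spectrogram
from pathospeech.synth import (ClassParams, default_class_params,
                               generate_clips, generate_dataset,
                               subject_ids, synthesize_clip)


def test_clip_is_deterministic_given_seed():
    p = default_class_params(0)
    a = synthesize_clip(p, 2.0, seed=42)
    b = synthesize_clip(p, 2.0, seed=42)
    c = synthesize_clip(p, 2.0, seed=43)
    np.testing.assert_array_equal(a.clip.samples, b.clip.samples)
    assert not np.array_equal(a.clip.samples, c.clip.samples)


def test_truth_segments_tile_the_clip():
    sc = synthesize_clip(default_class_params(1), 4.0, seed=5)
    segs = sc.truth.segments
    assert segs[0].start_s == 0.0
    for prev, nxt in zip(segs, segs[1:]):
        assert nxt.start_s == pytest.approx(prev.end_s)
    assert segs[-1].end_s == pytest.approx(4.0, abs=0.05)
    assert sc.clip.samples.size == 4 * 44100
    assert np.abs(sc.clip.samples).max() <= 1.0


def test_zero_pause_rate_produces_no_pauses():
    p = ClassParams(pause_rate_per_s=0.0)
    sc = synthesize_clip(p, 4.0, seed=1)
    assert sc.truth.pauses() == []


def test_param_validation():
    with pytest.raises(ValueError):
        ClassParams(devoice_prob=1.5)
    with pytest.raises(ValueError):
        ClassParams(lowpass_cutoff_hz=30000.0)
    with pytest.raises(ValueError):
        ClassParams(pause_dur_range_s=(0.5, 0.1))
    with pytest.raises(ValueError):
        default_class_params(2)
    with pytest.raises(ValueError):
        synthesize_clip(ClassParams(), 0.5, seed=0)


def _band_fraction_above(clip, cutoff_hz):
    spec = compute_spectrogram(clip)
    power = 10.0 ** (spec.values / 10.0)
    hi = power[spec.freq_axis > cutoff_hz].sum()
    return hi / power.sum()


def test_planted_class_contrasts_are_present(small_clips):
    controls = [c for c in small_clips if c.label == 0]
    patients = [c for c in small_clips if c.label == 1]

    # wide-band vs low-passed energy above 5 kHz
    hi_c = np.mean([_band_fraction_above(c.clip, 5000.0) for c in controls])
    hi_p = np.mean([_band_fraction_above(c.clip, 5000.0) for c in patients])
    assert hi_c > 10 * hi_p

    # flat-affect pitch: true contour variability collapses
    sd_c = np.mean([c.truth.voiced_f0_sd() for c in controls])
    sd_p = np.mean([c.truth.voiced_f0_sd() for c in patients])
    assert sd_c > 3 * sd_p

    # longer pauses in the patient class (true annotations)
    max_c = max(c.truth.max_pause_s() for c in controls)
    assert all(lo >= 0 for lo, _ in patients[0].truth.pauses() or [(0, 0)])
    assert max((c.truth.max_pause_s() for c in patients), default=0) >= max_c


def test_detected_features_track_the_truth(small_clips):
    sc = next(c for c in small_clips if c.label == 0)
    seg = vad_segment(sc.clip)
    # detected voiced time within 15% of annotated non-pause time
    true_voiced = sc.clip.duration_s - sum(e - s for s, e in sc.truth.pauses())
    assert seg.total_voiced_s() == pytest.approx(true_voiced, rel=0.15)
    # frame-wise: detected F0 tracks the true contour where both agree
    # the frame is voiced (both grids use the same 10 ms hop)
    f0, _ = pitch_track(sc.clip)
    n = min(f0.size, sc.truth.f0_hz.size)
    both = (f0[:n] > 0) & (sc.truth.f0_hz[:n] > 0)
    assert both.mean() > 0.2
    err = np.abs(f0[:n][both] - sc.truth.f0_hz[:n][both])
    assert np.median(err) < 10.0


def test_generate_clips_balance_and_per_clip_seeds():
    clips = generate_clips(3, duration_s=1.5, seed=9)
    assert [c.label for c in clips] == [0, 0, 0, 1, 1, 1]
    assert len({c.seed for c in clips}) == 6
    again = generate_clips(3, duration_s=1.5, seed=9)
    np.testing.assert_array_equal(clips[4].clip.samples, again[4].clip.samples)
    with pytest.raises(ValueError):
        generate_clips(0)


def test_subject_ids_group_four_clips_per_speaker():
    clips = generate_clips(6, duration_s=1.0, seed=2)
    ids = subject_ids(clips, clips_per_subject=4)
    assert ids.shape == (12,)
    # 6 clips/class -> 2 speakers per class, never shared across classes
    assert len(set(ids)) == 4
    for c, sid in zip(clips, ids):
        assert sid.startswith(f"s{c.label}_")


def test_dataset_on_disk_roundtrip(tmp_path):
    manifest = generate_dataset(tmp_path / "data", n_per_class=2,
                                duration_s=1.0, seed=3)
    assert manifest.exists()
    lines = manifest.read_text().strip().splitlines()
    assert lines[0] == "clip_path,label,subject_id"
    assert len(lines) == 5
    truth = json.loads((tmp_path / "data" / "truth.json").read_text())
    assert len(truth) == 4
    for name, entry in truth.items():
        assert (tmp_path / "data" / name).exists()
        assert entry["label"] in (0, 1)
        assert entry["segments"][0]["start_s"] == 0.0
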