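"""Acoustic feature bank: framing, energy, pitch, VAD, spectra, ERB scale."""

from __future__ import annotations

import numpy as np
import pytest

from pathospeech.audio import AudioClip
from pathospeech.features import (FEATURE_SETS, ClipFeatures,
                                  extract_feature_set, feature_length)
from pathospeech.features.prosody import (FrameSpec, frame_signal, pitch_track,
                                          short_term_energy, vad_segment)
from pathospeech.features.spectral import (dct_matrix, erb_bandwidth,
                                           erb_rate_to_hz,
                                           gammatone_center_freqs,
                                           gammatone_filterbank, gtcc,
                                           hz_to_erb_rate, mel_filterbank, mfcc)

SR = 44100


def _tone(f_hz=200.0, duration=1.0, amp=0.5):
    t = np.arange(int(duration * SR)) / SR
    return AudioClip(samples=amp * np.sin(2 * np.pi * f_hz * t), sample_rate=SR)


def test_framing_counts_and_padding():
    frames = frame_signal(np.arange(1000.0), frame_len=100, hop=50)
    assert frames.shape == (19, 100)
    np.testing.assert_array_equal(frames[1], np.arange(50.0, 150.0))
    short = frame_signal(np.ones(10), frame_len=100, hop=50)
    assert short.shape == (1, 100)
    assert short[0, 10:].sum() == 0.0


def test_frame_spec_validation():
    with pytest.raises(ValueError):
        FrameSpec(frame_length_s=-0.01)
    with pytest.raises(ValueError):
        FrameSpec(frame_length_s=0.01, hop_s=0.02)


def test_short_term_energy_scales_quadratically():
    _, quiet = short_term_energy(_tone(amp=0.1))
    _, loud = short_term_energy(_tone(amp=0.2))
    assert loud[0] == pytest.approx(4.0 * quiet[0], rel=1e-6)
    # constant-amplitude tone: tiny spread, zeroed higher moments guard
    _, const = short_term_energy(AudioClip(samples=np.ones(SR), sample_rate=SR))
    assert const[4] == 0.0 and const[5] == 0.0


def test_pitch_of_pure_tone_and_noise():
    _, summary = pitch_track(_tone(150.0))
    assert abs(summary[0] - 150.0) < 2.0
    assert summary[3] > 0.9
    noise = AudioClip(samples=np.random.default_rng(0).standard_normal(SR) * 0.1,
                      sample_rate=SR)
    f0, nsum = pitch_track(noise)
    assert nsum[3] < 0.3          # noise is mostly unvoiced


def test_pitch_range_validation_and_unvoiced_warning():
    with pytest.raises(ValueError, match="f0_range"):
        pitch_track(_tone(), f0_range=(500.0, 75.0))
    with pytest.raises(ValueError, match="frame too short"):
        pitch_track(_tone(), f0_range=(10.0, 500.0))
    silent = AudioClip(samples=np.full(SR, 1e-8), sample_rate=SR)
    with pytest.warns(UserWarning, match="no voiced frames"):
        _, summary = pitch_track(silent)
    np.testing.assert_array_equal(summary, np.zeros(4))


def test_vad_on_silence_and_continuous_speech():
    silent = AudioClip(samples=np.zeros(SR), sample_rate=SR)
    seg = vad_segment(silent)
    assert seg.voiced_segments == []
    assert seg.pauses == [(0.0, 1.0)]
    seg2 = vad_segment(_tone(duration=2.0))
    assert seg2.pauses == []
    assert seg2.total_voiced_s() == pytest.approx(2.0)
    assert seg2.max_pause_s() == 0.0


def test_vad_morphology_absorbs_short_gaps():
    # a 50 ms dip inside speech is below min_pause_s and must be absorbed
    x = 0.5 * np.sin(2 * np.pi * 200 * np.arange(2 * SR) / SR)
    x[SR:SR + int(0.05 * SR)] = 0.0
    seg = vad_segment(AudioClip(samples=x, sample_rate=SR))
    assert seg.pauses == []


def test_mel_and_gammatone_banks_cover_the_band():
    bank = mel_filterbank(26, 2048, SR)
    assert bank.shape == (26, 1025)
    assert (bank >= 0).all()
    assert (bank.sum(axis=1) > 0).all()
    gbank, centers = gammatone_filterbank(64, 2048, SR)
    assert gbank.shape == (64, 1025)
    np.testing.assert_allclose(gbank.max(axis=1), 1.0)
    assert (np.diff(centers) > 0).all()


def test_erb_scale_identities():
    assert erb_bandwidth(1000.0) == pytest.approx(24.7 * 5.37)
    f = np.array([100.0, 1000.0, 8000.0])
    np.testing.assert_allclose(erb_rate_to_hz(hz_to_erb_rate(f)), f, rtol=1e-12)
    # the ERB-rate derivative is the reciprocal bandwidth
    eps = 1e-3
    num = (hz_to_erb_rate(1000.0 + eps) - hz_to_erb_rate(1000.0 - eps)) / (2 * eps)
    assert num == pytest.approx(1.0 / erb_bandwidth(1000.0), rel=1e-6)
    centers = gammatone_center_freqs(10, 50.0, SR / 2)
    steps = np.diff(hz_to_erb_rate(centers))
    np.testing.assert_allclose(steps, steps[0], rtol=1e-9)  # even ERB spacing


def test_dct_matrix_is_orthonormal():
    d = dct_matrix(26, 26)
    np.testing.assert_allclose(d @ d.T, np.eye(26), atol=1e-12)


def test_cepstra_shapes_and_determinism():
    clip = _tone(300.0)
    c1, s1 = mfcc(clip)
    c2, s2 = mfcc(clip)
    assert c1.shape[1] == 13 and s1.shape == (26,)
    np.testing.assert_array_equal(s1, s2)
    g1, gs1 = gtcc(clip)
    assert g1.shape[1] == 13 and gs1.shape == (26,)


@pytest.mark.parametrize("set_name", FEATURE_SETS)
def test_every_feature_set_has_declared_length(set_name, small_clips):
    clip = small_clips[0].clip
    feats = extract_feature_set(clip, set_name)
    assert feats.values.shape == (feature_length(set_name),)
    assert len(feats.names) == feature_length(set_name)
    assert np.isfinite(feats.values).all()


def test_feature_set_validation():
    with pytest.raises(ValueError, match="unknown feature set"):
        extract_feature_set(_tone(), "plp")
    with pytest.raises(ValueError, match="unknown feature set"):
        feature_length("plp")
    with pytest.raises(ValueError, match="disagree"):
        ClipFeatures("ste", np.zeros(3), ("a", "b"))
    with pytest.raises(ValueError, match="non-finite"):
        ClipFeatures("ste", np.array([np.nan]), ("a",))
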