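"""WAV round-trips, spectrogram geometry and the input-image normalization."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.io import wavfile

from pathospeech.audio import (AudioClip, AudioDecodeError, EmptyAudioError,
                               load_audio, save_wav)
from pathospeech.spectrogram import (NET_INPUT_SHAPE, ClipTooShortError,
                                     clip_to_net_input, compute_spectrogram,
                                     net_input_row_freqs, standardize,
                                     to_net_input)

SR = 44100


def _tone(f_hz=440.0, duration=1.0, sr=SR, amp=0.5):
    t = np.arange(int(duration * sr)) / sr
    return AudioClip(samples=amp * np.sin(2 * np.pi * f_hz * t), sample_rate=sr)


def test_wav_roundtrip_is_faithful(tmp_path):
    clip = _tone()
    path = tmp_path / "tone.wav"
    save_wav(path, clip)
    back = load_audio(path)
    assert back.sample_rate == SR
    assert back.samples.size == clip.samples.size
    np.testing.assert_allclose(back.samples, clip.samples, atol=1.0 / 32767)


def test_stereo_mixdown_and_resampling(tmp_path):
    t = np.arange(22050) / 22050
    left = 0.5 * np.sin(2 * np.pi * 300 * t)
    stereo = np.stack([left, -left], axis=1)  # cancels to silence in the mix
    path = tmp_path / "stereo.wav"
    wavfile.write(path, 22050, (stereo * 32767).astype(np.int16))
    clip = load_audio(path, target_rate=44100)
    assert clip.n_channels == 2
    assert clip.sample_rate == 44100
    assert clip.samples.size == 44100
    assert np.abs(clip.samples).max() < 1e-3


def test_corrupt_and_empty_files_raise(tmp_path):
    bad = tmp_path / "bad.wav"
    bad.write_bytes(b"not a wav file at all")
    with pytest.raises(AudioDecodeError):
        load_audio(bad)
    with pytest.raises(FileNotFoundError):
        load_audio(tmp_path / "missing.wav")
    with pytest.raises(EmptyAudioError):
        AudioClip(samples=np.array([]), sample_rate=SR)


def test_spectrogram_geometry_and_peak_reference():
    spec = compute_spectrogram(_tone(1000.0))
    assert spec.n_freq_bins == 1025
    assert spec.freq_axis[-1] == pytest.approx(SR / 2)
    assert spec.values.max() == pytest.approx(0.0)        # peak-referenced dB
    assert spec.values.min() >= -80.0 - 1e-9              # floored range
    # frame count from hop 512 over a 1 s clip
    assert spec.n_frames == (SR - 2048) // 512 + 1


def test_spectrogram_input_validation():
    with pytest.raises(ClipTooShortError):
        compute_spectrogram(AudioClip(samples=np.ones(512), sample_rate=SR))
    with pytest.raises(ValueError, match="power of two"):
        compute_spectrogram(_tone(), n_fft=1000)
    with pytest.raises(ValueError, match="hop_length"):
        compute_spectrogram(_tone(), hop_length=0)


def test_net_input_is_standardized_128x256():
    img = clip_to_net_input(_tone())
    assert img.pixels.shape == NET_INPUT_SHAPE
    assert img.pixels.mean() == pytest.approx(0.0, abs=1e-7)
    assert img.pixels.std() == pytest.approx(1.0, abs=1e-7)


def test_standardize_constant_image_maps_to_zeros():
    np.testing.assert_array_equal(standardize(np.full((4, 4), 7.0)),
                                  np.zeros((4, 4)))


def test_row_frequencies_are_monotone_and_bounded():
    freqs = net_input_row_freqs()
    assert freqs.shape == (128,)
    assert (np.diff(freqs) > 0).all()
    assert freqs[0] >= 0.0
    assert freqs[-1] <= SR / 2
    # a tone's energy concentrates in the row nearest its frequency
    img = clip_to_net_input(_tone(5000.0))
    assert abs(int(img.pixels.mean(axis=1).argmax())
               - int(np.abs(freqs - 5000.0).argmin())) <= 1


def test_silence_produces_finite_image():
    silent = AudioClip(samples=np.zeros(SR), sample_rate=SR)
    spec = compute_spectrogram(silent)
    assert np.isfinite(spec.values).all()
    assert np.isfinite(to_net_input(spec).pixels).all()
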