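"""Spectrogram-image augmentation.

Six transforms, applied in a fixed order: pad-and-random-crop, random
rotation, random rescaling, additive Gaussian noise, frequency masking
and time masking (mask fill value = image mean, which is ~0 on
z-scored inputs).  All magnitudes are mild by design; the policy is a
plain dataclass so a run's augmentation is fully logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import rotate as _ndrotate
from skimage.transform import resize as _resize

from .spectrogram import NET_INPUT_SHAPE, NetInputImage


@dataclass
class AugmentationPolicy:
    crop_pad_px: int = 8
    rotation_max_deg: float = 5.0
    rescale_range: tuple[float, float] = (0.9, 1.1)
    gauss_sigma: float = 0.05          # fraction of the image sd
    freq_mask_max_F: int = 16          # rows
    time_mask_max_T: int = 32          # columns
    n_freq_masks: int = 1
    n_time_masks: int = 1
    enabled: bool = True
    rng_seed: int | None = None

    def __post_init__(self):
        lo, hi = self.rescale_range
        if lo > hi:
            raise ValueError("rescale_range lo must be <= hi")
        for name in ("crop_pad_px", "rotation_max_deg", "gauss_sigma",
                     "freq_mask_max_F", "time_mask_max_T",
                     "n_freq_masks", "n_time_masks"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.freq_mask_max_F > NET_INPUT_SHAPE[0]:
            raise ValueError("freq_mask_max_F exceeds image height")
        if self.time_mask_max_T > NET_INPUT_SHAPE[1]:
            raise ValueError("time_mask_max_T exceeds image width")


def _center_crop_or_pad(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = img
    for axis, target in enumerate(shape):
        size = out.shape[axis]
        if size > target:
            start = (size - target) // 2
            out = out.take(np.arange(start, start + target), axis=axis)
        elif size < target:
            before = (target - size) // 2
            after = target - size - before
            pad = [(0, 0), (0, 0)]
            pad[axis] = (before, after)
            out = np.pad(out, pad, mode="edge")
    return out


def augment(img: NetInputImage, policy: AugmentationPolicy,
            rng: np.random.Generator | None = None) -> NetInputImage:
    """Apply the augmentation pipeline; output shape is unchanged.

    A disabled policy returns the input unchanged.  The generator is
    seeded from ``policy.rng_seed`` unless one is passed explicitly.
    """
    if not policy.enabled:
        return img
    if rng is None:
        rng = np.random.default_rng(policy.rng_seed)
    h, w = NET_INPUT_SHAPE
    x = img.pixels.copy()

    if policy.crop_pad_px > 0:
        p = int(policy.crop_pad_px)
        padded = np.pad(x, p, mode="edge")
        r0 = int(rng.integers(0, 2 * p + 1))
        c0 = int(rng.integers(0, 2 * p + 1))
        x = padded[r0:r0 + h, c0:c0 + w]

    if policy.rotation_max_deg > 0:
        deg = float(rng.uniform(-policy.rotation_max_deg, policy.rotation_max_deg))
        x = _ndrotate(x, deg, reshape=False, order=1, mode="nearest")

    lo, hi = policy.rescale_range
    if not (lo == hi == 1.0):
        factor = float(rng.uniform(lo, hi))
        if abs(factor - 1.0) > 1e-9:
            new_shape = (max(1, round(h * factor)), max(1, round(w * factor)))
            x = _resize(x, new_shape, order=1, mode="edge",
                        anti_aliasing=False, preserve_range=True)
            x = _center_crop_or_pad(x, (h, w))

    if policy.gauss_sigma > 0:
        sd = policy.gauss_sigma * img.pixels.std()
        if sd > 0:
            x = x + rng.normal(0.0, sd, size=x.shape)

    fill = x.mean()
    for _ in range(policy.n_freq_masks):
        width = int(rng.integers(0, policy.freq_mask_max_F + 1))
        if width > 0:
            r0 = int(rng.integers(0, h - width + 1))
            x[r0:r0 + width, :] = fill
    for _ in range(policy.n_time_masks):
        width = int(rng.integers(0, policy.time_mask_max_T + 1))
        if width > 0:
            c0 = int(rng.integers(0, w - width + 1))
            x[:, c0:c0 + width] = fill

    return NetInputImage(pixels=x, provenance=img.provenance,
                         sample_rate=img.sample_rate, n_fft=img.n_fft)
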