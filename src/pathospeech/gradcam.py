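"""Gradient-weighted class activation maps from the fusion convolution.

The heatmap is computed at the last convolution of the network (the
512-filter fusion conv, post BN+ReLU): channel weights are the spatial
means of the target logit's gradient, the map is the ReLU of the
weighted activation sum, bilinearly upsampled to the 128x256 input
geometry.  Gradients are taken on the pre-softmax logit, so the map is
invariant to adding a constant to all logits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _resize

from .model import SkipAttentionNet
from .nn.tensor import Tensor
from .spectrogram import NET_INPUT_SHAPE, NetInputImage, net_input_row_freqs


@dataclass
class Heatmap:
    values: np.ndarray       # last-conv resolution, >= 0
    upsampled: np.ndarray    # 128x256, >= 0, raw scale
    normalized: np.ndarray   # 128x256 in [0, 1] for rendering
    target_class: int
    predicted_class: int
    probabilities: np.ndarray


def grad_cam(model: SkipAttentionNet, img: NetInputImage | np.ndarray,
             target_class: int | None = None) -> Heatmap:
    """Class activation heatmap for one input image.

    ``target_class`` defaults to the model's predicted class.
    """
    pixels = img.pixels if isinstance(img, NetInputImage) else np.asarray(img)
    if pixels.shape != NET_INPUT_SHAPE:
        raise ValueError(f"expected a {NET_INPUT_SHAPE} image, got {pixels.shape}")
    model.eval()
    dtype = model.fc1.weight.dtype
    x = Tensor(pixels.astype(dtype)[None, :, :, None])
    logits, fused = model.forward(x, capture_fusion=True)
    fused.retain_grad = True

    probs = np.exp(logits.data[0] - logits.data[0].max())
    probs = probs / probs.sum()
    predicted = int(np.argmax(logits.data[0]))
    if target_class is None:
        target_class = predicted
    if target_class not in (0, 1):
        raise ValueError(f"target_class must be 0 or 1, got {target_class}")

    seed = np.zeros_like(logits.data)
    seed[0, target_class] = 1.0   # pre-softmax logit of the target class
    model.zero_grad()
    logits.backward(seed)

    activ = fused.data[0]                      # (h, w, c)
    alpha = fused.grad[0].mean(axis=(0, 1))    # spatial mean per channel
    cam = np.maximum(activ @ alpha, 0.0).astype(np.float64)
    up = _resize(cam, NET_INPUT_SHAPE, order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    up = np.maximum(up, 0.0)
    peak = up.max()
    norm = up / peak if peak > 0 else np.zeros_like(up)
    return Heatmap(values=cam, upsampled=up, normalized=norm,
                   target_class=target_class, predicted_class=predicted,
                   probabilities=probs)


def band_energy_share(hm: Heatmap, cutoff_hz: float,
                      sample_rate: int = 44100, n_fft: int = 2048) -> float:
    """Fraction of heat mass in rows above ``cutoff_hz``.

    An all-zero heatmap yields 0 with a warning.
    """
    if not (0 <= cutoff_hz <= sample_rate / 2):
        raise ValueError(f"cutoff {cutoff_hz} Hz outside [0, Nyquist]")
    freqs = net_input_row_freqs(sample_rate=sample_rate, n_fft=n_fft)
    total = hm.upsampled.sum()
    if total <= 0:
        warnings.warn("all-zero heatmap; band energy share defined as 0")
        return 0.0
    return float(hm.upsampled[freqs > cutoff_hz, :].sum() / total)


def render_overlay(img: NetInputImage | np.ndarray, hm: Heatmap, path,
                   alpha: float = 0.4) -> None:
    """Side-by-side spectrogram image and heatmap overlay PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pixels = img.pixels if isinstance(img, NetInputImage) else np.asarray(img)
    fig, axes = plt.subplots(1, 2, figsize=(10, 3.2))
    for ax in axes:
        ax.set_xlabel("time frame")
        ax.set_ylabel("frequency row")
    axes[0].imshow(pixels, origin="lower", aspect="auto", cmap="magma")
    axes[0].set_title("input spectrogram image")
    axes[1].imshow(pixels, origin="lower", aspect="auto", cmap="gray")
    axes[1].imshow(hm.normalized, origin="lower", aspect="auto",
                   cmap="viridis", alpha=alpha)
    axes[1].set_title(f"class {hm.target_class} activation map")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
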