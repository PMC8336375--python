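"""Skip-attention spectrogram CNN for two-class pathological-speech detection.

The architecture is a VGG-style backbone of four double-conv blocks
(64/128/256/512 filters at full width, 3x3 kernels, Conv-BN-ReLU, 2x2
max pooling) whose three intermediate block outputs are routed past the
deeper layers through skip connections: each tap is average-pooled to
the final 8x16 grid, projected by its own 3x3 conv to 512 channels, and
concatenated with the backbone output into a 2048-channel map.  A
convolutional block attention module (CBAM: channel gating from shared
avg/max-pooled MLPs, then spatial gating from a 7x7 conv over the
channel mean/max) refines the merged map, a 512-filter 3x3 fusion conv
condenses it, and global average pooling feeds a 512-2 classification
head with softmax output.

At width scale 1 the main path has exactly 12 convolution layers
(8 backbone + 3 skip projections + 1 fusion).  ``width_scale`` shrinks
every filter count proportionally for desk-scale experiments; the
2-way head is fixed.  Ablation variants disable the skip connections
and/or the attention module.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor

VARIANTS = ("backbone", "backbone_sc", "backbone_cbam", "full")


class ConfigError(ValueError):
    pass


@dataclass
class NetConfig:
    block_filters: tuple[int, int, int, int] = (64, 128, 256, 512)
    skip_filters: int = 512
    merged_channels: int | None = None   # validated against the concat identity
    cbam_reduction_ratio: int = 16
    cbam_spatial_kernel: int = 7
    fusion_filters: int = 512
    head_sizes: tuple[int, int] = (512, 2)
    input_shape: tuple[int, int, int] = (1, 128, 256)
    width_scale: float = 1.0
    variant: str = "full"
    merge_mode: str = "concat"           # "concat" honors the 2048-wide merge; "add" optional
    seed: int = 0

    def scaled(self, n: int) -> int:
        return max(1, round(n * self.width_scale))

    @property
    def merged_width(self) -> int:
        if self.merge_mode == "add":
            return self.scaled(self.block_filters[3])
        return self.scaled(self.block_filters[3]) + 3 * self.scaled(self.skip_filters)

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(f"variant must be one of {VARIANTS}")
        if self.width_scale <= 0:
            raise ConfigError("width_scale must be positive")
        if self.head_sizes[1] != 2:
            raise ConfigError("the classification head is fixed at 2 outputs")
        if self.merge_mode not in ("concat", "add"):
            raise ConfigError("merge_mode must be 'concat' or 'add'")
        if self.merged_channels is not None and self.merged_channels != self.merged_width:
            raise ConfigError(
                "merged_channels mismatch: expected block_filters[3]*ws + "
                f"3*skip_filters*ws = {self.merged_width}, got {self.merged_channels}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        d = dict(d)
        for key in ("block_filters", "head_sizes", "input_shape"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class AttentionOutput:
    """CBAM result: sigmoid gate values and the refined feature map."""

    channel_weights: np.ndarray   # (N, C), in (0, 1)
    spatial_map: np.ndarray       # (N, H, W), in (0, 1)
    refined: Tensor


class CBAM(nn.Module):
    """Convolutional block attention: channel gating then spatial gating.

    Channel attention: sigmoid(MLP(avgpool(f)) + MLP(maxpool(f))) with a
    shared two-layer MLP (C -> C/r -> C, ReLU between).  Spatial
    attention: sigmoid(conv_kxk(concat(channel-mean, channel-max))).
    """

    def __init__(self, channels: int, reduction: int, spatial_kernel: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        hidden = channels // reduction
        if hidden < 1:
            warnings.warn(f"CBAM reduction {reduction} exceeds channel count "
                          f"{channels}; flooring MLP hidden size at 1")
            hidden = 1
        self.fc1 = nn.Linear(channels, hidden, rng, dtype=dtype)
        self.fc2 = nn.Linear(hidden, channels, rng, dtype=dtype)
        self.spatial_conv = nn.Conv2d(2, 1, spatial_kernel, rng, bias=True, dtype=dtype)

    def _channel_gate(self, f: Tensor) -> Tensor:
        avg = T.global_avgpool(f)
        mx = T.spatial_max(f)
        shared = lambda v: self.fc2(T.relu(self.fc1(v)))
        return T.sigmoid(T.add(shared(avg), shared(mx)))  # (N, C)

    def forward(self, f: Tensor) -> AttentionOutput:
        n, h, w, c = f.shape
        mc = self._channel_gate(f)
        f_c = T.mul(f, T.reshape(mc, (n, 1, 1, c)))
        pooled = T.concat([T.channel_mean(f_c), T.channel_max(f_c)], axis=3)
        ms = T.sigmoid(self.spatial_conv(pooled))  # (N, H, W, 1)
        refined = T.mul(f_c, ms)
        return AttentionOutput(channel_weights=mc.data,
                               spatial_map=ms.data[..., 0], refined=refined)


class SkipAttentionNet(nn.Module):
    """The full detector; ``config.variant`` selects ablation variants."""

    def __init__(self, config: NetConfig, dtype=np.float32):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        s = config.scaled
        cin = config.input_shape[0]
        self.blocks: list[list[nn.Module]] = []
        for bf in config.block_filters:
            cout = s(bf)
            self.blocks.append([nn.ConvBNReLU(cin, cout, 3, rng, dtype=dtype),
                                nn.ConvBNReLU(cout, cout, 3, rng, dtype=dtype)])
            cin = cout
        self._block_modules = [m for blk in self.blocks for m in blk]

        self.use_skips = config.variant in ("backbone_sc", "full")
        self.use_cbam = config.variant in ("backbone_cbam", "full")
        self.skip_pool_strides = (8, 4, 2)
        if self.use_skips:
            skip_out = s(config.skip_filters)
            self.skip_projs = [nn.ConvBNReLU(s(bf), skip_out, 3, rng, dtype=dtype)
                               for bf in config.block_filters[:3]]
            fusion_in = config.merged_width
        else:
            self.skip_projs = []
            fusion_in = s(config.block_filters[3])
        if self.use_cbam:
            self.cbam_module = CBAM(fusion_in, config.cbam_reduction_ratio,
                                    config.cbam_spatial_kernel, rng, dtype=dtype)
        else:
            self.cbam_module = None
        self.fusion = nn.ConvBNReLU(fusion_in, s(config.fusion_filters), 3, rng, dtype=dtype)
        self.fc1 = nn.Linear(s(config.fusion_filters), s(config.head_sizes[0]), rng, dtype=dtype)
        self.fc2 = nn.Linear(s(config.head_sizes[0]), config.head_sizes[1], rng, dtype=dtype)

    # -- pieces, exposed for inspection and tests ----------------------
    def forward_backbone(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        """Run the four blocks; returns (final 512ch@8x16, taps of blocks 1-3).

        ``x`` is (N, H, W, 1); feature maps are channels-last throughout.
        """
        _, h, w, _ = x.shape
        expected = self.config.input_shape[1:]
        if (h, w) != expected:
            raise ValueError(f"input spatial size {(h, w)} does not match "
                             f"expected {expected}")
        taps = []
        out = x
        for i, blk in enumerate(self.blocks):
            for unit in blk:
                out = unit(out)
            out = T.maxpool2x2(out)
            if i < 3:
                taps.append(out)
        return out, taps

    def apply_skip_connections(self, final: Tensor, taps: list[Tensor]) -> Tensor:
        pieces = []
        for tap, proj, stride in zip(taps, self.skip_projs, self.skip_pool_strides):
            pieces.append(proj(T.avgpool(tap, stride)))
        if self.config.merge_mode == "add":
            merged = final
            for p in pieces:
                merged = T.add(merged, p)
            return merged
        return T.concat(pieces + [final], axis=3)

    def cbam(self, f: Tensor) -> AttentionOutput:
        if self.cbam_module is None:
            raise RuntimeError(f"variant {self.config.variant!r} has no CBAM")
        return self.cbam_module(f)

    def classify_from_fusion(self, fused: Tensor) -> Tensor:
        pooled = T.global_avgpool(fused)
        hidden = T.relu(self.fc1(pooled))
        return self.fc2(hidden)  # logits; softmax applied by callers

    # -- full forward ---------------------------------------------------
    def forward(self, x: Tensor, capture_fusion: bool = False):
        final, taps = self.forward_backbone(x)
        merged = self.apply_skip_connections(final, taps) if self.use_skips else final
        if self.use_cbam:
            merged = self.cbam_module(merged).refined
        fused = self.fusion(merged)
        logits = self.classify_from_fusion(fused)
        if capture_fusion:
            return logits, fused
        return logits

    def predict_proba(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Class probabilities for (N, H, W) or (N, H, W, 1) image arrays."""
        if images.ndim == 3:
            images = images[..., None]
        self.eval()
        out = []
        dtype = self.fc1.weight.dtype
        with T.no_grad():
            for i in range(0, images.shape[0], batch_size):
                logits = self.forward(Tensor(images[i:i + batch_size].astype(dtype)))
                out.append(T.softmax(logits.data, axis=1))
        return np.concatenate(out, axis=0)

    # -- introspection ---------------------------------------------------
    def conv_layer_count(self) -> int:
        """Main-path convolution layers (backbone + skip projections + fusion)."""
        return len(self._block_modules) + len(self.skip_projs) + 1

    def layer_inventory(self) -> dict:
        s = self.config.scaled
        return {
            "conv_layers": self.conv_layer_count(),
            "max_pool_layers": len(self.blocks),
            "skip_avg_pool_layers": len(self.skip_projs),
            "global_avg_pool_layers": 1,
            "merged_channels": (self.config.merged_width if self.use_skips
                                else s(self.config.block_filters[3])),
            "head_sizes": (s(self.config.head_sizes[0]), self.config.head_sizes[1]),
            "cbam": self.use_cbam,
            "skip_connections": self.use_skips,
            "n_parameters": self.n_parameters(),
        }

    def summary_json(self) -> str:
        return json.dumps({"config": self.config.to_dict(),
                           "inventory": self.layer_inventory()}, indent=2)

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        state = self.state_dict()
        state["__config__"] = np.array(json.dumps(self.config.to_dict()))
        np.savez(Path(path), **state)

    @classmethod
    def load(cls, path: str | Path) -> "SkipAttentionNet":
        with np.load(Path(path), allow_pickle=False) as data:
            cfg = NetConfig.from_dict(json.loads(str(data["__config__"])))
            model = cls(cfg)
            state = {k: data[k] for k in data.files if k != "__config__"}
        model.load_state_dict(state)
        return model


def build_model(config: NetConfig | None = None, **overrides) -> SkipAttentionNet:
    """Build the detector from a config (validated) or keyword overrides."""
    if config is None:
        config = NetConfig(**overrides)
    return SkipAttentionNet(config)
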