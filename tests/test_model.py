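"""Architecture, variants, persistence and the width-scaling rules."""

from __future__ import annotations

import numpy as np
import pytest

from pathospeech.model import (VARIANTS, CBAM, ConfigError, NetConfig,
                               SkipAttentionNet, build_model)
from pathospeech.nn.tensor import Tensor

SMALL = dict(width_scale=0.0625, seed=0)


def test_full_width_inventory_is_frozen():
    inv = build_model(NetConfig()).layer_inventory()
    assert inv == {
        "conv_layers": 12,
        "max_pool_layers": 4,
        "skip_avg_pool_layers": 3,
        "global_avg_pool_layers": 1,
        "merged_channels": 2048,
        "head_sizes": (512, 2),
        "cbam": True,
        "skip_connections": True,
        "n_parameters": 16982053,
    }


def test_width_scale_shrinks_channels_not_structure():
    model = build_model(NetConfig(**SMALL))
    inv = model.layer_inventory()
    assert inv["conv_layers"] == 12
    assert inv["merged_channels"] == 32 + 3 * 32   # 2048 / 16
    assert inv["head_sizes"] == (32, 2)
    assert inv["n_parameters"] < 200_000


@pytest.mark.parametrize("variant", VARIANTS)
def test_variants_toggle_skips_and_attention(variant):
    model = build_model(NetConfig(variant=variant, **SMALL))
    inv = model.layer_inventory()
    assert inv["skip_connections"] == (variant in ("backbone_sc", "full"))
    assert inv["cbam"] == (variant in ("backbone_cbam", "full"))
    assert inv["conv_layers"] == (12 if inv["skip_connections"] else 9)
    rng = np.random.default_rng(1)
    probs = model.predict_proba(rng.standard_normal((2, 128, 256)))
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_forward_rejects_wrong_spatial_size():
    model = build_model(NetConfig(**SMALL))
    with pytest.raises(ValueError, match="spatial size"):
        model.forward(Tensor(np.zeros((1, 64, 256, 1), dtype=np.float32)))


def test_config_validation_errors():
    with pytest.raises(ConfigError):
        build_model(NetConfig(variant="resnet"))
    with pytest.raises(ConfigError):
        build_model(NetConfig(width_scale=0.0))
    with pytest.raises(ConfigError):
        build_model(NetConfig(head_sizes=(512, 3)))
    with pytest.raises(ConfigError):
        build_model(NetConfig(merged_channels=1000))
    NetConfig(merged_channels=2048).validate()  # the true merge width is fine


def test_save_load_roundtrip(tmp_path):
    model = build_model(NetConfig(**SMALL))
    rng = np.random.default_rng(4)
    images = rng.standard_normal((3, 128, 256))
    before = model.predict_proba(images)
    path = tmp_path / "model.npz"
    model.save(path)
    restored = SkipAttentionNet.load(path)
    assert restored.config == model.config
    np.testing.assert_allclose(restored.predict_proba(images), before, atol=1e-7)


def test_seed_controls_initialization():
    a = build_model(NetConfig(width_scale=0.0625, seed=1))
    b = build_model(NetConfig(width_scale=0.0625, seed=1))
    c = build_model(NetConfig(width_scale=0.0625, seed=2))
    img = np.zeros((1, 128, 256))
    img[0, 40:60, 100:140] = 1.0
    np.testing.assert_array_equal(a.predict_proba(img), b.predict_proba(img))
    assert not np.array_equal(a.predict_proba(img), c.predict_proba(img))


def test_cbam_warns_when_reduction_exceeds_channels():
    with pytest.warns(UserWarning, match="reduction"):
        CBAM(channels=4, reduction=16, spatial_kernel=7,
             rng=np.random.default_rng(0))


def test_capture_fusion_returns_last_conv_map():
    model = build_model(NetConfig(**SMALL))
    x = Tensor(np.random.default_rng(0).standard_normal(
        (1, 128, 256, 1)).astype(np.float32))
    logits, fused = model.forward(x, capture_fusion=True)
    assert logits.shape == (1, 2)
    assert fused.shape == (1, 8, 16, model.config.scaled(512))
    assert (fused.data >= 0).all()   # post-ReLU activations
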