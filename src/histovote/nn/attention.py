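"""Channel and spatial attention (CBAM-style sequential gating).

Channel attention answers *what* feature channels matter: global
average- and max-pooled channel descriptors pass through a shared
two-layer bottleneck, are summed, and squashed with a sigmoid into
per-channel gates in (0, 1).  Spatial attention answers *where*:
channel-wise average and max maps are stacked and convolved with a
single wide kernel, and the sigmoid of the response gates every spatial
location.  Both preserve the tensor shape; applied sequentially,
channel first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Conv2D, Layer, _he_normal

__all__ = [
    "AttentionConfig",
    "ChannelAttention",
    "SpatialAttention",
    "channel_attention",
    "spatial_attention",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class AttentionConfig:
    """Channel-bottleneck reduction ratio and spatial kernel width."""

    reduction_ratio: int = 16
    spatial_kernel: int = 7

    def __post_init__(self) -> None:
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be a positive integer")
        if self.spatial_kernel < 1 or self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be an odd positive integer")


class ChannelAttention(Layer):
    """Per-channel sigmoid gates from a shared pooled-descriptor MLP."""

    def __init__(self, channels: int, cfg: AttentionConfig = AttentionConfig(),
                 rng: np.random.Generator | None = None):
        if channels < 1:
            raise ValueError("channel count must be positive")
        if rng is None:
            rng = np.random.default_rng(0)
        hidden = max(channels // cfg.reduction_ratio, 1)
        self.channels = channels
        self.w1 = _he_normal(rng, (channels, hidden), channels)
        self.w2 = _he_normal(rng, (hidden, channels), hidden)
        self.n_params = channels * hidden + hidden * channels

    def gates(self, x: np.ndarray) -> np.ndarray:
        avg = x.mean(axis=(1, 2))  # N x C
        mx = x.max(axis=(1, 2))
        logits = np.maximum(avg @ self.w1, 0) @ self.w2 + np.maximum(mx @ self.w1, 0) @ self.w2
        return _sigmoid(logits)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x * self.gates(x)[:, None, None, :]


class SpatialAttention(Layer):
    """Per-location sigmoid gates from a wide conv over pooled maps."""

    def __init__(self, cfg: AttentionConfig = AttentionConfig(),
                 rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.conv = Conv2D(2, 1, cfg.spatial_kernel, rng)
        self.n_params = self.conv.n_params

    def gates(self, x: np.ndarray) -> np.ndarray:
        maps = np.stack([x.mean(axis=3), x.max(axis=3)], axis=3)  # N,H,W,2
        return _sigmoid(self.conv(maps)[..., 0])

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x * self.gates(x)[..., None]


def channel_attention(feature_map: np.ndarray, cfg: AttentionConfig = AttentionConfig(),
                      module: ChannelAttention | None = None,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply channel attention to one H x W x C map (or an NHWC batch)."""
    x = np.asarray(feature_map, dtype=np.float32)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    if module is None:
        module = ChannelAttention(x.shape[3], cfg, rng)
    out = module(x)
    return out[0] if squeeze else out


def spatial_attention(feature_map: np.ndarray, cfg: AttentionConfig = AttentionConfig(),
                      module: SpatialAttention | None = None,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply spatial attention to one H x W x C map (or an NHWC batch)."""
    x = np.asarray(feature_map, dtype=np.float32)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    if module is None:
        module = SpatialAttention(cfg, rng)
    out = module(x)
    return out[0] if squeeze else out
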