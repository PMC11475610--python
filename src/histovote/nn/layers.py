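"""Minimal NumPy layer zoo: forward passes and trainable-parameter counts.

Tensors are NHWC ``float32``.  Batch normalization and dropout run in
inference mode (identity transforms with the standard parameter
bookkeeping), which is all the desk-scale builders need.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "MaxPool2",
    "GlobalAvgPool",
    "Flatten",
    "Dense",
    "Dropout",
    "Softmax",
]


class Layer:
    """Base: a forward map plus a trainable-parameter count."""

    n_params: int = 0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv2D(Layer):
    """k x k convolution, stride 1, same padding, with bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator | None = None):
        if in_channels < 1 or out_channels < 1 or kernel < 1:
            raise ValueError("convolution dimensions must be positive")
        if rng is None:
            rng = np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = kernel * kernel * in_channels
        # weight layout: (Cin, k, k, Cout) so the forward contraction is
        # a single tensordot over the window axes
        self.weight = _he_normal(rng, (in_channels, kernel, kernel, out_channels), fan_in)
        self.bias = np.zeros(out_channels, dtype=np.float32)
        self.n_params = fan_in * out_channels + out_channels

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        k = self.kernel
        if k == 1:
            out = np.tensordot(x, self.weight[:, 0, 0, :], axes=([3], [0]))
        else:
            pad = k // 2
            xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
            win = sliding_window_view(xp, (k, k), axis=(1, 2))  # N,H,W,C,k,k
            out = np.tensordot(win, self.weight, axes=([3, 4, 5], [0, 1, 2]))
        return (out + self.bias).astype(np.float32)


class BatchNorm(Layer):
    """Per-channel affine normalization (inference statistics).

    Counts the two trainable vectors (scale, shift); the running mean
    and variance start at 0 and 1 so an untrained layer is the identity.
    """

    def __init__(self, channels: int):
        self.channels = channels
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps = 1e-3
        self.n_params = 2 * channels

    def forward(self, x: np.ndarray) -> np.ndarray:
        scale = self.gamma / np.sqrt(self.running_var + self.eps)
        return (x - self.running_mean) * scale + self.beta


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.maximum(x, 0)


class MaxPool2(Layer):
    """2 x 2 max pooling, stride 2; odd trailing rows/columns dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        if h2 < 1 or w2 < 1:
            raise ValueError("spatial size collapsed below 2 x 2 before pooling")
        return x[:, : h2 * 2, : w2 * 2].reshape(n, h2, 2, w2, 2, c).max(axis=(2, 4))


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.mean(axis=(1, 2))


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.reshape(x.shape[0], -1)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = _he_normal(rng, (in_features, out_features), in_features)
        self.bias = np.zeros(out_features, dtype=np.float32)
        self.n_params = in_features * out_features + out_features

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x @ self.weight + self.bias


class Dropout(Layer):
    """Identity at inference; kept in the graph for spec fidelity."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x


class Softmax(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)
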