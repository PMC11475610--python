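"""Build model graphs from specs: forward pass, summary, parameter count."""

from __future__ import annotations

import numpy as np

from .attention import AttentionConfig, ChannelAttention, SpatialAttention
from .layers import (
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    GlobalAvgPool,
    Layer,
    MaxPool2,
    ReLU,
    Softmax,
)
from .specs import BlockSpec, ModelSpec

__all__ = [
    "Block",
    "Model",
    "build_block",
    "build_model",
    "build_transfer_head",
    "count_parameters",
]


class Block(Layer):
    """One convolution block instance bound to its input channel count.

    Layout: [1x1 conv + BN + ReLU] (when a pointwise bottleneck is
    specified) -> 3x3 conv, same padding + BN + ReLU -> channel
    attention -> spatial attention (when attention is on).
    """

    def __init__(self, spec: BlockSpec, in_channels: int,
                 cfg: AttentionConfig = AttentionConfig(),
                 rng: np.random.Generator | None = None):
        if in_channels < 1:
            raise ValueError("in_channels must be positive")
        if rng is None:
            rng = np.random.default_rng(0)
        self.spec = spec
        self.in_channels = in_channels
        self.layers: list[Layer] = []
        c = in_channels
        if spec.pointwise_filters is not None:
            self.layers += [Conv2D(c, spec.pointwise_filters, 1, rng),
                            BatchNorm(spec.pointwise_filters), ReLU()]
            c = spec.pointwise_filters
        self.layers += [Conv2D(c, spec.conv_filters, 3, rng),
                        BatchNorm(spec.conv_filters), ReLU()]
        self.attention_modules: list[Layer] = []
        if spec.attention:
            self.attention_modules = [
                ChannelAttention(spec.conv_filters, cfg, rng),
                SpatialAttention(cfg, rng),
            ]
        self.out_channels = spec.conv_filters

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers + self.attention_modules)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        for layer in self.attention_modules:
            x = layer(x)
        return x


def build_block(spec: BlockSpec, in_channels: int,
                cfg: AttentionConfig = AttentionConfig(),
                rng: np.random.Generator | None = None) -> Block:
    """One block instance for a given input channel count."""
    return Block(spec, in_channels, cfg, rng)


class Model:
    """A built network: pooled block stages plus a dense head."""

    def __init__(self, spec: ModelSpec, stages: list[tuple[list[Block], bool]],
                 head: list[Layer]):
        self.spec = spec
        self.stages = stages
        self.head = head

    @property
    def n_params(self) -> int:
        total = sum(b.n_params for blocks, _ in self.stages for b in blocks)
        return total + sum(l.n_params for l in self.head)

    @property
    def n_blocks(self) -> int:
        return sum(len(blocks) for blocks, _ in self.stages)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map an NHWC float batch to stochastic class-probability rows."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[3] != self.spec.channels:
            raise ValueError(
                f"expected NHWC input with {self.spec.channels} channels"
            )
        pool = MaxPool2()
        for stage_idx, (blocks, pooled) in enumerate(self.stages):
            # concatenation links are active from the second stage on
            concat = self.spec.residual_concat and stage_idx >= 1
            for block in blocks:
                out = block(x)
                x = np.concatenate([out, x], axis=3) if concat else out
            if concat:
                x = out  # links reset at the pooling boundary
            if pooled:
                x = pool(x)
        for layer in self.head:
            x = layer(x)
        return x

    __call__ = forward

    def summary(self) -> str:
        lines = [f"model: {self.spec.name}",
                 f"input: {self.spec.input_size}x{self.spec.input_size}x{self.spec.channels}",
                 f"stages: {len(self.stages)} "
                 f"(blocks per stage: {', '.join(str(len(b)) for b, _ in self.stages)})",
                 f"blocks total: {self.n_blocks}"]
        for i, (blocks, pooled) in enumerate(self.stages, start=1):
            b = blocks[0].spec
            pw = f"1x1/{b.pointwise_filters} + " if b.pointwise_filters else ""
            attn = " +attention" if b.attention else ""
            lines.append(
                f"  stage {i}: {len(blocks)} x [{pw}3x3/{b.conv_filters}]{attn}"
                + (" -> maxpool" if pooled else "")
            )
        head_desc = "GAP" if self.spec.global_pool else "flatten"
        dense = " -> ".join(str(u) for u in self.spec.dense_units)
        lines.append(
            f"head: {head_desc} -> {dense} (dropout {self.spec.dropout_rate}) "
            f"-> softmax/{self.spec.num_categories}"
        )
        lines.append(f"trainable parameters: {self.n_params}")
        return "\n".join(lines)


def build_model(spec: ModelSpec, cfg: AttentionConfig = AttentionConfig(),
                seed: int = 0) -> Model:
    """Instantiate a spec into a forward-capable graph.

    Stages are chained with 2x2 max pooling; when concatenation links
    are on, block k of a stage (second stage onward) receives
    ``concat(output_{k-1}, input_{k-1})`` along channels, and the links
    reset at each pooling boundary.  The head is global average pooling
    (or flatten) -> dense stack with ReLU, dropout after the first dense
    layer -> softmax.
    """
    rng = np.random.default_rng(seed)
    stages: list[tuple[list[Block], bool]] = []
    channels = spec.channels
    size = spec.input_size
    for stage_idx, stage in enumerate(spec.stages):
        concat = spec.residual_concat and stage_idx >= 1
        blocks: list[Block] = []
        for bspec in stage.blocks:
            for _ in range(bspec.repeat):
                block = Block(bspec, channels, cfg, rng)
                blocks.append(block)
                channels = block.out_channels + channels if concat else block.out_channels
        if concat:
            channels = blocks[-1].out_channels
        if stage.followed_by_pool:
            size //= 2
            if size < 1:
                raise ValueError("pooling collapsed the spatial size below 1 px")
        stages.append((blocks, stage.followed_by_pool))

    head: list[Layer] = []
    if spec.global_pool:
        head.append(GlobalAvgPool())
        feat = channels
    else:
        head.append(Flatten())
        feat = channels * size * size
    for i, units in enumerate(spec.dense_units):
        head += [Dense(feat, units, rng), ReLU()]
        if i == 0:
            head.append(Dropout(spec.dropout_rate))
        feat = units
    head += [Dense(feat, spec.num_categories, rng), Softmax()]
    return Model(spec, stages, head)


class TransferHead(Layer):
    """Dense classification head appended to a backbone's pooled features."""

    def __init__(self, layers: list[Layer], dense_units: tuple[int, ...],
                 dropout_rate: float):
        self.layers = layers
        self.dense_units = dense_units
        self.dropout_rate = dropout_rate

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            x = layer(x)
        return x


def build_transfer_head(feature_dim: int, dense_units: tuple[int, int] = (512, 256),
                        dropout_rate: float = 0.2, num_categories: int = 8,
                        seed: int = 0) -> TransferHead:
    """Classification head for the transfer-learning path.

    Defaults follow the grid-search optimum for that path: dense 512 ->
    dense 256 -> dropout 0.2 -> softmax over 8 categories.  Maps
    N x feature_dim feature batches to stochastic N x num_categories rows.
    """
    if feature_dim < 1:
        raise ValueError("feature_dim must be positive")
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    feat = feature_dim
    for units in dense_units:
        layers += [Dense(feat, units, rng), ReLU()]
        feat = units
    layers += [Dropout(dropout_rate), Dense(feat, num_categories, rng), Softmax()]
    return TransferHead(layers, tuple(dense_units), dropout_rate)


def count_parameters(model: Model | Layer) -> int:
    """Total trainable parameters of a built model, head, or single layer."""
    return model.n_params
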