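"""Declarative model specs for the custom CNN family (C1-C20).

A model is a chain of pooled stages.  Each stage repeats one or more
convolution blocks; a block is an optional 1x1 pointwise convolution
(channel bottleneck) followed by a 3x3 convolution, each batch
normalized, optionally capped by channel+spatial attention.  Models may
additionally link blocks within a stage by channel concatenation
(DenseNet-style): from the second stage on, block k receives the
concatenation of block k-1's output with block k-1's input.  The head
is global average pooling (or flatten) into a small dense stack with
dropout and a softmax over the tumor categories.

``multihisnet_spec`` is the deepest preset of the family: 28
attention-bearing blocks in 6 pooled stages with per-stage repeats
(2, 2, 4, 4, 10, 6), concatenation links, and a 512 -> dropout 0.4 ->
128 -> 8 head.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Sequence

import yaml

__all__ = [
    "BlockSpec",
    "StageSpec",
    "ModelSpec",
    "multihisnet_spec",
    "custom_spec",
    "CUSTOM_MODEL_IDS",
]


@dataclass(frozen=True)
class BlockSpec:
    """One convolution block, possibly repeated within its stage."""

    conv_filters: int
    pointwise_filters: int | None = None
    attention: bool = False
    repeat: int = 1

    def __post_init__(self) -> None:
        if self.conv_filters < 1:
            raise ValueError("conv_filters must be positive")
        if self.pointwise_filters is not None and self.pointwise_filters < 1:
            raise ValueError("pointwise_filters must be positive when set")
        if self.repeat < 1:
            raise ValueError("repeat must be at least 1")


@dataclass(frozen=True)
class StageSpec:
    """Blocks executed at one spatial resolution, then optionally pooled."""

    blocks: tuple[BlockSpec, ...]
    followed_by_pool: bool = True

    def __post_init__(self) -> None:
        if len(self.blocks) < 1:
            raise ValueError("a stage needs at least one block")

    @property
    def n_blocks(self) -> int:
        return sum(b.repeat for b in self.blocks)


@dataclass(frozen=True)
class ModelSpec:
    """Full architecture description: stages plus the dense head."""

    stages: tuple[StageSpec, ...]
    input_size: int = 224
    channels: int = 3
    residual_concat: bool = False
    global_pool: bool = True
    dense_units: tuple[int, ...] = (512, 128)
    dropout_rate: float = 0.4
    num_categories: int = 8
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.stages) < 1:
            raise ValueError("a model needs at least one stage")
        if not self.dense_units:
            raise ValueError("dense_units must be non-empty")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        n_pools = sum(s.followed_by_pool for s in self.stages)
        if self.input_size // (2 ** n_pools) < 1:
            raise ValueError(
                f"input size {self.input_size} collapses below 1 px after "
                f"{n_pools} pooling stages"
            )

    @property
    def n_blocks(self) -> int:
        return sum(s.n_blocks for s in self.stages)

    @property
    def stage_block_counts(self) -> tuple[int, ...]:
        return tuple(s.n_blocks for s in self.stages)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        stages = tuple(
            StageSpec(
                blocks=tuple(BlockSpec(**b) for b in s["blocks"]),
                followed_by_pool=s.get("followed_by_pool", True),
            )
            for s in d["stages"]
        )
        rest = {k: v for k, v in d.items() if k != "stages"}
        for key in ("dense_units",):
            if key in rest:
                rest[key] = tuple(rest[key])
        return cls(stages=stages, **rest)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(text))


def _stage(entries: Sequence[tuple[int | None, int, int]], attention: bool) -> StageSpec:
    """Build a stage from (pointwise, conv, repeat) triples."""
    return StageSpec(
        blocks=tuple(
            BlockSpec(conv_filters=c, pointwise_filters=pw, attention=attention, repeat=r)
            for pw, c, r in entries
        )
    )


# The grid: per model, stage layer triples (pointwise, 3x3 filters, repeat),
# head layout, and which structural features are switched on.
_PLAIN = {
    # id: (stages, flatten_head, dense1, dropout, dense2, residual)
    "C1": ([[(None, 16, 1)], [(None, 32, 2)], [(None, 64, 2)], [(None, 128, 2)],
            [(None, 256, 3)]], True, 512, 0.2, 256, False),
    "C2": ([[(None, 16, 1)], [(None, 32, 2)], [(None, 64, 2)], [(None, 128, 2)],
            [(None, 256, 3)]], False, 512, 0.2, 256, False),
    "C3": ([[(None, 16, 2)], [(None, 32, 2)], [(None, 64, 2)], [(None, 128, 2)],
            [(None, 256, 2)], [(None, 512, 2)]], False, 512, 0.2, 256, False),
    "C4": ([[(None, 16, 2)], [(None, 32, 2)], [(None, 64, 2)], [(None, 128, 2)],
            [(None, 256, 2), (None, 512, 2)]], False, 512, 0.2, 256, False),
    "C5": ([[(None, 16, 2)], [(None, 32, 2)], [(None, 64, 2)], [(None, 128, 2)],
            [(None, 256, 3)]], False, 1024, 0.2, 256, False),
    "C6": ([[(None, 16, 2)], [(None, 32, 2)], [(None, 64, 2)], [(None, 128, 2)],
            [(None, 256, 2), (None, 512, 1)]], False, 512, 0.3, 128, False),
    "C7": ([[(None, 16, 2)], [(None, 32, 2)], [(None, 64, 2)], [(None, 128, 2)],
            [(None, 256, 1), (None, 512, 2)]], False, 512, 0.2, 128, False),
    "C8": ([[(None, 16, 2)], [(None, 32, 2)], [(None, 64, 2)], [(None, 128, 2)],
            [(None, 256, 2)], [(None, 256, 2)], [(None, 512, 3)]],
           False, 512, 0.4, 128, True),
    "C9": ([[(None, 16, 2)], [(None, 32, 2)], [(None, 64, 2)], [(None, 128, 2)],
            [(None, 256, 3)], [(None, 256, 1), (None, 512, 2)]],
           False, 512, 0.2, 96, True),
    "C10": ([[(None, 16, 2)], [(None, 32, 1), (None, 128, 1)],
             [(64, 64, 1), (None, 256, 1)], [(128, 128, 1), (None, 512, 1)],
             [(256, 256, 1), (None, 256, 1), (None, 512, 1)],
             [(256, 256, 1), (None, 512, 2)]], False, 512, 0.2, 128, True),
}

# Attention models share the Block A-E filter plan of the family:
# stage 1 = 3x3/32, then pointwise/conv pairs 32/64, 64/128, 128/256,
# 256/512; only the per-stage repeats (and C18's wide last stage) vary.
_ATTENTION = {
    # id: (stage repeats, dropout, residual, last_stage_conv)
    "C11": ((2, 2, 4, 4, 5, 8), 0.4, False, 512),
    "C12": ((2, 2, 4, 4, 5, 9), 0.4, False, 512),
    "C13": ((2, 3, 4, 5, 6, 9), 0.4, False, 512),
    "C14": ((2, 2, 4, 6, 4, 8), 0.3, False, 512),
    "C15": ((2, 2, 4, 4, 9, 5), 0.4, False, 512),
    "C16": ((2, 3, 4, 4, 5, 8), 0.4, False, 512),
    "C17": ((2, 2, 2, 3, 7), 0.4, False, 512),
    "C18": ((2, 2, 3, 3, 7, 3), 0.4, False, 1024),
    "C19": ((2, 2, 4, 4, 9, 5), 0.4, True, 512),
    "C20": ((2, 2, 4, 4, 10, 6), 0.4, True, 512),
}

_BLOCK_PLAN = [(None, 32), (32, 64), (64, 128), (128, 256), (256, 512), (256, 512)]

CUSTOM_MODEL_IDS: tuple[str, ...] = tuple(_PLAIN) + tuple(_ATTENTION)


def custom_spec(model_id: str) -> ModelSpec:
    """Spec for one member of the custom grid, ``C1`` through ``C20``."""
    mid = model_id.upper()
    if mid in _PLAIN:
        stages, flatten, d1, drop, d2, residual = _PLAIN[mid]
        return ModelSpec(
            stages=tuple(_stage(s, attention=False) for s in stages),
            residual_concat=residual,
            global_pool=not flatten,
            dense_units=(d1, d2),
            dropout_rate=drop,
            name=mid,
        )
    if mid in _ATTENTION:
        repeats, drop, residual, last_conv = _ATTENTION[mid]
        stages = []
        for i, rep in enumerate(repeats):
            pw, conv = _BLOCK_PLAN[i]
            if i == len(repeats) - 1 and i == 5:
                conv = last_conv
            stages.append(_stage([(pw, conv, rep)], attention=True))
        return ModelSpec(
            stages=tuple(stages),
            residual_concat=residual,
            global_pool=True,
            dense_units=(512, 128),
            dropout_rate=drop,
            name=mid,
        )
    raise KeyError(f"unknown custom model id {model_id!r}; expected C1..C20")


def multihisnet_spec() -> ModelSpec:
    """The deepest preset (grid id C20), called MultiHisNet.

    Five block types A-E with filter pairs (3x3/32, 1x1 32 + 3x3 64,
    1x1 64 + 3x3 128, 1x1 128 + 3x3 256, 1x1 256 + 3x3 512) repeated
    (2, 2, 4, 4, 10, 6) times across 6 pooled stages — 28 blocks in
    total, all attention-bearing, with in-stage concatenation links and
    a 512 -> dropout 0.4 -> 128 -> 8 dense head.
    """
    return replace(custom_spec("C20"), name="MultiHisNet")
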