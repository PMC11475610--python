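"""Model specs, attention gating, block/model building, parameter counts."""

import numpy as np
import pytest
from dataclasses import replace

from histovote.nn import (
    AttentionConfig,
    BlockSpec,
    ChannelAttention,
    Conv2D,
    Dense,
    ModelSpec,
    SpatialAttention,
    StageSpec,
    build_block,
    build_model,
    build_transfer_head,
    channel_attention,
    count_parameters,
    custom_spec,
    multihisnet_spec,
    spatial_attention,
)


class TestAttention:
    def setup_method(self):
        self.rng = np.random.default_rng(0)
        self.x = self.rng.uniform(0, 1, size=(12, 10, 16)).astype(np.float32)

    @pytest.mark.parametrize("fn", [channel_attention, spatial_attention])
    def test_shape_preserved(self, fn):
        out = fn(self.x, AttentionConfig(reduction_ratio=4, spatial_kernel=5))
        assert out.shape == self.x.shape

    @pytest.mark.parametrize("fn", [channel_attention, spatial_attention])
    def test_gates_shrink_nonnegative_inputs(self, fn):
        out = fn(self.x)
        assert np.all(out <= self.x + 1e-7)
        assert np.all(out >= 0)

    def test_channel_gate_forced_to_half(self):
        module = ChannelAttention(16, AttentionConfig())
        module.w2[:] = 0.0  # logits 0 -> sigmoid gives 0.5 per channel
        out = channel_attention(self.x, module=module)
        np.testing.assert_allclose(out, 0.5 * self.x, rtol=1e-6)

    def test_spatial_gate_forced_to_half(self):
        module = SpatialAttention(AttentionConfig())
        module.conv.weight[:] = 0.0
        module.conv.bias[:] = 0.0
        out = spatial_attention(self.x, module=module)
        np.testing.assert_allclose(out, 0.5 * self.x, rtol=1e-6)

    def test_reduction_ratio_clipped_to_channels(self):
        module = ChannelAttention(4, AttentionConfig(reduction_ratio=16))
        assert module.w1.shape == (4, 1)

    def test_even_spatial_kernel_rejected(self):
        with pytest.raises(ValueError):
            AttentionConfig(spatial_kernel=4)


class TestBlocks:
    def test_block_e_shapes(self):
        # deepest block type: 1x1/256 bottleneck then 3x3/512
        block = build_block(
            BlockSpec(conv_filters=512, pointwise_filters=256, attention=True),
            in_channels=256,
        )
        x = np.random.default_rng(1).normal(size=(1, 14, 14, 256)).astype(np.float32)
        assert block(x).shape == (1, 14, 14, 512)

    def test_attention_off_reduces_to_conv_bn(self):
        block = build_block(BlockSpec(conv_filters=8, attention=False), in_channels=3)
        assert block.attention_modules == []

    def test_pointwise_reduces_channels_before_conv(self):
        block = build_block(
            BlockSpec(conv_filters=512, pointwise_filters=256), in_channels=512
        )
        pointwise = block.layers[0]
        assert isinstance(pointwise, Conv2D)
        assert pointwise.kernel == 1
        assert (pointwise.in_channels, pointwise.out_channels) == (512, 256)


class TestSpecGrid:
    def test_multihisnet_census(self):
        spec = multihisnet_spec()
        assert spec.n_blocks == 28
        assert spec.stage_block_counts == (2, 2, 4, 4, 10, 6)
        assert spec.dense_units == (512, 128)
        assert spec.dropout_rate == 0.4
        assert spec.residual_concat and spec.global_pool
        assert all(b.attention for s in spec.stages for b in s.blocks)

    def test_multihisnet_block_filter_plan(self):
        spec = multihisnet_spec()
        plan = [(s.blocks[0].pointwise_filters, s.blocks[0].conv_filters)
                for s in spec.stages]
        assert plan == [(None, 32), (32, 64), (64, 128), (128, 256),
                        (256, 512), (256, 512)]

    def test_c1_uses_flatten_head(self):
        spec = custom_spec("C1")
        assert not spec.global_pool
        assert spec.dense_units == (512, 256)
        assert spec.dropout_rate == 0.2
        assert not spec.residual_concat

    def test_c10_stage2_holds_32_and_128_filter_convs(self):
        spec = custom_spec("C10")
        filters = [b.conv_filters for b in spec.stages[1].blocks]
        assert filters == [32, 128]

    def test_c15_stage5_repeat(self):
        spec = custom_spec("C15")
        assert spec.stages[4].blocks[0].repeat == 9

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError):
            custom_spec("C21")

    def test_spec_round_trips_through_yaml(self):
        spec = custom_spec("C10")
        assert ModelSpec.from_yaml(spec.to_yaml()) == spec

    def test_spatial_collapse_rejected(self):
        stages = tuple(
            StageSpec(blocks=(BlockSpec(conv_filters=4),)) for _ in range(6)
        )
        with pytest.raises(ValueError):
            ModelSpec(stages=stages, input_size=32)


class TestBuildModel:
    def small_spec(self, **over):
        base = dict(
            stages=(
                StageSpec(blocks=(BlockSpec(conv_filters=4, attention=True, repeat=2),)),
                StageSpec(blocks=(BlockSpec(conv_filters=8, pointwise_filters=4,
                                            attention=True, repeat=2),)),
            ),
            input_size=32,
            residual_concat=True,
            dense_units=(16, 8),
            dropout_rate=0.4,
        )
        base.update(over)
        return ModelSpec(**base)

    def test_forward_emits_stochastic_rows(self):
        model = build_model(self.small_spec(), seed=0)
        x = np.random.default_rng(0).uniform(size=(3, 32, 32, 3)).astype(np.float32)
        probs = model(x)
        assert probs.shape == (3, 8)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert np.all(probs >= 0)

    def test_concat_links_grow_block_inputs_within_stage(self):
        model = build_model(self.small_spec(), seed=0)
        stage2 = model.stages[1][0]
        # first block sees the pooled stage-1 output; the second sees
        # concat(first block's output, first block's input)
        assert stage2[0].in_channels == 4
        assert stage2[1].in_channels == 8 + 4

    def test_no_concat_without_residual_flag(self):
        model = build_model(self.small_spec(residual_concat=False), seed=0)
        stage2 = model.stages[1][0]
        assert stage2[1].in_channels == 8

    def test_attention_identity_swap_changes_only_attention_params(self):
        spec = self.small_spec()
        with_attn = build_model(spec, seed=0)
        plain = build_model(
            replace(
                spec,
                stages=tuple(
                    StageSpec(
                        blocks=tuple(replace(b, attention=False) for b in s.blocks),
                        followed_by_pool=s.followed_by_pool,
                    )
                    for s in spec.stages
                ),
            ),
            seed=0,
        )
        attn_params = sum(
            m.n_params
            for blocks, _ in with_attn.stages
            for b in blocks
            for m in b.attention_modules
        )
        assert with_attn.n_params - plain.n_params == attn_params

    def test_multihisnet_builds_with_28_blocks(self):
        model = build_model(multihisnet_spec(), seed=0)
        assert model.n_blocks == 28
        assert [len(b) for b, _ in model.stages] == [2, 2, 4, 4, 10, 6]
        assert "28" in model.summary()


class TestTransferHead:
    def test_default_widths_and_dropout(self):
        head = build_transfer_head(1280)
        assert head.dense_units == (512, 256)
        assert head.dropout_rate == 0.2

    def test_forward_rows_sum_to_one(self):
        head = build_transfer_head(64)
        x = np.random.default_rng(2).normal(size=(5, 64))
        probs = head(x)
        assert probs.shape == (5, 8)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)


class TestParameterCounts:
    def test_dense_layer(self):
        assert count_parameters(Dense(10, 5)) == 55

    def test_conv_layer(self):
        assert count_parameters(Conv2D(3, 16, 3)) == 448

    def test_pointwise_cheaper_than_full_conv(self):
        model = build_model(multihisnet_spec(), seed=0)
        total = model.n_params
        # the same graph with every 1x1 convolution widened to 3x3
        variant = total
        for blocks, _ in model.stages:
            for block in blocks:
                for layer in block.layers:
                    if isinstance(layer, Conv2D) and layer.kernel == 1:
                        weights = layer.in_channels * layer.out_channels
                        variant += 8 * weights  # 3x3 has 9x the kernel weights
        assert total < variant
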