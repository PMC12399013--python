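"""Architecture-level tests: reference primitives, MSFE block semantics,
shape arithmetic, parameter budgets, determinism and serialization."""

import numpy as np
import pytest

from gallnet import nn
from gallnet.model_core import (ArchitectureConfig, ConfigError, ConvStageSpec,
                                DenseHeadSpec, MSFEBlockSpec, Model,
                                build_model, build_msfe_block,
                                config_from_dict, config_to_dict,
                                conv2d_reference, count_trainable_parameters,
                                default_ablation_config, default_full_config,
                                load_checkpoint, load_config, relu,
                                save_checkpoint, save_config)
from .test_nn import quad_loop_conv


class TestReferenceConv:
    def test_identity_1x1_kernel(self, rng):
        x = rng.random((5, 6, 1))
        k = np.ones((1, 1, 1, 1))
        np.testing.assert_array_equal(conv2d_reference(x, k), x)

    def test_zero_kernel_gives_zero(self, rng):
        x = rng.random((5, 5, 2))
        out = conv2d_reference(x, np.zeros((3, 3, 2, 4)))
        assert out.shape == (3, 3, 4)
        assert not out.any()

    def test_matches_four_nested_loop_evaluation(self, rng):
        x = rng.standard_normal((6, 6, 2))
        k = rng.standard_normal((3, 3, 2, 3))
        b = rng.standard_normal(3)
        np.testing.assert_allclose(conv2d_reference(x, k, b),
                                   quad_loop_conv(x, k, b), atol=1e-10)

    def test_channel_mismatch_raises(self):
        with pytest.raises(ValueError, match="channel"):
            conv2d_reference(np.zeros((4, 4, 2)), np.zeros((3, 3, 3, 1)))


def test_relu_cases():
    assert relu(3.0) == 3.0
    assert relu(-2.0) == 0.0
    assert relu(0.0) == 0.0


class TestMSFEBlock:
    def test_shape_arithmetic(self, rng):
        block, pool = build_msfe_block(MSFEBlockSpec(8, 8, 8), 4, rng)
        x = rng.random((2, 16, 16, 4)).astype(np.float32)
        out = pool.forward(block.forward(x))
        assert out.shape == (2, 8, 8, 24)

    def test_zero_kernels_give_zero_prepool_activations(self, rng):
        block, _ = build_msfe_block(MSFEBlockSpec(2, 2, 2), 3, rng)
        for branch in block.branches:
            branch[0].w[...] = 0.0
        x = np.ones((1, 8, 8, 3), dtype=np.float32)
        assert not block.forward(x).any()

    def test_first_channels_equal_standalone_1x1_branch(self, rng):
        """Concatenation preserves branch order: the first f1 output
        channels are exactly the 1x1 branch passed through the matching
        slice of the merge batch-norm."""
        spec = MSFEBlockSpec(3, 2, 2)
        block, _ = build_msfe_block(spec, 4, rng, dtype=np.float64)
        x = rng.random((2, 8, 8, 4))
        out = block.forward(x)
        h = x
        for layer in block.branches[0]:
            h = layer.forward(h)
        eps = block.merge_bn.eps
        scale = block.merge_bn.gamma[:3] / np.sqrt(
            block.merge_bn.running_var[:3] + eps)
        expected = scale * (h - block.merge_bn.running_mean[:3]) \
            + block.merge_bn.beta[:3]
        np.testing.assert_allclose(out[..., :3], expected, rtol=1e-12)

    def test_odd_extent_rejected_by_pool(self, rng):
        block, pool = build_msfe_block(MSFEBlockSpec(2, 2, 2), 1, rng)
        with pytest.raises(ValueError, match="even"):
            pool.forward(block.forward(np.zeros((1, 7, 7, 1), np.float32)))


class TestArchitectureConfig:
    def test_stage_count_enforced(self):
        with pytest.raises(ConfigError, match="6 stages"):
            ArchitectureConfig(stages=(ConvStageSpec(8),) * 5)

    @pytest.mark.parametrize("n_msfe", [1, 3])
    def test_msfe_count_enforced(self, n_msfe):
        stages = [MSFEBlockSpec(2, 2, 2)] * n_msfe \
            + [ConvStageSpec(8)] * (6 - n_msfe)
        with pytest.raises(ConfigError, match="MSFE"):
            ArchitectureConfig(stages=tuple(stages))

    def test_serialization_roundtrip(self, tmp_path):
        config = default_full_config()
        assert config_from_dict(config_to_dict(config)) == config
        for name in ("arch.yaml", "arch.json"):
            save_config(config, tmp_path / name)
            assert load_config(tmp_path / name) == config


class TestBuildModel:
    def test_parameter_budgets_match_published_sizes(self):
        full = count_trainable_parameters(build_model(default_full_config()))
        abl = count_trainable_parameters(build_model(default_ablation_config()))
        assert round(full / 1e6, 2) == 1.91
        assert round(abl / 1e6, 2) == 0.87
        assert abl < full  # removing the MSFE stages shrinks the model

    def test_parameter_count_seed_invariant(self, tiny_config):
        a = count_trainable_parameters(build_model(tiny_config, seed=1))
        b = count_trainable_parameters(build_model(tiny_config, seed=99))
        assert a == b

    def test_flattened_feature_length(self, tiny_config):
        model = build_model(tiny_config, seed=0)
        flat_in = model.layer("fc1").w.shape[0]
        assert flat_in == tiny_config.final_spatial ** 2 \
            * tiny_config.final_channels

    def test_equal_seeds_give_identical_parameters(self, tiny_config):
        a = build_model(tiny_config, seed=3).named_params()
        b = build_model(tiny_config, seed=3).named_params()
        c = build_model(tiny_config, seed=4).named_params()
        assert all(np.array_equal(a[k], b[k]) for k in a)
        assert any(not np.array_equal(a[k], c[k]) for k in a)

    def test_forward_yields_simplex_probabilities(self, tiny_model, rng):
        x = rng.random((3, 64, 64, 1)).astype(np.float32)
        probs = tiny_model.predict_proba(x)
        assert probs.shape == (3, 9)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_spatial_extent_halves_at_every_stage(self, tiny_model, rng):
        x = rng.random((1, 64, 64, 1)).astype(np.float32)
        pools = [n for n in tiny_model.layer_names if n.endswith(".pool")]
        _, acts = tiny_model.forward_collect(x, set(pools))
        for s, name in enumerate(sorted(pools), start=1):
            assert acts[name].shape[1] == 64 // 2 ** s

    def test_toy_layer_counting_rules(self, rng):
        config = default_full_config()
        dense = Model(config, [nn.Dense(10, 5, "d", rng)])
        assert count_trainable_parameters(dense) == 55
        conv = Model(config, [nn.Conv2D(1, 8, 3, "c", rng)])
        assert count_trainable_parameters(conv) == 80


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tiny_model, tmp_path, rng):
        x = rng.random((2, 64, 64, 1)).astype(np.float32)
        save_checkpoint(tiny_model, tmp_path / "model.npz")
        restored = load_checkpoint(tmp_path / "model.npz")
        np.testing.assert_array_equal(restored.predict_proba(x),
                                      tiny_model.predict_proba(x))

    def test_same_padded_layer_agrees_with_reference_on_interior(self, rng):
        conv = nn.Conv2D(2, 3, 3, "c", rng, dtype=np.float64)
        x = rng.random((1, 8, 8, 2))
        out = conv.forward(x)
        ref = conv2d_reference(x[0], conv.w, conv.b)
        np.testing.assert_allclose(out[0, 1:-1, 1:-1, :], ref, atol=1e-10)
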