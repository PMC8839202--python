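"""Architecture: pathway coherence, blocks, normalization, assembly, counting."""

import numpy as np
import pytest

from multipath_unet import (
    CoherenceError,
    ModelConfig,
    NormParams,
    PathwaySpec,
    build_multipath_unet,
    count_trainable_parameters,
    interconnect_layer_norm,
    predict_mask,
    spatial_dropout,
    validate_pathway_coherence,
)
from multipath_unet import nn
from multipath_unet.losses import combined_loss_and_grad
from multipath_unet.model import ConvBlock


def pw(pool, depth, filters=4, bottleneck=4):
    return PathwaySpec(pool, (filters,) * depth, bottleneck)


class TestPathwayCoherence:
    def test_published_pair_is_coherent_with_factor_16(self):
        assert validate_pathway_coherence([pw(4, 2), pw(2, 4)]) == 16

    def test_single_pathway_is_self_coherent(self):
        assert validate_pathway_coherence([pw(2, 3)]) == 8

    def test_mismatched_factors_raise_naming_the_pathway(self):
        with pytest.raises(CoherenceError, match="pathway 1"):
            validate_pathway_coherence([pw(4, 2), pw(2, 3)])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            validate_pathway_coherence([])

    def test_exhaustive_grid_accepts_iff_factors_agree(self):
        pools, depths = (2, 3, 4), (1, 2, 3, 4)
        specs = [(p, d) for p in pools for d in depths]
        for p1, d1 in specs:
            for p2, d2 in specs:
                pair = [pw(p1, d1), pw(p2, d2)]
                if p1 ** d1 == p2 ** d2:
                    assert validate_pathway_coherence(pair) == p1 ** d1
                else:
                    with pytest.raises(CoherenceError):
                        validate_pathway_coherence(pair)


class TestPathwaySpec:
    def test_decoder_filters_are_reversed_encoder_filters(self):
        spec = PathwaySpec(2, (40, 80, 160, 220), 220)
        assert spec.decoder_filters == (220, 160, 80, 40)
        assert spec.depth == 4
        assert spec.downsampling_factor == 16

    @pytest.mark.parametrize("kwargs", [
        dict(pool_window=1, encoder_filters=(4,), bottleneck_filters=4),
        dict(pool_window=2, encoder_filters=(), bottleneck_filters=4),
        dict(pool_window=2, encoder_filters=(0,), bottleneck_filters=4),
        dict(pool_window=2, encoder_filters=(4,), bottleneck_filters=0),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PathwaySpec(**kwargs)


class TestModelConfig:
    def test_input_must_divide_downsampling_factor(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(input_height=100, input_width=100, input_channels=3,
                        pathways=(pw(4, 2), pw(2, 4)))

    def test_incoherent_pathways_rejected_at_config_time(self):
        with pytest.raises(CoherenceError):
            ModelConfig(input_height=64, input_width=64, input_channels=1,
                        pathways=(pw(4, 2), pw(2, 3)))

    def test_yaml_round_trip(self, tiny_config, tmp_path):
        path = tmp_path / "cfg.yaml"
        tiny_config.to_yaml(path)
        assert ModelConfig.from_yaml(path) == tiny_config


class TestConvBlock:
    def test_shape_contract_and_channel_count(self, tiny_config, rng):
        block = ConvBlock(3, 6, tiny_config, rng)
        y = block.forward(rng.standard_normal((2, 3, 16, 16)))
        assert y.shape == (2, 6, 16, 16)

    def test_zero_input_with_zero_bias_stays_zero(self, tiny_config, rng):
        block = ConvBlock(2, 4, tiny_config, rng)
        y = block.forward(np.zeros((1, 2, 12, 12)))
        assert np.allclose(y, 0.0)

    def test_leaky_relu_slope_on_negative_preactivation(self):
        act = nn.LeakyReLU(0.1)
        x = np.array([[[[-2.0, 3.0]]]])
        assert np.allclose(act.forward(x), [[[[-0.2, 3.0]]]])

    def test_degenerate_spatial_dims_raise(self, tiny_config, rng):
        block = ConvBlock(1, 2, tiny_config, rng)
        with pytest.raises(ValueError, match="smaller than kernel"):
            block.forward(np.zeros((1, 1, 2, 2)))


class TestSpatialDropout:
    def test_rate_zero_and_inference_are_identity(self, rng):
        x = rng.standard_normal((2, 5, 4, 4))
        assert spatial_dropout(x, 0.0, training=True) is not None
        np.testing.assert_array_equal(spatial_dropout(x, 0.0, training=True), x)
        np.testing.assert_array_equal(
            spatial_dropout(x, 0.7, training=False, seed=1), x)

    def test_channel_zeroing_rate_matches_binomial(self):
        x = np.ones((1, 10_000, 2, 2))
        out = spatial_dropout(x, 0.5, training=True, seed=42)
        zeroed = np.all(out == 0.0, axis=(2, 3))
        # every dropped channel is uniformly zero; survivors rescaled by 2
        assert set(np.unique(out)) <= {0.0, 2.0}
        frac = zeroed.mean()
        se = np.sqrt(0.5 * 0.5 / 10_000)
        assert abs(frac - 0.5) < 3 * se

    def test_training_mode_preserves_expectation(self, rng):
        x = np.ones((4, 2000, 1, 1))
        out = spatial_dropout(x, 0.3, training=True, seed=7)
        assert abs(out.mean() - 1.0) < 0.05


class TestInterconnectLayerNorm:
    def test_constant_across_channels_maps_to_zero(self):
        x = np.full((2, 6, 3, 3), 3.7)
        params = NormParams(np.ones((3, 3)), np.zeros((3, 3)))
        assert np.allclose(interconnect_layer_norm(x, params), 0.0)

    def test_two_channel_hand_example(self):
        x = np.zeros((1, 2, 1, 1))
        x[0, :, 0, 0] = [1.0, 3.0]
        params = NormParams(np.ones((1, 1)), np.zeros((1, 1)))
        out = interconnect_layer_norm(x, params, epsilon=0.0)
        np.testing.assert_allclose(out[0, :, 0, 0], [-1.0, 1.0])

    def test_zero_gain_returns_bias(self, rng):
        x = rng.standard_normal((2, 5, 4, 4))
        bias = rng.standard_normal((4, 4))
        params = NormParams(np.zeros((4, 4)), bias)
        out = interconnect_layer_norm(x, params)
        for n in range(2):
            for c in range(5):
                np.testing.assert_allclose(out[n, c], bias)

    def test_shape_mismatch_raises(self, rng):
        x = rng.standard_normal((1, 4, 5, 5))
        with pytest.raises(ValueError, match="does not match"):
            interconnect_layer_norm(x, NormParams(np.ones((3, 3)),
                                                  np.zeros((3, 3))))

    def test_shift_invariance_per_position(self, rng):
        x = rng.standard_normal((2, 8, 4, 4))
        shift = rng.standard_normal((2, 1, 4, 4))
        params = NormParams(np.ones((4, 4)), np.zeros((4, 4)))
        np.testing.assert_allclose(
            interconnect_layer_norm(x, params),
            interconnect_layer_norm(x + shift, params), atol=1e-9)


class TestAssembly:
    def test_reference_geometry_bottleneck(self):
        cfg = ModelConfig(
            input_height=512, input_width=512, input_channels=3,
            pathways=(PathwaySpec(4, (40, 240), 240),
                      PathwaySpec(2, (40, 80, 160, 220), 220)))
        model = build_multipath_unet(cfg)
        assert model.bottleneck_spatial == (32, 32)
        assert model.bottleneck_channels == 460

    def test_forward_preserves_spatial_dims_and_probabilities(
            self, tiny_config, rng):
        model = build_multipath_unet(tiny_config)
        probs = model.forward(rng.standard_normal((2, 1, 16, 16)))
        assert probs.shape == (2, 2, 16, 16)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert (probs >= 0).all()

    def test_parameter_count_is_pure_function_of_config(self, tiny_config):
        m1 = build_multipath_unet(tiny_config)
        cfg2 = ModelConfig.from_dict({**tiny_config.to_dict(), "seed": 99})
        m2 = build_multipath_unet(cfg2)
        assert m1.num_parameters == m2.num_parameters

    def test_weight_save_load_round_trip(self, tiny_config, rng, tmp_path):
        model = build_multipath_unet(tiny_config)
        x = rng.standard_normal((1, 1, 16, 16))
        before = model.forward(x)
        model.save_weights(tmp_path / "w.npz")
        other = build_multipath_unet(
            ModelConfig.from_dict({**tiny_config.to_dict(), "seed": 50}))
        other.load_weights(tmp_path / "w.npz")
        np.testing.assert_allclose(other.forward(x), before)


class TestParameterCounting:
    def test_single_conv_with_bias(self, rng):
        layer = nn.Conv2d(1, 1, kernel=3, bias=True, rng=rng)

        class Holder:
            def parameters(self):
                return layer.parameters()

        assert count_trainable_parameters(Holder()) == 10

    def test_two_stacked_convs_with_biases(self, rng):
        layers = [nn.Conv2d(3, 40, 3, bias=True, rng=rng),
                  nn.Conv2d(40, 40, 3, bias=True, rng=rng)]

        class Holder:
            def parameters(self):
                return [p for l in layers for p in l.parameters()]

        assert count_trainable_parameters(Holder()) == 1120 + 14440 == 15560


class TestPredictMask:
    def test_certain_foreground_gives_full_mask(self):
        probs = np.stack([np.zeros((4, 4)), np.ones((4, 4))])
        assert predict_mask(probs).all()

    def test_ties_resolve_to_background(self):
        probs = np.stack([np.full((4, 4), 0.5), np.full((4, 4), 0.5)])
        assert not predict_mask(probs, threshold=0.5).any()

    def test_mixed_probabilities(self):
        fg = np.array([[0.2, 0.7]])
        probs = np.stack([1.0 - fg, fg])
        np.testing.assert_array_equal(predict_mask(probs), [[0, 1]])


class TestBackpropagation:
    def test_analytic_gradients_match_finite_differences(self, tiny_config,
                                                         rng):
        """End-to-end check that the hand-derived backward passes compose
        correctly through pooling, norms, skips and the softmax."""
        model = build_multipath_unet(tiny_config)
        x = rng.standard_normal((2, 1, 16, 16))
        y = (rng.random((2, 16, 16)) > 0.5).astype(int)

        def loss():
            return combined_loss_and_grad(model.forward(x), y)

        _, dprobs = loss()
        for p in model.parameters():
            p.grad[...] = 0.0
        model.backward(dprobs)
        params = model.parameters()
        pick = np.random.default_rng(0)
        eps = 1e-6
        for k in pick.choice(len(params), size=10, replace=False):
            par = params[k]
            flat = par.value.ravel()
            i = pick.integers(flat.size)
            old = flat[i]
            flat[i] = old + eps
            lp = loss()[0]
            flat[i] = old - eps
            lm = loss()[0]
            flat[i] = old
            num = (lp - lm) / (2 * eps)
            ana = par.grad.ravel()[i]
            assert abs(num - ana) <= 1e-5 + 1e-4 * abs(num), par.name
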