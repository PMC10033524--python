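"""Architecture structure, stride policy, shapes and gradient flow."""

import numpy as np
import pytest

from bladderseg.nn import Adam
from bladderseg.unet3d import (
    ModelSpec,
    ShapeFeasibilityError,
    build_model,
    default_stride_policy,
    summarize,
)


@pytest.fixture(scope="module")
def tiny_model():
    # deepest feature map stays > 1 voxel so batch normalization (which is
    # degenerate over a single element) keeps a live gradient everywhere
    spec = ModelSpec(num_blocks=4, base_filters=2,
                     input_shape=(32, 32, 16, 1), seed=1)
    return build_model(spec)


class TestStridePolicy:
    def test_five_blocks_halve_everything(self):
        policy = default_stride_policy(5, (128, 128, 32, 1))
        assert policy == ((2, 2, 2),) * 5

    def test_six_blocks_clamp_depth_axis(self):
        policy = default_stride_policy(6, (128, 128, 32, 1))
        assert policy[:5] == ((2, 2, 2),) * 5
        assert policy[5] == (2, 2, 1)  # depth 32 -> 1 after five halvings

    @pytest.mark.parametrize("blocks,deepest", [(4, (8, 8, 2)), (5, (4, 4, 1))])
    def test_deepest_feature_map_size(self, blocks, deepest):
        policy = default_stride_policy(blocks, (128, 128, 32, 1))
        spatial = [128, 128, 32]
        for stride in policy:
            spatial = [d // s for d, s in zip(spatial, stride)]
        assert tuple(spatial) == deepest

    def test_infeasible_explicit_policy_rejected(self):
        spec = ModelSpec(num_blocks=4, input_shape=(128, 128, 8, 1),
                         stride_policy=((2, 2, 2),) * 4)  # depth 8 -> 1 -> x
        with pytest.raises(ShapeFeasibilityError, match="axis 2"):
            spec.validate()


class TestStructure:
    @pytest.mark.parametrize("blocks,enc_convs", [(4, 12), (5, 15), (6, 18)])
    def test_encoder_conv_count_is_three_per_level(self, blocks, enc_convs):
        spec = ModelSpec(num_blocks=blocks, base_filters=2,
                         input_shape=(64, 64, 32, 1))
        summary = summarize(build_model(spec))
        assert summary.encoder_convs == enc_convs
        assert summary.decoder_convs == 2 * blocks
        assert summary.count("bridge") == 2
        assert summary.count("residual") == 2

    def test_head_is_three_filter_pointwise_conv(self, tiny_model):
        head = summarize(tiny_model).head
        assert head.filters == 3
        assert head.kernel == (1, 1, 1)

    def test_only_residual_convs_lack_normalization(self, tiny_model):
        summary = summarize(tiny_model)
        assert summary.unnormalized_convs == 2
        assert summary.count("residual", normalized=False) == 2

    def test_dilation_schedule_alternates_within_levels(self, tiny_model):
        encoder = [r for r in summarize(tiny_model).records
                   if r.role == "encoder"]
        assert [r.dilation for r in encoder] == [1, 2, 4] * 4

    def test_parameter_count_matches_layer_table(self):
        # growth 1 keeps the closed form easy to audit by hand
        spec = ModelSpec(num_blocks=4, base_filters=2, filter_growth=1.0,
                         input_shape=(16, 16, 8, 1))
        model = build_model(spec)
        assert summarize(model).parameter_count() == model.num_parameters()

    def test_same_seed_same_weights(self):
        spec = ModelSpec(num_blocks=4, base_filters=2,
                         input_shape=(16, 16, 8, 1), seed=9)
        w1 = build_model(spec).params()[0].value
        w2 = build_model(spec).params()[0].value
        np.testing.assert_array_equal(w1, w2)


class TestForwardBackward:
    def test_output_shape_and_softmax_normalization(self, tiny_model):
        x = np.random.default_rng(0).normal(size=(1, 32, 32, 16, 1))
        probs = tiny_model.forward(x.astype(np.float32))
        assert probs.shape == (1, 32, 32, 16, 3)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-5)

    def test_one_step_updates_every_parameter(self, tiny_model):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 32, 32, 16, 1)).astype(np.float32)
        y = np.zeros((1, 32, 32, 16, 3), dtype=np.float32)
        y[..., 0] = 1.0
        before = {p.name: p.value.copy() for p in tiny_model.params()}
        opt = Adam(tiny_model.params(), lr=1e-3)
        probs = tiny_model.forward(x)
        grad = (probs - y) / np.prod(probs.shape[:-1])
        opt.zero_grad()
        tiny_model.backward(grad)
        opt.step()
        stuck = [p.name for p in tiny_model.params()
                 if np.array_equal(p.value, before[p.name])]
        assert stuck == []

    def test_analytic_gradient_matches_finite_differences(self):
        spec = ModelSpec(num_blocks=4, base_filters=2,
                         input_shape=(8, 8, 8, 1), seed=4)
        model = build_model(spec)
        rng = np.random.default_rng(5)
        x = rng.normal(size=(1, 8, 8, 8, 1)).astype(np.float32)
        y = np.zeros((1, 8, 8, 8, 3), dtype=np.float32)
        y[..., 1] = 1.0

        def loss():
            p = model.forward(x)
            return -(y * np.log(np.clip(p, 1e-7, 1.0))).sum(-1).mean()

        probs = model.forward(x)
        for p in model.params():
            p.zero_grad()
        n_vox = np.prod(probs.shape[:-1])
        model.backward((-(y / np.clip(probs, 1e-7, 1.0)) / n_vox).astype(np.float32))
        for par in [model.params()[0], model.params()[-3]]:
            idx = tuple(rng.integers(0, s) for s in par.value.shape)
            eps, old = 1e-2, par.value[idx]
            par.value[idx] = old + eps
            up = loss()
            par.value[idx] = old - eps
            down = loss()
            par.value[idx] = old
            numeric = (up - down) / (2 * eps)
            assert numeric == pytest.approx(par.grad[idx], rel=0.15, abs=5e-4)

    def test_shape_round_trip_all_architectures(self):
        # full-size input contract at a thin filter budget
        for blocks in (4, 5, 6):
            spec = ModelSpec(num_blocks=blocks, base_filters=2,
                             input_shape=(128, 128, 32, 1), seed=0)
            model = build_model(spec)
            x = np.zeros((1, 128, 128, 32, 1), dtype=np.float32)
            assert model.predict(x).shape == (1, 128, 128, 32, 3)
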