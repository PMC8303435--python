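"""Architecture and training-recipe contracts for BiFPN-U-Net(T)."""

import numpy as np
import pytest

import hyotrack.nn.tensor as T
from hyotrack import PhantomSpec, make_phantom
from hyotrack.losses import focal_loss, focal_loss_from_logits
from hyotrack.model import BiFPNLayer, ConfigurationError, NetworkConfig, build_network
from hyotrack.nn import BotBlock, MultiHeadSelfAttention2d, Tensor, WeightedFusion, fuse_features, no_grad
from hyotrack.training import load_checkpoint, predict, save_checkpoint, train

RNG = np.random.default_rng(42)


def tiny_config(**kw):
    base = dict(input_size=(16, 16), encoder_widths=(2, 2, 4, 4, 4),
                bifpn_channels=4, bot_heads=2, batch_size=2, seed=0,
                max_epochs=30, patience=20)
    base.update(kw)
    return NetworkConfig(**base)


def tiny_data(n=4, size=16, seed=0):
    r = np.random.default_rng(seed)
    x = r.random((n, 1, size, size), dtype=np.float32)
    y = (x[:, 0] > 0.75).astype(np.int64) * 2  # a bright class vs background
    return x, y


class TestNetworkContracts:
    @pytest.mark.parametrize("size", [(96, 96), (224, 224)])
    def test_output_shape(self, size):
        cfg = NetworkConfig(input_size=size, encoder_widths=(4, 4, 8, 8, 8),
                            bifpn_channels=4, bot_heads=2, seed=0)
        model = build_network(cfg)
        x = RNG.random((2, 1, *size), dtype=np.float32)
        with no_grad():
            out = model(Tensor(x))
        assert out.shape == (2, 4, *size)

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ConfigurationError, match="divisible by 16"):
            NetworkConfig(input_size=(100, 96)).validate()

    def test_same_seed_identical_initial_weights(self):
        cfg = tiny_config(seed=11)
        m1, m2 = build_network(cfg), build_network(cfg)
        for (k1, p1), (k2, p2) in zip(m1.named_parameters(), m2.named_parameters()):
            assert k1 == k2
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_learning_rate_linear_scaling_rule(self):
        assert NetworkConfig(batch_size=8).base_lr == pytest.approx(0.003125)
        assert NetworkConfig(batch_size=256).base_lr == pytest.approx(0.1)


class TestWeightedFusion:
    def test_identical_inputs_unit_weights_recover_input(self):
        a = RNG.standard_normal((1, 2, 4, 4)).astype(np.float32)
        out = fuse_features([Tensor(a), Tensor(a)], [1.0, 1.0], eps=1e-12)
        np.testing.assert_allclose(out.data, a, rtol=1e-5)

    def test_zero_weight_selects_other_input(self):
        a = RNG.standard_normal((1, 2, 3, 3)).astype(np.float32)
        b = RNG.standard_normal((1, 2, 3, 3)).astype(np.float32)
        out = fuse_features([Tensor(a), Tensor(b)], [0.0, 5.0], eps=1e-12)
        np.testing.assert_allclose(out.data, b, rtol=1e-5)

    def test_scalar_arithmetic_oracle(self):
        out = fuse_features([Tensor(np.array(0.0)), Tensor(np.array(4.0))],
                            [1.0, 3.0], eps=1e-4)
        assert float(out.data) == pytest.approx(3 * 4 / (4 + 1e-4), rel=1e-6)

    def test_all_zero_weights_guarded_by_epsilon(self):
        a = RNG.standard_normal((1, 2, 3, 3)).astype(np.float32)
        out = fuse_features([Tensor(a), Tensor(a)], [0.0, 0.0], eps=1e-4)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-6)

    def test_output_inside_scaled_envelope(self):
        # convex combination scaled by sum(w)/(eps + sum(w))
        a = RNG.standard_normal((2, 3, 4, 4)).astype(np.float32)
        b = RNG.standard_normal((2, 3, 4, 4)).astype(np.float32)
        w = (0.7, 1.8)
        eps = 1e-4
        out = fuse_features([Tensor(a), Tensor(b)], w, eps=eps).data
        scale = sum(w) / (eps + sum(w))
        lo = np.minimum(a, b) * scale
        hi = np.maximum(a, b) * scale
        assert (out >= np.minimum(lo, hi) - 1e-5).all()
        assert (out <= np.maximum(lo, hi) + 1e-5).all()

    def test_module_normalized_weights_sum_to_one(self):
        fusion = WeightedFusion(3)
        fusion.weights.data = np.array([0.2, 1.3, 2.5], np.float32)
        assert fusion.normalized_weights().sum() == pytest.approx(1.0, abs=1e-4)

    def test_shape_mismatch_rejected(self):
        fusion = WeightedFusion(2)
        with pytest.raises(ValueError, match="mismatch"):
            fusion([Tensor(np.zeros((1, 2, 4, 4))), Tensor(np.zeros((1, 2, 2, 2)))])


class TestBidirectionalPass:
    def _pyramid(self, channels=(2, 2, 4, 4, 4), base=16, n=1):
        return [Tensor(RNG.standard_normal((n, c, base // 2 ** i, base // 2 ** i))
                       .astype(np.float32))
                for i, c in enumerate(channels)]

    def test_output_channels_and_sizes(self):
        layer = BiFPNLayer([2, 2, 4, 4, 4], 4, np.random.default_rng(0))
        pyr = self._pyramid()
        out = layer(pyr)
        for i, o in enumerate(out):
            assert o.shape[1] == 4
            assert o.shape[2:] == pyr[i].shape[2:]

    def test_zero_pyramid_maps_to_zero_with_biases_disabled(self):
        layer = BiFPNLayer([2, 2, 4, 4, 4], 4, np.random.default_rng(0))
        for name, p in layer.named_parameters():
            if name.endswith("bias"):
                p.data[:] = 0.0
        zeros = [Tensor(np.zeros_like(p.data)) for p in self._pyramid()]
        out = layer(zeros)
        for o in out:
            np.testing.assert_allclose(o.data, 0.0, atol=1e-7)


class TestBotBlock:
    def test_attention_rows_sum_to_one(self):
        mhsa = MultiHeadSelfAttention2d(4, 2, 3, 3, np.random.default_rng(0))
        x = Tensor(RNG.standard_normal((2, 4, 3, 3)).astype(np.float32))
        attn = mhsa.attention(x).data
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-5)

    def test_output_shape_preserved(self):
        bot = BotBlock(4, 2, 3, 3, np.random.default_rng(0))
        x = Tensor(RNG.standard_normal((1, 4, 3, 3)).astype(np.float32))
        assert bot(x).shape == x.shape

    def test_identity_attention_reduces_to_residual_value_path(self):
        # with the attention matrix forced to the identity, the block is
        # x + expand(value_projection(relu(reduce(x)))) — computed by hand
        rng = np.random.default_rng(1)
        bot = BotBlock(4, 2, 2, 2, rng)
        x = RNG.standard_normal((1, 4, 2, 2)).astype(np.float32)
        eye = np.eye(4, dtype=np.float32)[None].repeat(2, axis=0)  # (heads, HW, HW)
        out = bot(Tensor(x), attn_override=eye).data

        def conv1x1(w, b, v):
            y = np.einsum("oi,nihw->nohw", w.data[:, :, 0, 0], v)
            return y + (0 if b is None else b.data[None, :, None, None])

        y = np.maximum(conv1x1(bot.reduce.weight, bot.reduce.bias, x), 0)
        v = conv1x1(bot.mhsa.wv.weight, None, y)
        expected = x + conv1x1(bot.expand.weight, bot.expand.bias, v)
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_spatial_cap_enforced(self):
        with pytest.raises(ValueError, match="4096"):
            MultiHeadSelfAttention2d(4, 2, 65, 64, np.random.default_rng(0))


class TestFocalLoss:
    def test_perfect_prediction_zero_loss(self):
        probs = np.zeros((2, 3, 4))
        labels = np.full((2, 3), 2)
        probs[..., 2] = 1.0
        assert float(focal_loss(probs, labels, 1.0, 2.0).data) == pytest.approx(0.0, abs=1e-6)

    def test_gamma_zero_is_alpha_scaled_cross_entropy(self):
        probs = RNG.dirichlet(np.ones(4), size=(3, 5)).astype(np.float32)
        labels = RNG.integers(0, 4, (3, 5))
        pt = np.take_along_axis(probs, labels[..., None], axis=-1)[..., 0]
        ce = -np.log(np.maximum(pt, 1e-7)).mean()
        got = float(focal_loss(probs, labels, 0.25, 0.0).data)
        assert got == pytest.approx(0.25 * ce, abs=1e-6)

    def test_scalar_oracle_pt09_gamma2(self):
        probs = np.array([[0.1, 0.9]])
        got = float(focal_loss(probs, np.array([1]), 1.0, 2.0).data)
        assert got == pytest.approx(0.01 * 0.1053605, rel=1e-4)

    def test_half_probability_gamma0_is_ln2(self):
        probs = np.array([[0.5, 0.5]])
        got = float(focal_loss(probs, np.array([0]), 1.0, 0.0).data)
        assert got == pytest.approx(np.log(2), rel=1e-5)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([[1.0, 0.0]]), np.array([0]), 1.0, -1.0)

    def test_loss_nonnegative_and_decreasing_in_pt(self):
        pts = np.linspace(0.05, 0.999, 30)
        losses = [float(focal_loss(np.array([[1 - p, p]]), np.array([1]), 0.5, 2.0).data)
                  for p in pts]
        assert all(l >= 0 for l in losses)
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_logits_path_agrees_with_probability_path(self):
        logits = RNG.standard_normal((2, 4, 3, 3)).astype(np.float32)
        labels = RNG.integers(0, 4, (2, 3, 3))
        z = logits - logits.max(1, keepdims=True)
        probs = np.exp(z) / np.exp(z).sum(1, keepdims=True)
        a = float(focal_loss_from_logits(Tensor(logits), labels, 0.25, 2.0).data)
        b = float(focal_loss(probs.transpose(0, 2, 3, 1), labels, 0.25, 2.0).data)
        assert a == pytest.approx(b, rel=1e-5)


class TestTraining:
    def test_gradient_reaches_every_submodule(self):
        cfg = tiny_config()
        model = build_network(cfg)
        before = {k: p.data.copy() for k, p in model.named_parameters()}
        x, y = tiny_data()
        train(model, (x, y), (x, y), tiny_config(max_epochs=1, patience=0))
        groups = {"stages": 0.0, "bifpn": 0.0, "bot": 0.0, "dec_": 0.0, "head": 0.0}
        for k, p in model.named_parameters():
            delta = float(np.abs(p.data - before[k]).sum())
            for g in groups:
                if k.startswith(g):
                    groups[g] += delta
        assert all(v > 0 for v in groups.values()), groups

    def test_early_stopping_on_flat_validation(self):
        cfg = tiny_config(max_epochs=30, patience=20)
        model = build_network(cfg)
        x, y = tiny_data()
        _, history = train(model, (x, y), (x, y), cfg,
                           val_loss_fn=lambda m, e: 1.0)
        assert len(history) <= 0 + 20 + 1

    def test_training_reproducible_for_fixed_seed(self):
        x, y = tiny_data()
        hists = []
        for _ in range(2):
            cfg = tiny_config(max_epochs=2, patience=1, seed=5)
            model = build_network(cfg)
            _, h = train(model, (x, y), (x, y), cfg)
            hists.append(h)
        np.testing.assert_array_equal(hists[0].train_loss.values,
                                      hists[1].train_loss.values)

    def test_loss_decreases_on_easy_phantom(self):
        spec = PhantomSpec(frame_count=16, frame_size=(48, 48),
                           coin_diameter_px=12.0, motion_period_frames=12,
                           jitter_px=0.0, noise_sd=0.01, seed=2)
        frames, truth = make_phantom(spec)
        cfg = NetworkConfig(input_size=(48, 48), encoder_widths=(4, 8, 8, 16, 16),
                            bifpn_channels=8, bot_heads=2, batch_size=8,
                            max_epochs=4, patience=3, seed=0)
        model = build_network(cfg)
        _, history = train(model, (frames, truth.label_masks),
                           (frames[:4], truth.label_masks[:4]), cfg)
        assert history.train_loss.iloc[-1] < history.train_loss.iloc[0]

    def test_empty_dataset_rejected(self):
        cfg = tiny_config()
        model = build_network(cfg)
        with pytest.raises(ValueError):
            train(model, (np.zeros((0, 1, 16, 16)), np.zeros((0, 16, 16))),
                  (np.zeros((0, 1, 16, 16)), np.zeros((0, 16, 16))), cfg)


class TestPredict:
    def test_probabilities_on_simplex(self):
        model = build_network(tiny_config())
        frames = RNG.random((3, 16, 16), dtype=np.float32)
        probs = predict(model, frames)
        assert probs.shape == (3, 16, 16, 4)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(-1), 1.0, atol=1e-5)

    def test_inference_deterministic(self):
        model = build_network(tiny_config())
        frame = RNG.random((1, 16, 16), dtype=np.float32)
        np.testing.assert_array_equal(predict(model, frame), predict(model, frame))

    def test_empty_stack_rejected(self):
        model = build_network(tiny_config())
        with pytest.raises(ValueError):
            predict(model, np.zeros((0, 16, 16)))


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        model = build_network(tiny_config(seed=9))
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        assert restored.config == model.config
        frame = RNG.random((1, 16, 16), dtype=np.float32)
        np.testing.assert_array_equal(predict(model, frame), predict(restored, frame))
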