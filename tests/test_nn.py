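"""Network blocks against loop oracles, closed forms and shape contracts."""

import numpy as np
import pytest

from ppgid.nn import (
    Activation,
    Conv2d,
    Dense,
    DepthwiseConv2d,
    LSTM,
    MBConv,
    SEBlock,
    build_model,
    softmax,
    softmax_cross_entropy,
    swish,
)
from ppgid.nn.model import paper_scale_config, tiny_config, PpgNet


def conv_loop_oracle(x, Q, B, stride=1):
    """Naive evaluation of the convolution definition: quadruple loop over
    output position, kernel offsets and channels, zero padding, centered
    odd kernel, output side ceil(input/stride)."""
    H, W, C = x.shape
    M, N, _, K = Q.shape
    Ho, Wo = -(-H // stride), -(-W // stride)
    y = np.zeros((Ho, Wo, K))
    for i in range(Ho):
        for j in range(Wo):
            for k in range(K):
                acc = B[k]
                for m in range(M):
                    for n in range(N):
                        r = i * stride + m - M // 2
                        c = j * stride + n - N // 2
                        if 0 <= r < H and 0 <= c < W:
                            acc += float(x[r, c] @ Q[m, n, :, k])
                y[i, j, k] = acc
    return y


class TestConv2d:
    def test_identity_1x1_kernel(self):
        rng = np.random.default_rng(0)
        x = rng.random((2, 6, 6, 3))
        conv = Conv2d(3, 3, kernel_size=1, rng=rng)
        conv.Q.value[...] = np.eye(3)[None, None]
        conv.B.value[...] = 0.0
        assert np.allclose(conv.forward(x), x)

    def test_bias_only(self):
        rng = np.random.default_rng(1)
        x = rng.random((1, 4, 4, 2))
        conv = Conv2d(2, 3, kernel_size=3, rng=rng)
        conv.Q.value[...] = 0.0
        conv.B.value[...] = [1.5, -2.0, 0.25]
        out = conv.forward(x)
        for k, beta in enumerate([1.5, -2.0, 0.25]):
            assert np.allclose(out[..., k], beta)

    @pytest.mark.parametrize("stride", [1, 2])
    def test_matches_loop_oracle(self, stride):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=(5, 5, 2))
            conv = Conv2d(2, 3, kernel_size=3, stride=stride, rng=rng)
            out = conv.forward(x[None])[0]
            expect = conv_loop_oracle(x, conv.Q.value, conv.B.value, stride)
            assert out.shape == expect.shape
            assert np.allclose(out, expect, atol=1e-10)

    def test_channel_mismatch_rejected(self):
        conv = Conv2d(3, 4)
        with pytest.raises(ValueError, match="channel"):
            conv.forward(np.zeros((1, 4, 4, 2)))


class TestDepthwise:
    def test_matches_per_channel_loop_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(size=(6, 6, 3))
            dw = DepthwiseConv2d(3, kernel_size=3, rng=rng)
            out = dw.forward(x[None])[0]
            # depthwise = full conv with kernels that never mix channels
            Q = np.zeros((3, 3, 3, 3))
            for c in range(3):
                Q[:, :, c, c] = dw.W.value[:, :, c]
            expect = conv_loop_oracle(x, Q, np.zeros(3))
            assert np.allclose(out, expect, atol=1e-10)


class TestSwish:
    def test_closed_forms(self):
        assert swish(0.0) == 0.0
        assert np.isclose(swish(1.0), 1.0 / (1.0 + np.exp(-1.0)))
        assert np.isclose(swish(20.0) / 20.0, 1.0, atol=1e-6)


class TestSEBlock:
    def test_squeeze_is_channel_mean(self):
        x = np.zeros((2, 3, 4, 2))
        x[..., 0] = 1.5
        x[..., 1] = -0.5
        se = SEBlock(2, rng=np.random.default_rng(0))
        se.forward(x)
        _, z, _, _ = se._cache
        assert np.allclose(z, [[1.5, -0.5], [1.5, -0.5]])

    def test_zero_weights_halve_input(self):
        rng = np.random.default_rng(1)
        x = rng.random((2, 4, 4, 3))
        se = SEBlock(3, rng=rng)
        for p in (se.W1, se.b1, se.W2, se.b2):
            p.value[...] = 0.0
        assert np.allclose(se.forward(x), x / 2.0)

    def test_gate_in_open_interval(self):
        rng = np.random.default_rng(2)
        se = SEBlock(4, rng=rng)
        se.forward(rng.normal(size=(3, 5, 5, 4)))
        gate = se._cache[3]
        assert np.all(gate > 0) and np.all(gate < 1)

    def test_identity_limit_large_gate_bias(self):
        rng = np.random.default_rng(3)
        x = rng.random((2, 4, 4, 3))
        se = SEBlock(3, rng=rng)
        se.b2.value[...] = 20.0
        assert np.allclose(se.forward(x), x, atol=1e-6)


class TestMBConv:
    def test_zero_weights_residual_identity(self):
        rng = np.random.default_rng(4)
        x = rng.random((2, 6, 6, 4))
        blk = MBConv(4, 4, expansion=2, stride=1, rng=rng)
        for p in blk.params:
            p.value[...] = 0.0
        assert np.allclose(blk.forward(x, train=False), x)

    @pytest.mark.parametrize("side,expected", [(6, 3), (7, 4)])
    def test_stride_two_halves_side_ceil(self, side, expected):
        rng = np.random.default_rng(5)
        blk = MBConv(3, 8, expansion=2, stride=2, rng=rng)
        out = blk.forward(rng.random((1, side, side, 3)))
        assert out.shape == (1, expected, expected, 8)


class TestLSTMAndHead:
    def test_lstm_final_state_shape_and_determinism(self):
        rng = np.random.default_rng(6)
        lstm = LSTM(5, 7, rng=rng)
        x = rng.normal(size=(3, 4, 5))
        a, b = lstm.forward(x), lstm.forward(x)
        assert a.shape == (3, 7)
        assert np.array_equal(a, b)

    def test_softmax_simplex(self):
        rng = np.random.default_rng(7)
        p = softmax(rng.normal(size=(10, 6)) * 10)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_uniform_probs_from_zero_head(self):
        model = build_model(config=tiny_config(n_classes=5, input_side=16), seed=0)
        model.head.W.value[...] = 0.0
        model.head.b.value[...] = 0.0
        p = model.predict_proba(np.random.default_rng(0).random((2, 16, 16)))
        assert np.allclose(p, 0.2, atol=1e-12)

    def test_permuting_head_permutes_probs(self):
        rng = np.random.default_rng(8)
        model = build_model(config=tiny_config(n_classes=4, input_side=16), seed=1)
        x = rng.random((3, 16, 16))
        p = model.predict_proba(x)
        perm = np.array([2, 0, 3, 1])
        model.head.W.value[...] = model.head.W.value[:, perm]
        model.head.b.value[...] = model.head.b.value[perm]
        assert np.allclose(model.predict_proba(x), p[:, perm], atol=1e-12)


class TestModel:
    def test_same_seed_same_outputs(self):
        x = np.random.default_rng(0).random((2, 32, 32))
        a = build_model(config=tiny_config(n_classes=6), seed=42).predict_proba(x)
        b = build_model(config=tiny_config(n_classes=6), seed=42).predict_proba(x)
        assert np.array_equal(a, b)

    def test_tiny_preset_parameter_budget(self):
        model = build_model(preset="tiny", n_classes=8, seed=0)
        assert model.parameter_count() < 200_000

    def test_feature_shape_contract(self):
        model = build_model(config=tiny_config(n_classes=8, input_side=32), seed=0)
        # stem stride 2 (32 -> 16), one stride-2 block (16 -> 8)
        assert model.feature_shape == (8, 8, 24)
        feats = model.extract_features(np.zeros((1, 32, 32)), train=False)
        assert feats.shape == (1, 8, 8, 24)

    def test_paper_scale_layer_count_near_b0_depth(self):
        model = build_model(preset="paper_scale", n_classes=40, seed=0)
        assert 50 <= model.layer_count() <= 80

    def test_wrong_input_side_rejected(self):
        model = build_model(config=tiny_config(n_classes=4, input_side=32), seed=0)
        with pytest.raises(ValueError, match="expected 32x32"):
            model.predict_proba(np.zeros((1, 16, 16)))

    def test_save_load_roundtrip(self, tmp_path):
        model = build_model(config=tiny_config(n_classes=5, input_side=16), seed=9)
        model.classes = [f"S{i}" for i in range(5)]
        x = np.random.default_rng(1).random((2, 16, 16))
        before = model.predict_proba(x)
        path = str(tmp_path / "ckpt.npz")
        model.save(path, seed=9)
        loaded = PpgNet.load(path)
        assert loaded.classes == model.classes
        assert np.allclose(loaded.predict_proba(x), before, atol=1e-12)


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """End-to-end reverse-mode gradients vs central differences."""
        model = build_model(config=tiny_config(n_classes=3, input_side=16), seed=1)
        rng = np.random.default_rng(0)
        X = rng.random((4, 16, 16))
        y = np.array([0, 1, 2, 0])

        def loss():
            return softmax_cross_entropy(model.forward_logits(X, train=True), y)[0]

        for p in model.params:
            p.grad[...] = 0.0
        _, d = softmax_cross_entropy(model.forward_logits(X, train=True), y)
        model.backward(d)
        check_rng = np.random.default_rng(5)
        worst = 0.0
        for p in model.params[::4]:
            idx = tuple(check_rng.integers(0, s) for s in p.value.shape)
            eps, old = 1e-6, p.value[idx]
            p.value[idx] = old + eps
            lp = loss()
            p.value[idx] = old - eps
            lm = loss()
            p.value[idx] = old
            num = (lp - lm) / (2 * eps)
            rel = abs(num - p.grad[idx]) / max(1e-8, abs(num) + abs(p.grad[idx]))
            worst = max(worst, rel)
        assert worst < 1e-5
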