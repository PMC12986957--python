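"""Dual-stream change fusion: channel exchange, excitation weights, and the
difference-branch equations checked against straight-line transcriptions."""

import numpy as np
import pytest
from scipy.special import expit

import tidalcd as tc
from tidalcd import nn
from tidalcd.dscf import DAU, DSCF, ConnectionBranch, SELayer, channel_exchange


def _t(arr):
    return nn.Tensor(np.asarray(arr, np.float32))


class TestChannelExchange:
    def test_identical_inputs_are_fixed_points(self, rng):
        f = _t(rng.normal(size=(1, 4, 3, 3)))
        f12, f21 = channel_exchange(f, _t(f.data.copy()))
        np.testing.assert_array_equal(f12.data, f.data)
        np.testing.assert_array_equal(f21.data, f.data)

    def test_alternating_mask_pattern_at_c4(self, rng):
        f1 = _t(rng.normal(size=(1, 4, 2, 2)))
        f2 = _t(rng.normal(size=(1, 4, 2, 2)))
        f12, f21 = channel_exchange(f1, f2)
        expected12 = np.stack([f1.data[0, 0], f2.data[0, 1],
                               f1.data[0, 2], f2.data[0, 3]])
        expected21 = np.stack([f2.data[0, 0], f1.data[0, 1],
                               f2.data[0, 2], f1.data[0, 3]])
        np.testing.assert_array_equal(f12.data[0], expected12)
        np.testing.assert_array_equal(f21.data[0], expected21)

    def test_channel_multiset_is_conserved(self, rng):
        """Sort-and-compare: channels of (f12, f21) == channels of (f1, f2)."""
        f1 = _t(rng.normal(size=(2, 6, 4, 4)))
        f2 = _t(rng.normal(size=(2, 6, 4, 4)))
        f12, f21 = channel_exchange(f1, f2)
        before = np.sort(np.concatenate(
            [f1.data, f2.data], axis=1).reshape(2, 12, -1), axis=1)
        after = np.sort(np.concatenate(
            [f12.data, f21.data], axis=1).reshape(2, 12, -1), axis=1)
        np.testing.assert_allclose(before, after)

    def test_shape_mismatch_is_rejected(self, rng):
        with pytest.raises(ValueError):
            channel_exchange(_t(np.zeros((1, 4, 2, 2))),
                             _t(np.zeros((1, 4, 3, 3))))


class TestSEWeights:
    def test_zero_initialized_perceptrons_give_half(self, rng):
        se = SELayer(np.random.default_rng(0), c=8)
        for p in se.parameters():
            p.data[...] = 0.0
        ws = se(_t(np.zeros((1, 8, 4, 4))))
        np.testing.assert_allclose(ws.data, 0.5)

    def test_outputs_strictly_inside_unit_interval(self, rng):
        se = SELayer(np.random.default_rng(1), c=8)
        ws = se(_t(rng.normal(size=(2, 8, 4, 4))))
        assert (ws.data > 0).all() and (ws.data < 1).all()
        assert ws.shape == (2, 8)

    def test_matches_hand_evaluated_two_layer_branches(self, rng):
        """Fixed 4-channel input with hand-set weights reproduces the scalar
        computation sigmoid(sum_k W2_k relu(W1_k pooled))."""
        se = SELayer(np.random.default_rng(2), c=4, k=4, hidden=2)
        fd = rng.normal(size=(1, 4, 2, 2)).astype(np.float32)
        pooled = fd.mean(axis=(2, 3))[0]
        acc = np.zeros(4)
        for branch in se.branches.layers:
            w1, b1 = branch.layers[0].weight.data, branch.layers[0].bias.data
            w2, b2 = branch.layers[2].weight.data, branch.layers[2].bias.data
            acc += w2 @ np.maximum(w1 @ pooled + b1, 0) + b2
        expected = expit(acc)
        ws = se(_t(fd))
        np.testing.assert_allclose(ws.data[0], expected, rtol=1e-5)


def _dau_oracle(dau: DAU, f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """Straight-line non-modular transcription of the difference branch:
    signed difference, alternating channel exchange, per-path depthwise
    separable + wavelet convolutions with sigmoid gates, multi-branch
    excitation gate, gated concatenation reduced by the output DSConv."""

    def conv1x1(x, w):  # x: (C,H,W), w: (O, C, 1, 1)
        return np.einsum("chw,oc->ohw", x, w[:, :, 0, 0])

    def depthwise3(x, w):  # w: (C,1,3,3)
        c, h, wd = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
        out = np.zeros_like(x)
        for i in range(3):
            for j in range(3):
                out += xp[:, i:i + h, j:j + wd] * w[:, 0, i, j][:, None, None]
        return out

    def bn_train(x, gamma, beta, eps=1e-5):
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = ((x - mu) ** 2).mean(axis=(1, 2), keepdims=True)
        return gamma[:, None, None] * (x - mu) / np.sqrt(var + eps) \
            + beta[:, None, None]

    def dsconv(block, x):
        x = depthwise3(x, block.depthwise.weight.data)
        x = conv1x1(x, block.pointwise.weight.data)
        x = bn_train(x, block.bn.weight.data, block.bn.bias.data)
        return np.maximum(x, 0)

    def haar(x):
        c, h, w = x.shape
        blocks = x.reshape(c, h // 2, 2, w // 2, 2)
        f = 0.5 * np.array([[[1, 1], [1, 1]], [[1, -1], [1, -1]],
                            [[1, 1], [-1, -1]], [[1, -1], [-1, 1]]])
        return np.einsum("chiwj,sij->schw", blocks, f).reshape(
            4 * c, h // 2, w // 2)

    def ihaar(y):
        c4, hh, wh = y.shape
        c = c4 // 4
        f = 0.5 * np.array([[[1, 1], [1, 1]], [[1, -1], [1, -1]],
                            [[1, 1], [-1, -1]], [[1, -1], [-1, 1]]])
        return np.einsum("schw,sij->chiwj", y.reshape(4, c, hh, wh),
                         f).reshape(c, 2 * hh, 2 * wh)

    def wtconv(block, x):
        return ihaar(depthwise3(haar(x), block.band_conv.weight.data))

    fd = f1 - f2
    c = f1.shape[0]
    even = np.arange(c) % 2 == 0
    f12 = np.where(even[:, None, None], f1, f2)
    f21 = np.where(even[:, None, None], f2, f1)
    w1 = expit(wtconv(dau.wt1, dsconv(dau.ds1, np.concatenate([fd, f12]))))
    w2 = expit(wtconv(dau.wt2, dsconv(dau.ds2, np.concatenate([fd, f21]))))
    pooled = fd.mean(axis=(1, 2))
    acc = np.zeros(c)
    for branch in dau.se.branches.layers:
        wa, ba = branch.layers[0].weight.data, branch.layers[0].bias.data
        wb, bb = branch.layers[2].weight.data, branch.layers[2].bias.data
        acc += wb @ np.maximum(wa @ pooled + ba, 0) + bb
    ws = expit(acc)[:, None, None]
    gated = np.concatenate([ws * w1 * f1, ws * w2 * f2])
    return dsconv(dau.out, gated)


class TestDAU:
    def test_zero_input_with_zero_affines_gives_zero(self):
        dau = DAU(np.random.default_rng(0), c=4, cfg=tc.ModelConfig())
        zero = _t(np.zeros((1, 4, 4, 4)))
        out = dau(zero, _t(np.zeros((1, 4, 4, 4))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-6)

    def test_output_shape_preserved(self, rng):
        dau = DAU(np.random.default_rng(1), c=8, cfg=tc.ModelConfig())
        out = dau(_t(rng.normal(size=(2, 8, 4, 4))),
                  _t(rng.normal(size=(2, 8, 4, 4))))
        assert out.shape == (2, 8, 4, 4)

    def test_matches_straight_line_transcription(self, rng):
        """2x2 spatial, 4-channel fixture with the module's own weights."""
        dau = DAU(np.random.default_rng(2), c=4, cfg=tc.ModelConfig())
        f1 = rng.normal(size=(1, 4, 2, 2)).astype(np.float32)
        f2 = rng.normal(size=(1, 4, 2, 2)).astype(np.float32)
        out = dau(_t(f1), _t(f2))
        expected = _dau_oracle(dau, f1[0], f2[0])
        np.testing.assert_allclose(out.data[0], expected, rtol=1e-4,
                                   atol=1e-5)

    def test_gates_stay_strictly_inside_unit_interval(self, rng):
        dau = DAU(np.random.default_rng(3), c=4, cfg=tc.ModelConfig())
        _, inter = dau(_t(rng.normal(size=(1, 4, 4, 4))),
                       _t(rng.normal(size=(1, 4, 4, 4))),
                       return_intermediates=True)
        for gate in (inter.w1, inter.w2, inter.ws):
            assert (gate.data > 0).all() and (gate.data < 1).all()

    def test_abs_variant_makes_difference_symmetric(self, rng):
        cfg = tc.ModelConfig(abs_difference=True)
        dau = DAU(np.random.default_rng(4), c=4, cfg=cfg)
        f1 = _t(rng.normal(size=(1, 4, 2, 2)))
        f2 = _t(rng.normal(size=(1, 4, 2, 2)))
        d12 = dau.difference(f1, f2)
        d21 = dau.difference(f2, f1)
        np.testing.assert_allclose(d12.data, d21.data, atol=1e-6)


class TestConnectionBranch:
    def test_output_channels_match_inputs(self, rng):
        cb = ConnectionBranch(np.random.default_rng(0), c=8)
        out = cb(_t(rng.normal(size=(1, 8, 4, 4))),
                 _t(rng.normal(size=(1, 8, 4, 4))))
        assert out.shape == (1, 8, 4, 4)

    def test_hand_computed_convolution_arithmetic(self):
        """Identity-like 1x1 second conv over a hand-convolved 2x2 input."""
        cb = ConnectionBranch(np.random.default_rng(1), c=2)
        conv3 = cb.block.layers[0]
        f1 = np.arange(8, dtype=np.float32).reshape(1, 2, 2, 2)
        f2 = -f1
        x = np.concatenate([f1, f2], axis=1)
        # hand 3x3 convolution at the (0,0) output position
        w = conv3.weight.data
        xp = np.pad(x[0], ((0, 0), (1, 1), (1, 1)))
        hand = sum(xp[c, i, j] * w[0, c, i, j]
                   for c in range(4) for i in range(3) for j in range(3))
        out = nn.conv2d(_t(x), conv3.weight, padding=1)
        assert np.isclose(out.data[0, 0, 0, 0], hand, rtol=1e-5)


class TestDSCF:
    @pytest.fixture
    def feats(self, rng):
        return (_t(rng.normal(size=(1, 8, 4, 4))),
                _t(rng.normal(size=(1, 8, 4, 4))))

    def test_sum_variant_is_additive_in_branches(self, feats):
        cfg = tc.ModelConfig(fusion="sum")
        mod = DSCF(np.random.default_rng(0), c=8, cfg=cfg)
        f1, f2 = feats
        out = mod(f1, f2)
        expected = mod.connection(f1, f2).data + mod.dau(f1, f2).data
        np.testing.assert_allclose(out.data, expected, rtol=1e-4, atol=1e-5)

    def test_sum_variant_with_zero_connection_equals_difference_branch(
            self, feats):
        cfg = tc.ModelConfig(fusion="sum")
        mod = DSCF(np.random.default_rng(1), c=8, cfg=cfg)
        for p in mod.connection.parameters():
            p.data[...] = 0.0
        f1, f2 = feats
        np.testing.assert_allclose(mod(f1, f2).data,
                                   mod.dau(f1, f2).data, rtol=1e-4,
                                   atol=1e-6)

    def test_dilated_variant_preserves_shape(self, feats):
        mod = DSCF(np.random.default_rng(2), c=8, cfg=tc.ModelConfig())
        out = mod(*feats)
        assert out.shape == (1, 8, 4, 4)

    def test_gating_never_amplifies_feature_magnitude(self, rng):
        """|gate * F| <= |F| element-wise since every gate lies in (0,1)."""
        dau = DAU(np.random.default_rng(5), c=4, cfg=tc.ModelConfig())
        f1 = _t(rng.normal(size=(1, 4, 4, 4)))
        f2 = _t(rng.normal(size=(1, 4, 4, 4)))
        _, inter = dau(f1, f2, return_intermediates=True)
        ws = inter.ws.data[:, :, None, None]
        gated = ws * inter.w1.data * f1.data
        assert (np.abs(gated) <= np.abs(f1.data) + 1e-7).all()
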