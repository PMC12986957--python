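"""Deep-guided decoder: guidance map, guided fusion (against a straight-line
transcription), grouped refinement, and the change head contract."""

import numpy as np
import pytest
from scipy.special import expit

import tidalcd as tc
from tidalcd import nn
from tidalcd.dgmd import DFG, DFGF, ChangeHead, FeatureRefine


def _t(arr):
    return nn.Tensor(np.asarray(arr, np.float32))


class TestDFG:
    def test_output_is_single_channel_at_stride_16(self, rng):
        dfg = DFG(np.random.default_rng(0), c3=8, c4=16, cfg=tc.ModelConfig(
            base_width=16, sa_dim=8))
        x3 = _t(rng.normal(size=(1, 8, 16, 16)))    # 256-px input, stride 16
        x4 = _t(rng.normal(size=(1, 16, 8, 8)))
        out = dfg(x3, x4)
        assert out.shape == (1, 1, 16, 16)

    def test_zero_initialized_layers_give_half(self):
        dfg = DFG(np.random.default_rng(1), c3=8, c4=16,
                  cfg=tc.ModelConfig(base_width=16, sa_dim=8))
        for p in dfg.parameters():
            p.data[...] = 0.0
        out = dfg(_t(np.zeros((1, 8, 8, 8))), _t(np.zeros((1, 16, 4, 4))))
        np.testing.assert_allclose(out.data, 0.5)

    def test_outputs_strictly_inside_unit_interval(self, rng):
        dfg = DFG(np.random.default_rng(2), c3=8, c4=16,
                  cfg=tc.ModelConfig(base_width=16, sa_dim=8))
        out = dfg(_t(rng.normal(size=(2, 8, 8, 8))),
                  _t(rng.normal(size=(2, 16, 4, 4))))
        assert (out.data > 0).all() and (out.data < 1).all()

    def test_mismatched_pyramid_scales_are_rejected(self, rng):
        dfg = DFG(np.random.default_rng(3), c3=8, c4=16,
                  cfg=tc.ModelConfig(base_width=16, sa_dim=8))
        with pytest.raises(ValueError, match="scale"):
            dfg(_t(np.zeros((1, 8, 8, 8))), _t(np.zeros((1, 16, 8, 8))))


def _dfgf_oracle(mod: DFGF, xi, y_next, fdfg):
    """Independent straight-line transcription of guided cross-scale fusion:
    expand both features to 2C, gate their concatenation by sigmoid(guide)+1,
    append broadcast channel means, channel-attend with the shared bottleneck
    on max/avg pooling, project the attention to 2C, gate both features and
    reduce to C."""
    def conv1x1(x, w, b=None):
        out = np.einsum("chw,oc->ohw", x, w[:, :, 0, 0])
        if b is not None:
            out += b[:, None, None]
        return out

    def bn_train(x, gamma, beta, eps=1e-5):
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = ((x - mu) ** 2).mean(axis=(1, 2), keepdims=True)
        return gamma[:, None, None] * (x - mu) / np.sqrt(var + eps) \
            + beta[:, None, None]

    def upx2(x):  # bilinear, align_corners=False, exact 2x
        c, h, w = x.shape
        out = np.zeros((c, 2 * h, 2 * w), np.float32)
        src = (np.arange(2 * h) + 0.5) / 2 - 0.5
        lo = np.clip(np.floor(src).astype(int), 0, h - 1)
        hi = np.clip(lo + 1, 0, h - 1)
        fr = np.clip(src - lo, 0, 1)
        rows = x[:, lo] * (1 - fr)[None, :, None] \
            + x[:, hi] * fr[None, :, None]
        src = (np.arange(2 * w) + 0.5) / 2 - 0.5
        lo = np.clip(np.floor(src).astype(int), 0, w - 1)
        hi = np.clip(lo + 1, 0, w - 1)
        fr = np.clip(src - lo, 0, 1)
        return rows[:, :, lo] * (1 - fr)[None, None, :] \
            + rows[:, :, hi] * fr[None, None, :]

    c, h, w = xi.shape
    fh = conv1x1(upx2(y_next), mod.expand_h.weight.data,
                 mod.expand_h.bias.data)
    fl = conv1x1(xi, mod.expand_l.weight.data, mod.expand_l.bias.data)
    guide = expit(fdfg) + 1.0  # fdfg already at (h, w)
    fga = conv1x1(np.concatenate([fh, fl]) * guide, mod.ga.weight.data,
                  mod.ga.bias.data)
    mean_h = np.tile(fh.mean(axis=(1, 2))[:, None, None], (1, h, w))
    mean_l = np.tile(fl.mean(axis=(1, 2))[:, None, None], (1, h, w))
    fc = np.concatenate([mean_h, mean_l, fga])

    def mlp(v):
        l1, l2 = mod.ca_mlp.layers[0], mod.ca_mlp.layers[2]
        return l2.weight.data @ np.maximum(
            l1.weight.data @ v + l1.bias.data, 0) + l2.bias.data

    fca = mlp(fc.max(axis=(1, 2))) + mlp(fc.mean(axis=(1, 2)))
    a = expit(mod.attn_proj.weight.data @ fca + mod.attn_proj.bias.data)
    fused = a[:, None, None] * fl + a[:, None, None] * fh
    out = conv1x1(fused, mod.out.layers[0].weight.data)
    out = bn_train(out, mod.out.layers[1].weight.data,
                   mod.out.layers[1].bias.data)
    return np.maximum(out, 0)


class TestDFGF:
    def test_output_shape_matches_level_feature(self, rng):
        mod = DFGF(np.random.default_rng(0), c=8, cfg=tc.ModelConfig())
        out = mod(_t(rng.normal(size=(1, 8, 8, 8))),
                  _t(rng.normal(size=(1, 16, 4, 4))),
                  _t(rng.normal(size=(1, 1, 4, 4))))
        assert out.shape == (1, 8, 8, 8)

    def test_guided_multiplier_lies_in_one_two(self, rng):
        guide = rng.normal(size=(1, 1, 4, 4)).astype(np.float32)
        mult = expit(guide) + 1.0
        assert (mult > 1.0).all() and (mult < 2.0).all()

    def test_matches_straight_line_transcription(self, rng):
        """4-channel fixture with the module's weights, 2x2 deep level."""
        mod = DFGF(np.random.default_rng(1), c=4, cfg=tc.ModelConfig())
        xi = rng.normal(size=(1, 4, 4, 4)).astype(np.float32)
        y_next = rng.normal(size=(1, 8, 2, 2)).astype(np.float32)
        fdfg = rng.normal(size=(1, 1, 4, 4)).astype(np.float32)
        out = mod(_t(xi), _t(y_next), _t(fdfg))
        expected = _dfgf_oracle(mod, xi[0], y_next[0], fdfg[0, 0])
        np.testing.assert_allclose(out.data[0], expected, rtol=1e-4,
                                   atol=1e-5)

    def test_wrong_deeper_resolution_is_rejected(self, rng):
        mod = DFGF(np.random.default_rng(2), c=4, cfg=tc.ModelConfig())
        with pytest.raises(ValueError, match="incompatible"):
            mod(_t(np.zeros((1, 4, 4, 4))), _t(np.zeros((1, 8, 4, 4))),
                _t(np.zeros((1, 1, 4, 4))))


class TestFeatureRefine:
    def test_shape_preserved(self, rng):
        fr = FeatureRefine(np.random.default_rng(0), c=8)
        out = fr(_t(rng.normal(size=(2, 8, 4, 4))))
        assert out.shape == (2, 8, 4, 4)

    def test_zero_input_gives_zero_output(self):
        fr = FeatureRefine(np.random.default_rng(1), c=8)
        out = fr(_t(np.zeros((1, 8, 4, 4))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-7)

    def test_parameter_count_matches_closed_form(self):
        """At C=64: 4 groups of depthwise 3x3 (9*16 each) plus 1x1 gates
        (16*16 + 16 each)."""
        fr = FeatureRefine(np.random.default_rng(2), c=64)
        g = 16
        expected = 4 * (9 * g) + 4 * (g * g + g)
        assert fr.n_parameters() == expected

    def test_rejects_indivisible_channels(self):
        with pytest.raises(ValueError, match="divisible"):
            FeatureRefine(np.random.default_rng(3), c=6)


class TestChangeHead:
    def test_full_resolution_two_channel_logits(self, rng):
        head = ChangeHead(np.random.default_rng(0), [8, 16, 32, 64],
                          width=16)
        ys = [_t(rng.normal(size=(1, c, s, s)))
              for c, s in zip([8, 16, 32, 64], [16, 8, 4, 2])]
        out = head(ys)
        assert out.shape == (1, 2, 64, 64)

    def test_softmax_normalizes_per_pixel(self, rng):
        head = ChangeHead(np.random.default_rng(1), [8, 16], width=8)
        head.projs = nn.Sequential(*head.projs.layers[:2])
        ys = [_t(rng.normal(size=(1, 8, 8, 8))),
              _t(rng.normal(size=(1, 16, 4, 4)))]
        out = head(ys)
        probs = nn.softmax(out, axis=1)
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, rtol=1e-5)

    def test_missing_level_is_a_contract_error(self, rng):
        head = ChangeHead(np.random.default_rng(2), [8, 16, 32, 64],
                          width=8)
        with pytest.raises(ValueError, match="refined levels"):
            head([_t(np.zeros((1, 8, 8, 8)))])


class TestFullModel:
    def test_forward_contract_and_determinism(self, narrow_model, rng):
        x1 = rng.normal(size=(1, 3, 64, 64)).astype(np.float32)
        x2 = rng.normal(size=(1, 3, 64, 64)).astype(np.float32)
        narrow_model.eval()
        with nn.no_grad():
            a = narrow_model(_t(x1), _t(x2))
            b = narrow_model(_t(x1.copy()), _t(x2.copy()))
        assert a.shape == (1, 2, 64, 64)
        assert np.isfinite(a.data).all()
        np.testing.assert_array_equal(a.data, b.data)

    def test_guidance_gate_changes_outputs(self, rng):
        """The guidance path is live: ablating it alters the logits."""
        full = tc.ChangeDetectionNet(tc.ModelConfig(base_width=16), seed=5)
        ablated = tc.ChangeDetectionNet(
            tc.ModelConfig(base_width=16, use_dfg=False), seed=5)
        # share every parameter the two variants have in common
        state = full.state_dict()
        partial = {k: v for k, v in ablated.state_dict().items()}
        for k in partial:
            if k in state:
                partial[k] = state[k]
        ablated.load_state_dict(partial)
        x1 = rng.normal(size=(1, 3, 64, 64)).astype(np.float32)
        x2 = rng.normal(size=(1, 3, 64, 64)).astype(np.float32)
        full.eval()
        ablated.eval()
        with nn.no_grad():
            a = full(_t(x1), _t(x2))
            b = ablated(_t(x1.copy()), _t(x2.copy()))
        assert not np.allclose(a.data, b.data)

    def test_deepest_path_composes_guidance_resize_gate_refine(self, rng):
        """Y4 equals refine(X4 * resize(guidance)) composed by hand."""
        model = tc.ChangeDetectionNet(tc.ModelConfig(base_width=16), seed=6)
        model.eval()
        x1 = _t(rng.normal(size=(1, 3, 64, 64)))
        x2 = _t(rng.normal(size=(1, 3, 64, 64)))
        with nn.no_grad():
            f1, f2 = model.siamese(x1, x2)
            xs = model.fuse_pyramids(f1, f2)
            fdfg = model.guidance(xs)
            gate = nn.interpolate_bilinear(
                fdfg, (xs[3].shape[2], xs[3].shape[3]))
            y4_hand = model.refine.layers[3](nn.mul(xs[3], gate))
            logits = model.decode(xs, fdfg)
        # recompute decode's own y4 and compare
        with nn.no_grad():
            gate2 = nn.interpolate_bilinear(
                fdfg, (xs[3].shape[2], xs[3].shape[3]))
            y4_decode = model.refine.layers[3](nn.mul(xs[3], gate2))
        np.testing.assert_allclose(y4_hand.data, y4_decode.data, atol=1e-6)
        assert logits.shape == (1, 2, 64, 64)
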