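"""Dual-axis squeeze attention and the attention-guided ROI alignment block."""

import numpy as np
import pytest

from rowline.attention import (AttentionROIAlign, DAEConfig, axis_squeeze,
                               dot_product_count, dual_axis_attention,
                               full_attention, scatter_line_query)
from rowline.geometry import InvalidInputError
from rowline.nn import functional as F
from rowline.nn.tensor import Tensor


class TestAxisSqueeze:
    def test_horizontal_row_means(self):
        m = np.array([[[1.0, 3.0], [5.0, 7.0]]])     # C=1, H=2, W=2
        out = axis_squeeze(m, "horizontal").data
        np.testing.assert_allclose(out[:, 0], [2.0, 6.0])

    def test_vertical_column_means(self):
        m = np.array([[[1.0, 3.0], [5.0, 7.0]]])
        out = axis_squeeze(m, "vertical").data
        np.testing.assert_allclose(out[:, 0], [3.0, 5.0])

    def test_width_one_is_identity_copy(self):
        m = np.arange(6.0).reshape(2, 3, 1)
        out = axis_squeeze(m, "horizontal").data   # (H, C)
        np.testing.assert_allclose(out, m[:, :, 0].T)

    def test_bad_axis(self):
        with pytest.raises(InvalidInputError):
            axis_squeeze(np.zeros((1, 2, 2)), "diagonal")


class TestScatterLineQuery:
    def test_integer_cell_no_spread(self):
        feats = np.array([[2.0, 5.0]])
        out = scatter_line_query(feats, np.array([[3.0, 1.0]]), 4, 6).data
        assert out[0, 1, 3] == pytest.approx(2.0)
        assert out.sum() == pytest.approx(7.0)
        assert (out != 0).sum() == 2

    def test_half_offset_splits_mass_four_ways(self):
        feats = np.array([[4.0]])
        out = scatter_line_query(feats, np.array([[1.5, 2.5]]), 5, 5).data[0]
        np.testing.assert_allclose(out[2:4, 1:3], 1.0)
        assert out.sum() == pytest.approx(4.0)

    def test_empty_line_gives_zero_map(self):
        out = scatter_line_query(np.zeros((0, 3)), np.zeros((0, 2)), 4, 4).data
        assert out.shape[1:] == (4, 4)
        assert not out.any()

    def test_mass_conservation_random(self):
        rng = np.random.default_rng(0)
        feats = rng.standard_normal((17, 5))
        pts = rng.uniform(0, 9, (17, 2))
        out = scatter_line_query(feats, pts, 10, 10)
        assert out.data.sum() == pytest.approx(feats.sum(), abs=1e-6)


class TestDualAxisAttention:
    def test_single_cell_doubles_value(self):
        q = Tensor(np.random.default_rng(0).standard_normal((3, 1, 1)))
        k = Tensor(np.random.default_rng(1).standard_normal((3, 1, 1)))
        v = Tensor(np.random.default_rng(2).standard_normal((2, 1, 1)))
        out = dual_axis_attention(q, k, v).data
        np.testing.assert_allclose(out, 2 * v.data, atol=1e-7)

    def test_constant_value_map_returns_doubled_constant(self):
        rng = np.random.default_rng(3)
        q = Tensor(rng.standard_normal((2, 3, 4)))
        k = Tensor(rng.standard_normal((2, 3, 4)))
        v = Tensor(np.full((5, 3, 4), 1.7))
        out = dual_axis_attention(q, k, v).data
        np.testing.assert_allclose(out, 2 * 1.7, atol=1e-6)

    def test_uniform_logits_average_rows(self):
        # H=2, W=1 with zero q: softmax uniform -> rows both equal the mean
        # of the two height-squeezed value rows plus the single width row
        q = Tensor(np.zeros((2, 2, 1)))
        k = Tensor(np.ones((2, 2, 1)))
        v = Tensor(np.array([[[1.0], [3.0]]]))     # C_v=1, H=2, W=1
        out = dual_axis_attention(q, k, v).data
        vh_mean = 2.0                              # mean of squeezed rows (1, 3)
        vv = 2.0                                   # vertical squeeze of H
        np.testing.assert_allclose(out[0, :, 0], vh_mean + vv, atol=1e-7)

    def test_attention_is_axis_sized_not_full(self):
        rng = np.random.default_rng(4)
        H, W = 6, 9
        q = Tensor(rng.standard_normal((3, H, W)))
        dual_axis_attention(q, q, q)
        assert dot_product_count() == H * H + W * W
        full_attention(q, q, q)
        assert dot_product_count() == (H * W) ** 2

    def test_value_width_independent_of_attention_shape(self):
        rng = np.random.default_rng(5)
        H, W = 4, 5
        q = Tensor(rng.standard_normal((3, H, W)))
        for cv in (2, 4, 8):
            v = Tensor(rng.standard_normal((cv, H, W)))
            out = dual_axis_attention(q, q, v)
            assert out.shape == (cv, H, W)
            assert dot_product_count() == H * H + W * W

    def test_full_and_dual_agree_on_1x1(self):
        rng = np.random.default_rng(6)
        q = Tensor(rng.standard_normal((3, 1, 1)))
        v = Tensor(rng.standard_normal((4, 1, 1)))
        np.testing.assert_allclose(dual_axis_attention(q, q, v).data,
                                   full_attention(q, q, v).data, atol=1e-7)

    def test_shape_mismatch_rejected(self):
        q = Tensor(np.zeros((3, 2, 2)))
        k = Tensor(np.zeros((3, 2, 3)))
        with pytest.raises(InvalidInputError):
            dual_axis_attention(q, k, q)


def _block(mode="dae", C=8, qk=4):
    cfg = DAEConfig(in_channels=C, qk_channels=qk, v_channels=C)
    return AttentionROIAlign(cfg, rng=np.random.default_rng(0), mode=mode)


class TestDetailGate:
    def test_zero_init_zero_input_gate_is_half(self):
        blk = _block()
        for p in blk.parameters():
            p.data[...] = 0.0
        blk.gate_bn.gamma.data[...] = 1.0
        fmap = Tensor(np.zeros((1, 8, 3, 4), dtype=np.float32))
        feats = Tensor(np.zeros((1, 5, 8), dtype=np.float32))
        gate = blk.detail_enhancement_gate(feats, fmap).data
        np.testing.assert_allclose(gate, 0.5, atol=1e-7)

    def test_gate_range(self):
        blk = _block()
        blk.eval()
        rng = np.random.default_rng(1)
        fmap = Tensor(rng.standard_normal((2, 8, 4, 6)).astype(np.float32) * 5)
        feats = Tensor(rng.standard_normal((2, 7, 8)).astype(np.float32) * 5)
        gate = blk.detail_enhancement_gate(feats, fmap).data
        assert gate.min() > 0.0 and gate.max() < 1.0

    def test_translation_equivariance_away_from_borders(self):
        # exact up to boundary effects: the 3x3 convolution zero-pads and the
        # group normalization couples every position to the (slightly
        # different) border statistics, so interior agreement is approximate
        blk = _block()
        blk.eval()
        rng = np.random.default_rng(2)
        fmap = rng.standard_normal((1, 8, 24, 30)).astype(np.float32)
        feats = Tensor(rng.standard_normal((1, 4, 8)).astype(np.float32))
        g1 = blk.detail_enhancement_gate(feats, Tensor(fmap)).data
        shifted = np.roll(fmap, 1, axis=3)
        g2 = blk.detail_enhancement_gate(feats, Tensor(shifted)).data
        np.testing.assert_allclose(g2[:, :, 3:-3, 3:-3],
                                   np.roll(g1, 1, axis=3)[:, :, 3:-3, 3:-3],
                                   atol=2e-2)


class TestAttentionROIAlign:
    def test_gate_zero_reduces_to_plain_attention(self):
        blk = _block()
        blk.eval()
        blk.gate_proj.weight.data[...] = 0.0
        blk.gate_proj.bias.data[...] = -60.0       # sigmoid -> ~0
        rng = np.random.default_rng(3)
        fmap = Tensor(rng.standard_normal((1, 8, 5, 6)).astype(np.float32))
        pts = rng.uniform(0, 4, (1, 9, 2))
        out = blk(fmap, pts).data
        # reference: dual-axis attention of the projected maps, sampled
        line = F.bilinear_sample(fmap, pts)
        qmap = blk.wq_s(F.bilinear_scatter(line, pts, 5, 6))
        y = F.bilinear_sample(
            Tensor(np.stack([dual_axis_attention(
                Tensor(qmap.data[0]), Tensor(blk.wk_s(fmap).data[0]),
                Tensor(blk.wv_s(fmap).data[0])).data])), pts).data
        np.testing.assert_allclose(out, y, atol=1e-5)

    def test_constant_inputs_give_identical_point_features(self):
        blk = _block()
        blk.eval()
        # interior points only: the gate's 3x3 convolution zero-pads, so
        # border cells legitimately differ
        fmap = Tensor(np.full((1, 8, 8, 8), 0.7, dtype=np.float32))
        pts = np.random.default_rng(4).uniform(2.0, 5.0, (1, 11, 2))
        out = blk(fmap, pts).data[0]
        assert np.abs(out - out[0:1]).max() < 1e-5

    def test_off_mode_is_plain_sampling(self):
        blk = _block(mode="off")
        rng = np.random.default_rng(5)
        fmap = Tensor(rng.standard_normal((1, 8, 5, 6)).astype(np.float32))
        pts = rng.uniform(0, 4, (1, 3, 2))
        np.testing.assert_allclose(blk(fmap, pts).data,
                                   F.bilinear_sample(fmap, pts).data)

    def test_fusion_requires_matching_channels(self):
        with pytest.raises(InvalidInputError):
            AttentionROIAlign(DAEConfig(in_channels=8, qk_channels=4,
                                        v_channels=16))

    def test_v_channel_cap(self):
        with pytest.raises(InvalidInputError):
            DAEConfig(in_channels=8, qk_channels=4, v_channels=1024,
                      max_v_channels=512)
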