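"""Numeric gradient checks for the autodiff core and NN primitives."""

import numpy as np
import pytest
from scipy.signal import correlate

from rowline.nn import functional as F
from rowline.nn.layers import BatchNorm2d, Conv1dSeq, Conv2d, Linear
from rowline.nn.tensor import Tensor, concat, stack


def numeric_grad(t, fval, eps=1e-6):
    g = np.zeros_like(t.data)
    it = np.nditer(t.data, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        o = t.data[i]
        t.data[i] = o + eps
        a = fval()
        t.data[i] = o - eps
        b = fval()
        t.data[i] = o
        g[i] = (a - b) / (2 * eps)
    return g


def check(t, fval, eps=1e-6, atol=1e-6):
    np.testing.assert_allclose(numeric_grad(t, fval, eps), t.grad, atol=atol)


class TestElementwise:
    def test_composite_expression(self):
        rng = np.random.default_rng(0)
        x = Tensor(rng.standard_normal((3, 4)), requires_grad=True)
        w = Tensor(rng.standard_normal((4, 2)), requires_grad=True)
        out = ((x @ w).relu().sigmoid() * 2.0 - 0.3).abs().mean()
        out.backward()

        def f():
            h = np.maximum(x.data @ w.data, 0)
            return float(np.abs(1 / (1 + np.exp(-h)) * 2 - 0.3).mean())
        check(x, f)
        check(w, f)

    def test_broadcasting_unbroadcast(self):
        rng = np.random.default_rng(1)
        a = Tensor(rng.standard_normal((2, 3, 4)), requires_grad=True)
        b = Tensor(rng.standard_normal((1, 3, 1)), requires_grad=True)
        ((a * b + b) ** 2).sum().backward()

        def f():
            return float(((a.data * b.data + b.data) ** 2).sum())
        check(a, f, atol=1e-5)
        check(b, f, atol=1e-5)

    def test_div_tan_sqrt_log(self):
        rng = np.random.default_rng(2)
        x = Tensor(rng.uniform(0.3, 1.2, (5,)), requires_grad=True)
        (x.tan() / x.sqrt() + x.log()).sum().backward()

        def f():
            return float((np.tan(x.data) / np.sqrt(x.data) + np.log(x.data)).sum())
        check(x, f, atol=1e-4)

    def test_clip_gradient_masked(self):
        x = Tensor(np.array([-1.0, 0.5, 2.0]), requires_grad=True)
        (x.clip(0.0, 1.0) * 3.0).sum().backward()
        np.testing.assert_array_equal(x.grad, [0.0, 3.0, 0.0])

    def test_getitem_advanced_indexing_accumulates(self):
        x = Tensor(np.arange(6.0).reshape(2, 3), requires_grad=True)
        idx = (np.array([0, 0, 1]), np.array([1, 1, 2]))
        x[idx].sum().backward()
        np.testing.assert_array_equal(x.grad, [[0, 2, 0], [0, 0, 1]])

    def test_concat_stack(self):
        a = Tensor(np.ones((2, 2)), requires_grad=True)
        b = Tensor(np.ones((2, 2)) * 2, requires_grad=True)
        (concat([a, b], axis=1) * np.arange(4.0)).sum().backward()
        np.testing.assert_array_equal(a.grad, [[0, 1], [0, 1]])
        np.testing.assert_array_equal(b.grad, [[2, 3], [2, 3]])
        a.grad = b.grad = None
        stack([a, b], axis=0).sum().backward()
        np.testing.assert_array_equal(a.grad, np.ones((2, 2)))


class TestConv:
    @pytest.mark.parametrize("shape,oc,k,s,p", [
        ((2, 3, 6, 7), 4, 3, 2, 1),
        ((2, 3, 9, 8), 4, 3, 1, 1),
        ((1, 2, 16, 16), 3, 7, 2, 3),
        ((2, 4, 6, 6), 5, 1, 2, 0),
        ((2, 4, 6, 6), 5, 1, 1, 0),
    ])
    def test_forward_matches_scipy_and_gradients(self, shape, oc, k, s, p):
        rng = np.random.default_rng(k * 10 + s)
        x = Tensor(rng.standard_normal(shape), requires_grad=True)
        w = Tensor(rng.standard_normal((oc, shape[1], k, k)) * 0.3,
                   requires_grad=True)
        b = Tensor(rng.standard_normal(oc) * 0.1, requires_grad=True)
        y = F.conv2d(x, w, b, stride=s, pad=p)
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
        for bb in range(shape[0]):
            for o in range(oc):
                ref = sum(correlate(xp[bb, c], w.data[o, c], mode="valid")
                          for c in range(shape[1]))[::s, ::s] + b.data[o]
                np.testing.assert_allclose(y.data[bb, o], ref, atol=1e-10)
        (y * y).sum().backward()

        def f():
            return float((F.conv2d(Tensor(x.data), Tensor(w.data),
                                   Tensor(b.data), stride=s, pad=p).data ** 2).sum())
        check(x, f, atol=2e-5)
        check(w, f, atol=2e-5)
        check(b, f, atol=2e-5)

    def test_conv1d_sequence(self):
        rng = np.random.default_rng(5)
        x = Tensor(rng.standard_normal((3, 4, 9)), requires_grad=True)
        w = Tensor(rng.standard_normal((5, 4, 3)) * 0.3, requires_grad=True)
        b = Tensor(np.zeros(5), requires_grad=True)
        y = F.conv1d_seq(x, w, b)
        assert y.shape == (3, 5, 9)
        (y * y).sum().backward()

        def f():
            return float((F.conv1d_seq(Tensor(x.data), Tensor(w.data),
                                       Tensor(b.data)).data ** 2).sum())
        check(x, f, atol=2e-5)
        check(w, f, atol=2e-5)


class TestPoolNormSample:
    def test_maxpool(self):
        rng = np.random.default_rng(6)
        x = Tensor(rng.standard_normal((2, 3, 6, 8)), requires_grad=True)
        y = F.maxpool2x2(x)
        assert y.shape == (2, 3, 3, 4)
        (y * y).sum().backward()

        def f():
            return float((F.maxpool2x2(Tensor(x.data)).data ** 2).sum())
        check(x, f, atol=1e-5)

    def test_batchnorm_training_mode(self):
        rng = np.random.default_rng(7)
        x = Tensor(rng.standard_normal((2, 3, 4, 5)), requires_grad=True)
        g = Tensor(rng.uniform(0.5, 1.5, 3), requires_grad=True)
        be = Tensor(rng.standard_normal(3) * 0.1, requires_grad=True)
        run = {"mean": np.zeros(3), "var": np.ones(3)}
        y = F.batchnorm(x, g, be, run, training=True)
        (y ** 3).sum().backward()

        def f():
            r = {"mean": np.zeros(3), "var": np.ones(3)}
            return float((F.batchnorm(Tensor(x.data), Tensor(g.data),
                                      Tensor(be.data), r, True).data ** 3).sum())
        check(x, f, atol=1e-4)
        check(g, f, atol=1e-4)
        check(be, f, atol=1e-4)

    def test_batchnorm_eval_uses_running_stats(self):
        x = Tensor(np.random.default_rng(0).standard_normal((2, 2, 3, 3)))
        run = {"mean": np.array([1.0, -1.0]), "var": np.array([4.0, 0.25])}
        g = Tensor(np.ones(2))
        b = Tensor(np.zeros(2))
        y = F.batchnorm(x, g, b, run, training=False)
        expect = (x.data - run["mean"].reshape(1, 2, 1, 1)) / np.sqrt(
            run["var"].reshape(1, 2, 1, 1) + 1e-5)
        np.testing.assert_allclose(y.data, expect, atol=1e-7)

    def test_upsample_nearest(self):
        x = Tensor(np.arange(4.0).reshape(1, 1, 2, 2), requires_grad=True)
        y = F.upsample_nearest(x, 2)
        np.testing.assert_array_equal(
            y.data[0, 0], [[0, 0, 1, 1], [0, 0, 1, 1], [2, 2, 3, 3], [2, 2, 3, 3]])
        y.sum().backward()
        np.testing.assert_array_equal(x.grad, np.full((1, 1, 2, 2), 4.0))

    def test_bilinear_sample_and_scatter_adjoint(self):
        rng = np.random.default_rng(8)
        fm = Tensor(rng.standard_normal((2, 3, 5, 6)), requires_grad=True)
        pts = rng.uniform(0, 4, (2, 7, 2))
        y = F.bilinear_sample(fm, pts)
        (y * y).sum().backward()

        def f():
            return float((F.bilinear_sample(Tensor(fm.data), pts).data ** 2).sum())
        check(fm, f, atol=1e-5)

        ft = Tensor(rng.standard_normal((2, 7, 3)), requires_grad=True)
        out = F.bilinear_scatter(ft, pts, 5, 6)
        assert float(out.data.sum()) == pytest.approx(float(ft.data.sum()), abs=1e-9)
        (out * out).sum().backward()

        def f2():
            return float((F.bilinear_scatter(Tensor(ft.data), pts, 5, 6).data ** 2).sum())
        check(ft, f2, atol=1e-5)

    def test_softmax_rows_sum_to_one_and_grad(self):
        rng = np.random.default_rng(9)
        x = Tensor(rng.standard_normal((4, 6)), requires_grad=True)
        s = F.softmax(x, axis=-1)
        np.testing.assert_allclose(s.data.sum(axis=-1), 1.0, atol=1e-12)
        (s * np.arange(6.0)).sum().backward()

        def f():
            e = np.exp(x.data - x.data.max(-1, keepdims=True))
            sm = e / e.sum(-1, keepdims=True)
            return float((sm * np.arange(6.0)).sum())
        check(x, f, atol=1e-6)


class TestLayers:
    def test_state_dict_roundtrip(self):
        rng = np.random.default_rng(10)
        lin = Linear(4, 3, rng=rng)
        bn = BatchNorm2d(3)
        bn.running["mean"][:] = 0.5
        state = {**{f"lin.{k}": v for k, v in
                    {"weight": lin.weight.data, "bias": lin.bias.data}.items()}}
        w0 = lin.weight.data.copy()
        lin2 = Linear(4, 3, rng=np.random.default_rng(99))
        lin2.load_state_dict({"weight": w0, "bias": lin.bias.data.copy()})
        np.testing.assert_array_equal(lin2.weight.data, w0)

    def test_conv_module_param_discovery(self):
        conv = Conv2d(3, 4, 3, rng=np.random.default_rng(0))
        names = [n for n, _ in conv.named_parameters()]
        assert set(names) == {"weight", "bias"}
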