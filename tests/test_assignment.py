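"""Dynamic positive assignment and the composite training objective."""

import numpy as np
import pytest

from rowline.assign import (Assignment, AssignmentParams, GtRow, assign,
                            build_costs, similarity_cost, total_loss,
                            _dynamic_k_select)
from rowline.geometry import (AnchorLine, InvalidInputError, SampledRow,
                              anchor_from_sampled, sample_y_positions)
from rowline.losses import LossWeights, RIoUConfig
from rowline.model import StageOutput
from rowline.nn.tensor import Tensor

N, W, H = 12, 320.0, 160.0
DIAG = float(np.hypot(W, H))


def _params(**over):
    base = dict(w_sim=1e6, w_cls=1.0, topk_pool=4, norm_width=W, norm_diag=DIAG)
    base.update(over)
    return AssignmentParams(**base)


def _gt(x0, slope=0.0):
    ys = sample_y_positions(N, H)
    xs = x0 + slope * (H - ys)
    row = SampledRow(xs=xs, valid=np.ones(N, bool), n_points=N, height=H)
    return GtRow(row=row, anchor=anchor_from_sampled(row))


def _pred_arrays(gts, jitter, rng):
    """Prediction xs/anchors derived from gts plus jitter."""
    xs, anch = [], []
    for g, dx in zip(gts, jitter):
        xs.append(np.where(g.row.valid, g.row.xs, 0.0) + dx)
        anch.append([g.anchor.start_x + dx, g.anchor.start_y,
                     g.anchor.theta, g.anchor.length])
    return np.array(xs), np.array(anch)


class TestSimilarityCost:
    def test_identical_is_zero(self):
        gt = _gt(100.0)
        out = similarity_cost(gt.row.xs, gt.anchor, gt, _params())
        assert out == (0.0, 0.0, 0.0, 0.0)

    def test_single_zero_component_zeroes_product(self):
        gt = _gt(100.0)
        # same start point and angle, shifted xs
        pred = AnchorLine(gt.anchor.start_x, gt.anchor.start_y,
                          gt.anchor.theta, gt.anchor.length)
        c_dis, c_xy, c_th, c_sim = similarity_cost(gt.row.xs + 40, pred, gt,
                                                   _params())
        assert c_dis > 0 and c_xy == 0.0 and c_sim == 0.0

    def test_half_half_half_squared_product(self):
        # c_dis = c_xy = c_theta = 0.5 -> c_sim = (0.125)^2
        gt = _gt(0.0)
        p = _params()
        pred = AnchorLine(
            start_x=gt.anchor.start_x + DIAG * 0.5, start_y=gt.anchor.start_y,
            theta=min(gt.anchor.theta + np.pi / 2, np.pi - 1e-6),
            length=gt.anchor.length)
        xs = gt.row.xs + 0.5 * W
        c_dis, c_xy, c_th, c_sim = similarity_cost(xs, pred, gt, p)
        assert (c_dis, c_xy) == (0.5, 0.5)
        assert c_th == pytest.approx(0.5, abs=1e-5)
        assert c_sim == pytest.approx(0.015625, abs=1e-6)

    def test_no_valid_points_is_maximal(self):
        row = SampledRow(np.zeros(N), np.zeros(N, bool), N, H)
        gt = GtRow(row=row, anchor=AnchorLine(0, H, 1.0, 0))
        out = similarity_cost(np.zeros(N), gt.anchor, gt, _params())
        assert out == (1.0, 1.0, 1.0, 1.0)


class TestAssign:
    def test_single_pred_single_gt_forced(self):
        gts = [_gt(100.0)]
        xs, anch = _pred_arrays(gts, [5.0], None)
        asg = assign(xs, anch, np.array([0.2]), gts, _params(), RIoUConfig())
        assert asg.pos_pairs == [(0, 0)]

    def test_two_identical_preds_both_positive(self):
        gts = [_gt(100.0)]
        xs = np.stack([gts[0].row.xs, gts[0].row.xs])
        a = [[gts[0].anchor.start_x, H, gts[0].anchor.theta, N]] * 2
        asg = assign(xs, np.array(a), np.array([0.5, 0.5]), gts,
                     _params(), RIoUConfig())
        assert sorted(p for p, _ in asg.pos_pairs) == [0, 1]

    def test_empty_gts(self):
        gts = [_gt(100.0)]
        xs, anch = _pred_arrays(gts, [0.0], None)
        asg = assign(xs, anch, np.array([0.5]), [], _params(), RIoUConfig())
        assert asg.pos_pairs == []

    def test_no_preds_raises(self):
        with pytest.raises(InvalidInputError):
            assign(np.zeros((0, N)), np.zeros((0, 4)), np.zeros(0),
                   [_gt(0.0)], _params(), RIoUConfig())

    def test_every_gt_gets_a_positive(self):
        rng = np.random.default_rng(0)
        gts = [_gt(60.0), _gt(160.0), _gt(260.0)]
        xs, anch = _pred_arrays(gts * 2, rng.uniform(-30, 30, 6), rng)
        asg = assign(xs, anch, rng.uniform(0, 1, 6), gts, _params(),
                     RIoUConfig())
        assert set(g for _, g in asg.pos_pairs) == {0, 1, 2}
        preds = [p for p, _ in asg.pos_pairs]
        assert len(preds) == len(set(preds))


def brute_force_rule(c_assign, riou, topk_pool):
    """Naive re-statement of the assignment rule with explicit loops."""
    P, G = c_assign.shape
    claimed = {}
    for g in range(G):
        top = sorted(riou[:, g], reverse=True)[:min(topk_pool, P)]
        s = sum(v for v in top if v > 0)
        k = int(min(max(round(s), 1), topk_pool))
        order = sorted(range(P), key=lambda p: (c_assign[p, g], p))[:k]
        for p in order:
            if p not in claimed or c_assign[p, g] < c_assign[p, claimed[p]]:
                claimed[p] = g
    for g in range(G):
        if g not in claimed.values():
            free = [p for p in sorted(range(P),
                                      key=lambda p: (c_assign[p, g], p))
                    if p not in claimed]
            if free:
                claimed[free[0]] = g
    return sorted((p, g) for p, g in claimed.items())


class TestDynamicKOracle:
    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.integers(1, 7)
        G = rng.integers(1, 4)
        c = rng.uniform(0, 10, (P, G))
        r = rng.uniform(-1, 1, (P, G))
        got = _dynamic_k_select(c, r, topk_pool=4)
        assert got == brute_force_rule(c, r, 4)

    def test_hand_set_three_by_two(self):
        c = np.array([[0.1, 5.0], [0.2, 0.3], [4.0, 0.05]])
        r = np.array([[0.9, -1.0], [0.8, 0.2], [-1.0, 0.95]])
        got = _dynamic_k_select(c, r, topk_pool=4)
        assert got == brute_force_rule(c, r, 4)
        # k for gt0 = round(0.9+0.8)=2 -> preds 0,1; gt1 k=round(0.95+0.2)=1 -> pred 2
        assert got == [(0, 0), (1, 0), (2, 1)]


def _stage_output(params_n, offsets, logits):
    """Build a StageOutput with autodiff tensors from plain arrays."""
    pt = Tensor(np.asarray(params_n, dtype=float), requires_grad=True)
    ot = Tensor(np.asarray(offsets, dtype=float), requires_grad=True)
    lt = Tensor(np.asarray(logits, dtype=float), requires_grad=True)
    st = lt.sigmoid()
    return StageOutput(scores=st.data, deltas=np.zeros_like(pt.data),
                       offsets=ot.data, scores_t=st, logits_t=lt,
                       params_t=pt, offsets_t=ot)


def _perfect_outputs(gts):
    """One stage whose single prediction per gt matches exactly."""
    params, offsets, logits = [], [], []
    ys = sample_y_positions(N, H)
    for g in gts:
        a = g.anchor
        params.append([a.start_x / W, a.start_y / H, a.theta / np.pi,
                       a.length / N])
        ref = a.start_x + (a.start_y - ys) / np.tan(a.theta)
        offsets.append(np.where(g.row.valid, g.row.xs - ref, 0.0))
        logits.append(12.0)
    return [_stage_output(np.array(params)[None], np.array(offsets)[None],
                          np.array(logits)[None])]


class TestTotalLoss:
    def test_perfect_predictions_near_zero(self):
        gts = [_gt(80.0), _gt(200.0, slope=0.2)]
        outs = _perfect_outputs(gts)
        w = LossWeights()
        total, br = total_loss(outs, [gts], w, RIoUConfig(), _params(),
                               W, H, N)
        assert br.riou == pytest.approx(0.0, abs=1e-9)
        assert br.xytl == pytest.approx(0.0, abs=1e-9)
        assert br.total < 0.05          # residual: focal terms at logit 12

    def test_zero_weights_zero_total(self):
        gts = [_gt(80.0)]
        outs = _perfect_outputs(gts)
        w = LossWeights(w_cls=0.0, w_xytl=0.0, w_riou=0.0)
        total, br = total_loss(outs, [gts], w, RIoUConfig(), _params(), W, H, N)
        assert float(total.data) == 0.0
        assert br.total == 0.0

    def test_riou_weight_linearity(self):
        rng = np.random.default_rng(1)
        gts = [_gt(80.0)]
        outs = _perfect_outputs(gts)
        outs[0].offsets_t.data += rng.uniform(-10, 10, outs[0].offsets_t.shape)
        outs[0].offsets = outs[0].offsets_t.data
        w1 = LossWeights(w_riou=1.0)
        w2 = LossWeights(w_riou=2.0)
        _, b1 = total_loss(outs, [gts], w1, RIoUConfig(), _params(), W, H, N)
        _, b2 = total_loss(outs, [gts], w2, RIoUConfig(), _params(), W, H, N)
        assert b1.riou == pytest.approx(b2.riou)
        # doubling the weight adds exactly one more riou contribution
        assert b2.total - b1.total == pytest.approx(b1.riou, rel=1e-9)

    def test_weight_swap_changes_only_that_field(self):
        gts = [_gt(80.0)]
        outs = _perfect_outputs(gts)
        outs[0].offsets_t.data += 3.0
        outs[0].offsets = outs[0].offsets_t.data
        wa = LossWeights(w_cls=1.0, w_xytl=2.0, w_riou=3.0)
        wb = LossWeights(w_cls=1.0, w_xytl=3.0, w_riou=2.0)
        _, ba = total_loss(outs, [gts], wa, RIoUConfig(), _params(), W, H, N)
        _, bb = total_loss(outs, [gts], wb, RIoUConfig(), _params(), W, H, N)
        assert ba.cls == pytest.approx(bb.cls)
        assert ba.riou == pytest.approx(bb.riou)
        assert ba.xytl == pytest.approx(bb.xytl)
        assert ba.total != pytest.approx(bb.total)

    def test_no_gts_classification_only(self):
        outs = _perfect_outputs([_gt(80.0)])
        total, br = total_loss(outs, [[]], LossWeights(), RIoUConfig(),
                               _params(), W, H, N)
        assert br.riou == 0.0 and br.xytl == 0.0
        assert br.cls > 0.0

    def test_smooth_l1_regression_arm(self):
        gts = [_gt(80.0)]
        outs = _perfect_outputs(gts)
        total, br = total_loss(outs, [gts], LossWeights(), RIoUConfig(),
                               _params(), W, H, N, regression="smooth_l1")
        assert br.riou == pytest.approx(0.0, abs=1e-9)

    def test_breakdown_total_is_weighted_sum(self):
        rng = np.random.default_rng(2)
        gts = [_gt(80.0), _gt(180.0)]
        outs = _perfect_outputs(gts)
        outs[0].offsets_t.data += rng.uniform(-20, 20, outs[0].offsets_t.shape)
        outs[0].offsets = outs[0].offsets_t.data
        w = LossWeights(w_cls=1.5, w_xytl=0.7, w_riou=2.5)
        total, br = total_loss(outs, [gts], w, RIoUConfig(), _params(), W, H, N)
        assert br.total == pytest.approx(
            w.w_cls * br.cls + w.w_xytl * br.xytl + w.w_riou * br.riou, rel=1e-9)
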