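"""Dynamic positive-sample assignment and the composite training objective.

Each ground-truth row claims a *variable* number k of predictions as
positives: k is the clamped, rounded sum of the top row-IoU values between
the gt and all predictions (a dynamic-k rule), and the k predictions with
the lowest assignment cost

    C_assign = w_sim * C_sim + w_cls * C_cls,
    C_sim    = (C_dis * C_xy * C_theta)^2

become positives.  The similarity components are each normalized to [0, 1]:
mean point distance over image width, start-point distance over the image
diagonal, and angle difference over pi.  A prediction claimed by several gts
goes to the gt with the lower cost; a gt left empty afterwards claims its
cheapest still-unassigned prediction.

The total loss is focal classification over all predictions plus smooth-l1
on the anchor parameters and the Row-IoU loss, the latter two averaged over
positives only; all cascade stages are supervised with equal weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (AnchorLine, InvalidInputError, SampledRow,
                       sample_y_positions)
from .losses import (LossBreakdown, LossWeights, RIoUConfig, focal_loss,
                     focal_loss_logits_t, focal_loss_t, riou_loss_t,
                     segment_iou, smooth_l1_t)
from .model import StageOutput, _THETA_LO, _THETA_HI
from .nn.tensor import Tensor

__all__ = ["AssignmentParams", "GtRow", "CostMatrix", "Assignment",
           "similarity_cost", "assign", "total_loss", "gt_arrays"]


@dataclass
class AssignmentParams:
    w_sim: float = 1.0e6
    w_cls: float = 1.0
    component_floor: float = 0.01
    topk_pool: int = 4
    norm_width: float = 800.0
    norm_diag: float = 861.6       # sqrt(800^2 + 320^2) by default

    def __post_init__(self):
        if self.w_sim < 0 or self.w_cls < 0:
            raise InvalidInputError("assignment weights must be nonnegative")
        if self.topk_pool < 1:
            raise InvalidInputError("topk_pool must be >= 1")


@dataclass
class GtRow:
    """A ground-truth row at network scale: sampled form plus fitted anchor."""
    row: SampledRow
    anchor: AnchorLine


@dataclass
class CostMatrix:
    c_assign: np.ndarray
    c_dis: np.ndarray
    c_xy: np.ndarray
    c_theta: np.ndarray
    c_sim: np.ndarray
    c_cls: np.ndarray


@dataclass
class Assignment:
    pos_pairs: list               # [(pred_idx, gt_idx)]
    pred_to_gt: dict


def similarity_cost(pred_xs: np.ndarray, pred_anchor: AnchorLine,
                    gt: GtRow, params: AssignmentParams):
    """(c_dis, c_xy, c_theta, c_sim) for one prediction/gt pair."""
    mask = gt.row.valid
    if not mask.any():
        return 1.0, 1.0, 1.0, 1.0
    c_dis = float(np.clip(np.mean(np.abs(pred_xs[mask] - gt.row.xs[mask]))
                          / params.norm_width, 0.0, 1.0))
    dxy = np.hypot(pred_anchor.start_x - gt.anchor.start_x,
                   pred_anchor.start_y - gt.anchor.start_y)
    c_xy = float(np.clip(dxy / params.norm_diag, 0.0, 1.0))
    c_theta = float(np.clip(abs(pred_anchor.theta - gt.anchor.theta) / np.pi, 0.0, 1.0))
    c_sim = (c_dis * c_xy * c_theta) ** 2
    return c_dis, c_xy, c_theta, c_sim


def _row_iou_matrix(pred_xs: np.ndarray, gts: list, cfg: RIoUConfig) -> np.ndarray:
    P = len(pred_xs)
    R = np.empty((P, len(gts)))
    for g, gt in enumerate(gts):
        mask = gt.row.valid
        d = np.abs(pred_xs[:, mask] - gt.row.xs[mask])
        e = cfg.extension_e
        R[:, g] = (2 * e - d).sum(axis=1) / ((2 * e + d).sum(axis=1) + cfg.eps)
    return R


def _anchor_array(pred_anchors) -> np.ndarray:
    if isinstance(pred_anchors, np.ndarray):
        return pred_anchors
    return np.array([[a.start_x, a.start_y, a.theta, a.length]
                     for a in pred_anchors])


def build_costs(pred_xs: np.ndarray, pred_anchors, scores: np.ndarray,
                gts: list, params: AssignmentParams,
                weights: LossWeights) -> CostMatrix:
    P, G = len(pred_xs), len(gts)
    anch = _anchor_array(pred_anchors)
    gt_anch = np.array([[g.anchor.start_x, g.anchor.start_y, g.anchor.theta]
                        for g in gts])
    lo = params.component_floor    # keeps the squared product from collapsing
    c_dis = np.ones((P, G))
    for g, gt in enumerate(gts):
        mask = gt.row.valid
        if mask.any():
            c_dis[:, g] = np.clip(
                np.abs(pred_xs[:, mask] - gt.row.xs[mask]).mean(axis=1)
                / params.norm_width, lo, 1.0)
    c_xy = np.clip(np.hypot(anch[:, 0, None] - gt_anch[None, :, 0],
                            anch[:, 1, None] - gt_anch[None, :, 1])
                   / params.norm_diag, lo, 1.0)
    c_th = np.clip(np.abs(anch[:, 2, None] - gt_anch[None, :, 2]) / np.pi, lo, 1.0)
    c_sim = (c_dis * c_xy * c_th) ** 2
    c_cls = np.repeat(focal_loss(scores, np.ones_like(scores, dtype=bool),
                                 weights.focal_alpha, weights.focal_gamma)[:, None], G, axis=1)
    c_assign = params.w_sim * c_sim + params.w_cls * c_cls
    return CostMatrix(c_assign=c_assign, c_dis=c_dis, c_xy=c_xy,
                      c_theta=c_th, c_sim=c_sim, c_cls=c_cls)


def assign(pred_xs: np.ndarray, pred_anchors, scores: np.ndarray,
           gts: list, params: AssignmentParams, cfg: RIoUConfig,
           weights: LossWeights | None = None) -> Assignment:
    """Dynamic-k assignment of predictions to ground-truth rows."""
    weights = weights or LossWeights()
    P = len(pred_xs)
    if P == 0:
        raise InvalidInputError("assign requires at least one prediction")
    if len(gts) == 0:
        return Assignment(pos_pairs=[], pred_to_gt={})
    costs = build_costs(pred_xs, pred_anchors, scores, gts, params, weights)
    riou = _row_iou_matrix(pred_xs, gts, cfg)
    pos_pairs = _dynamic_k_select(costs.c_assign, riou, params.topk_pool)
    return Assignment(pos_pairs=pos_pairs, pred_to_gt=dict(pos_pairs))


def _dynamic_k_select(c_assign: np.ndarray, riou: np.ndarray, topk_pool: int):
    """The assignment rule, shared by implementation and oracle tests."""
    P, G = c_assign.shape
    ks = []
    for g in range(G):
        top = np.sort(riou[:, g])[::-1][:min(topk_pool, P)]
        s = top[top > 0].sum()
        ks.append(int(np.clip(round(s), 1, topk_pool)))
    # candidate sets: k_g lowest-cost predictions per gt (stable order)
    claimed: dict[int, int] = {}
    for g in range(G):
        order = np.argsort(c_assign[:, g], kind="stable")[:ks[g]]
        for p in order:
            p = int(p)
            if p not in claimed or c_assign[p, g] < c_assign[p, claimed[p]]:
                claimed[p] = g
    # guarantee each gt >= 1 positive where possible
    have = set(claimed.values())
    for g in range(G):
        if g in have:
            continue
        free = [p for p in np.argsort(c_assign[:, g], kind="stable")
                if int(p) not in claimed]
        if free:
            claimed[int(free[0])] = g
            have.add(g)
    return sorted((p, g) for p, g in claimed.items())


# ----------------------------------------------------------------- training

def gt_arrays(gts: list):
    """Stack gt rows into (G, N) arrays plus anchor parameter rows."""
    xs = np.stack([np.where(g.row.valid, g.row.xs, 0.0) for g in gts])
    valid = np.stack([g.row.valid for g in gts])
    anch = np.array([[g.anchor.start_x, g.anchor.start_y, g.anchor.theta,
                      g.anchor.length] for g in gts])
    return xs, valid, anch


def _pred_xs_numpy(params: np.ndarray, offsets: np.ndarray, ys: np.ndarray,
                   W: float, H: float, N: int) -> np.ndarray:
    x = params[..., 0] * W
    y = params[..., 1] * H
    t = np.clip(params[..., 2], _THETA_LO, _THETA_HI) * np.pi
    return x[..., None] + (y[..., None] - ys) / np.tan(t)[..., None] + offsets


def total_loss(outputs: list[StageOutput], gts_per_image: list,
               weights: LossWeights, riou_cfg: RIoUConfig,
               assign_params: AssignmentParams, input_width: float,
               input_height: float, n_points: int,
               regression: str = "riou",
               assignments=None, static_priors: np.ndarray | None = None
               ) -> tuple[Tensor, LossBreakdown]:
    """Deep-supervised total loss over all cascade stages.

    gts_per_image: list (length B) of lists of GtRow at network scale.
    regression: "riou" (default) or "smooth_l1" (ablation arm) for the
    point-wise term.  When ``static_priors`` (A, 4) normalized anchor
    parameters are given, the assignment cost is computed from those fixed
    priors instead of the refined predictions (a stabilization phase early
    in training).  Returns (scalar loss tensor, detached breakdown).
    """
    ys = sample_y_positions(n_points, input_height)
    W, H, N = input_width, input_height, n_points
    cls_terms, xytl_terms, riou_terms = [], [], []

    # one dynamic assignment per image, computed from the final cascade stage
    # and shared by all supervised stages (stable anchor specialization)
    last = outputs[-1]
    B, A = last.scores.shape
    per_image_asg = []
    for b in range(B):
        gts = gts_per_image[b]
        if not gts:
            per_image_asg.append(None)
            continue
        if assignments is not None:
            per_image_asg.append(assignments[b])
            continue
        if static_priors is not None:
            prm = static_priors
            offs = np.zeros((prm.shape[0], N))
        else:
            prm = last.params_t.data[b]
            offs = last.offsets[b]
        pred_xs = _pred_xs_numpy(prm, offs, ys, W, H, N)
        pred_anchors = np.column_stack([
            prm[:, 0] * W, prm[:, 1] * H,
            np.clip(prm[:, 2], _THETA_LO, _THETA_HI) * np.pi,
            np.clip(prm[:, 3], 0, 1) * N])
        per_image_asg.append(assign(pred_xs, pred_anchors, last.scores[b], gts,
                                    assign_params, riou_cfg, weights))

    for s_idx, out in enumerate(outputs):
        targets = np.zeros((B, A), dtype=np.float32)
        pairs_b, pairs_a, pairs_g_img = [], [], []
        gt_xs_rows, gt_valid_rows, gt_anchor_rows = [], [], []
        for b in range(B):
            asg = per_image_asg[b]
            if asg is None:
                continue
            for p, g in asg.pos_pairs:
                targets[b, p] = 1.0
                pairs_b.append(b); pairs_a.append(p); pairs_g_img.append((b, g))
        n_pos = len(pairs_b)
        cls_all = focal_loss_logits_t(out.logits_t.reshape(B * A),
                                      targets.reshape(B * A),
                                      weights.focal_alpha, weights.focal_gamma)
        cls_terms.append(cls_all.sum() / max(n_pos, 1))
        if n_pos == 0:
            continue
        bi = np.array(pairs_b); ai = np.array(pairs_a)
        for b, g in pairs_g_img:
            gt = gts_per_image[b][g]
            gt_xs_rows.append(np.where(gt.row.valid, gt.row.xs, 0.0))
            gt_valid_rows.append(gt.row.valid)
            gt_anchor_rows.append([gt.anchor.start_x, gt.anchor.start_y,
                                   gt.anchor.theta, gt.anchor.length])
        gt_xs = np.stack(gt_xs_rows)
        gt_valid = np.stack(gt_valid_rows)
        gt_anch = np.array(gt_anchor_rows)

        sel = out.params_t[bi, ai]                      # (R, 4) normalized
        px = sel[:, 0] * W
        py = sel[:, 1] * H
        pt = sel[:, 2].clip(_THETA_LO, _THETA_HI) * np.pi
        pl = sel[:, 3] * N
        # smooth-l1 on (x/W, y/H, theta/pi, length/N): all components in
        # image-relative units so their gradients are commensurate
        beta_n = weights.smooth_l1_beta / 100.0
        gt_norm = gt_anch / np.array([W, H, np.pi, N])
        comps = [
            smooth_l1_t(sel[:, 0] - Tensor(gt_norm[:, 0]), beta_n),
            smooth_l1_t(sel[:, 1] - Tensor(gt_norm[:, 1]), beta_n),
            smooth_l1_t(sel[:, 2] - Tensor(gt_norm[:, 2]), beta_n),
            smooth_l1_t(sel[:, 3] - Tensor(gt_norm[:, 3]), beta_n),
        ]
        xytl = sum(c.mean() for c in comps) * 0.25
        if out.extent_t is not None:
            # per-point extent supervision carries the same information as
            # the scalar (start, length) pair but is locally decodable
            ext_sel = out.extent_t[bi, ai]              # (R, N) logits
            bce = focal_loss_logits_t(ext_sel.reshape(-1),
                                      gt_valid.astype(np.float64).reshape(-1),
                                      alpha=0.5, gamma=0.0)
            xytl = xytl + 6.0 * bce.mean()
        xytl_terms.append(xytl)

        offs = out.offsets_t[bi, ai]                    # (R, N) px
        R = len(bi)
        # the start point is trained by its smooth-l1 term only: the
        # abscissa model is invariant to sliding (x, y) along the line, and
        # letting the Row-IoU gradient reach y lets it drag the start point
        # through that gauge direction until the validity gate empties
        py_det = py.detach()
        xs_pred = (px.reshape(R, 1)
                   + (py_det.reshape(R, 1) - Tensor(ys.reshape(1, N))) / pt.tan().reshape(R, 1)
                   + offs)
        if regression == "smooth_l1":
            m = gt_valid.astype(np.float32)
            per = smooth_l1_t((xs_pred - Tensor(gt_xs)) * Tensor(m), weights.smooth_l1_beta)
            riou_terms.append(per.sum() / max(m.sum(), 1.0))
        else:
            riou_terms.append(riou_loss_t(xs_pred, gt_xs, gt_valid, riou_cfg))

    n_stages = len(outputs)
    cls_v = sum(cls_terms) / n_stages
    xytl_v = sum(xytl_terms) / n_stages if xytl_terms else Tensor(np.float32(0.0))
    riou_v = sum(riou_terms) / n_stages if riou_terms else Tensor(np.float32(0.0))
    total = weights.w_cls * cls_v + weights.w_xytl * xytl_v + weights.w_riou * riou_v
    breakdown = LossBreakdown(
        cls=float(cls_v.data), xytl=float(xytl_v.data), riou=float(riou_v.data),
        total=float(total.data))
    return total, breakdown
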