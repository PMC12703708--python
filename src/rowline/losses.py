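"""Row-IoU geometry and the training losses.

At every sampled vertical position the predicted and ground-truth abscissae
are extended horizontally by a half-length ``e``; the signed 1-D IoU of the
two extended segments is ``(2e - d) / (2e + d)`` with ``d = |x_p - x_g|``,
negative when the segments do not overlap.  The row-level RIoU is the ratio
of the *summed* overlaps to the *summed* unions over the ground-truth row's
valid sampling positions (a ratio of sums, not a mean of per-position IoUs),
and the loss is ``1 - RIoU`` in [0, 2].

Both plain-NumPy entry points (evaluation, NMS) and autodiff entry points
(training) are provided; the ``*_t`` functions operate on ``rowline.nn``
tensors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import AnchorLine, InvalidInputError, SampledRow
from .nn.tensor import Tensor

__all__ = [
    "RIoUConfig", "LossWeights", "LossBreakdown", "InvalidTargetError",
    "segment_iou", "row_iou", "riou_loss", "smooth_l1_xytl", "focal_loss",
    "riou_loss_t", "smooth_l1_t", "focal_loss_t", "focal_loss_logits_t",
]

_PEPS = 1e-6      # probability clamp for the focal loss


class InvalidTargetError(ValueError):
    """Raised when a loss target has no valid sampling positions."""


@dataclass
class RIoUConfig:
    """Segment half-extension ``e`` (px) and a denominator stabilizer."""

    extension_e: float = 15.0
    eps: float = 1e-9

    def __post_init__(self):
        if self.extension_e <= 0 or self.eps <= 0:
            raise InvalidInputError("extension_e and eps must be positive")


@dataclass
class LossWeights:
    w_cls: float = 2.0
    w_xytl: float = 0.2
    w_riou: float = 2.0
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    smooth_l1_beta: float = 1.0

    def __post_init__(self):
        vals = (self.w_cls, self.w_xytl, self.w_riou,
                self.focal_alpha, self.focal_gamma, self.smooth_l1_beta)
        if any(v < 0 for v in vals):
            raise InvalidInputError("loss weights must be nonnegative")


@dataclass
class LossBreakdown:
    cls: float
    xytl: float
    riou: float
    total: float


# --------------------------------------------------------------------- numpy

def segment_iou(xp, xg, cfg: RIoUConfig):
    """Signed IoU of the two horizontally extended segments; in (-1, 1]."""
    e = cfg.extension_e
    xp = np.asarray(xp, dtype=np.float64)
    xg = np.asarray(xg, dtype=np.float64)
    num = np.minimum(xp + e, xg + e) - np.maximum(xp - e, xg - e)
    den = np.maximum(xp + e, xg + e) - np.minimum(xp - e, xg - e)
    return num / np.maximum(den, cfg.eps)


def row_iou(pred: SampledRow, gt: SampledRow, cfg: RIoUConfig) -> float:
    """Ratio of summed overlaps to summed unions over gt-valid positions."""
    if pred.n_points != gt.n_points:
        raise InvalidInputError("pred and gt must share n_points")
    mask = gt.valid
    if not mask.any():
        raise InvalidTargetError("ground-truth row has no valid samples")
    e = cfg.extension_e
    d = np.abs(pred.xs[mask] - gt.xs[mask])
    return float((2 * e - d).sum() / max((2 * e + d).sum(), cfg.eps))


def riou_loss(pred: SampledRow, gt: SampledRow, cfg: RIoUConfig) -> float:
    """1 - RIoU, in [0, 2]; zero exactly at the ground truth."""
    return 1.0 - row_iou(pred, gt, cfg)


def smooth_l1_xytl(pred: AnchorLine, gt: AnchorLine, beta: float = 1.0) -> float:
    """Mean smooth-l1 over (start_x, start_y, theta/pi, length).

    The angle enters in normalized units (theta/pi) so a degree-scale error
    stays commensurate with pixel-scale errors.
    """
    diffs = np.array([
        pred.start_x - gt.start_x,
        pred.start_y - gt.start_y,
        (pred.theta - gt.theta) / np.pi,
        pred.length - gt.length,
    ])
    return float(np.mean(_smooth_l1_np(diffs, beta)))


def _smooth_l1_np(d, beta):
    a = np.abs(d)
    return np.where(a < beta, 0.5 * d * d / beta, a - 0.5 * beta)


def focal_loss(score, is_positive, alpha: float = 0.25, gamma: float = 2.0):
    """Focal binary classification loss; scores clamped away from {0, 1}."""
    p = np.clip(np.asarray(score, dtype=np.float64), _PEPS, 1 - _PEPS)
    pos = np.asarray(is_positive, dtype=bool)
    out = np.where(pos,
                   -alpha * (1 - p) ** gamma * np.log(p),
                   -(1 - alpha) * p ** gamma * np.log(1 - p))
    return out if out.ndim else float(out)


# ------------------------------------------------------------------ autodiff

def riou_loss_t(xs_pred: Tensor, xs_gt: np.ndarray, gt_valid: np.ndarray,
                cfg: RIoUConfig) -> Tensor:
    """Differentiable 1 - RIoU for a batch of rows.

    xs_pred: (R, N) tensor; xs_gt: (R, N); gt_valid: (R, N) bool.
    Returns the mean loss over the R rows.
    """
    e = cfg.extension_e
    mask = gt_valid.astype(xs_pred.dtype.type)
    gt = np.where(gt_valid, xs_gt, 0.0)
    d = ((xs_pred * Tensor(mask)) - Tensor(gt * mask)).abs()
    num = (Tensor(2 * e * mask) - d).sum(axis=1)
    den = (Tensor(2 * e * mask) + d).sum(axis=1)
    return (1.0 - num / den.clip(cfg.eps, np.inf)).mean()


def smooth_l1_t(diff: Tensor, beta: float) -> Tensor:
    a = diff.abs()
    quad_mask = (a.data < beta).astype(diff.dtype.type)
    quad = (diff * diff) * (0.5 / beta)
    lin = a - 0.5 * beta
    return quad * Tensor(quad_mask) + lin * Tensor(1.0 - quad_mask)


def focal_loss_t(scores: Tensor, targets: np.ndarray,
                 alpha: float, gamma: float) -> Tensor:
    """Differentiable focal loss; targets in {0,1}; returns elementwise losses."""
    t = targets.astype(scores.dtype.type)
    p = scores.clip(_PEPS, 1 - _PEPS)
    pos = -alpha * ((1.0 - p) ** gamma) * p.log()
    neg = -(1 - alpha) * (p ** gamma) * (1.0 - p).log()
    return pos * Tensor(t) + neg * Tensor(1.0 - t)


def _softplus_t(z: Tensor) -> Tensor:
    # log(1 + e^z) = relu(z) + log(1 + e^{-|z|}), numerically stable
    return z.relu() + (1.0 + (-z.abs()).exp()).log()


def focal_loss_logits_t(logits: Tensor, targets: np.ndarray,
                        alpha: float, gamma: float) -> Tensor:
    """Focal loss computed from logits (stable; no vanishing gradient when a
    score saturates on the wrong side)."""
    t = targets.astype(logits.dtype.type)
    p = logits.sigmoid()
    log_p = -_softplus_t(-logits)
    log_1mp = -_softplus_t(logits)
    pos = -alpha * ((1.0 - p).detach() ** gamma) * log_p
    neg = -(1 - alpha) * (p.detach() ** gamma) * log_1mp
    return pos * Tensor(t) + neg * Tensor(1.0 - t)
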