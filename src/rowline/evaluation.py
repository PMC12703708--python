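"""Thickened-mask evaluation protocol.

Row centerlines carry no area, so precision/recall are defined on *thickened*
masks: every polyline is stroked to a fixed width (50 px by default) on the
evaluation grid, predictions and ground truth are matched one-to-one by
optimal bipartite matching on the mask-IoU matrix, and a matched pair counts
as a true positive at threshold tau when its IoU strictly exceeds tau.  F1
is reported at tau = 0.50, 0.55, ..., 0.95 and mF1 is 100 x their mean.

Rasterization convention: square caps, joins filled, no anti-aliasing; a
pixel at (row r, column c) samples the plane point (x=c, y=r); the stroke
covers the half-open band [-w/2, w/2) across the line so a width-50 vertical
line at x=50 covers exactly columns 25..74.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import InvalidInputError, RowPolyline, SampledRow

__all__ = ["EvalConfig", "EvalResult", "thicken_mask", "mask_iou",
           "match_and_score", "evaluate_dataset", "write_results",
           "InvalidEvaluationError"]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


class InvalidEvaluationError(ValueError):
    """Raised when the evaluation problem is ill-posed (no ground truth)."""


@dataclass
class EvalConfig:
    thickness: float = 50.0
    thresholds: tuple = DEFAULT_THRESHOLDS
    eval_width: int = 1280
    eval_height: int = 720
    strict_greater: bool = True

    def __post_init__(self):
        th = tuple(self.thresholds)
        if not all(0 < t < 1 for t in th) or not all(b > a for a, b in zip(th, th[1:])):
            raise InvalidInputError("thresholds must be strictly increasing in (0, 1)")
        if self.thickness < 1:
            raise InvalidInputError("thickness must be >= 1")
        self.thresholds = th


@dataclass
class EvalResult:
    per_threshold: list           # [(tau, precision, recall, f1)] on 0-1 scale
    mf1: float                    # percent (0-100)

    def f1_at(self, tau: float) -> float:
        for t, _, _, f1 in self.per_threshold:
            if abs(t - tau) < 1e-9:
                return f1
        raise KeyError(tau)


def _points_of(row) -> np.ndarray:
    if isinstance(row, RowPolyline):
        return row.points
    if isinstance(row, SampledRow):
        ys = row.ys[row.valid]
        xs = row.xs[row.valid]
        return np.column_stack([xs, ys])
    raise InvalidInputError(f"cannot rasterize {type(row).__name__}")


def thicken_mask(row, cfg: EvalConfig) -> np.ndarray:
    """Stroke a row centerline to a binary (eval_height, eval_width) mask."""
    pts = _points_of(row)
    H, W = cfg.eval_height, cfg.eval_width
    mask = np.zeros((H, W), dtype=bool)
    if len(pts) < 2:
        log.warning("thicken_mask: fewer than 2 valid points; empty mask")
        return mask
    half = cfg.thickness / 2.0
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        _stroke_segment(mask, x0, y0, x1, y1, half)
    return mask


def _stroke_segment(mask, x0, y0, x1, y1, half):
    H, W = mask.shape
    dx, dy = x1 - x0, y1 - y0
    L = float(np.hypot(dx, dy))
    if L == 0.0:
        ux, uy = 0.0, 1.0
    else:
        ux, uy = dx / L, dy / L
    # square caps: extend by half along the direction at both ends
    cmin = max(int(np.floor(min(x0, x1) - half)) - 1, 0)
    cmax = min(int(np.ceil(max(x0, x1) + half)) + 1, W - 1)
    rmin = max(int(np.floor(min(y0, y1) - half)) - 1, 0)
    rmax = min(int(np.ceil(max(y0, y1) + half)) + 1, H - 1)
    if cmin > cmax or rmin > rmax:
        return
    cc, rr = np.meshgrid(np.arange(cmin, cmax + 1), np.arange(rmin, rmax + 1))
    px = cc - x0
    py = rr - y0
    t = px * ux + py * uy
    n = px * (-uy) + py * ux
    # half-open across the stroke: with the segment direction canonical
    # (y increasing), a width-w vertical band at x covers columns [x-w/2, x+w/2)
    inside = (t >= -half) & (t < L + half) & (n > -half) & (n <= half)
    mask[rmin:rmax + 1, cmin:cmax + 1] |= inside


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    if a.shape != b.shape:
        raise InvalidInputError("mask shapes must match")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def match_and_score(preds_per_image: list, gts_per_image: list,
                    cfg: EvalConfig) -> dict:
    """Accumulate (TP, FP, FN) per threshold over an image set.

    Matching is one-to-one and maximizes total mask IoU; the same matching
    is used at every threshold.
    """
    counts = {t: [0, 0, 0] for t in cfg.thresholds}       # tau -> [TP, FP, FN]
    for preds, gts in zip(preds_per_image, gts_per_image):
        pmasks = [thicken_mask(p, cfg) for p in preds]
        gmasks = [thicken_mask(g, cfg) for g in gts]
        P, G = len(pmasks), len(gmasks)
        iou = np.zeros((P, G))
        for i in range(P):
            for j in range(G):
                iou[i, j] = mask_iou(pmasks[i], gmasks[j])
        if P and G:
            ri, cj = linear_sum_assignment(-iou)
        else:
            ri = cj = np.array([], dtype=int)
        matched_iou = iou[ri, cj] if len(ri) else np.array([])
        for t in cfg.thresholds:
            hit = matched_iou > t if cfg.strict_greater else matched_iou >= t
            tp = int(hit.sum())
            counts[t][0] += tp
            counts[t][1] += P - tp
            counts[t][2] += G - tp
    return counts


def evaluate_dataset(preds_per_image: list, gts_per_image: list,
                     cfg: EvalConfig) -> EvalResult:
    """Precision/recall/F1 at each threshold and mF1 (0-100)."""
    if sum(len(g) for g in gts_per_image) == 0:
        raise InvalidEvaluationError("no ground-truth rows in the dataset")
    counts = match_and_score(preds_per_image, gts_per_image, cfg)
    rows = []
    for t in cfg.thresholds:
        tp, fp, fn = counts[t]
        prec = tp / (tp + fp) if (tp + fp) else 0.0
        rec = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        rows.append((float(t), prec, rec, f1))
    mf1 = 100.0 * float(np.mean([r[3] for r in rows]))
    return EvalResult(per_threshold=rows, mf1=mf1)


def write_results(result: EvalResult, csv_path, json_path):
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["threshold", "precision", "recall", "f1"])
        for t, p, r, f1 in result.per_threshold:
            w.writerow([f"{t:.2f}", f"{p:.6f}", f"{r:.6f}", f"{f1:.6f}"])
    with open(json_path, "w") as fh:
        json.dump({"mf1": result.mf1,
                   "per_threshold": [
                       {"threshold": t, "precision": p, "recall": r, "f1": f1}
                       for t, p, r, f1 in result.per_threshold]}, fh, indent=2)
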