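"""The anchor-line row detector: backbone, feature pyramid, cascade heads.

An 18-layer residual backbone (width-scalable) feeds a top-down feature
pyramid.  A fixed-cardinality set of *learnable* anchor lines is refined over
three cascade stages: stage 1 pools features along the prior anchors ``p0``
from the deepest map, predicts parameter deltas giving ``p1``; stage 2 pools
along ``p1`` from the mid-level fused map giving ``p2``; stage 3 pools along
``p2`` from the finest fused map and regresses the final scores, anchor
parameters and per-row horizontal offsets.

Anchor parameters are stored in normalized units — ``(x/W, y/H, theta/pi,
length/N)`` — so that a single optimizer step size is commensurate across
components; they are converted to pixels only when realizing geometry.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .attention import AttentionROIAlign, DAEConfig
from .geometry import (AnchorLine, InvalidInputError, RowPrediction, SampledRow,
                       anchor_to_points, sample_y_positions)
from .losses import RIoUConfig, row_iou
from .nn import functional as F
from .nn.layers import (Conv1dSeq, Conv2d, GroupNorm2d, Linear, Module,
                        Parameter, Sequential, ReLU)
from .nn.tensor import Tensor

__all__ = ["ModelConfig", "FeaturePyramid", "AnchorSet", "StageOutput",
           "CascadeResult", "RowDetector", "init_anchor_priors", "row_nms",
           "LinePool", "tiny_config", "full_config"]

_THETA_LO, _THETA_HI = 0.02, 0.98     # clamp for theta/pi at decode time

# per-stage bounds on normalized anchor parameters (x/W, y/H, theta/pi, len/N);
# the abscissa model x + (y - y_i)/tan(theta) is invariant to sliding the
# start point along the line, so without bounds the start can drift far
# outside the frame while the regression loss stays flat
_PARAM_LO = np.array([-0.5, 0.0, _THETA_LO, 0.0], dtype=np.float32)
_PARAM_HI = np.array([1.5, 1.0, _THETA_HI, 1.0], dtype=np.float32)


@dataclass
class ModelConfig:
    input_width: int = 800
    input_height: int = 320
    num_anchors: int = 64
    n_points: int = 40
    width_mult: float = 1.0
    fpn_channels: int = 64
    head_hidden: int = 128
    attention_mode: str = "dae"        # dae | full | off
    attention_qk: int = 32
    fpn_enabled: bool = True
    head_pointwise: bool = True        # per-point conv offset branch
    offsets_scale: float | None = None # px per unit head output; default W/8
    seed: int = 0

    def __post_init__(self):
        if self.offsets_scale is None:
            self.offsets_scale = self.input_width / 8.0


def tiny_config(**over) -> ModelConfig:
    """Reduced profile for CPU-scale experiments."""
    base = dict(input_width=320, input_height=160, num_anchors=64, n_points=36,
                width_mult=0.125, fpn_channels=32, head_hidden=64,
                attention_qk=16)
    base.update(over)
    return ModelConfig(**base)


def full_config(**over) -> ModelConfig:
    return ModelConfig(**over)


@dataclass
class FeaturePyramid:
    """Backbone maps (channels, height, width, stride) plus fused maps."""
    levels: list          # [(Tensor, stride), ...] backbone C1..C3
    fused: list           # [(Tensor, stride), ...] one per cascade stage


@dataclass
class AnchorSet:
    anchors: list         # list[AnchorLine], pixel units at network scale
    stage: int


@dataclass
class StageOutput:
    scores: np.ndarray            # (B, A) probabilities
    deltas: np.ndarray            # (B, A, 4) normalized-unit refinements
    offsets: np.ndarray           # (B, A, N) px
    extent: np.ndarray = None     # (B, A, N) per-point on-row logits (pointwise head)
    scores_t: Tensor = None
    logits_t: Tensor = None
    params_t: Tensor = None       # (B, A, 4) normalized anchor params after refinement
    offsets_t: Tensor = None
    extent_t: Tensor = None


@dataclass
class CascadeResult:
    stages: list                  # [StageOutput] * 3
    anchor_sets: list             # [AnchorSet p0, p1, p2] (first image of batch)
    pyramid: FeaturePyramid = None


# ----------------------------------------------------------------- backbone

class BasicBlock(Module):
    def __init__(self, cin, cout, stride, rng):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, rng=rng, bias=False)
        self.bn1 = GroupNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng=rng, bias=False)
        self.bn2 = GroupNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down = Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng, bias=False)
            self.down_bn = GroupNorm2d(cout)
        else:
            self.down = None

    def forward(self, x):
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        skip = self.down_bn(self.down(x)) if self.down is not None else x
        return (y + skip).relu()


class ResNet18(Module):
    """Standard 18-layer residual backbone with a width multiplier."""

    def __init__(self, width_mult=1.0, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = max(4, int(round(64 * width_mult)))
        self.widths = [w, 2 * w, 4 * w, 8 * w]
        self.stem = Conv2d(3, w, 7, stride=2, pad=3, rng=rng, bias=False)
        self.stem_bn = GroupNorm2d(w)

        def layer(cin, cout, stride):
            return Sequential(BasicBlock(cin, cout, stride, rng),
                              BasicBlock(cout, cout, 1, rng))
        self.layer1 = layer(w, w, 1)
        self.layer2 = layer(w, 2 * w, 2)
        self.layer3 = layer(2 * w, 4 * w, 2)
        self.layer4 = layer(4 * w, 8 * w, 2)

    def forward(self, x):
        x = self.stem_bn(self.stem(x)).relu()
        x = F.maxpool2x2(x)
        x = self.layer1(x)
        c1 = self.layer2(x)       # stride 8
        c2 = self.layer3(c1)      # stride 16
        c3 = self.layer4(c2)      # stride 32
        return c1, c2, c3


class FPN(Module):
    """Top-down fusion producing one map per cascade stage (strides 32/16/8).

    With fusion disabled the three maps are all derived from the deepest
    backbone level only, keeping the stage interface unchanged.
    """

    def __init__(self, in_channels, out_c, enabled=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.enabled = enabled
        c1, c2, c3 = in_channels
        self.lat3 = Conv2d(c3, out_c, 1, pad=0, rng=rng)
        self.lat2 = Conv2d(c2, out_c, 1, pad=0, rng=rng)
        self.lat1 = Conv2d(c1, out_c, 1, pad=0, rng=rng)
        self.smooth3 = Conv2d(out_c, out_c, 3, rng=rng)
        self.smooth2 = Conv2d(out_c, out_c, 3, rng=rng)
        self.smooth1 = Conv2d(out_c, out_c, 3, rng=rng)

    def forward(self, c1, c2, c3):
        p3 = self.lat3(c3)
        m32 = self.smooth3(p3)
        if self.enabled:
            p2 = self.lat2(c2) + F.upsample_nearest(p3, 2)
            m16 = self.smooth2(p2)
            p1 = self.lat1(c1) + F.upsample_nearest(p2, 2)
            m8 = self.smooth1(p1)
        else:
            m16 = self.smooth2(F.upsample_nearest(p3, 2))
            m8 = self.smooth1(F.upsample_nearest(F.upsample_nearest(p3, 2), 2))
        return m32, m16, m8


class LinePool(Module):
    """Bilinear sampling along anchor lines followed by a kernel-3 convolution
    applied sequentially along each line."""

    def __init__(self, channels, rng=None):
        super().__init__()
        self.conv = Conv1dSeq(channels, channels, 3, rng=rng)

    def forward(self, fmap: Tensor, points: np.ndarray, n_per_line: int) -> Tensor:
        B = fmap.shape[0]
        C = fmap.shape[1]
        sampled = F.bilinear_sample(fmap, points)                 # (B, A*N, C)
        A = points.shape[1] // n_per_line
        seq = sampled.reshape(B * A, n_per_line, C).transpose(0, 2, 1)
        out = self.conv(seq).relu()                               # (B*A, C, N)
        return out.transpose(0, 2, 1).reshape(B, A * n_per_line, C)

    def sample_only(self, fmap, points):
        return F.bilinear_sample(fmap, points)


class PredHead(Module):
    """Per-anchor head: shared FC trunk with score and delta branches, and a
    per-point convolutional offset branch along the line.

    Offsets are a local quantity (the lateral displacement of the row under
    each sampling point), so they are predicted point-wise by a small
    convolution over the pooled line sequence rather than from the flattened
    trunk.  Delta and offset branches are zero-initialized so that,
    untrained, each stage is the identity refinement; the score bias starts
    low as usual for focal-loss classifiers.
    """

    def __init__(self, channels, hidden, n_points, rng, pointwise=True):
        super().__init__()
        self.pointwise = pointwise
        in_dim = channels * n_points
        self.fc1 = Linear(in_dim, hidden, rng=rng)
        self.fc2 = Linear(hidden, hidden, rng=rng)
        self.score = Linear(hidden, 1, rng=rng)
        self.score.bias.data[...] = -2.0
        self.delta = Linear(hidden, 4, rng=rng, zero_init=True)
        if pointwise:
            mid = max(8, channels // 2)
            self.off1 = Conv1dSeq(channels, mid, 3, rng=rng)
            self.off2 = Conv1dSeq(mid, 1, 3, rng=rng)
            self.off2.weight.data[...] = 0.0
            self.off2.bias.data[...] = 0.0
            # per-point on-row validity logits; bias starts positive so an
            # untrained head marks the whole line valid
            self.ext = Conv1dSeq(mid, 1, 3, rng=rng)
            self.ext.weight.data[...] = 0.0
            self.ext.bias.data[...] = 1.0
        else:
            self.offset = Linear(hidden, n_points, rng=rng, zero_init=True)

    def forward(self, x, seq):
        """x: (B*A, N*C) flattened; seq: (B*A, C, N) line sequence.

        Returns (score logit, deltas, offsets, extent logits or None)."""
        h = self.fc2(self.fc1(x).relu()).relu()
        if self.pointwise:
            mid = self.off1(seq).relu()
            off = self.off2(mid)
            off = off.reshape(off.shape[0], off.shape[-1])
            ext = self.ext(mid)
            ext = ext.reshape(ext.shape[0], ext.shape[-1])
        else:
            off = self.offset(h)
            ext = None
        return self.score(h), self.delta(h), off, ext


def _longest_true_run(mask: np.ndarray):
    """(first, last) indices of the longest contiguous True run, or None."""
    best, cur_start, cur_len, best_len = None, None, 0, 0
    for i, v in enumerate(mask):
        if v:
            if cur_start is None:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_len = cur_len
                best = (cur_start, i)
        else:
            cur_start, cur_len = None, 0
    return best if best_len >= 2 else None


# ------------------------------------------------------------------ anchors

def init_anchor_priors(num_anchors: int, n_points: int, seed: int,
                       width: float = 800.0, height: float = 320.0) -> AnchorSet:
    """Deterministic anchor-line priors.

    Start points are spread uniformly along the bottom border (75%) and the
    lower halves of the side borders; each bottom position carries a small
    fan of angles so position-angle space is tiled systematically, with a
    seeded jitter.  All angles lie inside (15 deg, 165 deg); rows seen from a
    pitched camera are near-vertical in the image, so the bottom fan spans
    55-125 deg while side anchors lean toward the frame interior.  Initial
    length spans all sample rows.
    """
    if num_anchors < 1:
        raise InvalidInputError("num_anchors must be >= 1")
    rng = np.random.default_rng(seed)
    n_bottom = max(1, int(round(0.75 * num_anchors)))
    n_side = num_anchors - n_bottom
    n_left = n_side // 2
    n_right = n_side - n_left

    n_fan = min(4, n_bottom)
    fan = np.deg2rad(np.linspace(55.0, 125.0, n_fan))
    n_pos = int(np.ceil(n_bottom / n_fan))
    pos = (np.arange(n_pos) + 0.5) / n_pos * width
    bx = np.repeat(pos, n_fan)[:n_bottom]
    bt = np.tile(fan, n_pos)[:n_bottom]
    bt = bt + rng.uniform(-np.deg2rad(4), np.deg2rad(4), size=n_bottom)

    xs = np.concatenate([bx, np.zeros(n_left), np.full(n_right, width)])
    ys = np.concatenate([
        np.full(n_bottom, height),
        height * (0.5 + 0.5 * (np.arange(n_left) + 0.5) / max(n_left, 1)),
        height * (0.5 + 0.5 * (np.arange(n_right) + 0.5) / max(n_right, 1)),
    ])
    lt = rng.uniform(np.deg2rad(35.0), np.deg2rad(80.0), size=n_left)
    rt = rng.uniform(np.deg2rad(100.0), np.deg2rad(145.0), size=n_right)
    angles = np.clip(np.concatenate([bt, lt, rt]),
                     np.deg2rad(15.5), np.deg2rad(164.5))
    anchors = [AnchorLine(start_x=float(x), start_y=float(y), theta=float(t),
                          length=float(n_points))
               for x, y, t in zip(xs, ys, angles)]
    return AnchorSet(anchors=anchors, stage=0)


def _anchors_to_normalized(aset: AnchorSet, W, H, N) -> np.ndarray:
    arr = np.array([[a.start_x / W, a.start_y / H, a.theta / np.pi, a.length / N]
                    for a in aset.anchors], dtype=np.float32)
    return arr


def _normalized_to_anchor(row: np.ndarray, W, H, N) -> AnchorLine:
    xn, yn, tn, ln = (float(v) for v in row)
    return AnchorLine(start_x=xn * W, start_y=float(np.clip(yn, 0.0, 1.0)) * H,
                      theta=float(np.clip(tn, _THETA_LO, _THETA_HI)) * np.pi,
                      length=float(np.clip(ln, 0.0, 1.0)) * N)


# ----------------------------------------------------------------- detector

class RowDetector(Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.backbone = ResNet18(cfg.width_mult, rng=rng)
        self.fpn = FPN(self.backbone.widths[1:], cfg.fpn_channels,
                       enabled=cfg.fpn_enabled, rng=rng)
        C = cfg.fpn_channels
        self.pools = [LinePool(C, rng=rng) for _ in range(3)]
        if cfg.attention_mode != "off":
            acfg = DAEConfig(in_channels=C, qk_channels=cfg.attention_qk, v_channels=C)
            self.attns = [AttentionROIAlign(acfg, rng=rng, mode=cfg.attention_mode)
                          for _ in range(3)]
        else:
            self.attns = []
        self.heads = [PredHead(C, cfg.head_hidden, cfg.n_points, rng,
                               pointwise=cfg.head_pointwise)
                      for _ in range(3)]
        prior = init_anchor_priors(cfg.num_anchors, cfg.n_points, cfg.seed,
                                   width=cfg.input_width, height=cfg.input_height)
        self.anchor_params = Parameter(_anchors_to_normalized(
            prior, cfg.input_width, cfg.input_height, cfg.n_points))
        self._ys = sample_y_positions(cfg.n_points, cfg.input_height)

    # ------------------------------------------------------------- geometry
    def _line_points(self, params: np.ndarray, stride: float) -> np.ndarray:
        """Feature-map sampling positions for (B, A, 4) normalized anchors."""
        cfg = self.cfg
        x = params[..., 0] * cfg.input_width
        y = params[..., 1] * cfg.input_height
        t = np.clip(params[..., 2], _THETA_LO, _THETA_HI) * np.pi
        ys = self._ys
        xr = x[..., None] + (y[..., None] - ys) / np.tan(t)[..., None]   # (B,A,N)
        B, A, N = xr.shape
        pts = np.empty((B, A * N, 2), dtype=np.float32)
        pts[..., 0] = (xr / stride).reshape(B, A * N)
        pts[..., 1] = np.broadcast_to(ys / stride, (B, A, N)).reshape(B, A * N)
        return pts

    # -------------------------------------------------------------- forward
    def forward(self, images: Tensor | np.ndarray) -> CascadeResult:
        cfg = self.cfg
        F.clear_geometry_cache()
        x = images if isinstance(images, Tensor) else Tensor(np.asarray(images, dtype=np.float32))
        B = x.shape[0]
        c1, c2, c3 = self.backbone(x)
        maps = self.fpn(c1, c2, c3)
        strides = (32, 16, 8)
        A, N = cfg.num_anchors, cfg.n_points

        ones = Tensor(np.ones((B, 1, 1), dtype=np.float32))
        cur = self.anchor_params.reshape(1, A, 4) * ones       # (B,A,4) with grad
        stages = []
        anchor_sets = [self._anchor_set(cur.data[0], 0)]
        for k in range(3):
            fmap, stride = maps[k], strides[k]
            pts = self._line_points(cur.data, stride)
            feats = self.pools[k](fmap, pts, N)
            if self.attns:
                feats = feats + self.attns[k](fmap, pts)
            C = fmap.shape[1]
            h = feats.reshape(B * A, N * C)
            seq = feats.reshape(B * A, N, C).transpose(0, 2, 1)
            logit, delta, off, ext = self.heads[k](h, seq)
            logits = logit.reshape(B, A)
            scores = logits.sigmoid()
            delta = delta.reshape(B, A, 4)
            offsets = off.reshape(B, A, N) * cfg.offsets_scale
            ext = ext.reshape(B, A, N) if ext is not None else None
            cur = (cur + delta).clip_st(_PARAM_LO, _PARAM_HI)
            stages.append(StageOutput(
                scores=scores.data, deltas=delta.data, offsets=offsets.data,
                extent=None if ext is None else ext.data,
                scores_t=scores, logits_t=logits, params_t=cur,
                offsets_t=offsets, extent_t=ext))
            if k < 2:
                anchor_sets.append(self._anchor_set(cur.data[0], k + 1))
        pyramid = FeaturePyramid(
            levels=[(c1, 8), (c2, 16), (c3, 32)],
            fused=[(maps[0], 32), (maps[1], 16), (maps[2], 8)])
        return CascadeResult(stages=stages, anchor_sets=anchor_sets,
                             pyramid=pyramid)

    def _anchor_set(self, params: np.ndarray, stage: int) -> AnchorSet:
        cfg = self.cfg
        anchors = [_normalized_to_anchor(p, cfg.input_width, cfg.input_height,
                                         cfg.n_points) for p in params]
        return AnchorSet(anchors=anchors, stage=stage)

    # --------------------------------------------------------------- decode
    def decode(self, result: CascadeResult, image_index: int = 0) -> list[RowPrediction]:
        """Raw (pre-NMS) predictions for one image from the final stage.

        When the head provides per-point extent logits, the anchor's start
        row and length are taken from the longest above-threshold run of the
        extent, which localizes clipped rows far better than the regressed
        scalar length."""
        cfg = self.cfg
        last = result.stages[-1]
        ys = self._ys
        preds = []
        for a in range(cfg.num_anchors):
            anchor = _normalized_to_anchor(last.params_t.data[image_index, a],
                                           cfg.input_width, cfg.input_height, cfg.n_points)
            if last.extent is not None:
                run = _longest_true_run(last.extent[image_index, a] > 0.0)
                if run is not None:
                    i0, i1 = run
                    anchor = AnchorLine(start_x=anchor.start_x,
                                        start_y=float(ys[i1]),
                                        theta=anchor.theta,
                                        length=float(i1 - i0 + 1))
            preds.append(RowPrediction(
                score=float(np.clip(last.scores[image_index, a], 0.0, 1.0)),
                anchor=anchor,
                offsets=last.offsets[image_index, a].astype(np.float64)))
        return preds

    def predict(self, images, score_threshold=0.4, nms_iou=0.5,
                riou_cfg: RIoUConfig | None = None) -> list[list[RowPrediction]]:
        """Inference: forward, decode and suppress, per image."""
        was_training = self.training
        self.eval()
        result = self.forward(images)
        out = []
        B = result.stages[-1].scores.shape[0]
        for b in range(B):
            preds = self.decode(result, b)
            out.append(row_nms(preds, nms_iou, score_threshold,
                               riou_cfg or RIoUConfig(),
                               n_points=self.cfg.n_points,
                               height=self.cfg.input_height))
        if was_training:
            self.train()
        return out


def row_nms(preds: list[RowPrediction], iou_threshold: float,
            score_threshold: float, cfg: RIoUConfig,
            n_points: int, height: float) -> list[RowPrediction]:
    """Greedy line NMS using row-level IoU of realized rows."""
    cand = [p for p in preds if p.score >= score_threshold]
    cand.sort(key=lambda p: -p.score)
    rows = [p.to_sampled(n_points, height) for p in cand]
    kept: list[int] = []
    for i in range(len(cand)):
        ok = True
        for j in kept:
            ref = rows[j]
            if not ref.valid.any():
                continue
            if row_iou(rows[i], ref, cfg) > iou_threshold:
                ok = False
                break
        if ok:
            kept.append(i)
    return [cand[i] for i in kept]
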