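"""Canonical crop-row geometry.

A crop row is annotated as a *polyline* (ordered image points with strictly
increasing ``y``).  For regression and loss computation a row is discretized
into a :class:`SampledRow`: horizontal positions ``xs[i]`` at ``N`` uniformly
spaced vertical positions ``y_i = H/(N-1) * i``.  Predictions are expressed
relative to an :class:`AnchorLine` — a straight line prior parameterized by
its bottom end point, its angle to the positive x axis, and a (real-valued)
row length counted in sample rows — plus per-row horizontal offsets.

Coordinates are image pixels: origin top-left, x rightward, y downward,
continuous sub-pixel values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RowPolyline", "SampledRow", "AnchorLine", "RowPrediction",
    "sample_row", "anchor_to_points", "rescale_row",
    "polyline_from_sampled", "anchor_from_sampled", "sample_y_positions",
    "InvalidInputError",
]

_EPS_Y = 1e-6


class InvalidInputError(ValueError):
    """Raised when geometric input violates a precondition."""


@dataclass
class RowPolyline:
    """Annotated centerline of one crop row."""

    points: np.ndarray          # (M, 2) float array of (x, y)
    image_width: float
    image_height: float
    label: str = "row"

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise InvalidInputError("polyline needs at least 2 (x, y) points")
        if not np.all(np.diff(pts[:, 1]) > 0):
            raise InvalidInputError("polyline y coordinates must be strictly increasing")
        if (pts[:, 0].min() < 0 or pts[:, 0].max() > self.image_width
                or pts[:, 1].min() < 0 or pts[:, 1].max() > self.image_height):
            raise InvalidInputError("polyline points out of image bounds")
        self.points = pts

    @property
    def y_span(self) -> tuple[float, float]:
        return float(self.points[0, 1]), float(self.points[-1, 1])


@dataclass
class SampledRow:
    """A row discretized at N uniform vertical positions spanning [0, H]."""

    xs: np.ndarray              # (N,) horizontal positions, px
    valid: np.ndarray           # (N,) bool
    n_points: int
    height: float

    def __post_init__(self):
        self.xs = np.asarray(self.xs, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.xs) == len(self.valid) == self.n_points):
            raise InvalidInputError("xs/valid length must equal n_points")
        if self.valid.any() and not np.all(np.isfinite(self.xs[self.valid])):
            raise InvalidInputError("xs must be finite where valid")

    @property
    def ys(self) -> np.ndarray:
        return sample_y_positions(self.n_points, self.height)


@dataclass
class AnchorLine:
    """Straight line prior: bottom end point, direction angle, row length.

    ``theta`` is the angle between the row direction (pointing up the image)
    and the positive x axis, strictly inside (0, pi) so the line is never
    parallel to a sampling row.  ``length`` counts valid sample rows and is
    real-valued during regression.
    """

    start_x: float
    start_y: float
    theta: float
    length: float

    def __post_init__(self):
        if not (0.0 < self.theta < np.pi):
            raise InvalidInputError(f"theta must be in (0, pi), got {self.theta}")
        if self.length < 0:
            raise InvalidInputError("length must be nonnegative")


@dataclass
class RowPrediction:
    """Scored row hypothesis: anchor parameters plus per-row offsets."""

    score: float
    anchor: AnchorLine
    offsets: np.ndarray         # (N,) horizontal displacement from the anchor line

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise InvalidInputError("score must be in [0, 1]")
        self.offsets = np.asarray(self.offsets, dtype=np.float64)
        if not np.all(np.isfinite(self.offsets)):
            raise InvalidInputError("offsets must be finite")

    def to_sampled(self, n_points: int, height: float) -> SampledRow:
        return anchor_to_points(self.anchor, self.offsets, n_points, height)


def sample_y_positions(n_points: int, height: float) -> np.ndarray:
    """The uniform sampling rows y_i = H/(N-1) * i, i = 0..N-1."""
    return height / (n_points - 1) * np.arange(n_points, dtype=np.float64)


def sample_row(polyline: RowPolyline, n_points: int, height: float) -> SampledRow:
    """Discretize a polyline at the uniform sampling rows by linear interpolation.

    Sampling positions outside the polyline's y-span are marked invalid.  The
    bottom position ``y = height`` is clamped to ``height - eps`` for raster
    safety.
    """
    if n_points < 2:
        raise InvalidInputError("n_points must be >= 2")
    if height <= 0:
        raise InvalidInputError("height must be positive")
    pts = polyline.points
    if pts[-1, 1] - pts[0, 1] <= 0:
        raise InvalidInputError("degenerate polyline: no vertical extent")
    ys = sample_y_positions(n_points, height)
    ys_eval = np.minimum(ys, height - _EPS_Y)
    lo, hi = polyline.y_span
    valid = (ys_eval >= lo) & (ys_eval <= hi)
    xs = np.interp(ys_eval, pts[:, 1], pts[:, 0])
    xs[~valid] = np.nan
    return SampledRow(xs=xs, valid=valid, n_points=n_points, height=height)


def anchor_to_points(anchor: AnchorLine, offsets: np.ndarray,
                     n_points: int, height: float) -> SampledRow:
    """Realize an anchor line plus per-row offsets as a SampledRow.

    The straight reference abscissa at sampling row i is
    ``x_ref(i) = start_x + (start_y - y_i) / tan(theta)``; ``xs[i]`` adds the
    i-th offset.  Exactly ``ceil(length)`` rows are valid, counted upward
    (toward smaller y) from the sampling row nearest below-or-at ``start_y``.
    """
    if not (0.0 < anchor.theta < np.pi):
        raise InvalidInputError("invalid anchor angle")
    offsets = np.asarray(offsets, dtype=np.float64)
    if len(offsets) != n_points:
        raise InvalidInputError("offsets length must equal n_points")
    ys = sample_y_positions(n_points, height)
    xs = anchor.start_x + (anchor.start_y - ys) / np.tan(anchor.theta) + offsets
    below = np.nonzero(ys <= anchor.start_y + _EPS_Y)[0]
    k = int(np.ceil(anchor.length - 1e-9))
    k = max(0, min(k, len(below)))
    valid = np.zeros(n_points, dtype=bool)
    if k > 0:
        valid[below[-k:]] = True
    return SampledRow(xs=xs, valid=valid, n_points=n_points, height=height)


def rescale_row(row: SampledRow, from_w: float, from_h: float,
                to_w: float, to_h: float) -> SampledRow:
    """Rescale a sampled row between resolutions; exactly invertible."""
    if min(from_w, from_h, to_w, to_h) <= 0:
        raise InvalidInputError("dimensions must be positive")
    return SampledRow(xs=row.xs * (to_w / from_w), valid=row.valid.copy(),
                      n_points=row.n_points, height=to_h)


def polyline_from_sampled(row: SampledRow, image_width: float,
                          label: str = "row") -> RowPolyline:
    """The polyline through a sampled row's valid in-frame points.

    Samples whose abscissa falls outside the image are trimmed (annotation
    polylines are clipped at the frame the same way); clamping them to the
    border would fabricate a segment hugging the image edge.
    """
    keep = row.valid & (row.xs >= 0.0) & (row.xs <= image_width)
    ys = row.ys[keep]
    xs = row.xs[keep]
    if len(xs) < 2:
        raise InvalidInputError("need >= 2 valid in-frame samples for a polyline")
    return RowPolyline(points=np.column_stack([xs, np.clip(ys, 0, row.height)]),
                       image_width=image_width, image_height=row.height, label=label)


def anchor_from_sampled(row: SampledRow) -> AnchorLine:
    """Fit a ground-truth anchor: start at the lowest valid sample, angle from
    the bottom-to-top valid direction, length = number of valid rows."""
    idx = np.nonzero(row.valid)[0]
    if len(idx) < 2:
        raise InvalidInputError("need >= 2 valid samples to fit an anchor")
    ys = row.ys
    bx, by = row.xs[idx[-1]], ys[idx[-1]]
    tx, ty = row.xs[idx[0]], ys[idx[0]]
    theta = float(np.arctan2(by - ty, tx - bx))
    theta = float(np.clip(theta, 1e-3, np.pi - 1e-3))
    return AnchorLine(start_x=float(bx), start_y=float(by), theta=theta,
                      length=float(len(idx)))
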