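"""Synthetic maize-field scenes with exact row ground truth.

World-parallel row centerlines on a flat ground plane are projected through
a pinhole camera pitched down toward the ground (emulating 30/45/60-degree
rig angles), so rows converge toward a vanishing point exactly as in
field imagery.  Green plant blobs (clusters of elongated leaf ellipses) are
placed along each row with jitter and random gaps; weeds are isotropic blobs
scattered uniformly; the soil is textured noise.  Illumination gain, blur
and a lateral "lodging" displacement of the plants perturb the rendering but
never the returned ground-truth polylines, which are the exact projected
centerlines.

Annotations are read and written in the LabelMe JSON dialect with
``shape_type == "linestrip"`` and one label per row instance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .geometry import InvalidInputError, RowPolyline

__all__ = ["SceneConfig", "InvalidConfigError", "generate_scene",
           "generate_dataset", "read_labelme", "write_labelme", "project_rows"]

log = logging.getLogger(__name__)


class InvalidConfigError(ValueError):
    """Raised when a scene configuration cannot produce a usable scene."""


@dataclass
class SceneConfig:
    image_width: int = 1280
    image_height: int = 720
    n_rows: int = 5
    row_spacing_world: float = 0.6          # meters between adjacent rows
    camera_pitch_deg: float = 45.0          # optical axis vs horizontal
    camera_height: float = 1.6              # meters above ground
    plant_spacing: float = 0.25             # meters along a row
    plant_radius: tuple = (6.0, 11.0)       # px at the reference depth
    weed_density: float = 0.3               # blobs per kilopixel
    gap_probability: float = 0.10           # chance a plant is missing
    illumination_gain: tuple = (0.6, 1.4)   # multiplicative range
    blur_sigma: float = 0.6                 # px
    lodging_shear: float = 2.0              # px lateral plant displacement scale
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 1:
            raise InvalidInputError("n_rows must be >= 1")
        if not (0.0 <= self.gap_probability <= 1.0):
            raise InvalidInputError("gap_probability must be in [0, 1]")


def _camera(cfg: SceneConfig):
    W, H = cfg.image_width, cfg.image_height
    f = 0.9 * W
    return f, W / 2.0, H / 2.0


def _project(X, Z, cfg: SceneConfig):
    """Project ground points (lateral X, depth Z) to image (u, v)."""
    phi = np.deg2rad(cfg.camera_pitch_deg)
    h = cfg.camera_height
    f, cx, cy = _camera(cfg)
    zc = np.sin(phi) * h + np.cos(phi) * Z
    yc = np.cos(phi) * h - np.sin(phi) * Z
    u = cx + f * X / zc
    v = cy + f * yc / zc
    return u, v, zc


def project_rows(cfg: SceneConfig, rng: np.random.Generator):
    """Image-space centerlines of the world rows, clipped to the frame.

    Returns a list of (polyline_points, row_world_x) for visible rows.
    """
    W, H = cfg.image_width, cfg.image_height
    phi = np.deg2rad(cfg.camera_pitch_deg)
    z0 = cfg.camera_height / np.tan(phi)          # depth of the image center ray
    offset = rng.uniform(-0.5, 0.5) * cfg.row_spacing_world
    zs = np.geomspace(0.05 * z0, 40 * z0, 400)
    rows = []
    for k in range(cfg.n_rows):
        X = (k - (cfg.n_rows - 1) / 2.0) * cfg.row_spacing_world + offset
        u, v, _ = _project(np.full_like(zs, X), zs, cfg)
        inside = (u >= 0) & (u <= W) & (v >= 0) & (v <= H)
        if inside.sum() < 2:
            continue
        ui, vi = u[inside], v[inside]
        order = np.argsort(vi)
        ui, vi = ui[order], vi[order]
        # decimate to ~10 vertices at uniform v, keeping y strictly increasing
        v_grid = np.linspace(vi[0], vi[-1], 10)
        x_grid = np.interp(v_grid, vi, ui)
        keep = np.concatenate([[True], np.diff(v_grid) > 1e-6])
        pts = np.column_stack([np.clip(x_grid[keep], 0, W), v_grid[keep]])
        if len(pts) >= 2:
            rows.append((pts, X))
    return rows


def _draw_ellipse(img, cx0, cy0, a, b, alpha, color):
    H, W, _ = img.shape
    r0 = max(int(cy0 - max(a, b)) - 1, 0)
    r1 = min(int(cy0 + max(a, b)) + 2, H)
    c0 = max(int(cx0 - max(a, b)) - 1, 0)
    c1 = min(int(cx0 + max(a, b)) + 2, W)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx = xx - cx0
    dy = yy - cy0
    ca, sa = np.cos(alpha), np.sin(alpha)
    m = ((dx * ca + dy * sa) / a) ** 2 + ((-dx * sa + dy * ca) / b) ** 2 <= 1.0
    img[r0:r1, c0:c1][m] = color


def generate_scene(cfg: SceneConfig):
    """Render one scene; returns (H x W x 3 uint8 image, list of RowPolyline)."""
    rng = np.random.default_rng(cfg.seed)
    W, H = cfg.image_width, cfg.image_height
    rows = project_rows(cfg, rng)
    if not rows:
        raise InvalidConfigError("configuration yields zero visible rows")

    # soil: brown base with low-frequency blotches and per-pixel grain
    img = np.empty((H, W, 3), dtype=np.float64)
    base = np.array([115.0, 88.0, 62.0])
    blotch = gaussian_filter(rng.standard_normal((H, W)), sigma=max(4, W // 60)) * 30
    grain = rng.standard_normal((H, W)) * 8
    for c in range(3):
        img[:, :, c] = base[c] + blotch + grain

    phi = np.deg2rad(cfg.camera_pitch_deg)
    z0 = cfg.camera_height / np.tan(phi)
    rad_lo, rad_hi = cfg.plant_radius

    # plants clustered along the rows: elongated leaf ellipses
    for pts, X in rows:
        zs = np.arange(0.05 * z0, 40 * z0, cfg.plant_spacing)
        u, v, zc = _project(np.full_like(zs, X), zs, cfg)
        inside = (u >= -10) & (u <= W + 10) & (v >= -10) & (v <= H + 10)
        for uu, vv, zz in zip(u[inside], v[inside], zc[inside]):
            if rng.uniform() < cfg.gap_probability:
                continue
            scale = np.clip(z0 / zz, 0.15, 2.5)
            r = rng.uniform(rad_lo, rad_hi) * scale
            shear = rng.normal(0.0, cfg.lodging_shear)
            jx = rng.normal(0.0, 0.12 * r)
            n_leaves = rng.integers(3, 6)
            for _ in range(n_leaves):
                ang = rng.uniform(0, np.pi)
                green = np.array([40 + rng.uniform(-15, 15),
                                  135 + rng.uniform(-30, 30),
                                  45 + rng.uniform(-15, 15)])
                _draw_ellipse(img, uu + jx + shear + rng.normal(0, 0.3 * r),
                              vv + rng.normal(0, 0.3 * r),
                              a=r * rng.uniform(0.8, 1.4), b=r * rng.uniform(0.25, 0.45),
                              alpha=ang, color=green)

    # weeds: isotropic blobs, uniform over the frame
    n_weeds = int(round(cfg.weed_density * W * H / 1000.0))
    for _ in range(n_weeds):
        wx = rng.uniform(0, W)
        wy = rng.uniform(0, H)
        r = rng.uniform(0.3 * rad_lo, 0.8 * rad_hi)
        green = np.array([55 + rng.uniform(-15, 15),
                          120 + rng.uniform(-25, 25),
                          55 + rng.uniform(-15, 15)])
        _draw_ellipse(img, wx, wy, a=r * rng.uniform(0.8, 1.1),
                      b=r * rng.uniform(0.8, 1.1),
                      alpha=rng.uniform(0, np.pi), color=green)

    # photometric perturbations: never touch the ground truth
    gain = rng.uniform(*cfg.illumination_gain)
    img *= gain
    if cfg.blur_sigma > 0:
        img = gaussian_filter(img, sigma=(cfg.blur_sigma, cfg.blur_sigma, 0))
    img = np.clip(img, 0, 255).astype(np.uint8)

    polylines = [RowPolyline(points=pts, image_width=W, image_height=H,
                             label=f"row_{i}")
                 for i, (pts, _) in enumerate(rows)]
    return img, polylines


# ------------------------------------------------------------------ dataset

def derive_seed(master_seed: int, index: int) -> int:
    """Stable per-image seed from the master seed (below 2**31)."""
    digest = hashlib.sha256(f"{master_seed}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF


def generate_dataset(cfg: SceneConfig, n_images: int, split: str, out_dir):
    """Write PNG images + LabelMe JSON + a JSONL manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for i in range(n_images):
        seed_i = derive_seed(cfg.seed, i)
        scfg = SceneConfig(**{**cfg.__dict__, "seed": seed_i})
        img, rows = generate_scene(scfg)
        stem = f"{split}_{i:05d}"
        img_path = out / f"{stem}.png"
        ann_path = out / f"{stem}.json"
        Image.fromarray(img).save(img_path, format="PNG", optimize=False)
        write_labelme(rows, {"imagePath": img_path.name,
                             "imageHeight": cfg.image_height,
                             "imageWidth": cfg.image_width}, ann_path)
        records.append({"image": img_path.name, "annotation": ann_path.name,
                        "seed": seed_i})
    manifest = out / f"{split}_manifest.jsonl"
    with open(manifest, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")
    return manifest


# ------------------------------------------------------------------ labelme

def write_labelme(rows: list, image_meta: dict, path):
    """Serialize row polylines as LabelMe 'linestrip' shapes."""
    shapes = [{
        "label": r.label,
        "points": [[float(x), float(y)] for x, y in r.points],
        "group_id": None,
        "shape_type": "linestrip",
        "flags": {},
    } for r in rows]
    doc = {
        "version": "5.2.1",
        "flags": {},
        "shapes": shapes,
        "imagePath": image_meta.get("imagePath", ""),
        "imageData": None,
        "imageHeight": int(image_meta["imageHeight"]),
        "imageWidth": int(image_meta["imageWidth"]),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def read_labelme(path) -> list:
    """Parse a LabelMe JSON file into RowPolyline objects.

    Only ``linestrip`` shapes are kept (others are skipped with a warning);
    points whose y order is not ascending are re-sorted with a warning.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise InvalidInputError(f"malformed LabelMe JSON in {path}: {exc}") from exc
    for key in ("shapes", "imageHeight", "imageWidth"):
        if key not in doc:
            raise InvalidInputError(f"LabelMe file {path} missing required key {key!r}")
    W, H = doc["imageWidth"], doc["imageHeight"]
    rows = []
    for i, shape in enumerate(doc["shapes"]):
        for key in ("points", "shape_type"):
            if key not in shape:
                raise InvalidInputError(f"shape {i} in {path} missing key {key!r}")
        if shape["shape_type"] != "linestrip":
            log.warning("skipping non-linestrip shape %r in %s",
                        shape.get("label", i), path)
            continue
        pts = np.asarray(shape["points"], dtype=np.float64)
        if pts.ndim != 2 or pts.shape[0] < 2:
            raise InvalidInputError(f"shape {i} in {path}: need >= 2 points")
        if not np.all(np.diff(pts[:, 1]) > 0):
            log.warning("re-sorting points of shape %r in %s by ascending y",
                        shape.get("label", i), path)
            pts = pts[np.argsort(pts[:, 1], kind="stable")]
            keep = np.concatenate([[True], np.diff(pts[:, 1]) > 0])
            pts = pts[keep]
        pts[:, 0] = np.clip(pts[:, 0], 0, W)
        pts[:, 1] = np.clip(pts[:, 1], 0, H)
        rows.append(RowPolyline(points=pts, image_width=W, image_height=H,
                                label=shape.get("label", f"row_{i}")))
    return rows
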