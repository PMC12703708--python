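"""Training, inference and evaluation orchestration.

Everything is seeded: parameter init, data order, and augmentation all
derive from the run seed, so two CPU runs with the same configuration
produce identical loss curves.  Each run writes a resolved-config snapshot,
a JSON-lines metrics log, and the best-validation checkpoint.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
from PIL import Image

from .assign import AssignmentParams, GtRow, total_loss
from .config import save_config
from .evaluation import EvalConfig, evaluate_dataset, write_results
from .geometry import (InvalidInputError, RowPolyline, anchor_from_sampled,
                       polyline_from_sampled, rescale_row, sample_row)
from .losses import LossWeights, RIoUConfig
from .model import ModelConfig, RowDetector
from .nn.optim import AdamW, cosine_decay, poly_decay
from .synthetic import SceneConfig, generate_dataset, read_labelme, write_labelme

__all__ = ["prepare_synthetic", "load_split", "train", "infer",
           "evaluate_cmd", "ablate", "build_model"]

log = logging.getLogger(__name__)

_MEAN, _STD = 0.45, 0.225


def build_model(cfg: dict) -> RowDetector:
    m = cfg["model"]
    return RowDetector(ModelConfig(
        input_width=m["input_width"], input_height=m["input_height"],
        num_anchors=m["num_anchors"], n_points=m["n_points"],
        width_mult=m["width_mult"], fpn_channels=m["fpn_channels"],
        head_hidden=m["head_hidden"], attention_mode=m["attention_mode"],
        attention_qk=m["attention_qk"], fpn_enabled=m["fpn_enabled"],
        head_pointwise=m.get("head_pointwise", True), seed=m["seed"]))


def _loss_weights(cfg: dict) -> LossWeights:
    l = cfg["loss"]
    return LossWeights(w_cls=l["w_cls"], w_xytl=l["w_xytl"], w_riou=l["w_riou"],
                       focal_alpha=l["focal_alpha"], focal_gamma=l["focal_gamma"],
                       smooth_l1_beta=l["smooth_l1_beta"])


def _assign_params(cfg: dict) -> AssignmentParams:
    m = cfg["model"]
    diag = float(np.hypot(m["input_width"], m["input_height"]))
    a = cfg["assign"]
    return AssignmentParams(w_sim=a["w_sim"], w_cls=a["w_cls"],
                            topk_pool=a["topk_pool"],
                            norm_width=m["input_width"], norm_diag=diag)


def _riou_cfg(cfg: dict) -> RIoUConfig:
    return RIoUConfig(extension_e=cfg["riou"]["extension_e"], eps=cfg["riou"]["eps"])


def _eval_cfg(cfg: dict) -> EvalConfig:
    e = cfg["eval"]
    return EvalConfig(thickness=e["thickness"], eval_width=e["eval_width"],
                      eval_height=e["eval_height"],
                      strict_greater=e["strict_greater"])


def _scene_cfg(cfg: dict, seed_shift: int = 0) -> SceneConfig:
    s = cfg["synth"]
    return SceneConfig(
        image_width=s["image_width"], image_height=s["image_height"],
        n_rows=s["n_rows"], row_spacing_world=s["row_spacing_world"],
        camera_pitch_deg=s["camera_pitch_deg"], camera_height=s["camera_height"],
        plant_spacing=s["plant_spacing"], plant_radius=tuple(s["plant_radius"]),
        weed_density=s["weed_density"], gap_probability=s["gap_probability"],
        illumination_gain=tuple(s["illumination_gain"]),
        blur_sigma=s["blur_sigma"], lodging_shear=s["lodging_shear"],
        seed=int(s["seed"]) + seed_shift)


def prepare_synthetic(cfg: dict, out_dir) -> dict:
    """Generate train/val/test synthetic splits; returns manifest paths."""
    s = cfg["synth"]
    out = Path(out_dir)
    manifests = {}
    # disjoint master seeds per split so splits never share an image
    for shift, (split, n) in enumerate([("train", s["n_train"]),
                                        ("val", s["n_val"]),
                                        ("test", s["n_test"])]):
        scfg = _scene_cfg(cfg, seed_shift=1_000_003 * shift)
        manifests[split] = str(generate_dataset(scfg, n, split, out / split))
    return manifests


# --------------------------------------------------------------------- data

def load_split(manifest_path, cfg: dict) -> list[dict]:
    """Load a split into memory, preprocessed to network resolution."""
    m = cfg["model"]
    Wn, Hn, N = m["input_width"], m["input_height"], m["n_points"]
    base = Path(manifest_path).parent
    samples = []
    with open(manifest_path) as fh:
        for line in fh:
            rec = json.loads(line)
            img = Image.open(base / rec["image"]).convert("RGB")
            Wa, Ha = img.size
            if (Wa, Ha) != (Wn, Hn):
                net_img = img.resize((Wn, Hn), Image.BILINEAR)
            else:
                net_img = img
            arr = np.asarray(net_img, dtype=np.float32) / 255.0
            arr = (arr - _MEAN) / _STD
            polylines = read_labelme(base / rec["annotation"])
            gts = []
            for pl in polylines:
                scaled = RowPolyline(
                    points=np.column_stack([pl.points[:, 0] * Wn / Wa,
                                            pl.points[:, 1] * Hn / Ha]),
                    image_width=Wn, image_height=Hn, label=pl.label)
                row = sample_row(scaled, N, Hn)
                if row.valid.sum() >= 2:
                    gts.append(GtRow(row=row, anchor=anchor_from_sampled(row)))
            samples.append({"image": arr.transpose(2, 0, 1), "gts": gts,
                            "polylines": polylines, "ann_size": (Wa, Ha),
                            "stem": Path(rec["image"]).stem})
    return samples


def _flip_gt(gt: GtRow, width: float) -> GtRow:
    row = gt.row
    flipped = type(row)(xs=width - row.xs, valid=row.valid.copy(),
                        n_points=row.n_points, height=row.height)
    return GtRow(row=flipped, anchor=anchor_from_sampled(flipped))


def _batches(n, batch_size, rng):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


# -------------------------------------------------------------------- train

def train(cfg: dict, train_manifest, val_manifest, out_dir) -> dict:
    """Train a detector; returns {'checkpoint', 'history', 'best_mf1'}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out / "config.yaml")
    t = cfg["train"]
    model = build_model(cfg)
    # anchor priors define the (static) assignment geometry; keep them slow
    opt = AdamW(model.parameters(), lr=t["lr"], weight_decay=t["weight_decay"],
                lr_scales={id(model.anchor_params):
                           float(t.get("anchor_lr_scale", 0.1))})
    weights = _loss_weights(cfg)
    riou_cfg = _riou_cfg(cfg)
    ap = _assign_params(cfg)
    mcfg = cfg["model"]
    Wn, Hn, N = mcfg["input_width"], mcfg["input_height"], mcfg["n_points"]

    ema_decay = float(t.get("ema_decay", 0.0))
    ema = ({k: v.data.copy() for k, v in model.named_parameters()}
           if ema_decay > 0 else None)

    def _with_ema(fn):
        """Evaluate/save with EMA weights swapped in."""
        if ema is None:
            return fn()
        params = dict(model.named_parameters())
        backup = {k: p.data.copy() for k, p in params.items()}
        for k, p in params.items():
            p.data[...] = ema[k]
        try:
            return fn()
        finally:
            for k, p in params.items():
                p.data[...] = backup[k]

    tr = load_split(train_manifest, cfg)
    va = load_split(val_manifest, cfg) if val_manifest else []
    steps_per_epoch = max(1, int(np.ceil(len(tr) / t["batch_size"])))
    total_steps = steps_per_epoch * t["epochs"]
    sched = poly_decay if t["schedule"] == "poly" else cosine_decay

    history = []
    best_mf1, best_path = -1.0, out / "best.ckpt"
    log_path = out / "metrics.jsonl"
    step = 0
    with open(log_path, "w") as log_fh:
        for epoch in range(t["epochs"]):
            rng = np.random.default_rng((t["seed"], epoch))
            ep_losses = []
            for idx in _batches(len(tr), t["batch_size"], rng):
                imgs, gts_b = [], []
                for i in idx:
                    img = tr[i]["image"]
                    gts = tr[i]["gts"]
                    if rng.uniform() < t["flip_prob"]:
                        img = img[:, :, ::-1].copy()
                        gts = [_flip_gt(g, Wn) for g in gts]
                    if t["jitter"] > 0:
                        img = img * (1.0 + rng.uniform(-t["jitter"], t["jitter"]))
                    imgs.append(img)
                    gts_b.append(gts)
                batch = np.stack(imgs).astype(np.float32)
                warmup = int(t.get("warmup_steps", 0))
                if step < warmup:
                    opt.lr = t["lr"] * (step + 1) / warmup
                elif t["schedule"] == "poly":
                    opt.lr = poly_decay(t["lr"], step - warmup,
                                        total_steps - warmup, t["poly_power"])
                else:
                    opt.lr = cosine_decay(t["lr"], step - warmup, total_steps - warmup)
                result = model(batch)
                static = (epoch < int(cfg["assign"].get("static_epochs", 0)))
                loss, br = total_loss(
                    result.stages, gts_b, weights, riou_cfg, ap,
                    Wn, Hn, N, regression=cfg["loss"]["regression"],
                    static_priors=model.anchor_params.data.copy() if static else None)
                if not np.isfinite(br.total):
                    raise RuntimeError(
                        f"non-finite loss at step {step}: cls={br.cls} "
                        f"xytl={br.xytl} riou={br.riou}")
                model.zero_grad()
                loss.backward()
                opt.step()
                if ema is not None:
                    for k, p in model.named_parameters():
                        buf = ema[k]
                        buf *= ema_decay
                        buf += (1 - ema_decay) * p.data
                ep_losses.append([br.total, br.cls, br.xytl, br.riou])
                step += 1
            mean = np.mean(ep_losses, axis=0)
            rec = {"epoch": epoch, "loss": float(mean[0]), "cls": float(mean[1]),
                   "xytl": float(mean[2]), "riou": float(mean[3]),
                   "lr": float(opt.lr)}
            is_last = epoch == t["epochs"] - 1
            if va and (is_last or (epoch + 1) % t["val_every"] == 0):
                res = _with_ema(lambda: _evaluate_samples(model, va, cfg))
                rec["val_mf1"] = res.mf1
                rec["val_f1_50"] = 100.0 * res.f1_at(0.50)
                if res.mf1 >= best_mf1:
                    best_mf1 = res.mf1
                    _with_ema(lambda: model.save(best_path))
            history.append(rec)
            log_fh.write(json.dumps(rec) + "\n")
            log_fh.flush()
            log.info("epoch %d: %s", epoch, rec)
    _with_ema(lambda: model.save(out / "last.ckpt"))
    if best_mf1 < 0:
        _with_ema(lambda: model.save(best_path))
    return {"checkpoint": str(best_path), "last_checkpoint": str(out / "last.ckpt"),
            "history": history, "best_mf1": best_mf1, "model": model}


def _predict_polylines(model: RowDetector, sample: dict, cfg: dict):
    """Post-NMS predictions for one preloaded sample, at annotation scale."""
    inf = cfg["infer"]
    # NMS overlap uses a segment extension of half the evaluation stroke
    # width, so suppression mirrors the thickened-mask protocol
    nms_cfg = RIoUConfig(extension_e=inf.get("nms_extension_e", 25.0))
    preds = model.predict(sample["image"][None],
                          score_threshold=inf["score_threshold"],
                          nms_iou=inf["nms_iou"],
                          riou_cfg=nms_cfg)[0]
    preds = preds[:int(inf.get("max_detections", 8))]
    Wa, Ha = sample["ann_size"]
    m = cfg["model"]
    out = []
    for p in preds:
        row = p.to_sampled(m["n_points"], m["input_height"])
        row = rescale_row(row, m["input_width"], m["input_height"], Wa, Ha)
        if row.valid.sum() < 2:
            continue
        try:
            out.append((polyline_from_sampled(row, Wa), p.score))
        except InvalidInputError:
            continue
    return out


def _evaluate_samples(model, samples, cfg: dict):
    preds, gts = [], []
    for s in samples:
        preds.append([pl for pl, _ in _predict_polylines(model, s, cfg)])
        gts.append(s["polylines"])
    return evaluate_dataset(preds, gts, _eval_cfg(cfg))


# ---------------------------------------------------------------- inference

def infer(cfg: dict, checkpoint, image_paths, out_dir, render: bool = False):
    """Run the detector on image files; write LabelMe-dialect predictions."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = build_model(cfg)
    model.load(checkpoint)
    m = cfg["model"]
    written = []
    for path in image_paths:
        path = Path(path)
        img = Image.open(path).convert("RGB")
        Wa, Ha = img.size
        if (Wa, Ha) != (m["input_width"], m["input_height"]):
            log.info("resizing %s from %dx%d to %dx%d", path.name, Wa, Ha,
                     m["input_width"], m["input_height"])
            net = img.resize((m["input_width"], m["input_height"]), Image.BILINEAR)
        else:
            net = img
        arr = (np.asarray(net, dtype=np.float32) / 255.0 - _MEAN) / _STD
        sample = {"image": arr.transpose(2, 0, 1), "ann_size": (Wa, Ha)}
        rows = _predict_polylines(model, sample, cfg)
        ann_path = out / f"{path.stem}.json"
        _write_predictions(rows, Wa, Ha, path.name, ann_path)
        written.append(str(ann_path))
        if render:
            _render_overlay(img, [pl for pl, _ in rows], out / f"{path.stem}_overlay.png")
    return written


def _write_predictions(rows, W, H, image_name, ann_path):
    doc_rows = []
    for i, (pl, score) in enumerate(rows):
        pl.label = f"row_{i}"
        doc_rows.append(pl)
    write_labelme(doc_rows, {"imagePath": image_name, "imageHeight": H,
                             "imageWidth": W}, ann_path)
    # add scores to the serialized shapes
    with open(ann_path) as fh:
        doc = json.load(fh)
    for shape, (_, score) in zip(doc["shapes"], rows):
        shape["score"] = float(score)
    with open(ann_path, "w") as fh:
        json.dump(doc, fh, indent=2)


def _render_overlay(img: Image.Image, polylines, out_path):
    from PIL import ImageDraw
    img = img.copy()
    draw = ImageDraw.Draw(img)
    palette = [(255, 64, 64), (64, 160, 255), (255, 200, 0), (64, 255, 128),
               (220, 64, 255), (0, 255, 220), (255, 128, 0), (128, 128, 255)]
    for i, pl in enumerate(polylines):
        pts = [tuple(p) for p in pl.points]
        draw.line(pts, fill=palette[i % len(palette)], width=3)
    img.save(out_path)


# --------------------------------------------------------------- evaluation

def evaluate_cmd(pred_dir, gt_dir, cfg: dict, out_dir, allow_missing=False):
    """Evaluate a directory of prediction files against annotations."""
    pred_dir, gt_dir, out = Path(pred_dir), Path(gt_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gt_files = sorted(gt_dir.glob("*.json"))
    if not gt_files:
        raise InvalidInputError(f"no annotation files in {gt_dir}")
    missing = [f.stem for f in gt_files if not (pred_dir / f.name).exists()]
    if missing and not allow_missing:
        raise InvalidInputError(
            f"predictions missing for stems: {', '.join(sorted(missing))}")
    preds, gts = [], []
    for f in gt_files:
        gts.append(read_labelme(f))
        pf = pred_dir / f.name
        preds.append(read_labelme(pf) if pf.exists() else [])
    result = evaluate_dataset(preds, gts, _eval_cfg(cfg))
    write_results(result, out / "results.csv", out / "results.json")
    return result


# ----------------------------------------------------------------- ablation

ABLATION_ARMS = [
    ("baseline", {}),
    ("smooth_l1", {("loss", "regression"): "smooth_l1"}),
    ("attention_off", {("model", "attention_mode"): "off"}),
    ("attention_full", {("model", "attention_mode"): "full"}),
    ("fpn_off", {("model", "fpn_enabled"): False}),
]


def ablate(cfg: dict, out_dir, seeds=(0, 1, 2), epochs: int = 4,
           completion_epochs: int = 2, n_train: int = 64,
           n_val: int = 24) -> dict:
    """Run the component-toggle grid on synthetic data.

    The loss-function arms (Row-IoU vs smooth-l1) train on all seeds at
    ``epochs`` so their comparison is a median over seeds; the remaining
    toggle arms run once at ``completion_epochs`` to exercise the
    configuration.  Training is a shortened schedule of the tiny profile.
    """
    import copy
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = copy.deepcopy(cfg)
    base["synth"]["n_train"] = n_train
    base["synth"]["n_val"] = n_val
    base["synth"]["n_test"] = 0
    base["train"]["val_every"] = max(2, epochs // 2)
    manifests = prepare_synthetic(base, out / "data")
    summary = {}
    for arm, over in ABLATION_ARMS:
        compare = arm in ("baseline", "smooth_l1")
        arm_seeds = seeds if compare else seeds[:1]
        scores = {}
        for seed in arm_seeds:
            run_cfg = copy.deepcopy(base)
            for (sec, key), val in over.items():
                run_cfg[sec][key] = val
            run_cfg["train"]["epochs"] = epochs if compare else completion_epochs
            run_cfg["assign"]["static_epochs"] = run_cfg["train"]["epochs"]
            run_cfg["train"]["seed"] = seed
            run_cfg["model"]["seed"] = seed
            res = train(run_cfg, manifests["train"], manifests["val"],
                        out / f"{arm}_seed{seed}")
            scores[seed] = res["best_mf1"]
        summary[arm] = {"mf1_by_seed": scores,
                        "median_mf1": float(np.median(list(scores.values())))}
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
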