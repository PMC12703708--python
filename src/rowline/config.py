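"""Run configuration: profiles, YAML round-trip, dotted overrides.

The configuration is a nested dict with sections ``model``, ``train``,
``assign``, ``loss``, ``riou``, ``eval`` and ``synth``.  Two profiles are
provided: ``full`` mirrors the published training setup (3x800x320 input,
AdamW at 1e-4, polynomial decay with power 0.9, 70 epochs, batch 40) and
``tiny`` is a CPU-scale profile (3x320x160 input, 64 anchors, 36 sample
rows, reduced widths, 30 epochs, batch 8) used throughout the test suite.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["default_config", "load_config", "save_config", "apply_overrides"]


def default_config(profile: str = "full") -> dict:
    cfg = {
        "profile": profile,
        "model": {
            "input_width": 800, "input_height": 320,
            "num_anchors": 64, "n_points": 40,
            "width_mult": 1.0, "fpn_channels": 64, "head_hidden": 128,
            "attention_mode": "dae", "attention_qk": 32,
            "fpn_enabled": True, "head_pointwise": True, "seed": 0,
        },
        "train": {
            "optimizer": "adamw", "lr": 1.0e-4, "weight_decay": 1.0e-4,
            "anchor_lr_scale": 0.1, "ema_decay": 0.99,
            "schedule": "poly", "poly_power": 0.9, "warmup_steps": 100,
            "epochs": 70, "batch_size": 40, "seed": 0,
            "val_every": 5, "flip_prob": 0.5, "jitter": 0.1,
        },
        "assign": {"w_sim": 1000.0, "w_cls": 1.0, "topk_pool": 4,
                   "static_epochs": 10},
        "loss": {"w_cls": 2.0, "w_xytl": 3.0, "w_riou": 20.0,
                 "focal_alpha": 0.5, "focal_gamma": 2.0,
                 "smooth_l1_beta": 1.0, "regression": "riou"},
        "riou": {"extension_e": 15.0, "eps": 1.0e-9},
        "eval": {"thickness": 50.0, "eval_width": 1280, "eval_height": 720,
                 "strict_greater": True},
        "infer": {"score_threshold": 0.25, "nms_iou": 0.1,
                  "nms_extension_e": 25.0, "max_detections": 8},
        "synth": {
            "image_width": 1280, "image_height": 720, "n_rows": 5,
            "row_spacing_world": 0.6, "camera_pitch_deg": 45.0,
            "camera_height": 1.6, "plant_spacing": 0.25,
            "plant_radius": [6.0, 11.0], "weed_density": 0.3,
            "gap_probability": 0.10, "illumination_gain": [0.6, 1.4],
            "blur_sigma": 0.6, "lodging_shear": 2.0, "seed": 0,
            "n_train": 200, "n_val": 50, "n_test": 50,
        },
    }
    if profile == "tiny":
        cfg["model"].update(input_width=320, input_height=160, n_points=36,
                            width_mult=0.125, fpn_channels=32, head_hidden=64,
                            attention_qk=16)
        cfg["train"].update(lr=1.0e-3, epochs=30, batch_size=8, val_every=5)
        cfg["assign"].update(static_epochs=30)
        cfg["eval"].update(eval_width=320, eval_height=160)
        cfg["synth"].update(image_width=320, image_height=160,
                            plant_radius=[2.5, 5.0])
    elif profile != "full":
        raise ValueError(f"unknown profile {profile!r}")
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config(user.get("profile", "full"))
    _deep_update(cfg, user)
    return cfg


def save_config(cfg: dict, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def apply_overrides(cfg: dict, overrides) -> dict:
    """Apply ``section.key=value`` overrides; values parsed as YAML scalars."""
    cfg = copy.deepcopy(cfg)
    for item in overrides or ():
        if "=" not in item:
            raise ValueError(f"override {item!r} must be key=value")
        key, raw = item.split("=", 1)
        node = cfg
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = yaml.safe_load(raw)
    return cfg


def _deep_update(dst: dict, src: dict):
    for k, v in src.items():
        if isinstance(v, dict) and isinstance(dst.get(k), dict):
            _deep_update(dst[k], v)
        else:
            dst[k] = v
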