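"""Run configuration: defaults, provenance marks, snapshots.

Every hyperparameter the method prescribes is a default here; values the
method leaves open are marked ``"decision"`` in the provenance table that
accompanies every emitted manifest, so a run can be audited for which
settings were prescribed and which are this package's choices.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "synth": {
        "n": 50, "image_size": 128, "seed": 0, "ratio": [3, 1, 1],
        "noise_sigma": 0.02, "overlap_target": 0.3,
    },
    "augment": {
        "scales": [0.5, 1.0, 1.5], "rotation_deg": [-90.0, 90.0],
        "flip_p": 0.5,
    },
    "detector": {
        "num_classes": 9, "channels": 16, "num_levels": 5,
        "anchor_base_scale": 8.0,
        "anchor_ratios": [0.25, 0.5, 1.0, 2.0, 4.0],
        "stage_batch": {"hroi": 256, "rroi": 512, "obb": 512},
        "stage_pos_frac": {"hroi": 0.5, "rroi": 0.25, "obb": 0.25},
        "head_fc_dim": 2048, "roi_size": 7,
        "rpn_pos_thr": 0.7, "rpn_neg_thr": 0.3, "roi_pos_thr": 0.5,
        "score_thr": 0.05, "nms_thr": 0.5, "warp_convention": "printed",
        "loss_alpha1": 1.0, "loss_alpha2": 1.0,
        "optimizer": "sgd", "lr": 0.02, "momentum": 0.9,
        "weight_decay": 1.0e-4, "iters": 1000, "seed": 0,
    },
    "segmenter": {
        "in_channels": 3, "base_channels": 8, "aspp_channels": 16,
        "aspp_rates": [6, 12, 18], "se_reduction": 16,
        "low_level_channels": 12, "decoder_channels": 24,
        "loss_alpha1": 1.0, "loss_alpha2": 0.4,
        "optimizer": "sgd", "lr": 0.01, "momentum": 0.9,
        "weight_decay": 5.0e-4, "poly_power": 0.9, "min_lr": 1.0e-4,
        "iters": 1000, "seed": 0,
    },
    "evaluate": {"iou_thresholds": [0.5, 0.85], "boxes_only": False},
}

# which defaults are prescribed by the method ("prescribed") and which are this
# package's own choices ("decision")
PROVENANCE: dict = {
    "synth": {"n": "decision", "image_size": "decision", "seed": "decision",
              "ratio": "prescribed", "noise_sigma": "decision",
              "overlap_target": "decision"},
    "augment": {"scales": "prescribed", "rotation_deg": "prescribed",
                "flip_p": "prescribed"},
    "detector": {
        "num_classes": "prescribed", "channels": "decision",
        "num_levels": "prescribed", "anchor_base_scale": "decision",
        "anchor_ratios": "prescribed", "stage_batch": "prescribed",
        "stage_pos_frac": "prescribed", "head_fc_dim": "prescribed",
        "roi_size": "prescribed", "rpn_pos_thr": "decision",
        "rpn_neg_thr": "decision", "roi_pos_thr": "decision",
        "score_thr": "decision", "nms_thr": "decision",
        "warp_convention": "decision", "loss_alpha1": "prescribed",
        "loss_alpha2": "prescribed", "optimizer": "prescribed", "lr": "prescribed",
        "momentum": "prescribed", "weight_decay": "prescribed",
        "iters": "decision", "seed": "decision",
    },
    "segmenter": {
        "in_channels": "decision", "base_channels": "decision",
        "aspp_channels": "decision", "aspp_rates": "decision",
        "se_reduction": "decision", "low_level_channels": "decision",
        "decoder_channels": "decision", "loss_alpha1": "prescribed",
        "loss_alpha2": "prescribed", "optimizer": "prescribed", "lr": "prescribed",
        "momentum": "prescribed", "weight_decay": "prescribed",
        "poly_power": "prescribed", "min_lr": "prescribed",
        "iters": "decision", "seed": "decision",
    },
    "evaluate": {"iou_thresholds": "prescribed", "boxes_only": "decision"},
}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Defaults, optionally updated from a YAML file and a flat override dict.

    Unknown keys raise :class:`ConfigError` naming the offending key.
    """
    cfg = copy.deepcopy(DEFAULTS)

    def merge(dst: dict, src: dict, prefix: str = "") -> None:
        for k, v in src.items():
            if k not in dst:
                raise ConfigError(f"unknown config key: {prefix}{k}")
            if isinstance(dst[k], dict) and isinstance(v, dict):
                merge(dst[k], v, f"{prefix}{k}.")
            else:
                dst[k] = v

    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a mapping")
        merge(cfg, user)
    for dotted, value in (overrides or {}).items():
        section = cfg
        parts = dotted.split(".")
        for p in parts[:-1]:
            if p not in section:
                raise ConfigError(f"unknown config key: {dotted}")
            section = section[p]
        if parts[-1] not in section:
            raise ConfigError(f"unknown config key: {dotted}")
        section[parts[-1]] = value
    return cfg


def snapshot(cfg: dict, path: str | Path) -> None:
    """Write the effective config plus the provenance marks."""
    with open(path, "w") as fh:
        json.dump({"config": cfg, "provenance": PROVENANCE}, fh, indent=2,
                  sort_keys=True)
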