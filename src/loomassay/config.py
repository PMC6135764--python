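"""Run configuration: defaults, YAML loading and schema validation.

A run config is a nested mapping with one section per pipeline stage plus a
master seed.  Validation rejects unknown keys and reports every violated
invariant with its dotted path into the document, so threshold-heavy analyses
stay auditable.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "config_hash"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "log_level": "INFO",
    "arena": {
        "diameter_mm": 30.0,
        "frame_rate": 60.0,
        "image_width": 1104,
        "image_height": 1040,
    },
    "stimulus": {
        "protocol": "open_loop_looming",
        "l_over_v_ms": 40.0,
        "expansion_ms": 450.0,
        "hold_ms": 50.0,
        "max_angle_deg": 78.0,
        "refresh_hz": 144.0,
        "trigger": {
            "window_ms": 500.0,
            "low_thresh_mm": 1.0,
            "high_thresh_mm": 7.5,
            "very_high_thresh_mm": 10.0,
            "refractory_s": 15.0,
            "mode": "low",
        },
    },
    "tracking": {
        "roi_size_px": 100,
        "pixel_delta_thresh": 10,
        "seg_offset": 25,
        "min_blob_area_px": 20,
        "background_subsample": 200,
        "max_invalid_frac": 0.2,
    },
    "ethogram": {
        "bin_ms": 500.0,
        "walk_thresh_mm_s": 4.0,
        "freeze_motion_thresh_px_s": 50.0,
        "jump_thresh_mm_s": 75.0,
        "pause_min_frames": 10,
        "pause_window_s": 1.0,
        "opto_success_frac": 0.25,
    },
    "stats": {
        "speed_bin_edges": [0, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 22, 24],
        "n_shuffles": 5000,
    },
    "simulate": {
        "n_flies": 10,
        "condition": "looming",
        "duration_s": None,
        "walk_speed_mean": 10.0,
        "p_freeze_max": 0.8,
        "freeze_speed_k": 0.5,
        "freeze_speed_mid": 6.0,
        "p_pause": 0.5,
        "p_jump": 0.06,
    },
    "io": {
        "frames": None,
        "trajectories": None,
    },
}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config merged over the defaults; None gives the defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh)
    if user is None:
        return cfg
    if not isinstance(user, dict):
        raise ConfigError("config root must be a mapping")
    _merge(cfg, user)
    return cfg


def _merge(base: dict, user: dict, path: str = "") -> None:
    for key, value in user.items():
        here = f"{path}{key}"
        if key not in base:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            _merge(base[key], value, here + ".")
        else:
            base[key] = value


def validate_config(cfg: dict | str | Path) -> list[str]:
    """Validate a config document; returns a list of dotted-path error strings.

    An empty list means the config is acceptable.
    """
    if not isinstance(cfg, dict):
        try:
            cfg = load_config(cfg)
        except ConfigError as exc:
            return [str(exc)]
        except yaml.YAMLError as exc:
            return [f"invalid YAML: {exc}"]
    errors: list[str] = []

    def positive(path: str) -> None:
        value = _get(cfg, path)
        if not isinstance(value, (int, float)) or isinstance(value, bool) or value <= 0:
            errors.append(f"{path}: must be a positive number")

    for path in (
        "arena.diameter_mm",
        "arena.frame_rate",
        "stimulus.l_over_v_ms",
        "stimulus.expansion_ms",
        "stimulus.refresh_hz",
        "stimulus.trigger.window_ms",
        "stimulus.trigger.low_thresh_mm",
        "stimulus.trigger.high_thresh_mm",
        "stimulus.trigger.very_high_thresh_mm",
        "stimulus.trigger.refractory_s",
        "tracking.pixel_delta_thresh",
        "tracking.seg_offset",
        "tracking.min_blob_area_px",
        "ethogram.bin_ms",
        "ethogram.walk_thresh_mm_s",
        "ethogram.freeze_motion_thresh_px_s",
        "ethogram.jump_thresh_mm_s",
        "ethogram.pause_min_frames",
        "ethogram.pause_window_s",
        "ethogram.opto_success_frac",
        "stats.n_shuffles",
        "simulate.n_flies",
    ):
        positive(path)

    max_angle = _get(cfg, "stimulus.max_angle_deg")
    if not isinstance(max_angle, (int, float)) or not 0 < max_angle < 180:
        errors.append("stimulus.max_angle_deg: must lie in (0, 180)")
    trig = cfg["stimulus"]["trigger"]
    if all(
        isinstance(trig[k], (int, float))
        for k in ("low_thresh_mm", "high_thresh_mm", "very_high_thresh_mm")
    ):
        if not trig["low_thresh_mm"] < trig["high_thresh_mm"] < trig["very_high_thresh_mm"]:
            errors.append(
                "stimulus.trigger: thresholds must satisfy low < high < very_high"
            )
    if trig.get("mode") not in ("low", "high", "very_high"):
        errors.append("stimulus.trigger.mode: must be low, high or very_high")
    roi = _get(cfg, "tracking.roi_size_px")
    if not isinstance(roi, int) or roi < 2 or roi % 2:
        errors.append("tracking.roi_size_px: must be an even integer >= 2")
    frac = _get(cfg, "tracking.max_invalid_frac")
    if not isinstance(frac, (int, float)) or not 0 <= frac <= 1:
        errors.append("tracking.max_invalid_frac: must lie in [0, 1]")
    edges = _get(cfg, "stats.speed_bin_edges")
    if (
        not isinstance(edges, (list, tuple))
        or len(edges) < 2
        or any(b <= a for a, b in zip(edges, edges[1:]))
    ):
        errors.append("stats.speed_bin_edges: must be a strictly increasing list")
    from .synthetic import COHORT_CONDITIONS

    if _get(cfg, "simulate.condition") not in COHORT_CONDITIONS:
        errors.append(
            f"simulate.condition: must be one of {', '.join(COHORT_CONDITIONS)}"
        )
    for key in ("p_freeze_max", "p_pause", "p_jump"):
        value = _get(cfg, f"simulate.{key}")
        if not isinstance(value, (int, float)) or not 0 <= value <= 1:
            errors.append(f"simulate.{key}: must lie in [0, 1]")
    seed = cfg.get("seed")
    if not isinstance(seed, int) or isinstance(seed, bool) or seed < 0:
        errors.append("seed: must be a non-negative integer")
    return errors


def _get(cfg: dict, dotted: str):
    node = cfg
    for part in dotted.split("."):
        if not isinstance(node, dict) or part not in node:
            return None
        node = node[part]
    return node


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config document, for output stamping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
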