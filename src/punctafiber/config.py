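"""Pipeline configuration: schema, validation with per-key error paths,
defaults, and stable hashing for provenance."""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

__all__ = ["ConfigError", "DEFAULT_CONFIG", "validate_config", "load_config", "config_hash"]

SCHEMA_ID = "punctafiber-config-v1"

DEFAULT_CONFIG: dict = {
    "schema": SCHEMA_ID,
    "seed": 0,
    "pixel_size_um": 0.16,
    "z_step_um": 1.0,
    "channels": {"pgp95": 0, "trpv1": 1},
    "threshold": 200.0,
    "connectivity": 8,
    "segmentation": {
        "backend": "rf",
        "n_trees": 100,
        "prob_threshold": 0.5,
        "min_object_px": 64,
        "scales": [1.0, 2.0, 4.0, 8.0, 16.0],
        "n_train_images": 3,
    },
    "staple": {"max_iter": 100, "tol": 1e-6},
    "simulate": {
        "n_images": 10,
        "image_shape": [128, 128],
        "n_fibers": 3,
        "fiber_thickness_px": 5,
        "fiber_amplitude": 3000.0,
        "n_puncta_on": 8,
        "n_puncta_off": 4,
        "punctum_sigma_px": 1.5,
        "punctum_amplitude": 1000.0,
        "background_level": 50.0,
        "noise_sd": 10.0,
    },
    "workdir": "punctafiber_run",
}

_NUMERIC = (int, float)

# key path -> (expected type(s), validator or None)
_VALIDATORS = {
    "schema": (str, lambda v: v == SCHEMA_ID or f"unsupported schema {v!r}"),
    "seed": (int, None),
    "pixel_size_um": (_NUMERIC, lambda v: v > 0 or "must be positive"),
    "z_step_um": (_NUMERIC, lambda v: v > 0 or "must be positive"),
    "channels.pgp95": (int, lambda v: v >= 0 or "must be >= 0"),
    "channels.trpv1": (int, lambda v: v >= 0 or "must be >= 0"),
    "threshold": (_NUMERIC, lambda v: v >= 0 or "must be >= 0"),
    "connectivity": (int, lambda v: v in (4, 8) or "must be 4 or 8"),
    "segmentation.backend": (str, lambda v: v in ("rf", "external") or "must be 'rf' or 'external'"),
    "segmentation.n_trees": (int, lambda v: v > 0 or "must be positive"),
    "segmentation.prob_threshold": (_NUMERIC, lambda v: 0 <= v <= 1 or "must be in [0,1]"),
    "segmentation.min_object_px": (int, lambda v: v >= 0 or "must be >= 0"),
    "segmentation.scales": (list, lambda v: all(isinstance(s, _NUMERIC) and s > 0 for s in v) or "must be positive numbers"),
    "segmentation.n_train_images": (int, lambda v: v > 0 or "must be positive"),
    "staple.max_iter": (int, lambda v: v > 0 or "must be positive"),
    "staple.tol": (_NUMERIC, lambda v: v > 0 or "must be positive"),
    "simulate.n_images": (int, lambda v: v >= 0 or "must be >= 0"),
    "simulate.image_shape": (list, lambda v: len(v) == 2 and all(isinstance(s, int) and s > 0 for s in v) or "must be [height, width]"),
    "simulate.n_fibers": (int, lambda v: v >= 0 or "must be >= 0"),
    "simulate.fiber_thickness_px": (int, lambda v: v > 0 or "must be positive"),
    "simulate.fiber_amplitude": (_NUMERIC, lambda v: v >= 0 or "must be >= 0"),
    "simulate.n_puncta_on": (int, lambda v: v >= 0 or "must be >= 0"),
    "simulate.n_puncta_off": (int, lambda v: v >= 0 or "must be >= 0"),
    "simulate.punctum_sigma_px": (_NUMERIC, lambda v: v > 0 or "must be positive"),
    "simulate.punctum_amplitude": (_NUMERIC, lambda v: v >= 0 or "must be >= 0"),
    "simulate.background_level": (_NUMERIC, lambda v: v >= 0 or "must be >= 0"),
    "simulate.noise_sd": (_NUMERIC, lambda v: v >= 0 or "must be >= 0"),
    "workdir": (str, None),
}


class ConfigError(ValueError):
    """Aggregated configuration problems, one message per offending key."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


def _walk(d: dict, prefix: str = ""):
    for key, value in d.items():
        path = f"{prefix}{key}"
        if isinstance(value, dict) and any(k.startswith(path + ".") for k in _VALIDATORS):
            yield from _walk(value, path + ".")
        else:
            yield path, value


def validate_config(raw: dict) -> dict:
    """Fill defaults, reject unknown keys, and type-check every value.

    Returns the normalized config dict; raises :class:`ConfigError` listing
    every problem with its dotted key path.
    """
    errors: list[str] = []
    merged = copy.deepcopy(DEFAULT_CONFIG)

    for path, value in _walk(raw):
        if path not in _VALIDATORS:
            errors.append(f"{path}: unknown key")
            continue
        expected, check = _VALIDATORS[path]
        if isinstance(value, bool) and expected is not bool:
            errors.append(f"{path}: expected {getattr(expected, '__name__', 'number')}, got bool")
            continue
        if not isinstance(value, expected):
            name = expected.__name__ if isinstance(expected, type) else "number"
            errors.append(f"{path}: expected {name}, got {type(value).__name__}")
            continue
        if check is not None:
            verdict = check(value)
            if verdict is not True:
                errors.append(f"{path}: {verdict}")
                continue
        # install into merged config
        node = merged
        parts = path.split(".")
        for part in parts[:-1]:
            node = node[part]
        node[parts[-1]] = value

    if errors:
        raise ConfigError(sorted(errors))
    return merged


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError([f"unparseable JSON: {exc}"]) from exc
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a JSON object"])
    return validate_config(raw)


def config_hash(config: dict) -> str:
    """Stable SHA-256 over the canonical JSON form."""
    payload = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()
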