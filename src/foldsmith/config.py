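"""Runtime configuration: packaged defaults plus user overrides.

``data/defaults.yaml`` holds every numeric default the command-line surface
exposes; a ``--config`` YAML overrides any subset (deep-merged).
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import yaml

from .assembler import BuildLimits


def load_defaults() -> dict:
    text = resources.files("foldsmith.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    cfg = load_defaults()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]


def build_limits_from(cfg: dict) -> BuildLimits:
    b = cfg["build"]
    return BuildLimits(
        moves_per_trajectory=int(b["moves_per_trajectory"]),
        trajectories_per_task=int(b["trajectories_per_task"]),
        perturbations_per_task=int(b["perturbations_per_task"]),
        temp_high=float(b["temp_high"]),
        temp_low=float(b["temp_low"]),
        restarts=int(b.get("restarts", 3)),
        backtracks=int(b.get("backtracks", 6)),
        max_total_trajectories=int(b.get("max_total_trajectories", 100000)),
    )
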