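"""Run configuration loading, validation and hashing for the CLI."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from .classifier import ModelConfig
from .datatypes import EpisodeSchedule, FogEpisode
from .errors import ConfigurationError
from .synth import default_profiles
from .utils import config_hash


def load_run_config(path: Optional[str], overrides: Optional[dict] = None) -> dict:
    """Load a YAML run config, apply CLI overrides, attach its hash."""
    cfg: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigurationError(f"config file not found: {path}")
        loaded = yaml.safe_load(p.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"{path}: top level must be a mapping")
        cfg.update(loaded)
    for key, value in (overrides or {}).items():
        if value is not None:
            cfg[key] = value
    cfg["config_hash"] = config_hash(
        {k: v for k, v in cfg.items() if k != "config_hash"}
    )
    return cfg


def validate_fields(cfg: dict, required: Dict[str, type]) -> List[str]:
    """Field-by-field validation; returns a list of error messages."""
    problems = []
    for name, typ in required.items():
        if name not in cfg:
            problems.append(f"missing required field {name!r}")
        elif typ is not None and not isinstance(cfg[name], typ):
            problems.append(
                f"field {name!r}: expected {typ.__name__}, "
                f"got {type(cfg[name]).__name__}"
            )
    return problems


def schedule_from_config(cfg: dict) -> EpisodeSchedule:
    n_days = int(cfg.get("n_days", 1))
    rates = {}
    for taxon, r in (cfg.get("rates") or {}).items():
        arr = np.full(n_days, float(r)) if np.isscalar(r) else np.asarray(r, float)
        if arr.shape != (n_days,):
            raise ConfigurationError(
                f"rates for {taxon}: expected scalar or list of {n_days} days"
            )
        rates[taxon] = arr
    fog = [
        FogEpisode(ep["start"], ep["end"], float(ep["rate"]))
        for ep in (cfg.get("fog_episodes") or [])
    ]
    return EpisodeSchedule(
        start_date=cfg.get("start_date", "2024-04-01"),
        rates=rates, fog_episodes=fog,
    )


def profiles_from_config(cfg: dict) -> dict:
    profiles = default_profiles()
    taxa = cfg.get("taxa")
    if taxa:
        unknown = set(taxa) - set(profiles)
        if unknown:
            raise ConfigurationError(f"unknown taxa (no profile): {sorted(unknown)}")
        profiles = {t: profiles[t] for t in taxa}
    return profiles


def model_config_from(cfg: dict, seed: Optional[int]) -> ModelConfig:
    m = dict(cfg.get("model") or {})
    if "class_names" not in m:
        raise ConfigurationError("model config requires class_names")
    if "conv_blocks" in m:
        m["conv_blocks"] = tuple(tuple(b) for b in m["conv_blocks"])
    if seed is not None:
        m["rng_seed"] = seed
    return ModelConfig(**{k: (tuple(v) if k == "class_names" else v)
                          for k, v in m.items()})
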