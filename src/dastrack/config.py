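"""YAML run configuration: flat keys mirroring the dataclass field names."""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .calling import NoiseProfile
from .pileup import FilterPolicy
from .simulate import SimParams


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _subset(cfg: dict, cls) -> dict:
    names = set(cls.__dataclass_fields__)
    return {k: v for k, v in cfg.items() if k in names}


def sim_params_from_config(cfg: dict, **overrides) -> SimParams:
    kwargs = _subset(cfg, SimParams)
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return SimParams(**kwargs)


def filter_policy_from_config(cfg: dict, **overrides) -> FilterPolicy:
    kwargs = _subset(cfg, FilterPolicy)
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return FilterPolicy(**kwargs)


def noise_profile_from_config(cfg: dict, **overrides) -> NoiseProfile:
    kwargs = _subset(cfg, NoiseProfile)
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return NoiseProfile(**kwargs)


def roundtrip_dict(obj) -> dict:
    """Dataclass -> plain dict for lossless YAML round trips."""
    return asdict(obj)
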