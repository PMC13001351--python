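"""Structured run configuration.

One YAML file with per-module blocks (phantom geometry, pose and
composition distributions, CTF, noise, target construction, training,
picking).  Every omitted field falls back to the documented default;
unknown keys are rejected by name so typos cannot silently change a
run.  CLI flags override config values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Tuple

import yaml

from .exceptions import ConfigError, ParameterError
from .models import TrainConfig
from .picker import PickerParams
from .simulate import CompositionParams, CTFParams, NoiseParams, PoseParams
from .targets import TargetParams
from .volumes import PhantomParams

__all__ = ["LibraryConfig", "SimulateConfig", "RunConfig", "load_config", "dump_config"]


@dataclass
class LibraryConfig:
    n_models: int = 15
    box_px: int = 256
    voxel_size: float = 4.36


@dataclass
class SimulateConfig:
    n: int = 100
    box_px_out: int = 128
    defocus_range_um: Tuple[float, float] = (0.8, 2.2)


@dataclass
class RunConfig:
    master_seed: int = 0
    library: LibraryConfig = field(default_factory=LibraryConfig)
    phantom: PhantomParams = field(default_factory=PhantomParams)
    pose: PoseParams = field(default_factory=PoseParams)
    composition: CompositionParams = field(default_factory=CompositionParams)
    ctf: CTFParams = field(default_factory=CTFParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    target: TargetParams = field(default_factory=TargetParams)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    denoiser: TrainConfig = field(default_factory=TrainConfig)
    segmenter: TrainConfig = field(default_factory=TrainConfig)
    picker: PickerParams = field(default_factory=PickerParams)


def _build_block(cls, data: dict, block: str):
    valid = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in valid:
            raise ConfigError(f"unknown key {block}.{key}")
        default = valid[key].default
        if isinstance(value, list) and (
            isinstance(default, tuple) or "Tuple" in str(valid[key].type)
        ):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ParameterError) as exc:
        raise ConfigError(f"invalid block {block!r}: {exc}") from exc


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a run configuration from YAML (or a dict)."""
    if isinstance(path_or_dict, dict):
        data = path_or_dict
    else:
        with open(path_or_dict) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")

    blocks = {f.name: f for f in dataclasses.fields(RunConfig)}
    kwargs = {}
    for key, value in data.items():
        if key not in blocks:
            raise ConfigError(f"unknown key {key}")
        if key == "master_seed":
            kwargs[key] = int(value)
            continue
        cls = blocks[key].default_factory  # type: ignore[union-attr]
        kwargs[key] = _build_block(cls, value or {}, key)
    cfg = RunConfig(**kwargs)

    # cross-block invariants
    try:
        cfg.composition.validate(cfg.library.n_models)
        cfg.pose.validate()
        cfg.noise.validate()
        cfg.target.validate()
        cfg.picker.validate()
        cfg.phantom.validate()
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def dump_config(cfg: RunConfig, path=None) -> str:
    """Serialize a configuration back to YAML (round-trips load_config)."""
    text = yaml.safe_dump(_to_plain(dataclasses.asdict(cfg)), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
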