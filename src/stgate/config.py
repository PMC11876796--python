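"""Run configuration: nested YAML sections with strict key checking.

Sections mirror the library's config dataclasses; unknown keys are rejected
with their full path so typos fail loudly.  Every run writes its resolved
config plus seeds back into the output directory as a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import ModelConfig
from .training import TrainConfig

__all__ = ["RunConfig", "SimulateConfig", "DataConfig", "DiscoverConfig",
           "load_config", "write_manifest", "set_global_seed"]


@dataclass
class DataConfig:
    series: str = ""
    adjacency: str = ""
    mask: str = ""
    format: str = ""        # inferred from extension when empty
    sigma: float = 0.0      # >0: adjacency file is a distance matrix
    kappa: float = 0.1


@dataclass
class SimulateConfig:
    n_series: int = 15
    n_windows: int = 14
    window: int = 24
    edge_density: float = 0.15
    n_shortcuts: int = 5
    background_sd: float = 0.5
    missing_mode: str = "point"
    point_rate: float = 0.25


@dataclass
class DiscoverConfig:
    layer: int = -1
    soft: bool = False
    truth: str = ""
    lo: float = 0.1
    hi: float = 0.9


@dataclass
class RunConfig:
    data: DataConfig = field(default_factory=DataConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    discover: DiscoverConfig = field(default_factory=DiscoverConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    seed: int = 0
    out_dir: str = "runs"
    log_level: str = "info"


def _build(cls, payload: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise KeyError(f"unknown config key {path}.{sorted(unknown)[0]}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in payload:
            continue
        val = payload[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in (
                "data", "model", "train", "discover", "simulate"):
            val = _build(_SECTION_TYPES[f.name], val, f"{path}.{f.name}")
        elif f.name == "training_rates" and isinstance(val, list):
            val = tuple(val)
        kwargs[f.name] = val
    return cls(**kwargs)


_SECTION_TYPES = {"data": DataConfig, "model": ModelConfig,
                  "train": TrainConfig, "discover": DiscoverConfig,
                  "simulate": SimulateConfig}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """YAML file + flat dotted overrides; precedence CLI > file > defaults."""
    payload: dict = {}
    if path:
        with open(path) as f:
            payload = yaml.safe_load(f) or {}
    for key, val in (overrides or {}).items():
        parts = key.split(".")
        node = payload
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = val
    return _build(RunConfig, payload, "config")


def set_global_seed(seed: int) -> dict:
    """Derive the per-stage seeds from one global seed; returns the record
    embedded in manifests."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(4)
    record = {"seed": int(seed),
              "simulate_seed": int(children[0].generate_state(1)[0] % 2**31),
              "train_seed": int(children[1].generate_state(1)[0] % 2**31),
              "mask_seed": int(children[2].generate_state(1)[0] % 2**31),
              "init_seed": int(children[3].generate_state(1)[0] % 2**31)}
    return record


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_manifest(out_dir: str | Path, config: RunConfig, seeds: dict,
                   inputs: list[str | Path] = (), outputs: list[str] = ()
                   ) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "seeds": seeds,
        "inputs": {str(p): _checksum(Path(p)) for p in inputs
                   if Path(p).exists()},
        "outputs": list(outputs),
        "version": "stgate 0.1.0",
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
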