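"""Run configuration: YAML round-tripping and deterministic seed fan-out."""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import yaml

from .nn.training import DenoiserSpec, TrainConfig
from .optics import OpticalModel
from .simulate import NoiseModel

__all__ = ["RunConfig", "load_config", "save_config", "stage_seed"]


@dataclasses.dataclass
class RunConfig:
    """Parameter blocks for a pipeline run plus global seed and output dir."""

    optical: dict = dataclasses.field(default_factory=dict)
    noise: dict = dataclasses.field(default_factory=dict)
    scene: dict = dataclasses.field(default_factory=dict)
    denoiser: dict = dataclasses.field(default_factory=dict)
    training: dict = dataclasses.field(default_factory=dict)
    analysis: dict = dataclasses.field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def optical_model(self) -> OpticalModel:
        return OpticalModel(**self.optical)

    def noise_model(self) -> NoiseModel:
        return NoiseModel(**self.noise)

    def denoiser_spec(self) -> DenoiserSpec:
        return DenoiserSpec(**self.denoiser)

    def train_config(self) -> TrainConfig:
        known = {f.name for f in dataclasses.fields(TrainConfig)}
        kwargs = {k: v for k, v in self.training.items() if k in known}
        kwargs.setdefault("seed", self.seed)
        return TrainConfig(**kwargs)

    def digest(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage child seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")
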