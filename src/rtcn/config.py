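"""Validated run configuration for the end-to-end pipeline.

A single master seed is fanned out deterministically per stage (hash of the
stage name) so any stage can be rerun in isolation with the same randomness.
Unknown keys are rejected before anything executes.
"""
from __future__ import annotations

import zlib

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataConfig(_Strict):
    records_per_class: dict[str, int] | int = 6
    duration_s: float = 10.0
    heart_rate_bpm: float = 72.0
    hr_jitter_frac: float = 0.03
    baseline_amp_mv: float = 0.15
    powerline_amp_mv: float = 0.05
    white_sigma_mv: float = 0.02


class PreprocessConfig(_Strict):
    lead: str = "ii"
    wavelet: str = "db6"
    n_levels: int = 5


class TransformConfig(_Strict):
    method: str = "stransform"  # stransform | stft | cwt
    f_max_hz: float = 50.0
    side: int = 64              # model-input side (must be divisible by 32)
    log1p: bool = False


class DdpmConfig(_Strict):
    enabled: bool = True
    T: int = 50
    beta_start: float = 1e-4
    beta_end: float = 0.05
    train_steps: int = 200
    batch_size: int = 16
    lr: float = 1e-3
    hidden: int = 32
    target_per_class: int | None = None  # None -> median class count


class ModelConfig(_Strict):
    variant: str = "rtcn"
    width_divisor: int = 8
    compressed_dim: int = 64
    n_heads: int = 4
    n_encoder_layers: int = 1
    dropout: float = 0.1
    vit_patch: int = 16


class SplitConfig(_Strict):
    paradigm: str = "inter_patient"
    train_fraction: float = 0.8


class TrainStageConfig(_Strict):
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 16
    epochs: int = 8
    val_fraction: float = 0.1


class RunConfig(_Strict):
    seed: int = 0
    data: DataConfig = Field(default_factory=DataConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    transform: TransformConfig = Field(default_factory=TransformConfig)
    ddpm: DdpmConfig = Field(default_factory=DdpmConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    split: SplitConfig = Field(default_factory=SplitConfig)
    train: TrainStageConfig = Field(default_factory=TrainStageConfig)
    explain_enabled: bool = False
    genqc_enabled: bool = False

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)
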