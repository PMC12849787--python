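"""YAML run configuration with schema validation.

One file drives the whole pipeline. Every key has a default (the protocol
values: 1-s windows at overlap 0.5, ten folds, Adam at lr 0.001 for 100
epochs with batch 64, dropout 0.5, focal gamma 2 / alpha 0.25, two 8-head
attention layers, encoder depth 4), so an empty file is a valid config.
Unknown keys are rejected, and validation errors name the offending key.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .errors import ConfigurationError
from .simulate import SimConfig
from .training import TrainConfig


class SimSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_channels: int = 16
    duration_s: float = 3000.0
    fs: float = 256.0
    base_coupling: float = 0.3
    seizure_rate: float = 20.0
    seizure_len_min_s: float = 40.0
    seizure_len_max_s: float = 110.0
    seizure_amp_gain: float = 3.0
    seizure_coupling: float = 0.8
    osc_freq_hz: float = 4.0
    seed: int = 0

    def to_sim_config(self) -> SimConfig:
        cfg = SimConfig(
            n_channels=self.n_channels, duration_s=self.duration_s, fs=self.fs,
            base_coupling=self.base_coupling, seizure_rate=self.seizure_rate,
            seizure_len_s=(self.seizure_len_min_s, self.seizure_len_max_s),
            seizure_amp_gain=self.seizure_amp_gain,
            seizure_coupling=self.seizure_coupling,
            osc_freq_hz=self.osc_freq_hz, seed=self.seed)
        cfg.validate()
        return cfg


class PreprocessSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    montage: str | None = None        # "chb-mit-16", "tuh-20", or None = keep all
    band_lo: float = 0.5
    band_hi: float = 48.0
    filter_order: int = 8
    window_s: float = 1.0
    overlap: float = 0.5
    label_threshold: float = 0.5

    @field_validator("overlap")
    @classmethod
    def _check_overlap(cls, v: float) -> float:
        if not 0 <= v < 1:
            raise ValueError("overlap must be in [0, 1)")
        return v


class TrainSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    lr: float = 0.001
    epochs: int = 100
    batch_size: int = 64
    dropout: float = 0.5
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    n_folds: int = 10
    fold_scheme: str = "blocked"
    seq_len: int = 8
    seq_stride: int = 1
    tau: float = 0.3
    mode: str = "combined"
    decision_threshold: float | str = "train"
    seed: int = 0
    gat_hidden: int = 64
    gat_heads: int = 8
    gat_activation: str = "elu"
    d_model: int = 128
    tx_heads: int = 4
    tx_depth: int = 4
    mlp_hidden: int | None = None

    @field_validator("focal_gamma")
    @classmethod
    def _check_gamma(cls, v: float) -> float:
        if v < 0:
            raise ValueError("focal_gamma must be >= 0")
        return v

    @field_validator("focal_alpha")
    @classmethod
    def _check_alpha(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("focal_alpha must be in (0, 1)")
        return v

    def to_train_config(self) -> TrainConfig:
        cfg = TrainConfig(**self.model_dump())
        cfg.validate()
        return cfg


class RunConfig(BaseModel):
    """Validated union of simulation, preprocessing and training settings."""

    model_config = ConfigDict(extra="forbid")

    sim: SimSection = SimSection()
    preprocess: PreprocessSection = PreprocessSection()
    train: TrainSection = TrainSection()
    log_level: str = "INFO"


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; missing file section keys default.

    An empty (or absent) file yields the pure defaults.
    """
    payload = {}
    if path is not None:
        text = Path(path).read_text()
        payload = yaml.safe_load(text) or {}
        if not isinstance(payload, dict):
            raise ConfigurationError(f"{path}: top level must be a mapping")
    try:
        return RunConfig(**payload)
    except ValidationError as exc:
        locs = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors())
        raise ConfigurationError(f"invalid configuration ({locs})") from exc
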