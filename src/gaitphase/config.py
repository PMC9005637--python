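"""Hierarchical run configuration: one validated YAML document per run.

Unknown keys are rejected (typos like ``windw_len`` fail loudly) and every
field carries a default, so an empty file is a valid all-defaults config.
The effective config is persisted next to each run's outputs for
provenance.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SimulateConfig(_Strict):
    n_subjects: int = Field(20, ge=1)
    conditions: list[str] = ["C1", "C2", "C3", "C4", "C5"]
    trials_per_condition: int = Field(2, ge=1)
    n_strides: int = Field(3, ge=1)
    variability_preset: str = "default"   # default | informative_torso | zero
    seed: int = 0


class WindowConfig(_Strict):
    window_len: int = Field(100, ge=1)
    train_stride: int = Field(1, ge=1)


class NetworkConfig(_Strict):
    hidden_units: list[int] = [128, 64, 64, 32]
    bidirectional: list[bool] = [True, False, False, False]


class TrainingConfig(_Strict):
    learning_rate: float = Field(1e-3, gt=0)
    batch_size: int = Field(64, ge=1)
    max_epochs: int = Field(100, ge=1)
    patience: int = Field(10, ge=1)
    val_fraction: float = Field(0.2, gt=0, lt=1)


class AblationConfig(_Strict):
    sets: list[str] = ["SET1", "SET2", "SET3", "SET4"]
    models: list[str] = ["general", "slow", "normal_fast"]
    n_prediction_subjects: int = Field(8, ge=1)
    base_seed: int = 0


class EvaluationConfig(_Strict):
    grf_threshold_n: float = Field(20.0, gt=0)
    grf_debounce_s: float = Field(0.1, gt=0)
    midstance_lo: float = 30.0
    midstance_hi: float = 50.0
    alpha: float = Field(0.05, gt=0, lt=1)


class RunConfig(_Strict):
    schema_version: int = 1
    simulate: SimulateConfig = SimulateConfig()
    windows: WindowConfig = WindowConfig()
    network: NetworkConfig = NetworkConfig()
    training: TrainingConfig = TrainingConfig()
    ablation: AblationConfig = AblationConfig()
    evaluation: EvaluationConfig = EvaluationConfig()


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; missing file fields take defaults.

    Raises a ``ValueError`` naming the offending key on schema violations.
    """
    if path is None:
        return RunConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    try:
        return RunConfig.model_validate(data)
    except ValidationError as e:
        locs = "; ".join(
            ".".join(str(x) for x in err["loc"]) + f": {err['msg']}"
            for err in e.errors())
        raise ValueError(f"invalid config {path}: {locs}") from e


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the effective configuration."""
    blob = yaml.safe_dump(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
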