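"""Run configuration: one YAML document drives the whole pipeline.

Defaults reproduce the published recipe (margin 10 px, patch side 64,
batch sizes 8/1, base learning rate 0.002 decayed by 0.95 every 10
epochs, 200 epochs, 5 folds, subgroup thresholds 14 years / 20 mm).
Unknown keys are rejected; violations are reported with their key path.
The single global seed is propagated to every stochastic stage.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .evaluation import MENARCHE_THRESHOLD_YEARS, TUMOR_SIZE_THRESHOLD_MM


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PhantomSection(_Strict):
    image_side: int = 256
    n_channels: int = 3
    lesion_radius_min: float = 12.0
    lesion_radius_max: float = 30.0
    spiculation_amplitude: float = 0.35
    ring_contrast: float = 0.35
    background_noise_scale: float = 0.06
    n_cases: int = 160
    class_balance: float = 84 / 160

    @model_validator(mode="after")
    def _ranges(self):
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie in (0, 1)")
        if self.n_cases < 2:
            raise ValueError("n_cases must be >= 2")
        return self


class PreprocessSection(_Strict):
    margin: int = 10
    side: int = 64
    mean: float = 0.5
    std: float = 0.5

    @model_validator(mode="after")
    def _ranges(self):
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.std == 0:
            raise ValueError("std must be nonzero")
        return self


class ModelSection(_Strict):
    n_classes: int = 2
    se_reduction_ratio: int = 16
    dropout_rate: float = 0.5
    attention_kernel_size: int = 7
    cross_wiring: str = "ltt1_channel"
    attention_dual_path: bool = False


class TrainSection(_Strict):
    batch_size_train: int = 8
    batch_size_eval: int = 1
    max_epochs: int = 200
    base_lr: float = 0.002
    lr_decay_factor: float = 0.95
    lr_decay_interval_epochs: int = 10
    optimizer_name: str = "rmsprop"
    l2_weight: float = 1e-4
    kernel_maxnorm: float = 2.0
    n_folds: int = 5
    test_fraction: float = 0.2
    val_fraction: float = 0.15
    augment: bool = True

    @model_validator(mode="after")
    def _ranges(self):
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if not 0 < self.lr_decay_factor <= 1:
            raise ValueError("lr_decay_factor must lie in (0, 1]")
        if self.batch_size_train < 1 or self.batch_size_eval < 1:
            raise ValueError("batch sizes must be >= 1")
        return self


class StrataSection(_Strict):
    menarche_threshold_years: float = MENARCHE_THRESHOLD_YEARS
    tumor_size_threshold_mm: float = TUMOR_SIZE_THRESHOLD_MM


class RunConfig(_Strict):
    seed: int = 0
    out_dir: str = "runs/default"
    phantom: PhantomSection = PhantomSection()
    preprocess: PreprocessSection = PreprocessSection()
    model: ModelSection = ModelSection()
    train: TrainSection = TrainSection()
    strata: StrataSection = StrataSection()

    # -- adapters to the library dataclasses -------------------------------
    def phantom_spec(self):
        from .synthetic import PhantomSpec

        p = self.phantom
        return PhantomSpec(
            image_side=p.image_side, n_channels=p.n_channels,
            lesion_radius_range=(p.lesion_radius_min, p.lesion_radius_max),
            spiculation_amplitude=p.spiculation_amplitude,
            ring_contrast=p.ring_contrast,
            background_noise_scale=p.background_noise_scale, seed=self.seed,
        )

    def cambnet_config(self):
        from .model import CambnetConfig

        m = self.model
        return CambnetConfig(
            input_side=self.preprocess.side, n_classes=m.n_classes,
            se_reduction_ratio=m.se_reduction_ratio,
            dropout_rate=m.dropout_rate,
            attention_kernel_size=m.attention_kernel_size,
            cross_wiring=m.cross_wiring,
            attention_dual_path=m.attention_dual_path,
        )

    def train_config(self):
        from .training import TrainConfig

        t = self.train
        return TrainConfig(
            batch_size_train=t.batch_size_train, batch_size_eval=t.batch_size_eval,
            max_epochs=t.max_epochs, base_lr=t.base_lr,
            lr_decay_factor=t.lr_decay_factor,
            lr_decay_interval_epochs=t.lr_decay_interval_epochs,
            optimizer_name=t.optimizer_name, l2_weight=t.l2_weight,
            kernel_maxnorm=t.kernel_maxnorm, seed=self.seed,
            n_folds=t.n_folds, test_fraction=t.test_fraction,
            val_fraction=t.val_fraction, augment=t.augment,
        )


class ConfigError(ValueError):
    """Configuration parse/validation failure, with key paths."""


def validate_config(raw: str | dict | None) -> RunConfig:
    """Parse a YAML document (or dict) into a validated :class:`RunConfig`.

    An empty document yields the full default set.
    """
    if raw is None:
        doc = {}
    elif isinstance(raw, str):
        doc = yaml.safe_load(raw) or {}
    else:
        doc = raw
    if not isinstance(doc, dict):
        raise ConfigError(f"config document must be a mapping, got {type(doc).__name__}")
    try:
        return RunConfig(**doc)
    except ValidationError as err:
        paths = "; ".join(
            ".".join(str(p) for p in e["loc"]) + ": " + e["msg"]
            for e in err.errors()
        )
        raise ConfigError(f"invalid config: {paths}") from err


def load_config(path) -> RunConfig:
    return validate_config(Path(path).read_text())


def dump_config(config: RunConfig) -> str:
    return yaml.safe_dump(config.model_dump(), sort_keys=False)


def config_hash(config: RunConfig) -> str:
    import hashlib

    return hashlib.sha256(dump_config(config).encode()).hexdigest()[:16]


__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config",
           "dump_config", "config_hash"]
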