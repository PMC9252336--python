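"""Experiment configuration: dataclasses, YAML round-trip, validation.

Validation is collected, not fail-fast: every violated invariant and every
unknown key is reported in a single :class:`ConfigError`, so a config file
can be fixed in one pass.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import yaml

from .cohort import CohortConfig, CohortConfigError
from .losses import LOSS_NAMES, LossParams
from .network import NetworkSpec
from .preprocessing import EraseParams
from .training import TrainConfig

__all__ = [
    "TASKS",
    "ConfigError",
    "PreprocessingConfig",
    "NetworkConfig",
    "LossConfig",
    "CohortSource",
    "ExperimentConfig",
    "load_config",
    "save_config",
    "validate_config",
]

TASKS = ("pd_vs_hc", "early_vs_modadv", "early_pd_vs_hc")


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""


@dataclass(frozen=True)
class PreprocessingConfig:
    """Pipeline settings between the raw table and the network input."""
    smote_k: int = 5
    test_fraction: float = 0.3
    elevation_side: int = 117
    image_side: int = 112
    split_first: bool = False       # leak-free variant: split before SMOTE
    val_fraction: float = 0.15      # carved from the training partition
    paper_faithful: bool = False    # monitor the test set during training
    erase_probability: float = 0.5
    erase_area_range: tuple[float, float] = (0.02, 0.33)
    erase_aspect_range: tuple[float, float] = (0.3, 3.3)
    erase_fill: str = "uniform-random"

    def erase_params(self) -> EraseParams:
        return EraseParams(self.erase_probability, tuple(self.erase_area_range),
                           tuple(self.erase_aspect_range), self.erase_fill)

    def problems(self) -> list[str]:
        out = []
        if self.smote_k < 1:
            out.append(f"preprocessing.smote_k must be >= 1, got {self.smote_k}")
        if not 0.0 < self.test_fraction < 1.0:
            out.append(f"preprocessing.test_fraction must be in (0, 1), "
                       f"got {self.test_fraction}")
        if self.elevation_side < 2 or self.image_side < 2:
            out.append("preprocessing elevation_side and image_side must be >= 2")
        if not 0.0 < self.val_fraction < 1.0:
            out.append(f"preprocessing.val_fraction must be in (0, 1), "
                       f"got {self.val_fraction}")
        try:
            self.erase_params().validate()
        except ValueError as exc:
            out.append(f"preprocessing erase settings: {exc}")
        return out


@dataclass(frozen=True)
class NetworkConfig:
    """Channel plan; the input side is taken from preprocessing.image_side."""
    stem_channels: int = 64
    layer_channels: tuple[int, ...] = (128, 256, 512)
    units_per_layer: int = 2

    def spec(self, input_side: int) -> NetworkSpec:
        return NetworkSpec(input_side=input_side, stem_channels=self.stem_channels,
                           layer_channels=tuple(self.layer_channels),
                           units_per_layer=self.units_per_layer)

    @classmethod
    def compact(cls) -> "NetworkConfig":
        return cls(stem_channels=8, layer_channels=(16, 32, 64))

    def problems(self, input_side: int) -> list[str]:
        try:
            self.spec(input_side).validate()
        except ValueError as exc:
            return [f"network: {exc}"]
        return []


@dataclass(frozen=True)
class LossConfig:
    name: str = "improved_focal"
    gamma: float = 2.0
    tau: float = 0.05

    def params(self) -> LossParams:
        return LossParams(gamma=self.gamma, tau=self.tau)

    def problems(self) -> list[str]:
        out = []
        if self.name not in LOSS_NAMES:
            out.append(f"loss.name must be one of {LOSS_NAMES}, got {self.name!r}")
        try:
            self.params()
        except ValueError as exc:
            out.append(f"loss: {exc}")
        return out


@dataclass(frozen=True)
class CohortSource:
    """Where the subject table comes from: the generator or a CSV file."""
    kind: str = "synthetic"
    path: str | None = None
    config: CohortConfig = field(default_factory=CohortConfig)

    def problems(self) -> list[str]:
        out = []
        if self.kind not in ("synthetic", "csv"):
            out.append(f"cohort.kind must be 'synthetic' or 'csv', got {self.kind!r}")
        if self.kind == "csv" and not self.path:
            out.append("cohort.path is required when cohort.kind = 'csv'")
        try:
            self.config.validate()
        except CohortConfigError as exc:
            out.append(f"cohort.config: {exc}")
        return out


@dataclass(frozen=True)
class ExperimentConfig:
    task: str = "pd_vs_hc"
    seed: int = 0
    output_dir: str | None = None
    cohort: CohortSource = field(default_factory=CohortSource)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    loss: LossConfig = field(default_factory=LossConfig)

    @classmethod
    def compact(cls, task: str = "pd_vs_hc", seed: int = 0,
                cohort: CohortConfig | None = None,
                max_epochs: int = 25, **train_overrides) -> "ExperimentConfig":
        """Desk-scale preset: elevation 24 -> image 20, narrow channels."""
        return cls(
            task=task, seed=seed,
            cohort=CohortSource(config=cohort or CohortConfig()),
            preprocessing=PreprocessingConfig(elevation_side=24, image_side=20),
            network=NetworkConfig.compact(),
            training=TrainConfig(max_epochs=max_epochs, **train_overrides),
        )


_SECTION_TYPES = {
    "cohort": CohortSource,
    "preprocessing": PreprocessingConfig,
    "network": NetworkConfig,
    "training": TrainConfig,
    "loss": LossConfig,
}


def _from_dict(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section {path!r} must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown key(s) under {path!r}: {unknown}")
    kwargs = {}
    for key, value in data.items():
        if cls is CohortSource and key == "config" and isinstance(value, dict):
            kwargs[key] = _from_dict(CohortConfig, value, f"{path}.config")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(data: dict) -> ExperimentConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    top_fields = {f.name for f in fields(ExperimentConfig)}
    unknown = sorted(set(data) - top_fields)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {unknown}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            kwargs[key] = _from_dict(_SECTION_TYPES[key], value or {}, key)
        else:
            kwargs[key] = value
    return ExperimentConfig(**kwargs)


def validate_config(config: ExperimentConfig) -> ExperimentConfig:
    """Check every invariant; raise :class:`ConfigError` listing all failures."""
    problems: list[str] = []
    if config.task not in TASKS:
        problems.append(f"task must be one of {TASKS}, got {config.task!r}")
    problems += config.cohort.problems()
    problems += config.preprocessing.problems()
    problems += config.network.problems(config.preprocessing.image_side)
    try:
        config.training.validate()
    except ValueError as exc:
        problems.append(f"training: {exc}")
    problems += config.loss.problems()
    if problems:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(problems))
    return config


def load_config(path) -> ExperimentConfig:
    """Load and fully validate a YAML experiment configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return validate_config(config_from_dict(data))


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)
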