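"""Run configuration: one YAML file (plus overrides) drives the pipeline."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .classifier import ConfigurationError, GeometricAugmentParams


@dataclasses.dataclass
class RunConfig:
    """Everything a reproducible end-to-end run needs.

    Defaults mirror the staged training protocol (phase settings live in
    :class:`~danioscope.classifier.PhaseConfig`); an empty config therefore
    reproduces the protocol shape on synthetic data.
    """

    master_seed: int = 0
    out_dir: str = "runs"
    backbone: str = "tiny"
    images_per_class: int = 50
    test_images_per_class: int = 20
    image_size: int | None = None  # default: the backbone's input size
    evaluation_ks: tuple[int, ...] = (1, 2, 3)
    phase_overrides: dict = dataclasses.field(default_factory=dict)
    augmentation: GeometricAugmentParams = dataclasses.field(
        default_factory=GeometricAugmentParams
    )
    red_boost: bool = False
    # dose-response simulation settings (used when no CSV is supplied)
    lc50_true: float = 0.64
    slope_true: float = 3.0
    concentrations: tuple[float, ...] = (0.05, 0.1, 0.25, 0.5, 1.0, 1.5, 2.0)
    n_per_dose: int = 20
    dose_response_csv: str | None = None

    def __post_init__(self) -> None:
        ks = tuple(int(k) for k in self.evaluation_ks)
        if not ks or any(k not in (1, 2, 3) for k in ks):
            raise ConfigurationError("evaluation_ks must be a non-empty subset of {1, 2, 3}")
        self.evaluation_ks = ks
        if isinstance(self.augmentation, dict):
            self.augmentation = GeometricAugmentParams(**self.augmentation)
        if self.images_per_class < 5 or self.test_images_per_class < 1:
            raise ConfigurationError("need >= 5 training and >= 1 test images per class")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["evaluation_ks"] = list(self.evaluation_ks)
        data["concentrations"] = list(self.concentrations)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
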