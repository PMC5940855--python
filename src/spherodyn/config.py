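"""Run configuration: a flat, YAML-serializable key namespace.

Every analysis parameter lives here with a default, and the fully resolved
configuration is echoed into the per-replicate parameter CSV so that any run
can be reproduced from its own outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import yaml

VALID_MODES = ("volume_3d", "per_frame_2d")
VALID_ENCLOSING = ("centroid", "welzl")
VALID_MODELS = ("linear", "quadratic", "exponential")


class ConfigError(ValueError):
    """Raised when a configuration value is invalid."""


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline, with defaults.

    Units: frame_interval in minutes, sigma_xy in pixels, sigma_t in frames,
    areas in px^2, prune_length in px.
    """

    # experiment
    input_root: Optional[str] = None
    output_root: Optional[str] = None
    frame_interval: float = 10.0  # minutes
    z_planes: int = 1
    pixel_size: Optional[float] = None  # um/px, informational only
    seed: int = 0

    # preprocessing
    sigma_xy: float = 1.5
    sigma_t: float = 1.0

    # segmentation
    mode: str = "volume_3d"
    lambda_spatial: float = 1.0
    lambda_temporal: float = 1.0
    contrast_sigma: Any = "auto"  # "auto" or positive float
    fill_holes: bool = True
    min_object_area: int = 4

    # morphometry
    prune_length: int = 5
    single_cell_min_area: int = 10
    single_cell_max_area: int = 500
    enclosing_mode: str = "centroid"

    # dynamics
    models: Sequence[str] = field(
        default_factory=lambda: ["linear", "quadratic", "exponential"]
    )
    welch: bool = False
    bh_correction: bool = False
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be > 0 minutes")
        if self.z_planes < 1:
            raise ConfigError("z_planes must be >= 1")
        if self.sigma_xy <= 0:
            raise ConfigError("sigma_xy must be > 0 px")
        if self.sigma_t < 0:
            raise ConfigError("sigma_t must be >= 0 frames")
        if self.mode not in VALID_MODES:
            raise ConfigError(f"mode must be one of {VALID_MODES}, got {self.mode!r}")
        if self.lambda_spatial < 0 or self.lambda_temporal < 0:
            raise ConfigError("lambda_spatial and lambda_temporal must be >= 0")
        if self.contrast_sigma != "auto":
            if not isinstance(self.contrast_sigma, (int, float)) or self.contrast_sigma <= 0:
                raise ConfigError("contrast_sigma must be 'auto' or a positive number")
        if self.min_object_area < 0:
            raise ConfigError("min_object_area must be >= 0")
        if self.enclosing_mode not in VALID_ENCLOSING:
            raise ConfigError(
                f"enclosing_mode must be one of {VALID_ENCLOSING}, got {self.enclosing_mode!r}"
            )
        bad = [m for m in self.models if m not in VALID_MODELS]
        if bad or not self.models:
            raise ConfigError(f"models must be a non-empty subset of {VALID_MODELS}")
        if not 0 < self.ci_level < 1:
            raise ConfigError("ci_level must lie in (0, 1)")

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
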