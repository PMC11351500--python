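"""Pipeline configuration.

One flat dataclass holds every tunable parameter of the pipeline; the CLI and
:func:`veinwidth.pipeline.run_pipeline` take a :class:`PipelineConfig` and the
YAML round trip (``load_config`` / ``save_config``) is a fixed point.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Tuple

import yaml

from .errors import ConfigurationError

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """All pipeline parameters with their defaults.

    Units are pixels and 8-bit intensities unless noted.  The level-set
    Dirac width ``ls_eps`` defaults to 2; the segmentation smoothing scale
    ``ls_sigma`` and the Canny parameters have conventional defaults since
    no canonical values exist for this imaging setup.
    """

    # -- preprocessing ------------------------------------------------------
    crop_box: Optional[Tuple[int, int, int, int]] = None  # (r0, r1, c0, c1), half-open
    crop_margin: int = 3
    stretch_low_pct: float = 1.0
    stretch_high_pct: float = 99.0
    median_window: int = 3
    enhance_mode: str = "unsharp"  # off | unsharp | autoencoder
    unsharp_amount: float = 1.0
    unsharp_sigma: float = 2.0
    enhance_model: Optional[str] = None  # user-supplied model for autoencoder mode
    clahe_clip: float = 0.01  # fraction of tile pixel count
    clahe_tiles: Tuple[int, int] = (8, 8)

    # -- level-set segmentation --------------------------------------------
    ls_sigma: float = 1.5
    ls_eps: float = 2.0
    ls_dt: float = 1.0
    ls_mu: float = 0.2  # needs mu * dt < 0.25 for stability
    ls_lambda: float = 5.0
    ls_alpha: float = -1.5  # negative: expand the dark-vessel region
    ls_steps: int = 200
    min_area: int = 30
    keep_components: int = 1  # how many largest mask components survive

    # -- Canny edge detection ----------------------------------------------
    canny_eta: float = 1.0
    canny_low: float = 0.1  # relative to max gradient magnitude
    canny_high: float = 0.2
    canny_absolute: bool = False
    edge_source: str = "mask"  # mask | image: where RETC edges come from

    # -- RETC ---------------------------------------------------------------
    r_max: Optional[int] = None  # default min(image dims) at run time
    r_step: int = 1
    edge_offset: str = "outside"  # inside | outside: edge pixel convention

    # -- skeletonization ----------------------------------------------------
    max_thin_iters: int = 100
    prune_spurs: int = 0  # minimum branch length kept; 0 disables pruning

    seed: int = 0

    def __post_init__(self) -> None:
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ConfigurationError("median_window must be odd and >= 3")
        if not (0 <= self.stretch_low_pct < self.stretch_high_pct <= 100):
            raise ConfigurationError("stretch percentiles must satisfy 0 <= low < high <= 100")
        if self.enhance_mode not in ("off", "unsharp", "autoencoder"):
            raise ConfigurationError(f"unknown enhance_mode {self.enhance_mode!r}")
        if self.clahe_clip <= 0:
            raise ConfigurationError("clahe_clip must be positive")
        self.clahe_tiles = tuple(self.clahe_tiles)
        if len(self.clahe_tiles) != 2 or min(self.clahe_tiles) < 1:
            raise ConfigurationError("clahe_tiles must be a pair of positive counts")
        if self.ls_eps <= 0 or self.ls_sigma <= 0 or self.ls_dt <= 0:
            raise ConfigurationError("ls_eps, ls_sigma and ls_dt must be positive")
        if not (0 <= self.canny_low < self.canny_high):
            raise ConfigurationError("canny thresholds must satisfy 0 <= low < high")
        if self.edge_source not in ("mask", "image"):
            raise ConfigurationError(f"unknown edge_source {self.edge_source!r}")
        if self.edge_offset not in ("inside", "outside"):
            raise ConfigurationError(f"unknown edge_offset {self.edge_offset!r}")
        if self.r_step < 1:
            raise ConfigurationError("r_step must be >= 1")
        if self.crop_box is not None:
            self.crop_box = tuple(int(v) for v in self.crop_box)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clahe_tiles"] = list(self.clahe_tiles)
        if self.crop_box is not None:
            d["crop_box"] = list(self.crop_box)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> PipelineConfig:
    """Parse a YAML config file into a :class:`PipelineConfig`."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} must hold a mapping")
    return PipelineConfig.from_dict(data)


def save_config(cfg: PipelineConfig, path) -> None:
    """Serialize a config to YAML (inverse of :func:`load_config`)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
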