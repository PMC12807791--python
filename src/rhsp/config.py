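"""Analysis configuration with YAML/JSON round-tripping.

Every tunable of the pipeline lives here so that a run's resolved
configuration can be embedded verbatim in its output report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class FovConfig:
    """Field-of-view extraction settings.

    ``min_offset`` is the distance from the frame centre (pixels) at which
    the outward scan for all-zero overlay rows/columns begins; ``trim_rows``
    rows are removed from the top and bottom of the cropped volume, where
    surface reflections and weak deep signal make the image unreliable.
    """

    min_offset: int = 50
    trim_rows: int = 10
    overlay_value: int = 0


@dataclass
class NLMConfig:
    """Non-local-means denoising: full window/patch widths in pixels.

    The denoise strength is sigma0 / strength_divisor where sigma0 is the
    standard deviation of the whole uncorrected volume x0.
    """

    search_window: int = 9
    patch_size: int = 3
    strength_divisor: float = 8.0

    def validate(self) -> None:
        if self.search_window % 2 == 0 or self.patch_size % 2 == 0:
            raise ConfigurationError("NLM window and patch sizes must be odd")
        if self.search_window <= self.patch_size:
            raise ConfigurationError("NLM search window must exceed patch size")
        if self.strength_divisor <= 0:
            raise ConfigurationError("strength_divisor must be positive")


@dataclass
class BiasConfig:
    """N4 bias-field correction settings.

    ``control_points`` is the B-spline control grid as (depth, lateral,
    elevational); depth gets the densest grid because attenuation makes the
    image far more inhomogeneous along depth than in-plane.
    """

    control_points: tuple[int, int, int] = (8, 4, 4)
    max_iterations: int = 50
    convergence_threshold: float = 1e-3
    shrink_factor: int = 2

    def validate(self) -> None:
        if len(self.control_points) != 3 or any(c < 2 for c in self.control_points):
            raise ConfigurationError("bias control_points must be three ints >= 2")
        if self.shrink_factor < 1:
            raise ConfigurationError("shrink_factor must be >= 1")


@dataclass
class ThresholdConfig:
    """Depth-adaptive segmentation threshold settings.

    The volume is split into ``n_slabs`` depth slabs; each slab's threshold
    is background_peak − k_sigma × mirrored_std over an ``n_bins`` histogram.
    """

    n_slabs: int = 10
    k_sigma: float = 2.0
    n_bins: int = 256


@dataclass
class MorphologyConfig:
    opening_iterations: int = 3


@dataclass
class SphereConfig:
    """Sphere geometry and watershed/area-filter settings."""

    diameter_mm: float = 2.0
    alpha1: float = 0.5
    alpha2: float = 1.25
    min_seed_distance: int = 5
    exclude_edge_spheres: bool = True

    def validate(self) -> None:
        if self.diameter_mm <= 0:
            raise ConfigurationError("sphere diameter must be positive")
        if not 0 < self.alpha1 <= self.alpha2:
            raise ConfigurationError("need 0 < alpha1 <= alpha2")


@dataclass
class LSNRConfig:
    """Per-sphere LSNR measurement and depth-curve settings."""

    n_curve_slabs: int = 25
    erosion_px: int = 3
    dilation_px: int = 1
    cylinder_diameter_factor: float = 4.0
    min_background_voxels: int = 100


@dataclass
class AnalysisConfig:
    """Bundle of all pipeline settings plus optional spacing overrides (mm)."""

    fov: FovConfig = field(default_factory=FovConfig)
    nlm: NLMConfig = field(default_factory=NLMConfig)
    bias: BiasConfig = field(default_factory=BiasConfig)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    morphology: MorphologyConfig = field(default_factory=MorphologyConfig)
    sphere: SphereConfig = field(default_factory=SphereConfig)
    lsnr: LSNRConfig = field(default_factory=LSNRConfig)
    pixel_spacing_mm: tuple[float, float] | None = None  # (axial, lateral) override

    def validate(self) -> "AnalysisConfig":
        self.nlm.validate()
        self.bias.validate()
        self.sphere.validate()
        if self.threshold.n_slabs < 1 or self.threshold.n_bins < 2:
            raise ConfigurationError("invalid threshold config")
        if self.pixel_spacing_mm is not None and any(s <= 0 for s in self.pixel_spacing_mm):
            raise ConfigurationError("pixel spacing must be positive")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # tuples -> lists for clean YAML/JSON round trips
        return json.loads(json.dumps(d))

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs = {}
        sections = {
            "fov": FovConfig,
            "nlm": NLMConfig,
            "bias": BiasConfig,
            "threshold": ThresholdConfig,
            "morphology": MorphologyConfig,
            "sphere": SphereConfig,
            "lsnr": LSNRConfig,
        }
        for key, typ in sections.items():
            if key in d and d[key] is not None:
                known = {f.name for f in dataclasses.fields(typ)}
                extra = set(d[key]) - known
                if extra:
                    raise ConfigurationError(f"unknown keys in '{key}': {sorted(extra)}")
                kwargs[key] = typ(**d[key])
        if d.get("pixel_spacing_mm") is not None:
            kwargs["pixel_spacing_mm"] = tuple(d["pixel_spacing_mm"])
        cfg = cls(**kwargs)
        if "bias" in kwargs:
            cfg.bias.control_points = tuple(cfg.bias.control_points)
        return cfg.validate()

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def save(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2))
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))
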