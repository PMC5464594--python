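"""Configuration objects for the segmentation pipeline.

Every tunable of the feature maps and the level-set evolution lives here,
with JSON round-tripping so a run's exact configuration can be captured
beside its outputs and replayed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class GacParams:
    """Level-set evolution weights and stopping rules.

    The three weights are dimensionless multipliers of the propagation
    (balloon), curvature-smoothing and edge-advection terms.  ``dt`` is
    normally derived from the CFL condition each run; setting it overrides
    the automatic step (useful for controlled experiments).
    """

    propagation_weight: float = 1.0
    curvature_weight: float = 0.3
    advection_weight: float = 1.0
    max_iterations: int = 500
    rms_tolerance: float = 1e-3
    init_radius_mm: float = 2.0
    reinit_interval: int = 20
    cfl: float = 0.45
    dt: float | None = None

    def __post_init__(self) -> None:
        if self.max_iterations <= 0:
            raise ValueError("max_iterations must be > 0")
        if self.rms_tolerance <= 0:
            raise ValueError("rms_tolerance must be > 0")
        for name in ("propagation_weight", "curvature_weight", "advection_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.init_radius_mm <= 0:
            raise ValueError("init_radius_mm must be > 0")


@dataclass
class SegmentationConfig:
    """All feature-map and pipeline parameters.

    Density sigmoid: ``alpha`` is the HU softness scale and ``beta`` the HU
    midpoint; solid nodules use beta = -200 HU, non-solid (part-solid or
    ground-glass) use beta = -500 HU, so parenchymal air is strongly
    down-weighted while nodular densities pass.
    """

    crop_radius_mm: float = 30.0
    sigmoid_alpha: float = 100.0
    sigmoid_beta_solid: float = -200.0
    sigmoid_beta_nonsolid: float = -500.0
    sato_scales_mm: tuple[float, ...] = (1.0, 2.0, 4.0)
    canny_sigma_mm: float = 1.0
    canny_low_pct: float = 70.0
    canny_high_pct: float = 90.0
    lung_threshold_hu: float = -500.0
    closing_radius_vox: int = 3
    use_chest_wall_map: bool = True
    use_vessel_map: bool = True
    use_edge_map: bool = True
    gac: GacParams = field(default_factory=GacParams)

    def __post_init__(self) -> None:
        if isinstance(self.gac, dict):
            self.gac = GacParams(**self.gac)
        self.sato_scales_mm = tuple(float(s) for s in self.sato_scales_mm)
        if self.crop_radius_mm <= 0:
            raise ValueError("crop_radius_mm must be > 0")
        if self.sigmoid_alpha == 0:
            raise ValueError("sigmoid_alpha must be non-zero")
        if not (0 <= self.canny_low_pct <= self.canny_high_pct <= 100):
            raise ValueError("canny percentiles must satisfy 0 <= low <= high <= 100")

    def beta_for(self, texture_class: str) -> float:
        """Density-sigmoid midpoint for a texture class."""
        if texture_class == "solid":
            return self.sigmoid_beta_solid
        if texture_class in ("part_solid", "ground_glass", "nonsolid", "non_solid"):
            return self.sigmoid_beta_nonsolid
        raise ValueError(f"unknown texture class {texture_class!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationConfig":
        return cls(**d)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "SegmentationConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
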