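"""Validated run configuration (YAML/JSON) for the pipeline commands.

The schema is strict: unknown keys are rejected, and ``RunConfig()`` with no
arguments reproduces the documented defaults (printable via
``RunConfig().model_dump()``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .phantom import PhantomConfig
from .synth import GeneratorSpec, WeightModel
from .transport import OpticalProperties, default_optics

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Strict):
    lateral_extent_mm: float = 20.0
    depth_extent_mm: float = 20.0
    skin_thickness_mm: float = 0.75
    fat_thickness_mm: float = 0.75
    implant_radius_mm: float = 4.0
    implant_thickness_mm: float = 2.0
    implant_top_depth_mm: float = 1.5
    collagen_thickness_um: float = 100.0

    def build(self) -> PhantomConfig:
        return PhantomConfig(
            lateral_extent=self.lateral_extent_mm,
            depth_extent=self.depth_extent_mm,
            skin_thickness=self.skin_thickness_mm,
            fat_thickness=self.fat_thickness_mm,
            implant_radius=self.implant_radius_mm,
            implant_thickness=self.implant_thickness_mm,
            implant_top_depth=self.implant_top_depth_mm,
            collagen_thickness_um=self.collagen_thickness_um,
        )


class MaterialOpticsSection(_Strict):
    mua: float
    musp: float
    n: float = 1.4


class DiscretizationSection(_Strict):
    base_spacing_mm: float = 0.6
    refined_spacing_mm: float = 0.08


class GridSection(_Strict):
    n_per_axis: int = 21
    half_extent_mm: float = 5.0


class GeneratorSection(_Strict):
    axis_start_cm1: float = 800.0
    axis_stop_cm1: float = 1800.0
    axis_step_cm1: float = 2.0
    count_scale: float = 1.0e4
    poisson_noise: bool = True
    target_snr_at_100um: float | None = None
    thicknesses_um: list[float] = Field(
        default_factory=lambda: [10, 20, 40, 60, 80, 100, 150, 200])
    replicates: int = 2
    weight_skin: float = 1.0
    weight_fat: float = 0.5
    weight_muscle: float = 0.2
    weight_polystyrene: float = 0.3
    collagen_weight_per_um: float = 0.0025

    def build_spec(self, seed: int) -> GeneratorSpec:
        return GeneratorSpec(
            axis_start=self.axis_start_cm1,
            axis_stop=self.axis_stop_cm1,
            axis_step=self.axis_step_cm1,
            count_scale=self.count_scale,
            poisson_noise=self.poisson_noise,
            seed=seed,
        )

    def build_weights(self) -> WeightModel:
        return WeightModel(
            base={
                "skin": self.weight_skin,
                "fat": self.weight_fat,
                "muscle": self.weight_muscle,
                "polystyrene": self.weight_polystyrene,
            },
            collagen_per_um=self.collagen_weight_per_um,
        )


class BandSection(_Strict):
    collagen_band_cm1: tuple[float, float] = (910.0, 950.0)
    baseline_edge_channels: int = 3
    normalization_window_cm1: tuple[float, float] = (990.0, 1020.0)


class InstrumentSection(_Strict):
    preset: Literal["point-point", "linear"] = "linear"
    laser_power_mw: float = 45.0
    line_length_mm: float = 10.0
    line_width_mm: float = 2.0
    point_diameter_mm: float = 0.1
    detector_area_mm2: float = 0.01


class RunConfig(_Strict):
    """Top-level configuration for `drs` commands."""

    phantom: PhantomSection = Field(default_factory=PhantomSection)
    optics: dict[str, MaterialOpticsSection] | None = None
    discretization: DiscretizationSection = Field(default_factory=DiscretizationSection)
    grid: GridSection = Field(default_factory=GridSection)
    generator: GeneratorSection = Field(default_factory=GeneratorSection)
    bands: BandSection = Field(default_factory=BandSection)
    instrument: InstrumentSection = Field(default_factory=InstrumentSection)
    output_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"

    def build_optics(self) -> OpticalProperties:
        if self.optics is None:
            return default_optics()
        return OpticalProperties.from_dict(
            {m: s.model_dump() for m, s in self.optics.items()})


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML/JSON config file (None → defaults)."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text())
    return RunConfig.model_validate(data or {})
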