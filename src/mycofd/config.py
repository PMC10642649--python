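"""Pipeline configuration schema.

YAML configs are validated with pydantic before any computation; unknown
keys are rejected so typos fail fast instead of silently using defaults.
Every run writes a resolved copy of its configuration next to its outputs
for provenance.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .preprocess import KuwaharaConfig, ThresholdMethod
from .fractal import DEFAULT_SIZES, FDPipelineConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KuwaharaSection(_Strict):
    variant: Literal["classic", "linear"] = "linear"
    window: int = 5
    n_orientations: int = 8

    def to_obj(self) -> KuwaharaConfig:
        cfg = KuwaharaConfig(self.variant, self.window, self.n_orientations)
        cfg.validate()
        return cfg


class ThresholdSection(_Strict):
    name: Literal["isodata", "otsu", "huang", "fixed"] = "isodata"
    fixed_value: int | None = None

    def to_obj(self) -> ThresholdMethod:
        method = ThresholdMethod(self.name, self.fixed_value)
        method.validate()
        return method


class PreprocessSection(_Strict):
    kuwahara: KuwaharaSection = Field(default_factory=KuwaharaSection)
    threshold: ThresholdSection = Field(default_factory=ThresholdSection)


class FDSection(_Strict):
    sizes: list[int] = Field(default_factory=lambda: list(DEFAULT_SIZES))
    min_scales: int = 3
    persist_intermediates: bool = False

    @field_validator("sizes")
    @classmethod
    def _increasing(cls, v: list[int]) -> list[int]:
        if len(v) < 3 or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("fd.sizes must be >= 3 strictly increasing integers")
        return v


class ColourSection(_Strict):
    min_particle_px: int = 0
    threshold: Literal["huang", "fixed"] = "huang"
    fixed_value: int | None = None


class MyceliumCondition(_Strict):
    name: str
    n_images: int = 3
    params: dict = Field(default_factory=dict)  # overrides of MyceliumParams fields


class FixtureSection(_Strict):
    kind: Literal["line", "filled_square", "sierpinski_carpet", "random_dust"]
    size_px: int
    level: int | None = None
    density: float | None = None


class DropEntry(_Strict):
    centre: list[float]
    radius: float
    red_fraction: float


class DropSceneSection(_Strict):
    name: str
    width_px: int = 640
    height_px: int = 480
    noise_sd: float = 4.0
    drops: list[DropEntry] = Field(default_factory=list)


class SimulateSection(_Strict):
    mycelium: list[MyceliumCondition] = Field(default_factory=list)
    fixtures: list[FixtureSection] = Field(default_factory=list)
    drop_scenes: list[DropSceneSection] = Field(default_factory=list)


class InputSection(_Strict):
    """External images instead of (or besides) simulated ones."""

    images: str | None = None  # glob, relative to the config file
    roi_suffix: str = ".roi.json"


class AnalysisSection(_Strict):
    name: str
    input: Literal["fd", "colour"]
    value: str
    factor_a: str
    factor_b: str | None = None
    tukey: bool = True
    welch: bool = False


class StatsSection(_Strict):
    analyses: list[AnalysisSection] = Field(default_factory=list)


class PipelineConfig(_Strict):
    version: int = 1
    seed: int = 0
    output_dir: str = "out"
    log_level: str = "INFO"
    inputs: InputSection = Field(default_factory=InputSection)
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    fd: FDSection = Field(default_factory=FDSection)
    colour: ColourSection = Field(default_factory=ColourSection)
    stats: StatsSection = Field(default_factory=StatsSection)

    def fd_pipeline_config(self) -> FDPipelineConfig:
        return FDPipelineConfig(
            kuwahara=self.preprocess.kuwahara.to_obj(),
            threshold=self.preprocess.threshold.to_obj(),
            sizes=tuple(self.fd.sizes),
            min_scales=self.fd.min_scales,
        )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=True)
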