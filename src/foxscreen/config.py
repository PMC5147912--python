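"""Run configuration: schema-validated, rejects unknown keys.

Every numeric constant the pipeline uses lives here with its assay default:
the 1.8 N/C-ratio cutoff, the 60% hit threshold, the 4 nM positive-control
dose, segmentation and ring geometry, the minimum cell count for well QC,
and the fit options. A resolved copy is written next to every run's outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class NoiseConfig(_Strict):
    background_level: float = Field(100.0, ge=0)
    read_noise_sd: float = Field(3.0, ge=0)
    shot_noise: bool = True


class StateConfig(_Strict):
    """Per-state N/C ratio distributions of the simulator (log-normal)."""

    median_resting: float = Field(1.0, gt=0)
    median_translocated: float = Field(3.0, gt=0)
    sd_log: float = Field(0.2, gt=0)


class DoseModelConfig(_Strict):
    """Generative translocation dose model (concentrations in uM)."""

    bottom_fraction: float = Field(0.05, ge=0, le=1)
    top_fraction: float = Field(0.95, ge=0, le=1)
    ec50_uM: float = Field(1.5, gt=0)
    hill: float = 1.0

    @model_validator(mode="after")
    def _ordered(self):
        if not self.bottom_fraction < self.top_fraction:
            raise ValueError("bottom_fraction must be < top_fraction")
        return self


class SeriesConfig(_Strict):
    top_conc: float = Field(50.0, gt=0)
    fold: float = Field(2.0, gt=1)
    n_points: int = Field(8, ge=1)
    unit: str = "uM"


class SimulateConfig(_Strict):
    """Simulate-first mode: dose plate for one compound."""

    compound: str = "LOM612"
    series: SeriesConfig = SeriesConfig(n_points=12)
    replicates: int = Field(3, ge=1)  # assay wells run in triplicate
    n_negative: int = Field(8, ge=2)  # full first column
    n_positive: int = Field(8, ge=2)  # full last column
    cells_per_well: int = Field(150, ge=0)
    image_shape: tuple[int, int] = (560, 560)
    cyt_thickness: int = Field(6, ge=1)
    noise: NoiseConfig = NoiseConfig()
    states: StateConfig = StateConfig()
    dose_model: DoseModelConfig = DoseModelConfig()


class SegmentationConfig(_Strict):
    block_size: int = Field(51, ge=3)
    offset_frac: float = Field(0.02, ge=0)
    min_area: int = Field(40, ge=1)
    max_area: int = Field(4000, ge=1)
    ring_gap: int = Field(1, ge=0)
    ring_width: int = Field(4, ge=1)


class FitConfig(_Strict):
    direction: str = "increasing"
    min_span: float = Field(10.0, ge=0)


class RunConfig(_Strict):
    """Top-level pipeline configuration; one seed drives all randomness."""

    seed: int = 0
    input_dir: str | None = None  # read images + layout.csv from here ...
    simulate: SimulateConfig | None = None  # ... or simulate them first
    nc_threshold: float = Field(1.8, gt=0)
    hit_threshold: float = Field(60.0)
    lmb_conc_nM: float = Field(4.0, gt=0)  # positive-control dose, for the record
    intensity_mode: str = "mean"  # or "integrated"
    min_cells: int = Field(50, ge=0)
    segmentation: SegmentationConfig = SegmentationConfig()
    fit: FitConfig = FitConfig()

    @model_validator(mode="after")
    def _one_source(self):
        if (self.input_dir is None) == (self.simulate is None):
            raise ValueError("exactly one of input_dir / simulate must be set")
        if self.intensity_mode not in ("mean", "integrated"):
            raise ValueError("intensity_mode must be 'mean' or 'integrated'")
        return self

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def write_resolved(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.model_dump(), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
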