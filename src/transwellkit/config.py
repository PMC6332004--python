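"""Study configuration: input paths, thresholds, QSPR options, seed.

A :class:`StudyConfig` fully determines a pipeline run; it serializes
to YAML and round-trips losslessly, so a report can always be traced
back to the exact configuration that produced it.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = ["GeometryConfig", "Thresholds", "QsprOptions", "StudyConfig"]


class GeometryConfig(BaseModel):
    area_cm2: float = Field(1.12, gt=0)
    vol_ap_ml: float = Field(0.5, gt=0)
    vol_bl_ml: float = Field(1.5, gt=0)


class Thresholds(BaseModel):
    teer_ohm_cm2: float = Field(1000.0, gt=0)
    well_cutoff_cm_s: float = Field(1e-5, gt=0)
    poor_cutoff_cm_s: float = Field(1e-6, gt=0)
    passive_ratio_cutoff: float = Field(2.0, gt=0)
    pgp_high_band: float = Field(1.9, gt=1)
    pgp_low_band: float = Field(0.55, gt=0, lt=1)
    alpha: float = Field(0.01, gt=0, lt=0.5)
    recovery_min_pct: float = Field(85.0, ge=0, le=100)
    intracellular_max_pct: float = Field(7.0, ge=0, le=100)

    @model_validator(mode="after")
    def _cutoffs_ordered(self) -> "Thresholds":
        if not self.poor_cutoff_cm_s < self.well_cutoff_cm_s:
            raise ValueError("poor cutoff must lie below well cutoff")
        return self


class QsprOptions(BaseModel):
    x0: float = 2.5
    x0_scan: list[float] | None = None  # breakpoint grid; overrides x0 when set
    free_amplitude: bool = False
    plateau_threshold: float = Field(0.6, gt=0)


class StudyConfig(BaseModel):
    """Everything a :func:`transwellkit.pipeline.run_study` call needs."""

    transport_csv: Path | None = None
    calibration_csv: Path | None = None
    compounds_csv: Path | None = None
    fluorescence_csv: Path | None = None
    geometry: GeometryConfig = GeometryConfig()
    thresholds: Thresholds = Thresholds()
    qspr: QsprOptions = QsprOptions()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path: str | Path) -> None:
        data = self.model_dump(mode="json")
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
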