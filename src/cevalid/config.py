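"""Validated configuration objects for the simulator and the pipeline.

All configuration is pydantic-validated with ``extra="forbid"`` so that a
mistyped YAML key fails loudly instead of silently falling back to a default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class SimulationConfig(BaseModel):
    """Parameters of the synthetic electropherogram generator.

    The defaults emulate the ertapenem-sodium CE assay that this package
    validates: a six-level calibration from 70 to 120 µg/mL in triplicate,
    a corrected-area response law ``area = 2281.7·C − 24495``, a single
    analyte peak near 3.2 min, and replicate scatter at the pure-error level
    of the reference validation study.

    Units: concentrations in µg/mL, times in minutes, signal in mAU,
    corrected areas in mAU·min per minute of migration (instrument counts).
    """

    model_config = ConfigDict(extra="forbid")

    calibration_levels: list[float] = Field(
        default=[70.0, 80.0, 90.0, 100.0, 110.0, 120.0],
        description="nominal calibration concentrations, µg/mL",
    )
    replicates: int = Field(default=3, ge=1)
    response_slope: float = Field(default=2281.7, description="corrected-area units per µg/mL")
    response_intercept: float = Field(default=-24495.0, description="corrected-area units")
    noise_sd: float = Field(default=1657.0, ge=0.0, description="SD of corrected-area noise")
    migration_time: float = Field(default=3.2, gt=0.0, description="nominal apex time, min")
    migration_jitter_sd: float = Field(default=0.02, ge=0.0, description="SD of apex time, min")
    peak_sigma: float = Field(default=0.0306, gt=0.0, description="Gaussian peak SD, min")
    sampling_rate: float = Field(default=600.0, gt=0.0, description="detector samples per minute")
    run_length: float = Field(default=5.0, gt=0.0, description="acquisition window, min")
    baseline_level: float = Field(default=2.0, description="baseline offset, mAU")
    baseline_drift_slope: float = Field(default=0.1, description="baseline drift, mAU per min")
    baseline_noise_sd: float = Field(default=0.05, ge=0.0, description="detector noise SD, mAU")
    seed: int = Field(default=1234, ge=0)

    @model_validator(mode="after")
    def _check_physics(self) -> "SimulationConfig":
        if not self.calibration_levels:
            raise ValueError("calibration_levels must be non-empty")
        if min(self.calibration_levels) <= 0:
            raise ValueError("all calibration concentrations must be > 0")
        lowest = min(self.calibration_levels)
        if self.response_slope * lowest + self.response_intercept <= 0:
            raise ValueError(
                f"response law gives a non-positive target area at {lowest} µg/mL"
            )
        # the sampling grid must cover the peak out to ±6 sigma
        if self.migration_time - 6 * self.peak_sigma < 0:
            raise ValueError("run must start at least 6 peak sigmas before the apex")
        if self.migration_time + 6 * self.peak_sigma > self.run_length:
            raise ValueError("run_length too short: apex + 6 peak sigmas exceeds the window")
        return self


class RobustnessStudySpec(BaseModel):
    """Ground-truth specification of a simulated robustness study.

    ``factor_effects`` is the true content shift (% per unit level step) of
    each of the seven design factors; a method that is truly robust has all
    effects at zero and only ``noise_sd`` scatter between runs.
    """

    model_config = ConfigDict(extra="forbid")

    factor_effects: list[float] = Field(default=[0.0] * 7)
    base_content: float = Field(default=100.0)
    noise_sd: float = Field(default=0.3, ge=0.0, description="% content")
    seed: int = Field(default=1234, ge=0)

    @model_validator(mode="after")
    def _check_len(self) -> "RobustnessStudySpec":
        if len(self.factor_effects) != 7:
            raise ValueError(
                f"factor_effects must have 7 entries (one per design factor), "
                f"got {len(self.factor_effects)}"
            )
        return self


class RecoveryLevelSpec(BaseModel):
    """One spiking level of the standard-addition recovery assay."""

    model_config = ConfigDict(extra="forbid")

    label: str
    cu: float = Field(gt=0.0, description="formulation concentration, µg/mL")
    ca: float = Field(gt=0.0, description="standard spike added, µg/mL")


class PipelineConfig(BaseModel):
    """Everything `run_full_validation` needs, in one validated object."""

    model_config = ConfigDict(extra="forbid")

    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    robustness: RobustnessStudySpec = Field(default_factory=RobustnessStudySpec)
    rsd_limit: float = Field(default=2.0, gt=0.0, description="SST acceptance RSD, %")
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    sst_replicates: int = Field(default=10, ge=2)
    content_replicates: int = Field(default=3, ge=2)
    repeatability_replicates: int = Field(default=7, ge=2)
    precision_days: int = Field(default=3, ge=2)
    recovery_levels: list[RecoveryLevelSpec] = Field(
        default=[
            RecoveryLevelSpec(label="R1", cu=70.0, ca=10.0),
            RecoveryLevelSpec(label="R2", cu=70.0, ca=30.0),
            RecoveryLevelSpec(label="R3", cu=70.0, ca=50.0),
        ]
    )
    min_peak_height: float = Field(default=1.0, gt=0.0, description="detection threshold, mAU")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw: Any = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
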