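"""Pipeline configuration (YAML) and run manifests.

The YAML schema groups knobs by stage: ``imaging`` (pixel size, diameter
filter, segmentation), ``scoring`` (cutoff, QC threshold, measurement
days), ``calibration`` (ORR table, tie-break note), ``stats`` (resampling
count, CI method, alpha, seed) and ``paths``.  Defaults are the assay's
published operating points: cutoff 0.7, QC threshold 0.9, minimum
diameter 40 um.  Every run writes a manifest (config snapshot, input
checksums, package version, seed, per-stage row counts) so outputs are
traceable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Literal

import yaml
from pydantic import BaseModel, Field, ValidationError

__all__ = [
    "ImagingConfig",
    "ScoringConfig",
    "CalibrationConfig",
    "StatsConfig",
    "PipelineConfig",
    "RunManifest",
    "load_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """Configuration failed validation; message lists offending fields."""


class ImagingConfig(BaseModel):
    pixel_size_um: float = Field(1.0, gt=0)
    min_diameter_um: float = Field(40.0, ge=0)
    inclusive_diameter: bool = False
    polarity: Literal["auto", "dark", "bright"] = "auto"
    opening_radius_px: int = Field(3, ge=0)


class ScoringConfig(BaseModel):
    cutoff: float = Field(0.7, gt=0)
    qc_threshold: float = Field(0.9, gt=0)
    t0_day: int = Field(0, ge=0)
    t1_day: int = Field(7, ge=1)
    min_replicates: int = Field(2, ge=1)
    normalize_by_control: bool = False


class CalibrationConfig(BaseModel):
    orr_table: dict[str, float] = Field(default_factory=dict)


class StatsConfig(BaseModel):
    resampling_draws: int = Field(1000, ge=1)
    ci_method: Literal["delong", "bootstrap"] = "delong"
    bootstrap_draws: int = Field(2000, ge=1)
    alpha: float = Field(0.05, gt=0, lt=1)
    seed: int = 0


class PipelineConfig(BaseModel):
    imaging: ImagingConfig = Field(default_factory=ImagingConfig)
    scoring: ScoringConfig = Field(default_factory=ScoringConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    outdir: str = "ptcscreen_out"


def load_config(path: str | Path | None = None,
                overrides: dict[str, Any] | None = None) -> PipelineConfig:
    """Load and validate a pipeline config; raises ConfigError with field paths."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        for key, val in overrides.items():
            section, _, leaf = key.partition(".")
            if leaf:
                data.setdefault(section, {})[leaf] = val
            else:
                data[section] = val
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as err:
        fields = "; ".join(
            ".".join(str(p) for p in e["loc"]) + ": " + e["msg"]
            for e in err.errors()
        )
        raise ConfigError(f"invalid configuration: {fields}") from err


class RunManifest:
    """Traceability record for one pipeline run."""

    def __init__(self, config: PipelineConfig, seed: int, version: str):
        self.data: dict[str, Any] = {
            "config": config.model_dump(),
            "seed": seed,
            "software_version": version,
            "inputs": {},
            "stage_counts": {},
        }

    def record_input(self, path: str | Path) -> None:
        p = Path(path)
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        self.data["inputs"][str(p)] = digest

    def record_stage(self, stage: str, **counts: int) -> None:
        self.data["stage_counts"][stage] = counts

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.data, indent=2, default=str))
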