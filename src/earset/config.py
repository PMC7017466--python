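"""Validated pipeline configuration (YAML-backed)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigError
from .segment import SegmentationParams

__all__ = ["PipelineConfig"]

_KNOWN_KEYS = {
    "input_volume",
    "expected_ears",
    "sieve_cutoff_mm",
    "segmentation",
    "calibration",
    "rng_seed",
    "out_dir",
    "profile_bins",
    "actual_table",
    "voxel_size_um",
}
_KNOWN_SEG_KEYS = {
    "grain_threshold",
    "opening_radius_mm",
    "marker_min_distance_mm",
    "min_region_voxels",
    "grain_floor_absorption",
}
_KNOWN_CAL_KEYS = {"factor_k", "subset_fraction"}


@dataclass
class CalibrationConfig:
    """Either a known factor, or a subset fraction fitted against the
    actual-weight table (about 10% of ears by default)."""

    factor_k: float | None = None
    subset_fraction: float = 0.10


@dataclass
class PipelineConfig:
    input_volume: str
    expected_ears: int = 1
    sieve_cutoff_mm: float = 2.0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    actual_table: str | None = None
    rng_seed: int = 0
    out_dir: str = "earset_out"
    profile_bins: int = 20
    voxel_size_um: float | None = None  # sidecar override; normally None

    def validate(self) -> None:
        if self.expected_ears < 1:
            raise ConfigError("expected_ears must be >= 1")
        if self.sieve_cutoff_mm < 0:
            raise ConfigError("sieve_cutoff_mm must be >= 0")
        if self.profile_bins < 2:
            raise ConfigError("profile_bins must be >= 2")
        if not 0 < self.calibration.subset_fraction <= 1:
            raise ConfigError("calibration.subset_fraction must be in (0, 1]")
        if self.calibration.factor_k is not None and not self.calibration.factor_k > 0:
            raise ConfigError("calibration.factor_k must be positive")
        if self.voxel_size_um is not None and not self.voxel_size_um > 0:
            raise ConfigError("voxel_size_um must be positive")
        try:
            self.segmentation.validate()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        seg_raw = raw.get("segmentation") or {}
        unknown = set(seg_raw) - _KNOWN_SEG_KEYS
        if unknown:
            raise ConfigError(f"unknown segmentation keys: {sorted(unknown)}")
        cal_raw = raw.get("calibration") or {}
        unknown = set(cal_raw) - _KNOWN_CAL_KEYS
        if unknown:
            raise ConfigError(f"unknown calibration keys: {sorted(unknown)}")
        if "input_volume" not in raw:
            raise ConfigError("configuration requires 'input_volume'")
        cfg = cls(
            input_volume=str(raw["input_volume"]),
            expected_ears=int(raw.get("expected_ears", 1)),
            sieve_cutoff_mm=float(raw.get("sieve_cutoff_mm", 2.0)),
            segmentation=SegmentationParams(**seg_raw),
            calibration=CalibrationConfig(**cal_raw),
            actual_table=raw.get("actual_table"),
            rng_seed=int(raw.get("rng_seed", 0)),
            out_dir=str(raw.get("out_dir", "earset_out")),
            profile_bins=int(raw.get("profile_bins", 20)),
            voxel_size_um=raw.get("voxel_size_um"),
        )
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)
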