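"""Pipeline configuration.

All tunable knobs of the evaluation pipeline live in a single
:class:`PipelineConfig` dataclass so that a run can be fully described by one
YAML file.  Defaults are the values used throughout: 2nd-order Butterworth
filters (20-495 Hz band-pass for EMG at 1000 Hz, 20 Hz low-pass for IMU at
100 Hz), a 3 deg/s gyro activity threshold with a 2 s hold, a 256 ms / 8 ms
EMG envelope window, and a 22 x 256 motion-data profile.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

EMG_RATE_HZ = 1000.0
IMU_RATE_HZ = 100.0
#: EMG samples per IMU sample (1000 Hz / 100 Hz).
RATE_RATIO = 10

N_EMG_CHANNELS = 10
N_IMU_AXES = 12  # acc1.xyz, acc2.xyz, gyro1.xyz, gyro2.xyz
N_CHANNELS = N_EMG_CHANNELS + N_IMU_AXES  # 22 rows of the motion data profile

VALID_METHODS = ("pcc", "dtw", "pca", "mds", "nmf", "lasso")


class ValidationError(ValueError):
    """Raised when input data or configuration violates a documented contract."""


@dataclass
class PipelineConfig:
    """Every knob of the evaluation pipeline, with field defaults as used in
    the reference analysis."""

    # --- preprocessing -------------------------------------------------
    emg_band_hz: tuple[float, float] = (20.0, 495.0)
    emg_filter_order: int = 2
    imu_cutoff_hz: float = 20.0
    imu_filter_order: int = 2
    zero_phase: bool = True

    # --- segmentation --------------------------------------------------
    threshold_deg_per_s: float = 3.0
    hold_s: float = 2.0
    min_segment_s: float = 0.3

    # --- features ------------------------------------------------------
    envelope_window_ms: float = 256.0
    envelope_step_ms: float = 8.0
    mdp_time_points: int = 256
    resampler: str = "linear"  # {linear, polyphase}
    ratio_cap: float = 1e6

    # --- scoring -------------------------------------------------------
    pcc_mode: str = "flattened"  # {flattened, row_mean}
    dtw_window: Optional[int] = None  # Sakoe-Chiba radius; None = unconstrained
    dtw_normalize_by_path: bool = False

    # --- evaluation-indicator models ----------------------------------
    method: str = "pca"
    master_seed: int = 0
    lambda_grid: Sequence[float] = field(
        default_factory=lambda: tuple(10.0 ** e for e in range(-4, 3))
    )
    sd_convention: str = "sample"  # {sample, population}
    nmf_sweeps: int = 200
    mds_tol: float = 1e-8
    mds_max_iter: int = 500
    task_norm: str = "healthy_max"  # {healthy_mean, healthy_max, global_max}

    def __post_init__(self) -> None:
        lo, hi = self.emg_band_hz
        if not (0.0 < lo < hi <= EMG_RATE_HZ / 2.0):
            raise ValidationError(f"EMG band {self.emg_band_hz} outside (0, Nyquist]")
        if not (0.0 < self.imu_cutoff_hz <= IMU_RATE_HZ / 2.0):
            raise ValidationError(f"IMU cutoff {self.imu_cutoff_hz} outside (0, Nyquist]")
        if self.emg_filter_order < 1 or self.imu_filter_order < 1:
            raise ValidationError("filter order must be >= 1")
        if self.threshold_deg_per_s <= 0:
            raise ValidationError("activity threshold must be positive")
        if self.method not in VALID_METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        if self.sd_convention not in ("sample", "population"):
            raise ValidationError(f"unknown sd convention {self.sd_convention!r}")

    # --- (de)serialization --------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["emg_band_hz"] = list(self.emg_band_hz)
        d["lambda_grid"] = [float(x) for x in self.lambda_grid]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "emg_band_hz" in d:
            d["emg_band_hz"] = tuple(d["emg_band_hz"])
        if "lambda_grid" in d:
            d["lambda_grid"] = tuple(d["lambda_grid"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text)
        if data is None:
            return cls()
        if not isinstance(data, dict):
            raise ValidationError("config YAML must be a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Stable hash of the canonical YAML form, embedded in every report."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
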