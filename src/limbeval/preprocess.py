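"""Noise-reduction filters applied before segmentation and feature extraction.

EMG channels (1000 Hz) are band-pass filtered with a 2nd-order Butterworth
within 20-495 Hz (the nominal 500 Hz upper edge equals Nyquist and is
unrealizable; content in 495-500 Hz is negligible at envelope scale).  IMU
axes (100 Hz) are low-pass filtered with a 2nd-order Butterworth at 20 Hz.
Both filters are applied forward-backward (zero phase) so that segment
boundaries are not phase-shifted between the EMG and IMU streams; edges are
handled by reflective padding.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .config import EMG_RATE_HZ, IMU_RATE_HZ, PipelineConfig, ValidationError
from .sensor_io import TrialRecording


@dataclass(frozen=True)
class FilterSpec:
    kind: str  # {"bandpass", "lowpass"}
    order: int
    band: tuple[float, ...]  # Hz edges
    applied_rate: float

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValidationError("filter order must be >= 1")
        nyq = self.applied_rate / 2.0
        if not all(0.0 < f <= nyq for f in self.band):
            raise ValidationError(f"band edges {self.band} outside (0, {nyq}]")

    def sos(self) -> np.ndarray:
        btype = "bandpass" if self.kind == "bandpass" else "lowpass"
        wn = self.band if self.kind == "bandpass" else self.band[0]
        return signal.butter(self.order, wn, btype=btype, fs=self.applied_rate, output="sos")


def emg_filter_spec(config: PipelineConfig | None = None) -> FilterSpec:
    cfg = config or PipelineConfig()
    return FilterSpec("bandpass", cfg.emg_filter_order, tuple(cfg.emg_band_hz), EMG_RATE_HZ)


def imu_filter_spec(config: PipelineConfig | None = None) -> FilterSpec:
    cfg = config or PipelineConfig()
    return FilterSpec("lowpass", cfg.imu_filter_order, (cfg.imu_cutoff_hz,), IMU_RATE_HZ)


def _apply(spec: FilterSpec, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite samples in filter input")
    sos = spec.sos()
    if zero_phase:
        # reflective ("even") padding of one settling length at each edge
        return signal.sosfiltfilt(sos, x, axis=0, padtype="even")
    return signal.sosfilt(sos, x, axis=0)


def filter_emg(series: np.ndarray, config: PipelineConfig | None = None) -> np.ndarray:
    """Band-pass filter EMG sampled at 1000 Hz; output length equals input."""
    cfg = config or PipelineConfig()
    return _apply(emg_filter_spec(cfg), series, cfg.zero_phase)


def filter_imu(series: np.ndarray, config: PipelineConfig | None = None) -> np.ndarray:
    """Low-pass filter an accelerometer or gyroscope axis sampled at 100 Hz."""
    cfg = config or PipelineConfig()
    return _apply(imu_filter_spec(cfg), series, cfg.zero_phase)


def preprocess_trial(trial: TrialRecording, config: PipelineConfig | None = None) -> TrialRecording:
    """Return a filtered copy of a trial (all 22 channels)."""
    cfg = config or PipelineConfig()
    trial.validate()
    return replace(
        trial,
        emg=filter_emg(trial.emg, cfg),
        acc1=filter_imu(trial.acc1, cfg),
        acc2=filter_imu(trial.acc2, cfg),
        gyro1=filter_imu(trial.gyro1, cfg),
        gyro2=filter_imu(trial.gyro2, cfg),
    )
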