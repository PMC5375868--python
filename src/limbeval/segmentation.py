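"""Task-repetition segmentation from combined gyroscope activity.

The activity series is S(t) = ||gyro1(t)|| + ||gyro2(t)|| (deg/s), the sum of
the two gyroscopes' instantaneous 3-axis vector magnitudes.  A repetition
onset is the first sample with S(t) strictly above the threshold T_R
(3 deg/s by default); the offset is the crossing sample after which S(t)
stays below the threshold for a full hold interval (2 s).  A sub-threshold
dip shorter than the hold does not interrupt a repetition.  Boundaries are
detected on the low-pass-filtered gyro signals and then applied to all 22
channels, with EMG indices scaled by the 1000/100 rate ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import IMU_RATE_HZ, RATE_RATIO, PipelineConfig, ValidationError
from .sensor_io import Segment, TrialRecording

logger = logging.getLogger(__name__)


@dataclass
class ActivitySeries:
    s: np.ndarray  # S(t), deg/s, >= 0
    rate: float = IMU_RATE_HZ
    threshold_tr: float = 3.0
    hold_s: float = 2.0

    def __post_init__(self) -> None:
        if self.threshold_tr <= 0:
            raise ValidationError("activity threshold must be positive")
        if np.any(self.s < 0):
            raise ValidationError("activity series must be nonnegative")


def gyro_magnitude_sum(gyro1: np.ndarray, gyro2: np.ndarray) -> np.ndarray:
    """Pointwise ||gyro1||_2 + ||gyro2||_2 over matched 3-axis series."""
    gyro1 = np.asarray(gyro1, dtype=float)
    gyro2 = np.asarray(gyro2, dtype=float)
    if gyro1.shape != gyro2.shape or gyro1.ndim != 2 or gyro1.shape[1] != 3:
        raise ValidationError(
            f"gyro series shapes {gyro1.shape} / {gyro2.shape} must match (n, 3)"
        )
    return np.linalg.norm(gyro1, axis=1) + np.linalg.norm(gyro2, axis=1)


def detect_segments(
    activity: ActivitySeries,
    min_segment_s: float = 0.3,
) -> list[tuple[int, int, bool]]:
    """Detect (onset, offset, truncated) triples on the activity series.

    Boundaries are half-open sample indices at the activity rate.  A segment
    is *truncated* when the record ends before a full hold interval could be
    verified after its offset.  Segments shorter than ``min_segment_s`` are
    discarded as twitches.
    """
    s = np.asarray(activity.s, dtype=float)
    n = s.size
    hold = int(round(activity.hold_s * activity.rate))
    min_len = int(round(min_segment_s * activity.rate))
    above = np.flatnonzero(s > activity.threshold_tr)
    if above.size == 0:
        return []
    # contiguous above-threshold runs as half-open (start, stop)
    breaks = np.flatnonzero(np.diff(above) > 1)
    starts = np.concatenate([[above[0]], above[breaks + 1]])
    stops = np.concatenate([above[breaks] + 1, [above[-1] + 1]])
    # merge runs separated by sub-threshold gaps shorter than the hold
    merged: list[list[int]] = [[int(starts[0]), int(stops[0])]]
    for a, b in zip(starts[1:], stops[1:]):
        if a - merged[-1][1] < hold:
            merged[-1][1] = int(b)
        else:
            merged.append([int(a), int(b)])
    out: list[tuple[int, int, bool]] = []
    for a, b in merged:
        if b - a < min_len:
            continue
        truncated = (n - b) < hold
        out.append((a, b, truncated))
    return out


def map_boundaries(index_imu: int, rate_ratio: int = RATE_RATIO) -> int:
    """Map an IMU-clock boundary index to the EMG clock."""
    if index_imu < 0:
        raise ValidationError("negative segment boundary")
    return index_imu * rate_ratio


def segment_trial(
    trial: TrialRecording, config: PipelineConfig | None = None
) -> list[Segment]:
    """Cut all 22 channels of a preprocessed trial at detected boundaries.

    A well-formed repetition block yields 3 segments; 0 segments or more
    than 3 are reported with a warning (extra segments are kept).
    """
    cfg = config or PipelineConfig()
    s = gyro_magnitude_sum(trial.gyro1, trial.gyro2)
    activity = ActivitySeries(
        s, rate=trial.imu_rate, threshold_tr=cfg.threshold_deg_per_s, hold_s=cfg.hold_s
    )
    bounds = detect_segments(activity, min_segment_s=cfg.min_segment_s)
    trial_name = f"{trial.subject_id}/task{trial.task_id}"
    if not bounds:
        logger.warning("no segments detected in trial %s", trial_name)
    elif len(bounds) > 3:
        logger.warning("%d segments detected in trial %s; all kept", len(bounds), trial_name)
    segments = []
    for onset, offset, truncated in bounds:
        e0, e1 = map_boundaries(onset), map_boundaries(offset)
        segments.append(
            Segment(
                subject_id=trial.subject_id,
                task_id=trial.task_id,
                onset=onset,
                offset=offset,
                emg=trial.emg[e0:e1],
                acc1=trial.acc1[onset:offset],
                acc2=trial.acc2[onset:offset],
                gyro1=trial.gyro1[onset:offset],
                gyro2=trial.gyro2[onset:offset],
                imu_rate=trial.imu_rate,
                emg_rate=trial.emg_rate,
                truncated=truncated,
            )
        )
    return segments
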