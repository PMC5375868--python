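"""Per-segment feature extraction: the seven feature families.

1. *Motion data profile* (MDP): a 22 x 256 matrix — 10 EMG envelopes
   (256 ms window, 8 ms step, mean of the rectified signal) jointly
   normalized by the maximal envelope value over all channels, plus 6
   accelerometer and 6 gyroscope axes each group-normalized by its maximal
   absolute value, every row resampled in time to 256 points.
2. *Time duration* of the segment (s).
3. *IMU extremum number*: strict interior local extrema summed over the 12
   filtered IMU axes (plateaus count once).
4. *EMG power distribution*: per-channel RMS fractions (10-vector, sums to 1).
5. *IMU power distribution*: per-device per-axis RMS fractions (four
   3-vectors).
6. *Accelerometer/gyroscope intensity ratio*: RMS of the IMU1 magnitude
   series over that of IMU2, for acc and gyro.
7. *Magnitude mean and maximum* of each device's 3-axis magnitude series
   (8 values).

Amplitude normalization of the MDP is per sensor group, so a common gain on
a group leaves the MDP unchanged; the RMS-based features are computed on the
filtered, unnormalized signals and therefore retain intensity information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .config import PipelineConfig, ValidationError
from .sensor_io import Segment

logger = logging.getLogger(__name__)

#: MDP row order: EMG 1-10, acc1.xyz, acc2.xyz, gyro1.xyz, gyro2.xyz.
MDP_ROWS = 22


@dataclass
class SupplementaryFeatures:
    """Feature families 2-7 for one segment."""

    duration: float
    extremum_count: int
    emg_power: np.ndarray  # (10,), sums to 1
    imu_power: np.ndarray  # (4, 3) rows acc1, acc2, gyro1, gyro2; rows sum to 1
    intensity_ratio_acc: float
    intensity_ratio_gyro: float
    magnitude_mean: np.ndarray  # (4,) acc1, acc2, gyro1, gyro2
    magnitude_max: np.ndarray  # (4,)

    def vector(self) -> np.ndarray:
        """The 12 supplementary entries in the evaluation-feature column
        order: duration, extremum count, intensity ratios, magnitude means,
        magnitude maxima."""
        return np.concatenate(
            [
                [self.duration, float(self.extremum_count)],
                [self.intensity_ratio_acc, self.intensity_ratio_gyro],
                self.magnitude_mean,
                self.magnitude_max,
            ]
        )


# ---------------------------------------------------------------------------
# EMG envelope


def emg_envelope(
    emg_channel: np.ndarray,
    rate: float = 1000.0,
    window_ms: float = 256.0,
    step_ms: float = 8.0,
) -> np.ndarray:
    """Moving-average envelope: mean |x| over a sliding window.

    Windows are fully contained in the segment; with N samples and a W-sample
    window stepped by S, the envelope has floor((N - W) / S) + 1 points.  A
    segment shorter than one window yields a single whole-segment window
    (logged).
    """
    x = np.abs(np.asarray(emg_channel, dtype=float))
    if x.ndim != 1 or x.size == 0:
        raise ValidationError("EMG channel must be a non-empty 1-D series")
    win = int(round(window_ms * rate / 1000.0))
    step = int(round(step_ms * rate / 1000.0))
    n = x.size
    if n < win:
        logger.debug("segment of %d samples shorter than %d-sample window", n, win)
        return np.array([x.mean()])
    csum = np.concatenate([[0.0], np.cumsum(x)])
    starts = np.arange(0, n - win + 1, step)
    return (csum[starts + win] - csum[starts]) / win


def _resample_row(row: np.ndarray, n_points: int, mode: str = "linear") -> np.ndarray:
    row = np.asarray(row, dtype=float)
    if row.size == 1:
        return np.full(n_points, row[0])
    if mode == "polyphase":
        return sp_signal.resample_poly(row, n_points, row.size)
    grid_in = np.linspace(0.0, 1.0, row.size)
    grid_out = np.linspace(0.0, 1.0, n_points)
    return np.interp(grid_out, grid_in, row)


def compute_mdp(segment: Segment, config: PipelineConfig | None = None) -> np.ndarray:
    """The 22 x 256 motion data profile of one segment.

    Rows are resampled to the common time grid first and normalized after,
    so the documented extrema (a joint maximum of exactly 1 for the EMG
    group, a joint max-abs of 1 for each IMU group) are attained on the
    output grid.  An all-zero group is left as zeros.
    """
    cfg = config or PipelineConfig()
    npts = cfg.mdp_time_points
    rows = np.empty((MDP_ROWS, npts))
    for c in range(10):
        env = emg_envelope(
            segment.emg[:, c], segment.emg_rate, cfg.envelope_window_ms, cfg.envelope_step_ms
        )
        rows[c] = _resample_row(env, npts, cfg.resampler)
    imu = segment.imu_matrix()  # columns: acc1.xyz, acc2.xyz, gyro1.xyz, gyro2.xyz
    for a in range(12):
        rows[10 + a] = _resample_row(imu[:, a], npts, cfg.resampler)
    for sl in (slice(0, 10), slice(10, 16), slice(16, 22)):
        peak = np.max(np.abs(rows[sl]))
        if peak > 0:
            rows[sl] /= peak
        else:
            logger.debug("all-zero channel group %s left unnormalized", sl)
    return rows


# ---------------------------------------------------------------------------
# scalar families


def duration(segment: Segment) -> float:
    """Segment duration in seconds (strictly positive by construction)."""
    return segment.duration_s


def _extrema_1d(x: np.ndarray) -> int:
    """Strict interior extrema; a plateau (run of equal values) counts once."""
    d = np.diff(np.asarray(x, dtype=float))
    signs = np.sign(d[d != 0])
    if signs.size < 2:
        return 0
    return int(np.count_nonzero(signs[1:] != signs[:-1]))


def extremum_count(segment: Segment) -> int:
    """Local minima and maxima summed over the 12 filtered IMU axes."""
    imu = segment.imu_matrix()
    return sum(_extrema_1d(imu[:, a]) for a in range(12))


def _rms(x: np.ndarray, axis: int = 0) -> np.ndarray:
    return np.sqrt(np.mean(np.square(x), axis=axis))


def emg_power_distribution(segment: Segment) -> np.ndarray:
    """Fraction of each channel's RMS in the 10-channel RMS total."""
    rms = _rms(segment.emg)
    total = rms.sum()
    if total == 0:
        return np.full(10, 0.1)
    return rms / total


def imu_power_distribution(segment: Segment) -> np.ndarray:
    """(4, 3) per-device axis RMS fractions, rows acc1, acc2, gyro1, gyro2."""
    out = np.empty((4, 3))
    for i, dev in enumerate((segment.acc1, segment.acc2, segment.gyro1, segment.gyro2)):
        rms = _rms(dev)
        total = rms.sum()
        out[i] = rms / total if total > 0 else np.full(3, 1.0 / 3.0)
    return out


def _magnitude(dev: np.ndarray) -> np.ndarray:
    return np.linalg.norm(dev, axis=1)


def intensity_ratios(
    segment: Segment, config: PipelineConfig | None = None
) -> tuple[float, float]:
    """(acc ratio, gyro ratio): RMS of the IMU1 magnitude series over IMU2's.

    A zero denominator is reported as the configured cap (logged)."""
    cfg = config or PipelineConfig()

    def ratio(v1: np.ndarray, v2: np.ndarray) -> float:
        num = float(_rms(_magnitude(v1)))
        den = float(_rms(_magnitude(v2)))
        if den == 0:
            logger.debug("zero IMU2 intensity; ratio capped at %g", cfg.ratio_cap)
            return cfg.ratio_cap
        return num / den

    return (
        ratio(segment.acc1, segment.acc2),
        ratio(segment.gyro1, segment.gyro2),
    )


def magnitude_stats(segment: Segment) -> tuple[np.ndarray, np.ndarray]:
    """Mean and max of each device's 3-axis magnitude series (4 + 4 values)."""
    devs = (segment.acc1, segment.acc2, segment.gyro1, segment.gyro2)
    mags = [_magnitude(d) for d in devs]
    return (
        np.array([m.mean() for m in mags]),
        np.array([m.max() for m in mags]),
    )


def supplementary_features(
    segment: Segment, config: PipelineConfig | None = None
) -> SupplementaryFeatures:
    acc_ratio, gyro_ratio = intensity_ratios(segment, config)
    mag_mean, mag_max = magnitude_stats(segment)
    return SupplementaryFeatures(
        duration=duration(segment),
        extremum_count=extremum_count(segment),
        emg_power=emg_power_distribution(segment),
        imu_power=imu_power_distribution(segment),
        intensity_ratio_acc=acc_ratio,
        intensity_ratio_gyro=gyro_ratio,
        magnitude_mean=mag_mean,
        magnitude_max=mag_max,
    )
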