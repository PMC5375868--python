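"""Synthetic cohort generator.

Emulates the statistical structure the evaluation pipeline assumes — a
cohort of healthy and hemiparetic subjects performing 11 canonical
upper-limb tasks, three repetitions per trial, recorded by 10 EMG channels
at 1000 Hz and two 6-axis IMUs at 100 Hz — without attempting biomechanical
realism.  Each task has a template of smooth bell-shaped angular-velocity
pulses on the two gyroscopes, derived accelerometer profiles, and EMG
activation envelopes time-locked to the movement; EMG is synthesized as an
envelope-modulated band-limited (20-450 Hz) Gaussian carrier, which is all
the envelope-level features of the pipeline can see.

Impairment is expressed through four mechanisms, each scaled by a level in
[0, 1]:

* **slowing** — repetition duration multiplied by 1 + 0.75 * level;
* **weakness** — movement and EMG amplitude multiplied by 1 - 0.5 * level;
* **tremor** — a 5 Hz oscillation (within the 20 Hz IMU passband) added to
  the gyro axes during movement, amplitude 20 * level deg/s;
* **co-contraction** — a fraction 0.6 * level of each agonist's EMG
  envelope added to its antagonist channel.

Healthy inter-subject variability is a per-subject random time warp and
amplitude jitter (both +/-10%), so the normal range is nontrivial and
reference-bank leakage is detectable.  Level 0 with unit jitter reproduces
the healthy template family exactly up to sampled noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sp_signal

from .config import EMG_RATE_HZ, IMU_RATE_HZ, RATE_RATIO, ValidationError
from .demographics import stroke_reference_cohort
from .sensor_io import SubjectMeta, TaskDefinition, TrialRecording, load_task_set

logger = logging.getLogger(__name__)

#: rest geometry of a trial (seconds): lead-in, between repetitions, tail
LEAD_S, REST_S, TAIL_S = 1.5, 3.0, 2.5

#: sensor noise levels: gyro deg/s, accelerometer g, EMG baseline mV
GYRO_NOISE = 0.3
ACC_NOISE = 0.01
EMG_NOISE = 0.01
EMG_GAIN_MV = 0.4

#: antagonist channel for each EMG channel (forearm ring opposites;
#: biceps <-> triceps)
ANTAGONIST = {1: 5, 2: 6, 3: 7, 4: 8, 5: 1, 6: 2, 7: 3, 8: 4, 9: 10, 10: 9}

_TASK_DURATION_S = (2.5, 2.5, 3.0, 3.0, 3.5, 4.0, 4.0, 3.5, 3.0, 3.5, 2.2)
_TASK_PULSES = (2, 2, 2, 2, 3, 3, 3, 2, 2, 4, 6)
_TASK_GYRO_AMP = (60.0, 60.0, 80.0, 80.0, 70.0, 90.0, 90.0, 100.0, 80.0, 120.0, 150.0)
_TASK_ACC_AMP = (0.3, 0.3, 0.5, 0.5, 0.4, 0.6, 0.6, 0.7, 0.5, 0.6, 0.8)


@dataclass
class ImpairmentProfile:
    """Severity of the four impairment mechanisms, all driven by ``level``."""

    level: float
    slowing_gain: float
    amplitude_gain: float
    tremor_amp: float  # deg/s added on the gyro axes at tremor_freq
    cocontraction: float  # fraction of agonist envelope mixed into antagonist
    tremor_freq: float = 5.0
    seed: int = 0

    @classmethod
    def from_level(cls, level: float, seed: int = 0) -> "ImpairmentProfile":
        if not (0.0 <= level <= 1.0):
            raise ValidationError(f"impairment level {level} outside [0, 1]")
        return cls(
            level=level,
            slowing_gain=1.0 + 0.75 * level,
            amplitude_gain=1.0 - 0.5 * level,
            tremor_amp=20.0 * level,
            cocontraction=0.6 * level,
            seed=seed,
        )


@dataclass
class TaskTemplate:
    """Healthy movement template for one task."""

    task_id: int
    duration_s: float
    n_pulses: int
    gyro_amp: float
    acc_amp: float
    gyro1_dir: np.ndarray
    gyro2_dir: np.ndarray
    acc1_dir: np.ndarray
    acc2_dir: np.ndarray
    emg_weights: np.ndarray  # (10,) activation weight per channel
    pulse_centers: np.ndarray = field(init=False)
    pulse_width: float = field(init=False)

    def __post_init__(self) -> None:
        width = 0.8 / self.n_pulses
        margin = width / 2 + 0.02
        self.pulse_width = width
        self.pulse_centers = (
            np.linspace(margin, 1.0 - margin, self.n_pulses)
            if self.n_pulses > 1
            else np.array([0.5])
        )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def build_task_templates(
    task_set: Optional[Sequence[TaskDefinition]] = None,
) -> dict[int, TaskTemplate]:
    """Deterministic templates for the 11-task battery.

    Movement directions and muscle activation patterns are drawn once per
    task from a task-indexed generator, so the template family is fixed
    across runs.
    """
    tasks = task_set or load_task_set()
    templates: dict[int, TaskTemplate] = {}
    for t in tasks:
        k = (t.task_id - 1) % 11
        rng = np.random.default_rng(7000 + t.task_id)
        weights = np.zeros(10)
        ring = 1 + rng.choice(8, size=3, replace=False)
        weights[ring - 1] = rng.uniform(0.5, 1.0, 3)
        proximal = 9 if t.task_id % 2 else 10
        weights[proximal - 1] = 0.8
        templates[t.task_id] = TaskTemplate(
            task_id=t.task_id,
            duration_s=_TASK_DURATION_S[k],
            n_pulses=_TASK_PULSES[k],
            gyro_amp=_TASK_GYRO_AMP[k],
            acc_amp=_TASK_ACC_AMP[k],
            gyro1_dir=_unit(rng.normal(size=3)),
            gyro2_dir=_unit(rng.normal(size=3)),
            acc1_dir=_unit(rng.normal(size=3)),
            acc2_dir=_unit(rng.normal(size=3)),
            emg_weights=weights,
        )
    return templates


def _bump_profile(
    n: int, centers: np.ndarray, width: float, alternate: bool
) -> np.ndarray:
    """Sum of raised-cosine pulses on [0, 1], optionally sign-alternating."""
    t = np.linspace(0.0, 1.0, n)
    prof = np.zeros(n)
    for p, c in enumerate(centers):
        sign = -1.0 if (alternate and p % 2) else 1.0
        mask = np.abs(t - c) < width / 2
        prof[mask] += sign * np.cos(np.pi * (t[mask] - c) / width) ** 2
    return prof


def _bandlimited_carrier(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to 20-450 Hz at 1000 Hz."""
    sos = sp_signal.butter(4, (20.0, 450.0), btype="bandpass", fs=EMG_RATE_HZ, output="sos")
    x = sp_signal.sosfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _repetition(
    template: TaskTemplate,
    impairment: ImpairmentProfile,
    rng: np.random.Generator,
    time_warp: float,
    amp_jitter: float,
    threshold: float = 3.0,
) -> dict:
    """Clean (noise-free) signals for one repetition plus its true boundaries."""
    dur = template.duration_s * impairment.slowing_gain * time_warp
    dur *= rng.uniform(0.97, 1.03)  # per-repetition jitter
    n = max(int(round(dur * IMU_RATE_HZ)), 16)
    gain = impairment.amplitude_gain * amp_jitter

    prof = _bump_profile(n, template.pulse_centers, template.pulse_width, alternate=True)
    env = np.abs(prof)
    peak = env.max()
    if peak > 0:
        env = env / peak

    gyro_amp = template.gyro_amp * gain
    gyro1 = np.outer(prof * gyro_amp, template.gyro1_dir)
    gyro2 = np.outer(prof * gyro_amp * 0.8, template.gyro2_dir)
    if impairment.tremor_amp > 0:
        t = np.arange(n) / IMU_RATE_HZ
        phase = rng.uniform(0, 2 * np.pi)
        trem = impairment.tremor_amp * env * np.sin(2 * np.pi * impairment.tremor_freq * t + phase)
        tdir = _unit(np.ones(3))
        gyro1 = gyro1 + np.outer(trem, tdir)
        gyro2 = gyro2 + np.outer(0.6 * trem, tdir)

    acc_prof = _bump_profile(n, template.pulse_centers, template.pulse_width, alternate=False)
    acc_amp = template.acc_amp * gain
    acc1 = np.outer(acc_prof * acc_amp, template.acc1_dir)
    acc2 = np.outer(acc_prof * acc_amp * 0.7, template.acc2_dir)
    if impairment.tremor_amp > 0:
        acc1 = acc1 + np.outer(0.003 * impairment.tremor_amp * env
                               * np.sin(2 * np.pi * impairment.tremor_freq * np.arange(n) / IMU_RATE_HZ),
                               _unit(np.ones(3)))

    emg_env = np.outer(env, template.emg_weights * gain)  # (n, 10) at 100 Hz
    if impairment.cocontraction > 0:
        mixed = emg_env.copy()
        for ch, ant in ANTAGONIST.items():
            mixed[:, ant - 1] += impairment.cocontraction * emg_env[:, ch - 1]
        emg_env = mixed

    s_clean = np.linalg.norm(gyro1, axis=1) + np.linalg.norm(gyro2, axis=1)
    active = np.flatnonzero(s_clean > threshold)
    if active.size == 0:
        raise ValidationError(
            f"task {template.task_id}: repetition never crosses the activity threshold"
        )
    return {
        "gyro1": gyro1,
        "gyro2": gyro2,
        "acc1": acc1,
        "acc2": acc2,
        "emg_env": emg_env,
        "onset": int(active[0]),
        "offset": int(active[-1] + 1),
    }


def generate_trial(
    template: TaskTemplate,
    impairment: ImpairmentProfile,
    seed: int,
    subject_id: str = "SYN",
    time_warp: float = 1.0,
    amp_jitter: float = 1.0,
    n_repetitions: int = 3,
) -> TrialRecording:
    """One trial: ``n_repetitions`` movement bursts separated by >= 2.5 s rest.

    The returned recording carries the constructed repetition boundaries
    (IMU samples, half-open) in ``ground_truth``.
    """
    rng = np.random.default_rng(seed)
    n_lead = int(LEAD_S * IMU_RATE_HZ)
    n_rest = int(REST_S * IMU_RATE_HZ)
    n_tail = int(TAIL_S * IMU_RATE_HZ)

    blocks = []
    truth: list[tuple[int, int]] = []
    cursor = n_lead
    blocks.append(np.zeros((n_lead, 22)))  # columns: acc1, acc2, gyro1, gyro2, emg_env(10)
    for r in range(n_repetitions):
        rep = _repetition(template, impairment, rng, time_warp, amp_jitter)
        n = rep["gyro1"].shape[0]
        block = np.hstack(
            [rep["acc1"], rep["acc2"], rep["gyro1"], rep["gyro2"], rep["emg_env"]]
        )
        blocks.append(block)
        truth.append((cursor + rep["onset"], cursor + rep["offset"]))
        cursor += n
        if r < n_repetitions - 1:
            blocks.append(np.zeros((n_rest, 22)))
            cursor += n_rest
    blocks.append(np.zeros((n_tail, 22)))
    clean = np.vstack(blocks)
    n_imu = clean.shape[0]

    acc = clean[:, 0:6] + rng.normal(0.0, ACC_NOISE, (n_imu, 6))
    gyro = clean[:, 6:12] + rng.normal(0.0, GYRO_NOISE, (n_imu, 6))

    n_emg = n_imu * RATE_RATIO
    env_up = np.repeat(clean[:, 12:22], RATE_RATIO, axis=0)
    emg = np.empty((n_emg, 10))
    for c in range(10):
        carrier = _bandlimited_carrier(n_emg, rng)
        emg[:, c] = EMG_GAIN_MV * env_up[:, c] * carrier + rng.normal(0.0, EMG_NOISE, n_emg)

    return TrialRecording(
        subject_id=subject_id,
        task_id=template.task_id,
        emg=emg,
        acc1=acc[:, 0:3],
        acc2=acc[:, 3:6],
        gyro1=gyro[:, 0:3],
        gyro2=gyro[:, 3:6],
        ground_truth=truth,
    )


def impairment_to_fmue(
    level: float,
    task_set: Sequence[TaskDefinition],
    rng: np.random.Generator,
) -> tuple[dict[int, int], int]:
    """Clinical-style item scores and total for an impairment level.

    Each task item is the full score scaled by (1 - level) plus rounding
    noise; the part of the 0-66 clinical scale not covered by the task items
    (66 - 42 = 24 points) is filled with a residual scaled the same way, so
    the reported total lies on the 0-66 scale and is monotone non-increasing
    in the level in expectation.
    """
    if not (0.0 <= level <= 1.0):
        raise ValidationError(f"impairment level {level} outside [0, 1]")
    items: dict[int, int] = {}
    for t in task_set:
        raw = t.full_score * (1.0 - level) + rng.normal(0.0, 0.25)
        items[t.task_id] = int(np.clip(round(raw), 0, t.full_score))
    covered = sum(t.full_score for t in task_set)
    residual_span = max(66 - covered, 0)
    residual = int(
        np.clip(round(residual_span * (1.0 - level) + rng.normal(0.0, 0.5)), 0, residual_span)
    )
    total = int(np.clip(sum(items.values()) + residual, 0, 66))
    return items, total


def generate_cohort(
    n_healthy: int = 16,
    n_stroke: int = 18,
    impairment_range: tuple[float, float] = (0.0, 0.8),
    master_seed: int = 0,
    task_set: Optional[Sequence[TaskDefinition]] = None,
) -> tuple[list[SubjectMeta], list[TrialRecording]]:
    """A full synthetic cohort: one trial (3 repetitions) per subject per task.

    Healthy subjects get levels jittered near 0 (and, by definition, full
    clinical scores); impaired subjects get levels spread evenly over
    ``impairment_range``.
    """
    if n_healthy < 2:
        raise ValidationError("need at least 2 healthy subjects")
    lo, hi = impairment_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValidationError(f"invalid impairment range {impairment_range}")
    rng = np.random.default_rng(master_seed)
    tasks = list(task_set or load_task_set())
    templates = build_task_templates(tasks)
    ref = stroke_reference_cohort()

    subjects: list[SubjectMeta] = []
    trials: list[TrialRecording] = []
    stroke_levels = (
        np.linspace(lo, hi, n_stroke) if n_stroke > 1 else np.array([(lo + hi) / 2])
    )

    plans = []
    for i in range(n_healthy):
        level = float(min(abs(rng.normal(0.0, 0.015)), 0.05))
        plans.append(("H%02d" % (i + 1), "healthy", level))
    for i in range(n_stroke):
        plans.append(("S%02d" % (i + 1), "stroke", float(stroke_levels[i])))

    for sid, group, level in plans:
        time_warp = rng.uniform(0.9, 1.1)
        amp_jitter = rng.uniform(0.9, 1.1)
        side = "left" if rng.random() < 0.5 else "right"
        if group == "healthy":
            age = float(rng.integers(24, 64))
            sex = "F" if rng.random() < 6 / 16 else "M"
            items = {t.task_id: t.full_score for t in tasks}
            total = 66
        else:
            row = ref.iloc[int(rng.integers(len(ref)))]
            age, sex = float(row["age"]), str(row["sex"])
            items, total = impairment_to_fmue(level, tasks, rng)
        subjects.append(
            SubjectMeta(
                subject_id=sid,
                group=group,
                tested_side=side,
                fmue_total=total,
                fmue_item_scores=items,
                age=age,
                sex=sex,
                impairment_level=level,
            )
        )
        impairment = ImpairmentProfile.from_level(level)
        for t in tasks:
            trial_seed = int(rng.integers(2**31))
            trials.append(
                generate_trial(
                    templates[t.task_id],
                    impairment,
                    trial_seed,
                    subject_id=sid,
                    time_warp=time_warp,
                    amp_jitter=amp_jitter,
                )
            )
    return subjects, trials
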