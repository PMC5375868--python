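"""Session data model and on-disk format.

A *session* is a directory holding one sub-directory per subject.  Each
subject directory contains a ``meta.txt`` key-value file and, per task, two
delimited text tables: ``taskNN_emg.csv`` (10 columns at 1000 Hz, millivolts)
and ``taskNN_imu.csv`` (12 columns at 100 Hz: acc1.xyz, acc2.xyz in g,
gyro1.xyz, gyro2.xyz in deg/s).  A ``manifest.txt`` at the session root lists
the subject ids in order.  The format is deliberately plain text: it is
human-inspectable, language-neutral and round-trips losslessly at the
declared precision.

Channel-order convention (fixed globally): EMG channels 1-8 are the forearm
ring, 9 the biceps, 10 the triceps; IMU1 sits on the forearm, IMU2 on the
upper arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import (
    IMU_RATE_HZ,
    EMG_RATE_HZ,
    RATE_RATIO,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Per-task full scores of the 11-task set, matched to the related items of
#: the upper-extremity Fugl-Meyer scale (sum = 42).
DEFAULT_FULL_SCORES = (2, 2, 2, 2, 6, 8, 8, 6, 2, 2, 2)

DEFAULT_TASK_NAMES = (
    "wrist flexion",
    "wrist extension",
    "shoulder flexion to 90 deg",
    "shoulder abduction to 90 deg",
    "flip a piece of paper",
    "fetch and hold a ball",
    "fetch and hold a cylindrical roll",
    "finger to nose",
    "touch the back of the shoulder",
    "forearm supination/pronation twice",
    "fast elbow flexion three times",
)

UNITS = {"emg": "mV", "acc": "g", "gyro": "deg_s"}

_EMG_COLUMNS = [f"emg{i}" for i in range(1, 11)]
_IMU_COLUMNS = [
    f"{dev}_{ax}" for dev in ("acc1", "acc2", "gyro1", "gyro2") for ax in "xyz"
]
_FLOAT_FMT = "%.17g"  # full double precision: lossless numeric round trip


@dataclass(frozen=True)
class TaskDefinition:
    """One canonical upper-limb task with its clinical full score."""

    task_id: int
    name: str
    full_score: int

    def __post_init__(self) -> None:
        if self.full_score < 0:
            raise ValidationError(f"task {self.task_id}: negative full score")


@dataclass
class SubjectMeta:
    subject_id: str
    group: str  # {"healthy", "stroke"}
    tested_side: str  # {"left", "right"}
    fmue_total: int
    fmue_item_scores: dict[int, int]
    age: float
    sex: str  # {"F", "M"}
    #: impairment level of the synthetic generator (None for real data)
    impairment_level: Optional[float] = None

    def validate(self, task_set: Sequence[TaskDefinition] | None = None) -> None:
        if self.group not in ("healthy", "stroke"):
            raise ValidationError(f"{self.subject_id}: unknown group {self.group!r}")
        if not (0 <= self.fmue_total <= 66):
            raise ValidationError(f"{self.subject_id}: FMUE total outside 0-66")
        if task_set is not None:
            full = {t.task_id: t.full_score for t in task_set}
            for tid, score in self.fmue_item_scores.items():
                if tid not in full:
                    raise ValidationError(f"{self.subject_id}: unknown task id {tid}")
                if not (0 <= score <= full[tid]):
                    raise ValidationError(
                        f"{self.subject_id}: item score {score} exceeds full "
                        f"score {full[tid]} for task {tid}"
                    )
            if self.group == "healthy":
                if self.fmue_total != 66 or any(
                    self.fmue_item_scores.get(t.task_id) != t.full_score
                    for t in task_set
                ):
                    raise ValidationError(
                        f"{self.subject_id}: healthy subjects carry full scores"
                    )


@dataclass
class TrialRecording:
    """One continuous recording of a task trial (up to 3 repetitions).

    ``emg`` is (n_emg, 10) at 1000 Hz; ``acc1``/``acc2``/``gyro1``/``gyro2``
    are (n_imu, 3) at 100 Hz, with n_emg = 10 * n_imu and a shared time
    origin.
    """

    subject_id: str
    task_id: int
    emg: np.ndarray
    acc1: np.ndarray
    acc2: np.ndarray
    gyro1: np.ndarray
    gyro2: np.ndarray
    emg_rate: float = EMG_RATE_HZ
    imu_rate: float = IMU_RATE_HZ
    #: constructed repetition boundaries (IMU samples), set by the synthetic
    #: generator, never serialized
    ground_truth: Optional[list[tuple[int, int]]] = None

    @property
    def n_imu(self) -> int:
        return self.acc1.shape[0]

    def imu_matrix(self) -> np.ndarray:
        """(n_imu, 12) matrix in the acc1, acc2, gyro1, gyro2 column order."""
        return np.hstack([self.acc1, self.acc2, self.gyro1, self.gyro2])

    def validate(self) -> None:
        if self.emg.ndim != 2 or self.emg.shape[1] != 10:
            raise ValidationError(
                f"{self.subject_id}/task{self.task_id}: EMG must have 10 channels"
            )
        for name in ("acc1", "acc2", "gyro1", "gyro2"):
            arr = getattr(self, name)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValidationError(
                    f"{self.subject_id}/task{self.task_id}: {name} must be 3-axis"
                )
            if arr.shape[0] != self.n_imu:
                raise ValidationError(
                    f"{self.subject_id}/task{self.task_id}: IMU channel lengths differ"
                )
        ratio = int(round(self.emg_rate / self.imu_rate))
        if self.emg.shape[0] != ratio * self.n_imu:
            raise ValidationError(
                f"{self.subject_id}/task{self.task_id}: EMG length "
                f"{self.emg.shape[0]} != {ratio} x IMU length {self.n_imu}"
            )
        for name in ("emg", "acc1", "acc2", "gyro1", "gyro2"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(
                    f"{self.subject_id}/task{self.task_id}: non-finite samples in {name}"
                )


@dataclass
class Segment:
    """All 22 channels of one detected task repetition.

    ``onset``/``offset`` are half-open IMU-clock sample indices; the EMG
    boundaries are the same indices scaled by the 1000/100 rate ratio.
    """

    subject_id: str
    task_id: int
    onset: int
    offset: int
    emg: np.ndarray  # (n, 10) at 1000 Hz
    acc1: np.ndarray
    acc2: np.ndarray
    gyro1: np.ndarray
    gyro2: np.ndarray
    imu_rate: float = IMU_RATE_HZ
    emg_rate: float = EMG_RATE_HZ
    truncated: bool = False  # record ended before the full hold elapsed

    def __post_init__(self) -> None:
        if self.onset < 0 or self.offset <= self.onset:
            raise ValidationError(
                f"segment boundaries ({self.onset}, {self.offset}) invalid"
            )

    @property
    def onset_emg(self) -> int:
        return self.onset * RATE_RATIO

    @property
    def offset_emg(self) -> int:
        return self.offset * RATE_RATIO

    @property
    def duration_s(self) -> float:
        return (self.offset - self.onset) / self.imu_rate

    def imu_matrix(self) -> np.ndarray:
        return np.hstack([self.acc1, self.acc2, self.gyro1, self.gyro2])


# ---------------------------------------------------------------------------
# task set


def load_task_set(config: Optional[Iterable[dict]] = None) -> list[TaskDefinition]:
    """Return the task set; the default is the 11-task canonical battery.

    ``config`` may be an iterable of mappings with keys ``task_id``, ``name``
    (optional) and ``full_score``.
    """
    if config is None:
        return [
            TaskDefinition(i + 1, DEFAULT_TASK_NAMES[i], DEFAULT_FULL_SCORES[i])
            for i in range(11)
        ]
    tasks = [
        TaskDefinition(
            int(item["task_id"]),
            str(item.get("name", f"task {item['task_id']}")),
            int(item["full_score"]),
        )
        for item in config
    ]
    ids = [t.task_id for t in tasks]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate task_id in task set")
    return tasks


# ---------------------------------------------------------------------------
# session writer / reader


def _meta_to_text(meta: SubjectMeta) -> str:
    items = ",".join(f"{tid}:{score}" for tid, score in sorted(meta.fmue_item_scores.items()))
    lines = [
        f"subject_id: {meta.subject_id}",
        f"group: {meta.group}",
        f"tested_side: {meta.tested_side}",
        f"fmue_total: {meta.fmue_total}",
        f"fmue_item_scores: {items}",
        f"age: {meta.age:g}",
        f"sex: {meta.sex}",
        f"emg_units: {UNITS['emg']}",
        f"acc_units: {UNITS['acc']}",
        f"gyro_units: {UNITS['gyro']}",
    ]
    if meta.impairment_level is not None:
        lines.append(f"impairment_level: {meta.impairment_level:.6f}")
    return "\n".join(lines) + "\n"


def _meta_from_text(text: str, path: Path) -> SubjectMeta:
    kv: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        kv[key.strip()] = value.strip()
    try:
        items: dict[int, int] = {}
        if kv.get("fmue_item_scores"):
            for pair in kv["fmue_item_scores"].split(","):
                tid, _, score = pair.partition(":")
                items[int(tid)] = int(score)
        for kind in ("emg", "acc", "gyro"):
            declared = kv.get(f"{kind}_units", UNITS[kind])
            if declared != UNITS[kind]:
                raise ValidationError(
                    f"{path}: {kind} units {declared!r} != expected {UNITS[kind]!r}"
                )
        level = kv.get("impairment_level")
        return SubjectMeta(
            subject_id=kv["subject_id"],
            group=kv["group"],
            tested_side=kv["tested_side"],
            fmue_total=int(kv["fmue_total"]),
            fmue_item_scores=items,
            age=float(kv["age"]),
            sex=kv["sex"],
            impairment_level=float(level) if level is not None else None,
        )
    except KeyError as exc:  # pragma: no cover - malformed file
        raise ValidationError(f"{path}: missing metadata key {exc}") from exc


SessionRecords = list[tuple[SubjectMeta, list[TrialRecording]]]


def write_session(records: SessionRecords, path: str | Path) -> None:
    """Write a session directory; deterministic layout, lossless round trip."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for meta, trials in records:
        meta.validate()
        for trial in trials:
            trial.validate()
    manifest = "\n".join(meta.subject_id for meta, _ in records)
    (root / "manifest.txt").write_text(manifest + ("\n" if manifest else ""))
    for meta, trials in records:
        sdir = root / meta.subject_id
        sdir.mkdir(exist_ok=True)
        (sdir / "meta.txt").write_text(_meta_to_text(meta))
        for trial in trials:
            stem = f"task{trial.task_id:02d}"
            emg = pd.DataFrame(trial.emg, columns=_EMG_COLUMNS)
            emg.to_csv(sdir / f"{stem}_emg.csv", index=False, float_format=_FLOAT_FMT)
            imu = pd.DataFrame(trial.imu_matrix(), columns=_IMU_COLUMNS)
            imu.to_csv(sdir / f"{stem}_imu.csv", index=False, float_format=_FLOAT_FMT)


def read_session(path: str | Path) -> SessionRecords:
    """Read a session directory written by :func:`write_session`."""
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"session directory {root} does not exist")
    manifest = root / "manifest.txt"
    if manifest.exists():
        subject_ids = [s for s in manifest.read_text().split() if s]
    else:
        subject_ids = sorted(p.name for p in root.iterdir() if p.is_dir())
    if not subject_ids:
        logger.warning("session %s contains no subjects", root)
        return []
    records: SessionRecords = []
    for sid in subject_ids:
        sdir = root / sid
        meta_path = sdir / "meta.txt"
        if not meta_path.exists():
            raise FileNotFoundError(f"missing metadata file for subject {sid}")
        meta = _meta_from_text(meta_path.read_text(), meta_path)
        trials: list[TrialRecording] = []
        for emg_path in sorted(sdir.glob("task*_emg.csv")):
            stem = emg_path.name[: -len("_emg.csv")]
            task_id = int(stem.removeprefix("task"))
            imu_path = sdir / f"{stem}_imu.csv"
            if not imu_path.exists():
                raise FileNotFoundError(
                    f"missing IMU file for trial {sid}/{stem}"
                )
            emg = pd.read_csv(emg_path, float_precision="round_trip").to_numpy(dtype=float)
            imu = pd.read_csv(imu_path, float_precision="round_trip").to_numpy(dtype=float)
            trial = TrialRecording(
                subject_id=sid,
                task_id=task_id,
                emg=emg,
                acc1=imu[:, 0:3],
                acc2=imu[:, 3:6],
                gyro1=imu[:, 6:9],
                gyro2=imu[:, 9:12],
            )
            trial.validate()
            trials.append(trial)
        records.append((meta, trials))
    return records
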