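"""Preliminary evaluation indicators against a healthy reference bank.

For each task, the motion data profiles (MDPs) and power distributions of
all healthy subjects' repetitions form the *normal reference bank* (48
entries for 16 healthy subjects x 3 repetitions).  A test repetition is
scored by

* the **maximal Pearson correlation** between its MDP and any bank MDP
  (matrices flattened to 5632-vectors),
* the **minimal DTW distance** between its MDP frame sequence (256 frames of
  dimension 22) and any bank MDP, and
* the **minimal Euclidean distance** between each of its five power
  distribution vectors (EMG 10-vector, and acc1/acc2/gyro1/gyro2 3-vectors)
  and the corresponding bank vectors,

giving 7 indicators per repetition; averaging over a subject's (up to 3)
repetitions yields the per-task preliminary evaluation indicator, and the
direct sum over the 11 tasks the global one.  When the test subject is
healthy, its own repetitions are excluded from the bank.

The DTW is the classic boundary-anchored dynamic program with step set
{(1,0), (0,1), (1,1)} and Euclidean frame-to-frame local cost; its inner
loop is JIT-compiled.  Because indicators for every cohort row are needed in
every leave-one-subject-out fold, the full row x bank-entry matrices of
correlations and distances are computed once per cohort
(:func:`compute_pairwise`) and per-fold indicators are masked maxima/minima
over them — an exact, cache-friendly restatement of the per-fold rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

from .config import PipelineConfig, ValidationError
from .features import SupplementaryFeatures, compute_mdp, supplementary_features
from .preprocess import preprocess_trial
from .segmentation import segment_trial
from .sensor_io import SubjectMeta, TrialRecording

logger = logging.getLogger(__name__)

#: names of the five Euclidean power-distance indicators, in order
EUCL_NAMES = ("eucl_emg_power", "eucl_acc1", "eucl_acc2", "eucl_gyro1", "eucl_gyro2")


@dataclass(frozen=True)
class PreliminaryIndicators:
    """The 7 preliminary indicators of one repetition (or their average)."""

    pcc: float
    dtw: float
    eucl_emg_power: float
    eucl_acc1: float
    eucl_acc2: float
    eucl_gyro1: float
    eucl_gyro2: float

    def vector(self) -> np.ndarray:
        return np.array(
            [
                self.pcc,
                self.dtw,
                self.eucl_emg_power,
                self.eucl_acc1,
                self.eucl_acc2,
                self.eucl_gyro1,
                self.eucl_gyro2,
            ]
        )


# ---------------------------------------------------------------------------
# Pearson correlation between MDPs


def _flat_corr(a: np.ndarray, b: np.ndarray) -> float:
    x = a.ravel() - a.mean()
    y = b.ravel() - b.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return np.nan
    return float(np.dot(x, y) / (nx * ny))


def _row_mean_corr(a: np.ndarray, b: np.ndarray) -> float:
    vals = [_flat_corr(a[r], b[r]) for r in range(a.shape[0])]
    vals = [v for v in vals if not np.isnan(v)]
    return float(np.mean(vals)) if vals else np.nan


def pcc_similarity(
    test_mdp: np.ndarray,
    bank_mdps: Sequence[np.ndarray],
    mode: str = "flattened",
) -> float:
    """Maximal Pearson correlation between the test MDP and any bank MDP.

    Zero-variance pairs are skipped; if every pair is degenerate a
    :class:`ValidationError` is raised.
    """
    if len(bank_mdps) == 0:
        raise ValidationError("empty reference bank")
    corr = _flat_corr if mode == "flattened" else _row_mean_corr
    vals = np.array([corr(test_mdp, ref) for ref in bank_mdps])
    if np.all(np.isnan(vals)):
        raise ValidationError("all correlation pairs degenerate (zero variance)")
    return float(np.nanmax(vals))


# ---------------------------------------------------------------------------
# dynamic time warping


@njit(cache=True)
def _dtw_dp(cost: np.ndarray) -> float:  # pragma: no cover - jitted
    n, m = cost.shape
    dp = np.empty((n + 1, m + 1))
    dp[:, :] = np.inf
    dp[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = dp[i - 1, j - 1]
            if dp[i - 1, j] < best:
                best = dp[i - 1, j]
            if dp[i, j - 1] < best:
                best = dp[i, j - 1]
            dp[i, j] = cost[i - 1, j - 1] + best
    return dp[n, m]


def _frame_cost(seq_a: np.ndarray, seq_b: np.ndarray) -> np.ndarray:
    a = np.asarray(seq_a, dtype=float)
    b = np.asarray(seq_b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValidationError("DTW input sequence is empty")
    if a.shape[1] != b.shape[1]:
        raise ValidationError(
            f"DTW frame dimensionality mismatch: {a.shape[1]} vs {b.shape[1]}"
        )
    return cdist(a, b)


def dtw_distance(
    seq_a: np.ndarray,
    seq_b: np.ndarray,
    window: Optional[int] = None,
    normalize_by_path: bool = False,
) -> float:
    """Boundary-anchored DTW alignment cost between two frame sequences.

    Sequences are (length, dim) arrays (1-D input is treated as dim 1).
    ``window`` applies a Sakoe-Chiba band of the given radius; the cost is
    not normalized by path length unless requested.
    """
    cost = _frame_cost(seq_a, seq_b)
    if window is not None:
        n, m = cost.shape
        i = np.arange(n)[:, None]
        j = np.arange(m)[None, :]
        # band around the rescaled diagonal
        diag = i * (m - 1) / max(n - 1, 1)
        cost = np.where(np.abs(j - diag) <= window, cost, np.inf)
    dist = float(_dtw_dp(np.ascontiguousarray(cost)))
    if normalize_by_path:
        dist /= cost.shape[0] + cost.shape[1]
    return dist


def dtw_similarity(
    test_mdp: np.ndarray,
    bank_mdps: Sequence[np.ndarray],
    config: PipelineConfig | None = None,
) -> float:
    """Minimal DTW distance from the test MDP to any bank MDP.

    MDPs are compared as 256-frame sequences of 22-dimensional frames
    (matrix transposed), so warping acts on the normalized time axis.
    """
    cfg = config or PipelineConfig()
    if len(bank_mdps) == 0:
        raise ValidationError("empty reference bank")
    return min(
        dtw_distance(test_mdp.T, ref.T, cfg.dtw_window, cfg.dtw_normalize_by_path)
        for ref in bank_mdps
    )


def power_distance(test_vec: np.ndarray, bank_vecs: Sequence[np.ndarray]) -> float:
    """Minimal Euclidean distance between distribution vectors."""
    if len(bank_vecs) == 0:
        raise ValidationError("empty reference bank")
    arr = np.asarray(bank_vecs, dtype=float)
    return float(np.min(np.linalg.norm(arr - np.asarray(test_vec, dtype=float), axis=1)))


# ---------------------------------------------------------------------------
# cohort feature extraction


@dataclass
class SegmentFeatures:
    """Extracted representation of one detected repetition."""

    subject_id: str
    task_id: int
    repetition: int
    mdp: np.ndarray  # (22, 256)
    supp: SupplementaryFeatures


#: task_id -> list of SegmentFeatures (row order: subject, then repetition)
CohortFeatures = dict[int, list[SegmentFeatures]]


def extract_cohort(
    trials: Iterable[TrialRecording], config: PipelineConfig | None = None
) -> CohortFeatures:
    """Preprocess, segment and featurize every trial of a cohort."""
    cfg = config or PipelineConfig()
    out: CohortFeatures = {}
    for trial in trials:
        filtered = preprocess_trial(trial, cfg)
        segments = segment_trial(filtered, cfg)
        for rep, seg in enumerate(segments):
            out.setdefault(trial.task_id, []).append(
                SegmentFeatures(
                    subject_id=trial.subject_id,
                    task_id=trial.task_id,
                    repetition=rep,
                    mdp=compute_mdp(seg, cfg),
                    supp=supplementary_features(seg, cfg),
                )
            )
    return out


# ---------------------------------------------------------------------------
# reference bank


@dataclass
class ReferenceBank:
    """Healthy-subject reference entries for one task."""

    task_id: int
    subject_ids: list[str] = field(default_factory=list)
    mdps: list[np.ndarray] = field(default_factory=list)
    supps: list[SupplementaryFeatures] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.mdps)


def build_reference_bank(
    cohort: CohortFeatures,
    healthy_ids: Iterable[str],
    exclude: Iterable[str] = (),
) -> dict[int, ReferenceBank]:
    """Per-task banks from healthy subjects' repetitions, minus ``exclude``."""
    healthy = set(healthy_ids) - set(exclude)
    banks: dict[int, ReferenceBank] = {}
    for task_id, entries in cohort.items():
        bank = ReferenceBank(task_id)
        for e in entries:
            if e.subject_id in healthy:
                bank.subject_ids.append(e.subject_id)
                bank.mdps.append(e.mdp)
                bank.supps.append(e.supp)
        banks[task_id] = bank
    return banks


def preliminary_ei(
    test_segments: Sequence[SegmentFeatures],
    bank: ReferenceBank,
    config: PipelineConfig | None = None,
) -> PreliminaryIndicators:
    """Repetition-averaged indicators of a subject's segments for one task."""
    cfg = config or PipelineConfig()
    if not test_segments:
        raise ValidationError("no test segments")
    if len(test_segments) < 3:
        logger.warning(
            "only %d repetition(s) for %s/task%d",
            len(test_segments),
            test_segments[0].subject_id,
            test_segments[0].task_id,
        )
    bank_power = [
        [s.emg_power for s in bank.supps],
        [s.imu_power[0] for s in bank.supps],
        [s.imu_power[1] for s in bank.supps],
        [s.imu_power[2] for s in bank.supps],
        [s.imu_power[3] for s in bank.supps],
    ]
    vectors = []
    for seg in test_segments:
        test_power = [
            seg.supp.emg_power,
            seg.supp.imu_power[0],
            seg.supp.imu_power[1],
            seg.supp.imu_power[2],
            seg.supp.imu_power[3],
        ]
        vectors.append(
            [pcc_similarity(seg.mdp, bank.mdps, cfg.pcc_mode)]
            + [dtw_similarity(seg.mdp, bank.mdps, cfg)]
            + [power_distance(t, b) for t, b in zip(test_power, bank_power)]
        )
    mean = np.mean(np.asarray(vectors), axis=0)
    return PreliminaryIndicators(*mean)


def global_preliminary_ei(
    per_task: Mapping[int, PreliminaryIndicators], method: str
) -> float:
    """Direct sum of one indicator component over the tasks."""
    if method not in ("pcc", "dtw"):
        raise ValidationError(f"global preliminary EI undefined for {method!r}")
    return float(sum(getattr(ind, method) for ind in per_task.values()))


# ---------------------------------------------------------------------------
# cohort-level pairwise caches


@dataclass
class TaskPairwise:
    """Row x bank-entry indicator matrices for one task.

    Rows cover every cohort repetition; columns cover healthy repetitions
    (the largest possible bank).  Any fold's bank is a column subset, so the
    fold indicator of row *i* excluding subjects E is the max (PCC) or min
    (distances) over columns whose subject is not in E.
    """

    task_id: int
    row_subjects: np.ndarray  # (K,) str
    col_subjects: np.ndarray  # (H,) str
    pcc: np.ndarray  # (K, H), NaN where degenerate
    dtw: np.ndarray  # (K, H)
    eucl: dict[str, np.ndarray]  # name -> (K, H)

    def indicators(self, row: int, exclude: frozenset[str]) -> np.ndarray:
        """7-vector [pcc, dtw, eucl x 5] for one row under a bank exclusion."""
        keep = ~np.isin(self.col_subjects, list(exclude))
        if not keep.any():
            raise ValidationError("bank exclusion leaves no reference entries")
        vec = np.empty(7)
        vec[0] = np.nanmax(self.pcc[row, keep])
        vec[1] = np.min(self.dtw[row, keep])
        for k, name in enumerate(EUCL_NAMES):
            vec[2 + k] = np.min(self.eucl[name][row, keep])
        return vec


def _pairwise_pcc(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """All-pairs Pearson correlation of flattened MDPs (NaN if degenerate)."""
    x = rows - rows.mean(axis=1, keepdims=True)
    y = cols - cols.mean(axis=1, keepdims=True)
    nx = np.linalg.norm(x, axis=1)
    ny = np.linalg.norm(y, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (x @ y.T) / np.outer(nx, ny)
    corr[:, ny == 0] = np.nan
    corr[nx == 0, :] = np.nan
    return corr


def compute_pairwise(
    entries: Sequence[SegmentFeatures],
    healthy_ids: Iterable[str],
    config: PipelineConfig | None = None,
) -> TaskPairwise:
    """Full indicator matrices of one task's entries vs the healthy entries."""
    cfg = config or PipelineConfig()
    healthy = set(healthy_ids)
    task_id = entries[0].task_id
    row_subjects = np.array([e.subject_id for e in entries])
    col_idx = [i for i, e in enumerate(entries) if e.subject_id in healthy]
    if not col_idx:
        raise ValidationError(f"task {task_id}: no healthy reference entries")
    col_subjects = row_subjects[col_idx]

    flat = np.array([e.mdp.ravel() for e in entries])
    if cfg.pcc_mode == "flattened":
        pcc = _pairwise_pcc(flat, flat[col_idx])
    else:
        pcc = np.array(
            [[_row_mean_corr(a.mdp, entries[j].mdp) for j in col_idx] for a in entries]
        )

    seqs = [np.ascontiguousarray(e.mdp.T) for e in entries]
    dtw = np.empty((len(entries), len(col_idx)))
    if cfg.dtw_window is None and not cfg.dtw_normalize_by_path:
        for i, a in enumerate(seqs):
            for k, j in enumerate(col_idx):
                cost = cdist(a, seqs[j])
                dtw[i, k] = _dtw_dp(cost)
    else:
        for i, a in enumerate(seqs):
            for k, j in enumerate(col_idx):
                dtw[i, k] = dtw_distance(
                    a, seqs[j], cfg.dtw_window, cfg.dtw_normalize_by_path
                )

    def dist_matrix(get) -> np.ndarray:
        vecs = np.array([get(e.supp) for e in entries])
        return cdist(vecs, vecs[col_idx])

    eucl = {
        "eucl_emg_power": dist_matrix(lambda s: s.emg_power),
        "eucl_acc1": dist_matrix(lambda s: s.imu_power[0]),
        "eucl_acc2": dist_matrix(lambda s: s.imu_power[1]),
        "eucl_gyro1": dist_matrix(lambda s: s.imu_power[2]),
        "eucl_gyro2": dist_matrix(lambda s: s.imu_power[3]),
    }
    return TaskPairwise(task_id, row_subjects, col_subjects, pcc, dtw, eucl)


def healthy_subject_ids(subjects: Sequence[SubjectMeta]) -> list[str]:
    return [m.subject_id for m in subjects if m.group == "healthy"]
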