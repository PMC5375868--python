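"""Shared fixtures and oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import limbeval as lv

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# independent oracles (deliberately slow / brute force)


def dtw_exhaustive(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum alignment cost over ALL monotone boundary-anchored paths with
    steps (1,0), (0,1), (1,1), by explicit path enumeration."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    n, m = a.shape[0], b.shape[0]

    def cost(i, j):
        return float(np.linalg.norm(a[i] - b[j]))

    best = [np.inf]

    def walk(i, j, acc):
        if i == n - 1 and j == m - 1:
            best[0] = min(best[0], acc)
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                walk(ni, nj, acc + cost(ni, nj))

    walk(0, 0, cost(0, 0))
    return best[0]


def pearson_textbook(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation via the summation formula, written longhand."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxy = sum(a * b for a, b in zip(x, y))
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    num = n * sxy - sx * sy
    den = np.sqrt(n * sxx - sx * sx) * np.sqrt(n * syy - sy * sy)
    return num / den


def extrema_slow(x) -> int:
    """Interior extrema with plateaus collapsed to single points."""
    vals = [x[0]]
    for v in x[1:]:
        if v != vals[-1]:
            vals.append(v)
    count = 0
    for i in range(1, len(vals) - 1):
        if (vals[i] - vals[i - 1]) * (vals[i + 1] - vals[i]) < 0:
            count += 1
    return count


def detect_slow(s, thr, hold):
    """Per-sample state-machine transcription of the onset/offset rule."""
    segs = []
    n = len(s)
    t = 0
    while t < n:
        if s[t] <= thr:
            t += 1
            continue
        onset = t
        last_above = t
        u = t + 1
        while u < n:
            if s[u] > thr:
                last_above = u
                u += 1
                continue
            v = u
            while v < n and s[v] <= thr:
                v += 1
            if v - u >= hold:
                break
            u = v
        truncated = (n - (last_above + 1)) < hold
        segs.append((onset, last_above + 1, truncated))
        t = last_above + 1
        while t < n and s[t] <= thr:
            t += 1
    return segs


# ---------------------------------------------------------------------------
# segment fixtures


def make_segment(
    emg: np.ndarray,
    imu: np.ndarray,
    subject_id: str = "T01",
    task_id: int = 1,
    onset: int = 0,
) -> lv.Segment:
    """Wrap raw channel arrays ((n*10, 10) EMG, (n, 12) IMU) in a Segment."""
    n = imu.shape[0]
    return lv.Segment(
        subject_id=subject_id,
        task_id=task_id,
        onset=onset,
        offset=onset + n,
        emg=emg,
        acc1=imu[:, 0:3],
        acc2=imu[:, 3:6],
        gyro1=imu[:, 6:9],
        gyro2=imu[:, 9:12],
    )


@pytest.fixture
def random_segment():
    rng = np.random.default_rng(7)
    n = 300
    return make_segment(rng.normal(0, 0.2, (n * 10, 10)), rng.normal(0, 1.0, (n, 12)))


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 3-healthy + 2-stroke cohort with features and pairwise caches."""
    subjects, trials = lv.generate_cohort(n_healthy=3, n_stroke=2, master_seed=11)
    cohort = lv.extract_cohort(trials)
    healthy = [m.subject_id for m in subjects if m.group == "healthy"]
    pairwise = {
        tid: lv.compute_pairwise(entries, healthy) for tid, entries in cohort.items()
    }
    return subjects, trials, cohort, pairwise
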