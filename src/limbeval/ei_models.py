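"""Evaluation-indicator models and the leave-one-subject-out harness.

Per task, every repetition contributes one row of the feature matrix
V (m x 19): the 7 preliminary indicators followed by 12 supplementary
features.  A rank-1 matrix factorization V = W H (s = 1) reduces each row to
a single raw score; three unsupervised learners (PCA, Sammon-criterion MDS,
NMF with multiplicative updates) and one supervised learner (LASSO on the
clinical item scores) provide the factorization.  Raw scores are normalized
to the task's clinical full score (healthy training mean maps to the full
score, clipped to [0, full score]); component indicators are summed over
tasks into a global indicator, and the healthy-subject mean of the global
indicator is expanded to 66 so the scale is directly comparable with the
upper-extremity Fugl-Meyer total.

Validity metrics: NDVR (normal data variation rate, 100 * 1.96 * SD / mean
of healthy indicators), the normal range (mean +/- 1.96 SD), and DC (the
determination coefficient R^2 of the linear regression between indicators
and clinical totals).

Sign conventions: a 1-D unsupervised component has an arbitrary sign; it is
oriented so that it correlates positively with the PCC feature column (a
known healthy-high feature).  NMF weights cannot be negated, so for NMF the
*columns* are oriented instead: any feature whose training correlation with
the PCC column is negative is reflected after min-max scaling, making every
column healthy-high before the nonnegative factorization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from .config import PipelineConfig, ValidationError
from .scoring import CohortFeatures, SegmentFeatures, TaskPairwise, compute_pairwise
from .sensor_io import SubjectMeta, TaskDefinition, load_task_set

logger = logging.getLogger(__name__)

#: fixed, versioned column order of the per-task feature matrix (n = 19)
FEATURE_COLUMNS = (
    "pcc",
    "dtw",
    "eucl_emg_power",
    "eucl_acc1",
    "eucl_acc2",
    "eucl_gyro1",
    "eucl_gyro2",
    "duration",
    "extremum_count",
    "acc_ratio",
    "gyro_ratio",
    "mean_acc1",
    "mean_acc2",
    "mean_gyro1",
    "mean_gyro2",
    "max_acc1",
    "max_acc2",
    "max_gyro1",
    "max_gyro2",
)

_EPS = 1e-12


@dataclass
class FeatureMatrix:
    """m x 19 per-task sample matrix with row provenance."""

    v: np.ndarray
    rows: list[tuple[str, int, int]]  # (subject_id, task_id, repetition)
    columns: tuple[str, ...] = FEATURE_COLUMNS

    def __post_init__(self) -> None:
        if self.v.ndim != 2 or self.v.shape[1] != len(self.columns):
            raise ValidationError(f"feature matrix must have {len(self.columns)} columns")
        if np.isnan(self.v).any():
            bad = int(np.flatnonzero(np.isnan(self.v).any(axis=1))[0])
            raise ValidationError(f"NaN features in segment {self.rows[bad]}")


def assemble_features(
    entries: Sequence[SegmentFeatures],
    pairwise: TaskPairwise,
    healthy_ids: Sequence[str],
    held_out: Optional[str] = None,
    indices: Optional[Sequence[int]] = None,
) -> FeatureMatrix:
    """Build the feature matrix for (a subset of) a task's entries.

    Indicator entries are computed against the bank that excludes the
    held-out subject and — for healthy rows — the row's own subject, per the
    leakage rule.
    """
    healthy = set(healthy_ids)
    if indices is None:
        indices = range(len(entries))
    rows = []
    prov = []
    for i in indices:
        e = entries[i]
        exclude = {held_out} if held_out is not None else set()
        if e.subject_id in healthy:
            exclude.add(e.subject_id)
        ind = pairwise.indicators(i, frozenset(exclude))
        rows.append(np.concatenate([ind, e.supp.vector()]))
        prov.append((e.subject_id, e.task_id, e.repetition))
    return FeatureMatrix(np.asarray(rows, dtype=float), prov)


# ---------------------------------------------------------------------------
# feature scaling


@dataclass
class ZScoreScaler:
    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, v: np.ndarray) -> "ZScoreScaler":
        std = v.std(axis=0, ddof=0)
        std = np.where(std < _EPS, 1.0, std)
        return cls(v.mean(axis=0), std)

    def transform(self, v: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(v) - self.mean) / self.std


@dataclass
class MinMaxScaler:
    """[0, 1] scaling on training statistics; out-of-range test values are
    clipped.  ``reflect`` marks columns flipped to the healthy-high
    direction (x -> 1 - x)."""

    lo: np.ndarray
    hi: np.ndarray
    reflect: np.ndarray  # bool mask

    @classmethod
    def fit(cls, v: np.ndarray, reflect: np.ndarray) -> "MinMaxScaler":
        return cls(v.min(axis=0), v.max(axis=0), reflect)

    def transform(self, v: np.ndarray) -> np.ndarray:
        span = np.where((self.hi - self.lo) < _EPS, 1.0, self.hi - self.lo)
        x = np.clip((np.atleast_2d(v) - self.lo) / span, 0.0, 1.0)
        return np.where(self.reflect, 1.0 - x, x)


@dataclass
class FactorModel:
    """A fitted 1-D projection: scaled feature row -> raw score -> component
    indicator on the task's clinical scale.

    The per-task normalization is an affine calibration anchored at two
    training statistics: the healthy training mean of the raw score maps to
    the task full score and the training minimum maps to 0, i.e.
    EI = full * (raw - floor) / (anchor - floor), clipped to [0, full].
    Anchoring the floor at the training minimum keeps the denominator on
    the scale of the observed score spread (a bare healthy-mean divisor is
    ill-conditioned for centered scores), while preserving the protocol's
    healthy-mean-to-full-score mapping exactly.
    """

    method: str
    weights: np.ndarray  # (n,)
    offset: float
    scaler: ZScoreScaler | MinMaxScaler
    calib_floor: float
    calib_anchor: float
    full_score: int
    s: int = 1
    nonneg: bool = False
    diagnostics: dict = field(default_factory=dict)

    def raw_score(self, rows: np.ndarray) -> np.ndarray:
        z = self.scaler.transform(rows)
        raw = z @ self.weights + self.offset
        if self.nonneg:
            raw = np.maximum(raw, 0.0)
        return raw

    def component_ei(self, rows: np.ndarray) -> np.ndarray:
        """Raw scores normalized to the task full score and clipped."""
        span = self.calib_anchor - self.calib_floor
        ei = self.full_score * (self.raw_score(rows) - self.calib_floor) / span
        return np.clip(ei, 0.0, self.full_score)


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa < _EPS or sb < _EPS:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _calibration(
    raw: np.ndarray, healthy_mask: np.ndarray, task_norm: str
) -> tuple[float, float]:
    """(floor, anchor) of the task-score calibration on training raw scores."""
    healthy_raw = raw[healthy_mask]
    if healthy_raw.size == 0:
        raise ValidationError("no healthy training rows for normalization")
    floor = float(raw.min())
    if task_norm == "healthy_mean":
        anchor = float(healthy_raw.mean())
    elif task_norm == "healthy_max":
        anchor = float(healthy_raw.max())
    elif task_norm == "global_max":
        anchor = float(raw.max())
    else:
        raise ValidationError(f"unknown task_norm {task_norm!r}")
    if anchor - floor < _EPS:
        raise ValidationError("degenerate score normalization (zero spread)")
    return floor, anchor


def _calibrate(
    model: "FactorModel",
    v: "FeatureMatrix",
    healthy_mask: np.ndarray,
    task_norm: str,
) -> "FactorModel":
    model.calib_floor, model.calib_anchor = _calibration(
        model.raw_score(v.v), healthy_mask, task_norm
    )
    return model


# ---------------------------------------------------------------------------
# PCA


def fit_pca(
    v: FeatureMatrix,
    full_score: int,
    healthy_mask: np.ndarray,
    config: PipelineConfig | None = None,
) -> FactorModel:
    """Leading principal component of the standardized feature matrix."""
    cfg = config or PipelineConfig()
    if v.v.shape[0] < 2:
        raise ValidationError("PCA needs at least 2 rows")
    scaler = ZScoreScaler.fit(v.v)
    z = scaler.transform(v.v)
    cov = np.cov(z, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(np.atleast_2d(cov))
    if eigvals[-1] < _EPS:
        raise ValidationError("zero-variance feature matrix")
    w = eigvecs[:, -1]
    scores = z @ w
    if _corr(scores, z[:, 0]) < 0:
        w = -w
        scores = -scores
    model = FactorModel(
        method="pca",
        weights=w,
        offset=0.0,  # z-scoring already centers the scores
        scaler=scaler,
        calib_floor=0.0,
        calib_anchor=1.0,
        full_score=full_score,
        diagnostics={"leading_eigenvalue": float(eigvals[-1])},
    )
    return _calibrate(model, v, healthy_mask, cfg.task_norm)


# ---------------------------------------------------------------------------
# Sammon-criterion MDS


def sammon_stress(d_high: np.ndarray, d_low: np.ndarray) -> float:
    """Sammon's stress between condensed high- and low-dimensional distances:
    (1 / sum d*) * sum (d* - d)^2 / d*."""
    c = d_high.sum()
    if c < _EPS:
        raise ValidationError("degenerate distance matrix (all-zero)")
    return float(np.sum((d_high - d_low) ** 2 / np.maximum(d_high, _EPS)) / c)


def _sammon_1d(
    d_star: np.ndarray,  # (m, m) square high-dimensional distances
    y0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, int]:
    """Gradient descent on Sammon stress for a 1-D embedding, keeping the
    best-seen configuration (so the result is never worse than the start)."""
    m = d_star.shape[0]
    iu = np.triu_indices(m, 1)
    c = d_star[iu].sum()
    y = y0.astype(float).copy()

    def stress_of(yv: np.ndarray) -> float:
        d = np.abs(yv[:, None] - yv[None, :])
        return float(np.sum((d_star[iu] - d[iu]) ** 2 / np.maximum(d_star[iu], _EPS)) / c)

    best_y = y.copy()
    best = prev = stress_of(y)
    step = 0.3
    it = 0
    for it in range(max_iter):
        d = np.abs(y[:, None] - y[None, :])
        np.fill_diagonal(d, 1.0)
        ds = np.maximum(d_star, _EPS)
        coef = (d_star - d) / (ds * d)
        np.fill_diagonal(coef, 0.0)
        grad = (-2.0 / c) * np.sum(coef * (y[:, None] - y[None, :]), axis=1)
        gnorm = np.linalg.norm(grad)
        if gnorm < _EPS:
            break
        scale = np.std(y) + _EPS
        y_new = y - step * scale * grad / gnorm
        s_new = stress_of(y_new)
        if s_new < prev:
            y = y_new
            if s_new < best:
                best, best_y = s_new, y_new.copy()
            if prev - s_new < tol * max(prev, _EPS):
                prev = s_new
                break
            prev = s_new
            step *= 1.1
        else:
            step *= 0.5
            if step < 1e-12:
                break
    return best_y, best, it + 1


def fit_mds(
    v: FeatureMatrix,
    full_score: int,
    healthy_mask: np.ndarray,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> FactorModel:
    """1-D metric MDS under Sammon's stress criterion.

    The embedding is optimized from both a PCA-projection start (with seeded
    jitter) and a random start, keeping the better solution; duplicate rows
    are perturbed by a seeded 1e-9 jitter to avoid zero reference distances.
    The out-of-sample map is an ordinary least-squares fit from standardized
    features to the embedded coordinate — the linear transform applied to
    test rows.
    """
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    scaler = ZScoreScaler.fit(v.v)
    z = scaler.transform(v.v)
    d_cond = pdist(z)
    if np.any(d_cond < _EPS):
        z = z + rng.normal(0.0, 1e-9, z.shape)
        d_cond = pdist(z)
    d_star = squareform(d_cond)

    # PCA start
    cov = np.cov(z, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(np.atleast_2d(cov))
    y_pca = z @ eigvecs[:, -1]
    y_pca = y_pca + rng.normal(0.0, 1e-6 * (np.std(y_pca) + _EPS), y_pca.shape)
    y1, s1, it1 = _sammon_1d(d_star, y_pca, cfg.mds_tol, cfg.mds_max_iter)
    # random start
    y_rand = rng.normal(0.0, np.std(d_cond) + _EPS, z.shape[0])
    y2, s2, it2 = _sammon_1d(d_star, y_rand, cfg.mds_tol, cfg.mds_max_iter)
    y, stress = (y1, s1) if s1 <= s2 else (y2, s2)
    if max(it1, it2) >= cfg.mds_max_iter:
        logger.warning("Sammon mapping hit max iterations; final stress %.3g", stress)

    # linear out-of-sample map: standardized features -> embedding
    design = np.column_stack([z, np.ones(z.shape[0])])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    w, offset = coef[:-1], float(coef[-1])
    scores = z @ w + offset
    if _corr(scores, z[:, 0]) < 0:
        w, offset = -w, -offset
    model = FactorModel(
        method="mds",
        weights=w,
        offset=offset,
        scaler=scaler,
        calib_floor=0.0,
        calib_anchor=1.0,
        full_score=full_score,
        diagnostics={"stress": stress, "iterations": int(max(it1, it2))},
    )
    return _calibrate(model, v, healthy_mask, cfg.task_norm)


# ---------------------------------------------------------------------------
# NMF


def nmf_rank1(
    v: np.ndarray, sweeps: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rank-1 NMF by multiplicative updates with per-sweep renormalization.

    Returns (W (m, 1), H (1, n), Frobenius error after each sweep).  The W
    column is renormalized to unit norm each sweep with the inverse scale
    absorbed into H, so the product — and the error sequence, which is
    non-increasing for multiplicative updates — is unchanged.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValidationError("NMF input must be nonnegative")
    if not np.any(v > 0):
        raise ValidationError("NMF input is identically zero")
    rng = np.random.default_rng(seed)
    m, n = v.shape
    w = rng.uniform(0.1, 1.0, (m, 1))
    h = rng.uniform(0.1, 1.0, (1, n))
    errors = np.empty(sweeps)
    for s in range(sweeps):
        w *= (v @ h.T) / np.maximum(w @ (h @ h.T), _EPS)
        h *= (w.T @ v) / np.maximum((w.T @ w) @ h, _EPS)
        nrm = np.linalg.norm(w[:, 0])
        if nrm > _EPS:
            w /= nrm
            h *= nrm
        errors[s] = np.linalg.norm(v - w @ h)
    return w, h, errors


def fit_nmf(
    v: FeatureMatrix,
    full_score: int,
    healthy_mask: np.ndarray,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> FactorModel:
    """Rank-1 NMF on the min-max-scaled, healthy-high-oriented features.

    The out-of-sample weight for a scaled test row x is the nonnegative
    least-squares projection max(0, x h' / h h') — the pseudo-inverse of H
    applied to the row.
    """
    cfg = config or PipelineConfig()
    ref_corr = np.array(
        [_corr(v.v[:, j], v.v[:, 0]) < 0 for j in range(v.v.shape[1])]
    )
    scaler = MinMaxScaler.fit(v.v, ref_corr)
    z = scaler.transform(v.v)
    w_col, h, errors = nmf_rank1(z, cfg.nmf_sweeps, seed)
    hh = float(np.dot(h[0], h[0]))
    weights = h[0] / max(hh, _EPS)
    model = FactorModel(
        method="nmf",
        weights=weights,
        offset=0.0,
        scaler=scaler,
        calib_floor=0.0,
        calib_anchor=1.0,
        full_score=full_score,
        nonneg=True,
        diagnostics={"reconstruction_error": float(errors[-1])},
    )
    return _calibrate(model, v, healthy_mask, cfg.task_norm)


# ---------------------------------------------------------------------------
# LASSO


def lasso_solve(
    v: np.ndarray,
    y: np.ndarray,
    lam: float,
    fit_intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 20000,
) -> tuple[np.ndarray, float]:
    """Minimize ||V z - y||_2^2 + lam ||z||_1; returns (z, intercept).

    lam = 0 reduces to exact least squares.  The coordinate-descent solver's
    penalty scale alpha = lam / (2 m) makes its objective proportional to
    this one.
    """
    v = np.asarray(v, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValidationError("lambda must be nonnegative")
    if lam == 0:
        if fit_intercept:
            design = np.column_stack([v, np.ones(v.shape[0])])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            return coef[:-1], float(coef[-1])
        coef, *_ = np.linalg.lstsq(v, y, rcond=None)
        return coef, 0.0
    est = Lasso(
        alpha=lam / (2.0 * v.shape[0]),
        fit_intercept=fit_intercept,
        max_iter=max_iter,
        tol=tol,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        est.fit(v, y)
    return est.coef_.copy(), float(est.intercept_) if fit_intercept else 0.0


def select_lambda(
    v: np.ndarray,
    y: np.ndarray,
    grid: Sequence[float],
    seed: int,
    n_folds: int = 5,
) -> float:
    """Inner k-fold cross-validation over a lambda grid (seeded shuffling)."""
    n_folds = min(n_folds, v.shape[0])
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    mse = np.zeros(len(grid))
    for tr, te in kf.split(v):
        for g, lam in enumerate(grid):
            # loose solver tolerance: adequate for grid selection
            z, b = lasso_solve(v[tr], y[tr], lam, tol=1e-5, max_iter=3000)
            mse[g] += float(np.mean((v[te] @ z + b - y[te]) ** 2))
    return float(grid[int(np.argmin(mse))])


def fit_lasso(
    v: FeatureMatrix,
    y: np.ndarray,
    full_score: int,
    healthy_mask: np.ndarray,
    config: PipelineConfig | None = None,
    seed: int = 0,
    lam: Optional[float] = None,
) -> FactorModel:
    """L1-penalized regression of the clinical item scores on the features."""
    cfg = config or PipelineConfig()
    y = np.asarray(y, dtype=float)
    if y.shape[0] != v.v.shape[0]:
        raise ValidationError("observations not aligned with feature rows")
    if np.ptp(y) < _EPS:
        raise ValidationError("all observation values equal; no signal to fit")
    scaler = ZScoreScaler.fit(v.v)
    z = scaler.transform(v.v)
    if lam is None:
        lam = select_lambda(z, y, cfg.lambda_grid, seed)
    weights, offset = lasso_solve(z, y, lam)
    model = FactorModel(
        method="lasso",
        weights=weights,
        offset=offset,
        scaler=scaler,
        calib_floor=0.0,
        calib_anchor=1.0,
        full_score=full_score,
        diagnostics={"lambda": float(lam), "n_active": int(np.count_nonzero(weights))},
    )
    return _calibrate(model, v, healthy_mask, cfg.task_norm)


def score_task(model: FactorModel, feature_row: np.ndarray) -> float:
    """Component indicator (points on the task scale) for one feature row."""
    row = np.asarray(feature_row, dtype=float)
    if row.shape[-1] != model.weights.shape[0]:
        raise ValidationError(
            f"feature row has {row.shape[-1]} entries; model expects "
            f"{model.weights.shape[0]}"
        )
    return float(model.component_ei(row)[0])


_FITTERS = {"pca": fit_pca, "mds": fit_mds, "nmf": fit_nmf, "lasso": fit_lasso}


# ---------------------------------------------------------------------------
# validity metrics


def _sd(x: np.ndarray, convention: str = "sample") -> float:
    ddof = 1 if convention == "sample" else 0
    return float(np.std(x, ddof=ddof)) if x.size > ddof else 0.0


def ndvr(healthy_eis: np.ndarray, sd_convention: str = "sample") -> float:
    """Normal data variation rate: 100 * 1.96 * SD / mean (percent)."""
    x = np.asarray(healthy_eis, dtype=float)
    mean = x.mean()
    if mean <= 0:
        raise ValidationError("NDVR undefined for non-positive mean")
    return 100.0 * 1.96 * _sd(x, sd_convention) / mean


def normal_range(
    healthy_eis: np.ndarray, sd_convention: str = "sample"
) -> tuple[float, float]:
    """(mean - 1.96 SD, mean + 1.96 SD) of the healthy indicators."""
    x = np.asarray(healthy_eis, dtype=float)
    mean, sd = x.mean(), _sd(x, sd_convention)
    return (float(mean - 1.96 * sd), float(mean + 1.96 * sd))


def determination_coefficient(eis: np.ndarray, fmue_scores: np.ndarray) -> float:
    """R^2 of the simple linear regression of clinical scores on indicators."""
    x = np.asarray(eis, dtype=float)
    y = np.asarray(fmue_scores, dtype=float)
    if x.std() < _EPS:
        logger.warning("zero-variance predictor; determination coefficient set to 0")
        return 0.0
    if y.std() < _EPS:
        return 0.0
    return float(stats.linregress(x, y).rvalue ** 2)


# ---------------------------------------------------------------------------
# leave-one-subject-out harness


@dataclass
class CohortResult:
    """Per-subject indicators and cohort-level validity metrics."""

    method: str
    subjects: list[SubjectMeta]
    component_ei: dict[str, dict[int, float]]  # task-scale points, unexpanded
    raw_global_ei: dict[str, float]
    global_ei: dict[str, float]  # after expansion (FMUE-comparable)
    expansion_factor: float
    normal_range: tuple[float, float]
    ndvr: float
    dc: float
    in_normal_range: dict[str, bool]
    diagnostics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        task_ids = sorted(next(iter(self.component_ei.values())).keys())
        rows = []
        for meta in self.subjects:
            sid = meta.subject_id
            row = {
                "subject_id": sid,
                "group": meta.group,
                "fmue_total": meta.fmue_total,
            }
            for tid in task_ids:
                row[f"ei_task{tid:02d}"] = self.component_ei[sid][tid]
            row["global_ei"] = self.global_ei[sid]
            row["in_normal_range"] = self.in_normal_range[sid]
            rows.append(row)
        return pd.DataFrame(rows)


def _fold_seed(master_seed: int, fold: int, task_id: int) -> int:
    return (master_seed * 1000003 + fold * 8191 + task_id) % (2**31)


def loso_evaluate(
    subjects: Sequence[SubjectMeta],
    cohort: CohortFeatures,
    method: str,
    config: PipelineConfig | None = None,
    task_set: Optional[Sequence[TaskDefinition]] = None,
    pairwise: Optional[Mapping[int, TaskPairwise]] = None,
) -> CohortResult:
    """N-fold leave-one-subject-out evaluation of one method.

    For each held-out subject, the reference bank, feature standardization
    and factor model are fitted on the remaining subjects only; the held-out
    subject's repetitions are scored out of sample.  The healthy-subject
    mean of the global indicator is expanded to 66 and the same factor
    applied to everyone.
    """
    cfg = config or PipelineConfig()
    tasks = {t.task_id: t for t in (task_set or load_task_set())}
    task_ids = sorted(tid for tid in cohort if tid in tasks)
    if not task_ids:
        raise ValidationError("no tasks shared between cohort and task set")
    healthy_ids = [m.subject_id for m in subjects if m.group == "healthy"]
    n_healthy = len(healthy_ids)
    if pairwise is None:
        pairwise = {
            tid: compute_pairwise(cohort[tid], healthy_ids, cfg) for tid in task_ids
        }

    component: dict[str, dict[int, float]] = {}
    for fold, meta in enumerate(subjects):
        h = meta.subject_id
        if n_healthy - (1 if meta.group == "healthy" else 0) < 2:
            raise ValidationError("fold with fewer than 2 healthy training subjects")
        component[h] = {}
        for tid in task_ids:
            entries = cohort[tid]
            pw = pairwise[tid]
            test_idx = [i for i, e in enumerate(entries) if e.subject_id == h]
            if not test_idx:
                logger.warning("subject %s has no segments for task %d", h, tid)
                component[h][tid] = 0.0
                continue
            if method in ("pcc", "dtw"):
                k = 0 if method == "pcc" else 1
                vals = [pw.indicators(i, frozenset({h}))[k] for i in test_idx]
                component[h][tid] = float(np.mean(vals))
                continue
            train_idx = [i for i, e in enumerate(entries) if e.subject_id != h]
            v_train = assemble_features(entries, pw, healthy_ids, h, train_idx)
            v_test = assemble_features(entries, pw, healthy_ids, h, test_idx)
            healthy_mask = np.array(
                [sid in set(healthy_ids) for sid, _, _ in v_train.rows]
            )
            seed = _fold_seed(cfg.master_seed, fold, tid)
            if method == "lasso":
                items = {
                    m.subject_id: m.fmue_item_scores.get(tid, 0) for m in subjects
                }
                y = np.array([items[sid] for sid, _, _ in v_train.rows], dtype=float)
                model = fit_lasso(
                    v_train, y, tasks[tid].full_score, healthy_mask, cfg, seed
                )
            elif method in ("mds", "nmf"):
                model = _FITTERS[method](
                    v_train, tasks[tid].full_score, healthy_mask, cfg, seed
                )
            elif method == "pca":
                model = fit_pca(v_train, tasks[tid].full_score, healthy_mask, cfg)
            else:
                raise ValidationError(f"unknown method {method!r}")
            component[h][tid] = float(np.mean(model.component_ei(v_test.v)))

    raw_global = {sid: float(sum(component[sid].values())) for sid in component}
    healthy_globals = np.array([raw_global[sid] for sid in healthy_ids])
    healthy_mean = healthy_globals.mean()
    if healthy_mean <= 0:
        raise ValidationError("non-positive healthy mean global indicator")
    expansion = 66.0 / healthy_mean
    scaled = {sid: g * expansion for sid, g in raw_global.items()}
    scaled_healthy = np.array([scaled[sid] for sid in healthy_ids])
    nr = normal_range(scaled_healthy, cfg.sd_convention)
    rate = ndvr(scaled_healthy, cfg.sd_convention)
    fmue = np.array([m.fmue_total for m in subjects], dtype=float)
    eis = np.array([scaled[m.subject_id] for m in subjects])
    dc = determination_coefficient(eis, fmue)
    in_range = {sid: bool(nr[0] <= scaled[sid] <= nr[1]) for sid in scaled}
    return CohortResult(
        method=method,
        subjects=list(subjects),
        component_ei=component,
        raw_global_ei=raw_global,
        global_ei=scaled,
        expansion_factor=float(expansion),
        normal_range=nr,
        ndvr=float(rate),
        dc=float(dc),
        in_normal_range=in_range,
        diagnostics={"n_folds": len(subjects), "n_healthy": n_healthy},
    )
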