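"""Factor models (PCA, Sammon MDS, NMF, LASSO), calibration and metrics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import limbeval as lv
from limbeval.ei_models import (
    FEATURE_COLUMNS,
    FeatureMatrix,
    fit_pca,
    fit_mds,
    fit_lasso,
)
from scipy.spatial.distance import pdist, squareform


def _fm(v, columns=None):
    v = np.asarray(v, dtype=float)
    cols = columns or tuple(f"f{i}" for i in range(v.shape[1]))
    rows = [(f"S{i:02d}", 1, 0) for i in range(v.shape[0])]
    return FeatureMatrix(v, rows, cols)


class TestFeatureMatrixAssembly:
    def test_row_counts_and_schema(self, tiny_cohort):
        subjects, _, cohort, pairwise = tiny_cohort
        healthy = [m.subject_id for m in subjects if m.group == "healthy"]
        fm = lv.assemble_features(cohort[1], pairwise[1], healthy)
        assert fm.v.shape == (3 * len(subjects), 19)
        assert fm.columns[0] == "pcc"
        assert fm.columns == FEATURE_COLUMNS

    def test_row_recomputed_independently(self, tiny_cohort):
        subjects, _, cohort, pairwise = tiny_cohort
        healthy = [m.subject_id for m in subjects if m.group == "healthy"]
        fm = lv.assemble_features(cohort[1], pairwise[1], healthy)
        i = 4
        entry = cohort[1][i]
        exclude = frozenset({entry.subject_id}) if entry.subject_id in healthy else frozenset()
        expected = np.concatenate(
            [pairwise[1].indicators(i, exclude), entry.supp.vector()]
        )
        np.testing.assert_allclose(fm.v[i], expected)

    def test_nan_rejected_with_provenance(self):
        v = np.zeros((3, 19))
        v[1, 4] = np.nan
        with pytest.raises(lv.ValidationError, match="S01"):
            _fm(v, FEATURE_COLUMNS)


class TestPca:
    def test_collinear_rows_closed_form(self):
        v = _fm([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        model = fit_pca(v, 2, np.array([True, True, True]),
                        lv.PipelineConfig(task_norm="healthy_mean"))
        scores = model.raw_score(v.v)
        centered = scores - scores.mean()
        # scores proportional to (-sqrt2, 0, sqrt2); variance = leading eigenvalue
        ratio = centered / np.array([-np.sqrt(2), np.nan, np.sqrt(2)])
        assert centered[1] == pytest.approx(0.0, abs=1e-12)
        assert ratio[0] == pytest.approx(ratio[2])
        assert np.var(centered, ddof=1) == pytest.approx(
            model.diagnostics["leading_eigenvalue"]
        )

    def test_single_active_column(self):
        rng = np.random.default_rng(0)
        v = np.ones((10, 3))
        v[:, 1] = rng.normal(size=10)
        model = fit_pca(_fm(v), 2, np.ones(10, dtype=bool))
        w = np.abs(model.weights)
        assert w[1] == pytest.approx(1.0) and w[[0, 2]] == pytest.approx(0.0)

    def test_matches_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(20, 5))
        model = fit_pca(_fm(v), 2, np.ones(20, dtype=bool))
        z = model.scaler.transform(v)
        _, _, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
        oracle = (z - z.mean(axis=0)) @ vt[0]
        scores = model.raw_score(v) - model.raw_score(v).mean()
        agreement = min(
            np.max(np.abs(scores - oracle)), np.max(np.abs(scores + oracle))
        )
        assert agreement < 1e-8

    def test_zero_variance_rejected(self):
        with pytest.raises(lv.ValidationError):
            fit_pca(_fm(np.ones((5, 3))), 2, np.ones(5, dtype=bool))


class TestSammonMds:
    def test_collinear_geometry_embeds_perfectly(self):
        t = np.linspace(0, 1, 8)
        v = np.column_stack([t, 2 * t + 1])  # points on a line
        model = fit_mds(_fm(v), 2, np.ones(8, dtype=bool), seed=0)
        assert model.diagnostics["stress"] < 1e-6

    def test_triangle_cannot_embed_in_1d(self):
        v = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        model = fit_mds(_fm(v), 2, np.ones(3, dtype=bool), seed=0)
        assert model.diagnostics["stress"] > 1e-4

    def test_never_worse_than_pca_start(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(10, 4))
        fm = _fm(v)
        model = fit_mds(fm, 2, np.ones(10, dtype=bool), seed=3)
        # Sammon stress of the plain PCA projection, from the formula
        z = model.scaler.transform(v)
        cov = np.cov(z, rowvar=False, ddof=1)
        _, vecs = np.linalg.eigh(cov)
        y_pca = z @ vecs[:, -1]
        d_star = squareform(pdist(z))
        d_low = np.abs(y_pca[:, None] - y_pca[None, :])
        iu = np.triu_indices(10, 1)
        c = d_star[iu].sum()
        pca_stress = np.sum((d_star[iu] - d_low[iu]) ** 2 / d_star[iu]) / c
        assert model.diagnostics["stress"] <= pca_stress + 1e-12

    def test_duplicate_rows_handled(self):
        v = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 1.0], [0.0, 0.0]])
        model = fit_mds(_fm(v), 2, np.ones(4, dtype=bool), seed=1)
        assert np.isfinite(model.diagnostics["stress"])

    def test_stress_formula(self):
        d_high = np.array([1.0, 2.0, 3.0])
        assert lv.sammon_stress(d_high, d_high) == 0.0
        got = lv.sammon_stress(d_high, np.array([1.0, 2.0, 2.0]))
        assert got == pytest.approx((1.0 / 6.0) * (1.0 / 3.0))


class TestNmf:
    def test_rank1_exact_recovery(self):
        rng = np.random.default_rng(3)
        w = rng.uniform(0.5, 2.0, 12)
        h = rng.uniform(0.5, 2.0, 5)
        v = np.outer(w, h)
        w_fit, h_fit, errors = lv.nmf_rank1(v, sweeps=300, seed=0)
        assert errors[-1] < 1e-8
        ratio = w_fit[:, 0] / w
        assert np.ptp(ratio) / ratio.mean() < 1e-6  # W proportional to w

    @given(seed=st.integers(0, 2**16))
    def test_error_monotone_nonincreasing(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 1, (15, 6))
        w, h, errors = lv.nmf_rank1(v, sweeps=100, seed=seed)
        assert np.all(np.diff(errors) <= 1e-10)
        # reported error verified against a direct recomputation
        assert errors[-1] == pytest.approx(np.linalg.norm(v - w @ h))

    def test_nonnegativity_and_guards(self):
        rng = np.random.default_rng(4)
        w, h, _ = lv.nmf_rank1(rng.uniform(0, 1, (8, 4)), sweeps=50, seed=1)
        assert np.all(w >= 0) and np.all(h >= 0)
        with pytest.raises(lv.ValidationError):
            lv.nmf_rank1(np.zeros((4, 4)), 10, 0)
        with pytest.raises(lv.ValidationError):
            lv.nmf_rank1(-np.ones((4, 4)), 10, 0)


class TestLasso:
    def test_unpenalized_limit_is_least_squares(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=(4, 4))
        y = rng.normal(size=4)
        z, b = lv.lasso_solve(v, y, 0.0, fit_intercept=False)
        np.testing.assert_allclose(v @ z, y, atol=1e-8)

    def test_orthonormal_soft_thresholding(self):
        # identity design: z_i = sign(y_i) * max(|y_i| - lam/2, 0)
        z, _ = lv.lasso_solve(np.eye(2), np.array([3.0, 1.0]), 1.0, fit_intercept=False)
        np.testing.assert_allclose(z, [2.5, 0.5], atol=1e-6)

    def test_full_shrinkage_at_large_lambda(self):
        rng = np.random.default_rng(6)
        z, _ = lv.lasso_solve(rng.normal(size=(10, 3)), rng.normal(size=10), 1e6,
                              fit_intercept=False)
        np.testing.assert_allclose(z, 0.0)

    def test_orthonormal_path_shrinks_monotonically(self):
        y = np.array([3.0, -2.0, 1.0])
        prev = None
        for lam in (0.0, 0.5, 1.0, 2.0, 4.0):
            z, _ = lv.lasso_solve(np.eye(3), y, lam, fit_intercept=False)
            if prev is not None:
                assert np.all(np.abs(z) <= np.abs(prev) + 1e-9)
            prev = z

    def test_constant_observations_rejected(self):
        rng = np.random.default_rng(7)
        fm = _fm(rng.normal(size=(6, 3)))
        with pytest.raises(lv.ValidationError, match="equal"):
            fit_lasso(fm, np.full(6, 2.0), 2, np.ones(6, dtype=bool))


class TestScoreCalibration:
    def test_healthy_mean_row_maps_to_full_score(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=(20, 5))
        healthy = np.zeros(20, dtype=bool)
        healthy[:10] = True
        cfg = lv.PipelineConfig(task_norm="healthy_mean")
        model = fit_pca(_fm(v), 8, healthy, cfg)
        # a synthetic row whose raw score equals the healthy training mean
        mean_row = v[healthy].mean(axis=0)
        assert lv.score_task(model, mean_row) == pytest.approx(8.0)

    def test_training_row_scores_consistently(self):
        rng = np.random.default_rng(9)
        v = rng.normal(size=(12, 4))
        model = fit_pca(_fm(v), 6, np.ones(12, dtype=bool))
        eis = model.component_ei(v)
        assert lv.score_task(model, v[3]) == pytest.approx(eis[3])

    def test_schema_mismatch_rejected(self):
        rng = np.random.default_rng(10)
        model = fit_pca(_fm(rng.normal(size=(6, 4))), 2, np.ones(6, dtype=bool))
        with pytest.raises(lv.ValidationError, match="expects"):
            lv.score_task(model, np.zeros(7))

    def test_clipping_to_task_scale(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=(15, 3))
        model = fit_pca(_fm(v), 4, np.ones(15, dtype=bool))
        eis = model.component_ei(rng.normal(size=(50, 3)) * 10)
        assert np.all(eis >= 0.0) and np.all(eis <= 4.0)


class TestMetrics:
    def test_ndvr_examples(self):
        assert lv.ndvr(np.full(5, 7.0)) == 0.0
        # values (8, 10, 12): sample SD 2, mean 10 -> 100 * 1.96 * 2 / 10
        assert lv.ndvr(np.array([8.0, 10.0, 12.0])) == pytest.approx(39.2)

    @given(c=st.floats(0.1, 100.0))
    def test_ndvr_scale_invariance(self, c):
        x = np.array([8.0, 10.0, 12.0])
        assert lv.ndvr(c * x) == pytest.approx(lv.ndvr(x))

    def test_ndvr_nonpositive_mean_rejected(self):
        with pytest.raises(lv.ValidationError):
            lv.ndvr(np.array([-1.0, 1.0]))

    def test_normal_range_examples(self):
        assert lv.normal_range(np.full(4, 3.0)) == (3.0, 3.0)
        lo, hi = lv.normal_range(np.array([8.0, 10.0, 12.0]))
        assert (lo, hi) == pytest.approx((6.08, 13.92))
        mid = (lo + hi) / 2
        assert mid == pytest.approx(10.0)

    def test_determination_coefficient_examples(self):
        x = np.array([1.0, 2.0, 3.0])
        assert lv.determination_coefficient(x, 2 * x + 1) == pytest.approx(1.0)
        assert lv.determination_coefficient(
            np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 2.0])
        ) == pytest.approx(0.75)

    def test_dc_affine_invariance(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=30)
        y = 2 * x + rng.normal(size=30)
        base = lv.determination_coefficient(x, y)
        assert lv.determination_coefficient(3 * x - 7, y) == pytest.approx(base)
        assert lv.determination_coefficient(x, -0.5 * y + 4) == pytest.approx(base)

    def test_dc_zero_variance_predictor_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            assert lv.determination_coefficient(np.ones(5), np.arange(5.0)) == 0.0
        assert "zero-variance" in caplog.text


class TestLosoHarness:
    def test_clone_cohort_gives_zero_ndvr(self):
        subjects, trials = lv.generate_cohort(n_healthy=2, n_stroke=0, master_seed=5)
        base_meta, base_trials = subjects[0], [t for t in trials if t.subject_id == "H01"]
        clones, clone_trials = [], []
        for k in range(4):
            sid = f"C{k:02d}"
            meta = lv.SubjectMeta(
                sid, "healthy", base_meta.tested_side, 66,
                dict(base_meta.fmue_item_scores), base_meta.age, base_meta.sex,
            )
            clones.append(meta)
            for t in base_trials:
                clone_trials.append(
                    lv.TrialRecording(sid, t.task_id, t.emg, t.acc1, t.acc2,
                                      t.gyro1, t.gyro2)
                )
        cohort = lv.extract_cohort(clone_trials)
        res = lv.loso_evaluate(clones, cohort, "pcc")
        eis = list(res.global_ei.values())
        assert np.ptp(eis) < 1e-9
        assert res.ndvr == pytest.approx(0.0, abs=1e-9)
        assert all(res.in_normal_range.values())

    def test_too_few_healthy_training_subjects_rejected(self):
        subjects, trials = lv.generate_cohort(n_healthy=2, n_stroke=1, master_seed=6)
        cohort = lv.extract_cohort(trials)
        with pytest.raises(lv.ValidationError, match="healthy training"):
            lv.loso_evaluate(subjects, cohort, "pcc")

    def test_expansion_sets_healthy_mean_to_66(self, tiny_cohort):
        subjects, _, cohort, pairwise = tiny_cohort
        res = lv.loso_evaluate(subjects, cohort, "pca", pairwise=pairwise)
        healthy_eis = [
            res.global_ei[m.subject_id] for m in subjects if m.group == "healthy"
        ]
        assert np.mean(healthy_eis) == pytest.approx(66.0, abs=1e-9)
        assert res.diagnostics["n_folds"] == len(subjects)

    def test_component_eis_on_task_scale(self, tiny_cohort):
        subjects, _, cohort, pairwise = tiny_cohort
        res = lv.loso_evaluate(subjects, cohort, "nmf", pairwise=pairwise)
        tasks = {t.task_id: t.full_score for t in lv.load_task_set()}
        for sid, comps in res.component_ei.items():
            for tid, ei in comps.items():
                assert 0.0 <= ei <= tasks[tid] + 1e-9

    def test_results_frame_schema(self, tiny_cohort):
        subjects, _, cohort, pairwise = tiny_cohort
        res = lv.loso_evaluate(subjects, cohort, "dtw", pairwise=pairwise)
        df = res.to_frame()
        assert len(df) == len(subjects)
        assert {"subject_id", "group", "fmue_total", "global_ei", "in_normal_range"} <= set(df.columns)
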