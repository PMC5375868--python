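"""Similarity scoring: PCC, DTW, power distances, and the reference bank."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import limbeval as lv
from limbeval.scoring import build_reference_bank, preliminary_ei

from conftest import dtw_exhaustive, pearson_textbook


def _random_mdp(rng):
    return rng.normal(0, 1, (22, 256))


class TestPccSimilarity:
    def test_identical_entry_gives_one(self):
        rng = np.random.default_rng(0)
        mdp = _random_mdp(rng)
        bank = [_random_mdp(rng), mdp.copy(), _random_mdp(rng)]
        assert lv.pcc_similarity(mdp, bank) == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        mdp = _random_mdp(rng)
        assert lv.pcc_similarity(3.0 * mdp + 2.0, [mdp]) == pytest.approx(1.0)

    def test_max_over_bank_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        mdp = _random_mdp(rng)
        bank = [_random_mdp(rng) for _ in range(5)]
        expected = max(pearson_textbook(mdp, ref) for ref in bank)
        assert lv.pcc_similarity(mdp, bank) == pytest.approx(expected)

    def test_all_degenerate_pairs_rejected(self):
        with pytest.raises(lv.ValidationError, match="degenerate"):
            lv.pcc_similarity(np.ones((22, 256)), [np.zeros((22, 256))])


class TestDtwDistance:
    def test_identical_sequences_zero(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(20, 22))
        assert lv.dtw_distance(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_known_small_case(self):
        # [1,2,3] vs [1,3] with |a-b| local cost: optimal alignment cost 1
        assert lv.dtw_distance(np.array([1.0, 2.0, 3.0]), np.array([1.0, 3.0])) == 1.0

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=60)
    def test_matches_exhaustive_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(1, 7), rng.integers(1, 7)
        d = int(rng.integers(1, 4))
        a = rng.normal(size=(n, d))
        b = rng.normal(size=(m, d))
        assert lv.dtw_distance(a, b) == pytest.approx(dtw_exhaustive(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(lv.ValidationError):
            lv.dtw_distance(np.empty((0, 2)), np.zeros((3, 2)))

    def test_bank_minimum_and_singleton(self):
        rng = np.random.default_rng(4)
        mdp = _random_mdp(rng)
        bank = [_random_mdp(rng) for _ in range(5)]
        expected = min(lv.dtw_distance(mdp.T, ref.T) for ref in bank)
        assert lv.dtw_similarity(mdp, bank) == pytest.approx(expected)
        assert lv.dtw_similarity(mdp, [bank[0]]) == pytest.approx(
            lv.dtw_distance(mdp.T, bank[0].T)
        )
        assert lv.dtw_similarity(mdp, [mdp]) == pytest.approx(0.0, abs=1e-12)


class TestPowerDistance:
    def test_identical_vectors(self):
        v = np.array([0.2, 0.3, 0.5])
        assert lv.power_distance(v, [v]) == 0.0

    def test_orthogonal_unit_vectors(self):
        a = np.eye(10)[0]
        b = np.eye(10)[1]
        assert lv.power_distance(a, [b]) == pytest.approx(np.sqrt(2))

    @given(seed=st.integers(0, 2**16))
    def test_matches_brute_force_minimum(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.dirichlet(np.ones(10))
        bank = [rng.dirichlet(np.ones(10)) for _ in range(6)]
        expected = min(
            np.sqrt(sum((x - y) ** 2 for x, y in zip(v, ref))) for ref in bank
        )
        assert lv.power_distance(v, bank) == pytest.approx(expected)


class TestReferenceBankAndIndicators:
    def test_bank_counts_and_exclusion(self, tiny_cohort):
        subjects, _, cohort, _ = tiny_cohort
        healthy = [m.subject_id for m in subjects if m.group == "healthy"]
        banks = build_reference_bank(cohort, healthy)
        assert len(banks[1]) == 3 * len(healthy)
        purged = build_reference_bank(cohort, healthy, exclude=[healthy[0]])
        assert len(purged[1]) == 3 * (len(healthy) - 1)
        assert healthy[0] not in purged[1].subject_ids

    def test_leakage_canary(self, tiny_cohort):
        """A healthy subject scored against a bank containing its own
        repetitions reaches PCC exactly 1; purging the bank removes that."""
        subjects, _, cohort, _ = tiny_cohort
        healthy = [m.subject_id for m in subjects if m.group == "healthy"]
        sid = healthy[0]
        own = [e for e in cohort[1] if e.subject_id == sid]
        leaky = build_reference_bank(cohort, healthy)[1]
        ind = preliminary_ei(own, leaky)
        assert ind.pcc == pytest.approx(1.0)
        assert ind.dtw == pytest.approx(0.0, abs=1e-9)
        clean = build_reference_bank(cohort, healthy, exclude=[sid])[1]
        ind2 = preliminary_ei(own, clean)
        assert ind2.pcc < 1.0 - 1e-6
        assert ind2.dtw > 1e-6

    def test_indicator_vector_has_seven_components(self, tiny_cohort):
        subjects, _, cohort, pairwise = tiny_cohort
        vec = pairwise[1].indicators(0, frozenset())
        assert vec.shape == (7,)

    def test_repetition_average(self, tiny_cohort):
        subjects, _, cohort, _ = tiny_cohort
        healthy = [m.subject_id for m in subjects if m.group == "healthy"]
        sid = subjects[-1].subject_id  # a stroke subject
        own = [e for e in cohort[2] if e.subject_id == sid]
        bank = build_reference_bank(cohort, healthy)[2]
        ind = preliminary_ei(own, bank)
        per_rep = [lv.pcc_similarity(e.mdp, bank.mdps) for e in own]
        assert ind.pcc == pytest.approx(np.mean(per_rep))

    def test_pairwise_cache_agrees_with_direct_path(self, tiny_cohort):
        """The masked-matrix fast path must reproduce the object-level
        bank computation exactly (same exclusions)."""
        subjects, _, cohort, pairwise = tiny_cohort
        healthy = [m.subject_id for m in subjects if m.group == "healthy"]
        tid = 3
        entries = cohort[tid]
        sid = healthy[1]
        own = [(i, e) for i, e in enumerate(entries) if e.subject_id == sid]
        bank = build_reference_bank(cohort, healthy, exclude=[sid])[tid]
        direct = preliminary_ei([e for _, e in own], bank).vector()
        fast = np.mean(
            [pairwise[tid].indicators(i, frozenset({sid})) for i, _ in own], axis=0
        )
        np.testing.assert_allclose(fast, direct, rtol=1e-10)

    def test_global_preliminary_ei_sums_components(self):
        per_task = {
            t: lv.PreliminaryIndicators(1.0, 2.0, 0.1, 0.1, 0.1, 0.1, 0.1)
            for t in range(1, 12)
        }
        assert lv.global_preliminary_ei(per_task, "pcc") == pytest.approx(11.0)
        assert lv.global_preliminary_ei(per_task, "dtw") == pytest.approx(22.0)
        with pytest.raises(lv.ValidationError):
            lv.global_preliminary_ei(per_task, "pca")

    def test_healthy_more_similar_than_impaired(self, tiny_cohort):
        subjects, _, cohort, pairwise = tiny_cohort
        groups = {m.subject_id: m.group for m in subjects}
        pcc_by_group = {"healthy": [], "stroke": []}
        dtw_by_group = {"healthy": [], "stroke": []}
        for tid, pw in pairwise.items():
            for i, sid in enumerate(pw.row_subjects):
                vec = pw.indicators(i, frozenset({sid}))
                pcc_by_group[groups[sid]].append(vec[0])
                dtw_by_group[groups[sid]].append(vec[1])
        assert np.mean(pcc_by_group["healthy"]) > np.mean(pcc_by_group["stroke"])
        assert np.mean(dtw_by_group["healthy"]) < np.mean(dtw_by_group["stroke"])
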