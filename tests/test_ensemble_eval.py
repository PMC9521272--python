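"""Soft voting, ranking, AUC, and cross-validation protocol."""

import numpy as np
import pytest

import cda_netfuse.ensemble_eval as ee
from cda_netfuse.core_data import AssociationMatrix, HyperParams, ScoreMatrix, SimilarityMatrix
from cda_netfuse.ensemble_eval import (
    auc_ranked,
    cross_validate,
    ensemble_combine,
    predict_scores,
    rank_for_disease,
    theta_sweep,
)
from cda_netfuse.synthetic import generate, small_preset
from tests.conftest import random_association, random_similarity


def score_matrix(values, circ=None, dis=None):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return ScoreMatrix(circ or [f"c{i}" for i in range(m)], dis or [f"d{j}" for j in range(n)], values)


class TestEnsembleCombine:
    def test_theta_zero_returns_p(self, rng):
        P = score_matrix(rng.random((3, 2)))
        F = score_matrix(rng.random((3, 2)))
        np.testing.assert_array_equal(ensemble_combine(P, F, 0.0).values, P.values)

    def test_hand_value(self):
        P, F = score_matrix([[0.2]]), score_matrix([[1.0]])
        assert ensemble_combine(P, F, 0.3).values[0, 0] == pytest.approx(0.5)

    def test_superposition(self, rng):
        P1, P2, F = (score_matrix(rng.random((3, 2))) for _ in range(3))
        a, b = 0.6, 1.3
        combined = ensemble_combine(score_matrix(a * P1.values + b * P2.values), F, 0.3)
        parts = (
            a * ensemble_combine(P1, F, 0.3).values
            + b * ensemble_combine(P2, F, 0.3).values
            - (a + b - 1) * 0.3 * F.values
        )
        np.testing.assert_allclose(combined.values, parts, atol=1e-12)

    def test_id_mismatch_errors(self, rng):
        P = score_matrix(rng.random((2, 2)))
        F = score_matrix(rng.random((2, 2)), circ=["cX", "c1"])
        with pytest.raises(ValueError, match="mismatched"):
            ensemble_combine(P, F, 0.3)


class TestRankForDisease:
    def setup_method(self):
        self.scores = score_matrix([[0.9], [0.1], [0.5]])
        self.Y = AssociationMatrix(["c0", "c1", "c2"], ["d0"], [[1], [0], [0]])

    def test_descending_order_with_known_flags(self):
        out = rank_for_disease(self.scores, self.Y, "d0")
        assert [r[0] for r in out] == ["c0", "c2", "c1"]
        assert [r[2] for r in out] == [True, False, False]

    def test_top_truncates(self):
        assert len(rank_for_disease(self.scores, self.Y, "d0", top=2)) == 2

    def test_exclude_known(self):
        out = rank_for_disease(self.scores, self.Y, "d0", include_known=False)
        assert [r[0] for r in out] == ["c2", "c1"]

    def test_all_equal_scores_rank_lexicographically(self):
        scores = score_matrix([[0.5], [0.5], [0.5]], circ=["b", "a", "c"])
        Y = AssociationMatrix(["b", "a", "c"], ["d0"], [[0], [0], [0]])
        out1 = rank_for_disease(scores, Y, "d0")
        out2 = rank_for_disease(scores, Y, "d0")
        assert [r[0] for r in out1] == ["a", "b", "c"]
        assert out1 == out2

    def test_unknown_disease_suggests_nearest(self):
        with pytest.raises(KeyError, match="d0"):
            rank_for_disease(self.scores, self.Y, "d0_typo")


class TestAucRanked:
    def test_perfect_ranking_is_one(self):
        scores = score_matrix([[0.9, 0.8], [0.1, 0.2]])
        assert auc_ranked(scores, {(0, 0), (0, 1)}, set()) == 1.0

    def test_pure_ties_are_half(self):
        scores = score_matrix(np.full((3, 3), 0.7))
        assert auc_ranked(scores, {(0, 0)}, {(1, 1)}) == 0.5

    def test_matches_brute_force_pair_count(self, rng):
        """O(P*N) double-loop oracle over all (positive, negative) pairs."""
        for _ in range(20):
            vals = rng.random((6, 4))
            scores = score_matrix(vals)
            cells = [(i, j) for i in range(6) for j in range(4)]
            rng.shuffle(cells)
            test_pos, train_pos = set(cells[:3]), set(cells[3:6])
            auc = auc_ranked(scores, test_pos, train_pos)
            negs = [c for c in cells if c not in test_pos and c not in train_pos]
            total = 0.0
            for p in test_pos:
                for q in negs:
                    if vals[p] > vals[q]:
                        total += 1.0
                    elif vals[p] == vals[q]:
                        total += 0.5
            assert auc == pytest.approx(total / (len(test_pos) * len(negs)), abs=1e-12)

    def test_matches_sklearn_on_random_instances(self, rng):
        """Independent cross-check against the library ROC-AUC."""
        from sklearn.metrics import roc_auc_score

        for _ in range(200):
            vals = np.round(rng.random((5, 4)), 1)  # coarse grid forces ties
            scores = score_matrix(vals)
            cells = [(i, j) for i in range(5) for j in range(4)]
            rng.shuffle(cells)
            test_pos, train_pos = set(cells[:2]), set(cells[2:4])
            auc = auc_ranked(scores, test_pos, train_pos)
            pop = [c for c in cells if c not in train_pos]
            y_true = [1 if c in test_pos else 0 for c in pop]
            y_score = [vals[c] for c in pop]
            assert auc == pytest.approx(roc_auc_score(y_true, y_score), abs=1e-12)

    def test_degenerate_sets_error(self):
        scores = score_matrix([[0.5]])
        with pytest.raises(ValueError, match="AUC undefined"):
            auc_ranked(scores, {(0, 0)}, set())
        with pytest.raises(ValueError, match="overlap"):
            auc_ranked(score_matrix([[0.5], [0.1]]), {(0, 0)}, {(0, 0)})


@pytest.fixture(scope="module")
def small_data():
    Y, sem, _ = generate(small_preset(17))
    return Y, sem


class TestCrossValidate:
    def test_deterministic_under_fixed_seed(self, small_data):
        Y, sem = small_data
        p = HyperParams()
        r1 = cross_validate(Y, sem, p, k=5, repeats=2, seed=3, model="rwr")
        r2 = cross_validate(Y, sem, p, k=5, repeats=2, seed=3, model="rwr")
        np.testing.assert_array_equal(r1.fold_aucs, r2.fold_aucs)
        assert r1.fold_assignment == r2.fold_assignment
        assert r1.mean_auc == r2.mean_auc

    def test_every_positive_in_exactly_one_fold_per_repeat(self, small_data):
        Y, sem = small_data
        res = cross_validate(Y, sem, HyperParams(), k=5, repeats=2, seed=0, model="lrls")
        for pair, folds in res.fold_assignment.items():
            assert len(folds) == 2
            assert all(0 <= f < 5 for f in folds)
        assert set(res.fold_assignment) == set(Y.positive_pairs())

    def test_mean_is_mean_of_fold_aucs(self, small_data):
        Y, sem = small_data
        res = cross_validate(Y, sem, HyperParams(), k=5, repeats=1, seed=1, model="lrls")
        assert res.mean_auc == pytest.approx(np.nanmean(res.fold_aucs), abs=1e-12)

    def test_no_test_label_leakage(self, rng, monkeypatch):
        """Sentinel guard: every similarity build and model fit inside a fold
        must see a Y in which that fold's test positives are zero."""
        Y = random_association(10, 6, rng, density=0.5)
        sem = random_similarity(6, rng, Y.disease_ids)
        seen_violation = []
        folds_seen = []

        real = ee._fold_model_scores

        def spy(Y_full, sem_arg, params_arg, test_pairs):
            import cda_netfuse.similarity as sim

            orig = sim.build_similarities

            def check(Y_masked, *a, **k):
                for i, j in test_pairs:
                    if Y_masked.values[i, j] != 0.0:
                        seen_violation.append((i, j))
                return orig(Y_masked, *a, **k)

            monkeypatch.setattr(ee, "build_similarities", check)
            try:
                out = real(Y_full, sem_arg, params_arg, test_pairs)
            finally:
                monkeypatch.setattr(ee, "build_similarities", orig)
            folds_seen.append(list(test_pairs))
            return out

        monkeypatch.setattr(ee, "_fold_model_scores", spy)
        cross_validate(Y, sem, HyperParams(), k=3, repeats=1, seed=5, model="ensemble")
        assert folds_seen and not seen_violation

    def test_ensemble_fold_uses_within_fold_matrices(self, small_data, monkeypatch):
        """The fold ensemble must combine the P and F fitted on that fold's
        masked Y — never full-data matrices.  Sentinel: make the fold LRLS
        scores a recognizable constant and confirm the ensemble AUC shifts."""
        Y, sem = small_data
        res_plain = cross_validate(Y, sem, HyperParams(theta=1e6), k=5, repeats=1, seed=2,
                                   model="ensemble")
        res_lrls = cross_validate(Y, sem, HyperParams(), k=5, repeats=1, seed=2, model="lrls")
        # with theta huge the ensemble ranking degenerates to the fold LRLS ranking
        np.testing.assert_allclose(res_plain.fold_aucs, res_lrls.fold_aucs, atol=1e-6)

    def test_requires_enough_positives(self, rng):
        Y = AssociationMatrix(["c1", "c2"], ["d1"], [[1], [0]])
        sem = SimilarityMatrix(["d1"], [[1.0]])
        with pytest.raises(ValueError, match="at least"):
            cross_validate(Y, sem, HyperParams(), k=5, repeats=1, seed=0)


class TestThetaSweep:
    def test_single_theta_matches_cross_validate(self, small_data):
        Y, sem = small_data
        p = HyperParams(theta=0.3)
        sweep = theta_sweep(Y, sem, p, [0.3], k=5, repeats=1, seed=4)
        cv = cross_validate(Y, sem, p, k=5, repeats=1, seed=4, model="ensemble")
        assert sweep[0][1] == pytest.approx(cv.mean_auc, abs=1e-12)

    def test_grid_shape_and_determinism(self, small_data):
        Y, sem = small_data
        thetas = [round(0.1 * i, 1) for i in range(1, 10)]
        s1 = theta_sweep(Y, sem, HyperParams(), thetas, k=5, repeats=1, seed=9)
        s2 = theta_sweep(Y, sem, HyperParams(), thetas, k=5, repeats=1, seed=9)
        assert len(s1) == 9 and s1 == s2

    def test_empty_thetas_error(self, small_data):
        Y, sem = small_data
        with pytest.raises(ValueError, match="non-empty"):
            theta_sweep(Y, sem, HyperParams(), [], k=5, repeats=1, seed=0)


class TestPredictScores:
    def test_theta_zero_ensemble_equals_rwr(self, small_data):
        Y, sem = small_data
        p = HyperParams(theta=0.0)
        ens = predict_scores(Y, sem, p, model="ensemble")
        rwr = predict_scores(Y, sem, p, model="rwr")
        np.testing.assert_allclose(ens.values, rwr.values, atol=1e-12)

    def test_unknown_model_errors(self, small_data):
        Y, sem = small_data
        with pytest.raises(ValueError, match="model"):
            predict_scores(Y, sem, HyperParams(), model="katz")
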