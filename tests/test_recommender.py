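import numpy as np
import pytest

from circrec.core_io import (
    AssociationMatrix,
    PipelineConfig,
    SimilarityMatrix,
    ValidationError,
)
from circrec.recommender import (
    circ_based_scores,
    cold_start_scores,
    disease_based_scores,
    importance,
    importance_matrix,
    integrate_scores,
    predict,
    resolve_k,
    top_k_neighbors,
)


def naive_scores(A, CS, DS, k_c, k_d, gamma):
    """Double-loop oracle for the neighborhood scoring equations."""
    n_d, n_c = len(A), len(A[0])
    crs = np.zeros((n_d, n_c))
    drs = np.zeros((n_d, n_c))
    for j in range(n_c):
        order = sorted((m for m in range(n_c) if m != j), key=lambda m: (-CS[m][j], m))
        for i in range(n_d):
            crs[i, j] = sum(A[i][n] * CS[n][j] for n in order[:k_c]) / k_c
    for i in range(n_d):
        order = sorted((m for m in range(n_d) if m != i), key=lambda m: (-DS[i][m], m))
        for j in range(n_c):
            drs[i, j] = sum(DS[i][m] * A[m][j] for m in order[:k_d]) / k_d
    return crs, drs, gamma * drs + (1 - gamma) * crs


def sim(ids, values):
    return SimilarityMatrix(ids, np.asarray(values, dtype=float))


def _random_sim(rng, n):
    values = rng.random((n, n))
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return values


class TestResolveK:
    @pytest.mark.parametrize(
        "n,frac,expected", [(200, 0.04, 8), (42, 0.04, 2), (2, 0.04, 1), (2, 1.0, 1), (10, 1.0, 9)]
    )
    def test_ceil_floor_and_cap(self, n, frac, expected):
        assert resolve_k(n, frac) == expected

    def test_too_few_entities_rejected(self):
        with pytest.raises(ValidationError):
            resolve_k(1, 0.04)


class TestTopKNeighbors:
    def test_most_similar_first(self):
        S = sim(["a", "b", "c"], [[1, 0.9, 0.2], [0.9, 1, 0.5], [0.2, 0.5, 1]])
        t = top_k_neighbors(S, 1)
        assert t.indices[0, 0] == 1

    def test_tie_broken_by_ascending_index(self):
        S = sim(["a", "b", "c"], [[1, 0.5, 0.5], [0.5, 1, 0.1], [0.5, 0.1, 1]])
        t = top_k_neighbors(S, 1)
        assert t.indices[0, 0] == 1

    def test_k_equals_n_minus_one_sorted(self):
        S = sim(["a", "b", "c"], [[1, 0.3, 0.8], [0.3, 1, 0.4], [0.8, 0.4, 1]])
        t = top_k_neighbors(S, 2)
        assert t.indices[0].tolist() == [2, 1]
        assert t.similarities[0].tolist() == [0.8, 0.3]

    def test_out_of_range_k_rejected(self):
        S = sim(["a", "b"], np.eye(2))
        with pytest.raises(ValidationError):
            top_k_neighbors(S, 2)


class TestNeighborhoodScores:
    def test_circ_side_hand_fixture(self):
        # top neighbor of c3 is c1 with CS=0.8 and d1 is associated with c1
        A = AssociationMatrix(
            ["d1", "d2"], ["c1", "c2", "c3"],
            np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
        )
        CS = sim(["c1", "c2", "c3"], [[1, 0.1, 0.8], [0.1, 1, 0.2], [0.8, 0.2, 1]])
        crs = circ_based_scores(A, CS, 1)
        assert crs.values[0, 2] == pytest.approx(0.8)
        assert crs.values[1, 2] == 0.0  # d2's association is not a neighbor of c3

    def test_disease_side_hand_fixture(self):
        # top neighbor of d2 is d1 with DS=0.7 and A(d1,c2)=1
        A = AssociationMatrix(
            ["d1", "d2"], ["c1", "c2"], np.array([[0.0, 1.0], [0.0, 0.0]])
        )
        DS = sim(["d1", "d2"], [[1, 0.7], [0.7, 1]])
        drs = disease_based_scores(A, DS, 1)
        assert drs.values[1, 1] == pytest.approx(0.7)

    def test_upper_bound_reached_with_saturated_neighborhood(self):
        A = AssociationMatrix(
            ["d1"], ["c1", "c2", "c3"], np.array([[1.0, 1.0, 1.0]])
        )
        CS = sim(["c1", "c2", "c3"], np.ones((3, 3)))
        crs = circ_based_scores(A, CS, 2)
        assert np.all(crs.values <= 1.0)
        assert crs.values[0, 0] == pytest.approx(1.0)

    def test_transpose_mirror_symmetry(self):
        rng = np.random.default_rng(2)
        A = (rng.random((4, 6)) < 0.4).astype(float)
        S = rng.random((6, 6))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        Am = AssociationMatrix([f"d{i}" for i in range(4)], [f"c{i}" for i in range(6)], A)
        At = AssociationMatrix([f"c{i}" for i in range(6)], [f"d{i}" for i in range(4)], A.T)
        CS = sim(Am.circ_ids, S)
        crs = circ_based_scores(Am, CS, 3)
        drs = disease_based_scores(At, sim(At.disease_ids, S), 3)
        assert np.allclose(crs.values, drs.values.T, atol=1e-15)

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            A = (rng.random((8, 12)) < 0.35).astype(float)
            CS = rng.random((12, 12)); CS = (CS + CS.T) / 2; np.fill_diagonal(CS, 1.0)
            DS = rng.random((8, 8)); DS = (DS + DS.T) / 2; np.fill_diagonal(DS, 1.0)
            Am = AssociationMatrix(
                [f"d{i}" for i in range(8)], [f"c{i}" for i in range(12)], A
            )
            k_c, k_d = 3, 2
            crs = circ_based_scores(Am, sim(Am.circ_ids, CS), k_c).values
            drs = disease_based_scores(Am, sim(Am.disease_ids, DS), k_d).values
            irs = integrate_scores(
                circ_based_scores(Am, sim(Am.circ_ids, CS), k_c),
                disease_based_scores(Am, sim(Am.disease_ids, DS), k_d),
                0.6,
            ).values
            ocrs, odrs, oirs = naive_scores(
                A.tolist(), CS.tolist(), DS.tolist(), k_c, k_d, 0.6
            )
            # oracle fuses gamma*DRS + (1-gamma)*CRS with gamma on the disease side
            assert np.abs(crs - ocrs).max() < 1e-12
            assert np.abs(drs - odrs).max() < 1e-12
            assert np.abs(irs - (0.6 * odrs + 0.4 * ocrs)).max() < 1e-12

    def test_monotone_in_selected_neighbor_similarity(self):
        A = AssociationMatrix(
            ["d1"], ["c1", "c2", "c3"], np.array([[1.0, 0.0, 0.0]])
        )
        base = np.array([[1, 0.2, 0.6], [0.2, 1, 0.3], [0.6, 0.3, 1]])
        raised = base.copy()
        raised[0, 2] = raised[2, 0] = 0.9  # strengthen c3's selected neighbor c1
        lo = circ_based_scores(A, sim(A.circ_ids, base), 1).values[0, 2]
        hi = circ_based_scores(A, sim(A.circ_ids, raised), 1).values[0, 2]
        assert hi >= lo


class TestImportance:
    def _A(self):
        # D(c1)={d1}, D(c2)={d1,d2}, D(c3)={} on 3 circRNAs
        return AssociationMatrix(
            ["d1", "d2"], ["c1", "c2", "c3"],
            np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 0.0]]),
        )

    def test_hand_value(self):
        # f_exp(c1)=1, f_ns(c2)=1/(2-1+1), shared diseases = 1
        assert importance(self._A(), 0, 1) == pytest.approx(0.5)

    def test_disjoint_disease_sets_score_zero(self):
        A = AssociationMatrix(
            ["d1", "d2"], ["c1", "c2"], np.array([[1.0, 0.0], [0.0, 1.0]])
        )
        assert importance(A, 0, 1) == 0.0

    def test_zero_degree_query_scores_zero(self):
        assert importance(self._A(), 2, 1) == 0.0

    def test_self_importance_rejected(self):
        with pytest.raises(ValidationError):
            importance(self._A(), 1, 1)

    def test_strict_count_requires_exactly_the_pair(self):
        # d1 is associated with both c1 and c2 but also nothing else,
        # so the strict count matches the plain count here ...
        A = self._A()
        assert importance_matrix(A, strict=True)[0, 1] == pytest.approx(0.5)
        # ... but adding a third association on d1 empties the strict count
        A2 = AssociationMatrix(
            ["d1", "d2"], ["c1", "c2", "c3"],
            np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 0.0]]),
        )
        assert importance_matrix(A2, strict=True)[0, 1] == 0.0
        assert importance_matrix(A2, strict=False)[0, 1] > 0.0


class TestColdStart:
    def test_single_contributor_hand_value(self):
        # c3 is cold (degree 1 via d1); c1 shares d1, IMP(c3,c1)=0.5, CS=0.6
        A = AssociationMatrix(
            ["d1", "d2"], ["c1", "c2", "c3"],
            np.array([[1.0, 0.0, 1.0], [1.0, 1.0, 0.0]]),
        )
        CS = sim(
            ["c1", "c2", "c3"], [[1, 0.3, 0.6], [0.3, 1, 0.4], [0.6, 0.4, 1]]
        )
        scores, cold = cold_start_scores(A, CS)
        assert cold.tolist() == [False, True, True]  # c2 and c3 have degree 1
        # IMP(c3,c1) = 1 * 1/(2-1+1) * 1 = 0.5; contribution 0.5*0.6
        assert scores[0, 2] == pytest.approx(0.3)

    def test_isolated_cold_circ_scores_zero(self):
        A = AssociationMatrix(
            ["d1", "d2"], ["c1", "c2"], np.array([[1.0, 0.0], [0.0, 1.0]])
        )
        CS = sim(["c1", "c2"], [[1, 0.9], [0.9, 1]])
        scores, cold = cold_start_scores(A, CS)
        assert np.all(scores[:, 1] == 0.0)

    def test_non_cold_columns_left_at_zero(self):
        A = AssociationMatrix(
            ["d1", "d2"], ["c1", "c2"], np.array([[1.0, 1.0], [1.0, 1.0]])
        )
        CS = sim(["c1", "c2"], [[1, 0.9], [0.9, 1]])
        scores, cold = cold_start_scores(A, CS)
        assert not cold.any()
        assert np.all(scores == 0.0)


class TestIntegrateAndPredict:
    def test_fusion_arithmetic_and_boundaries(self, tiny_A):
        from circrec.core_io import ScoreMatrix

        crs = ScoreMatrix(tiny_A.disease_ids, tiny_A.circ_ids, np.full((2, 3), 0.2))
        drs = ScoreMatrix(tiny_A.disease_ids, tiny_A.circ_ids, np.full((2, 3), 0.4))
        assert integrate_scores(crs, drs, 0.5).values[0, 0] == pytest.approx(0.3)
        assert np.allclose(integrate_scores(crs, drs, 1.0).values, drs.values)

    def test_predict_reduces_to_plain_composition_without_cold_circ(self):
        rng = np.random.default_rng(4)
        values = np.ones((3, 5))  # every circRNA has degree 3: none cold
        A = AssociationMatrix([f"d{i}" for i in range(3)], [f"c{i}" for i in range(5)], values)
        CS = rng.random((5, 5)); CS = (CS + CS.T) / 2; np.fill_diagonal(CS, 1.0)
        DS = rng.random((3, 3)); DS = (DS + DS.T) / 2; np.fill_diagonal(DS, 1.0)
        CSm, DSm = sim(A.circ_ids, CS), sim(A.disease_ids, DS)
        config = PipelineConfig(k_fraction=0.5)
        with_cold = predict(A, CSm, DSm, config)
        without = predict(A, CSm, DSm, PipelineConfig(k_fraction=0.5, cold_start=False))
        assert np.array_equal(with_cold.values, without.values)

    def test_deterministic_across_runs(self, small_dataset, small_side):
        from circrec.evaluation import fold_similarities

        A = small_dataset.associations
        config = PipelineConfig()
        CS, DS = fold_similarities(A, small_side, config)
        s1 = predict(A, CS, DS, config)
        s2 = predict(A, CS, DS, config)
        assert s1.values.tobytes() == s2.values.tobytes()

    def test_permuting_entities_and_back_is_identity(self, small_dataset):
        # random similarities: continuous values make neighbor ties
        # (which break by index, not by label) measure-zero
        rng = np.random.default_rng(31)
        A = small_dataset.associations
        config = PipelineConfig()
        CS = sim(A.circ_ids, _random_sim(rng, A.n_circ))
        DS = sim(A.disease_ids, _random_sim(rng, A.n_diseases))
        base = predict(A, CS, DS, config).values

        pc = rng.permutation(A.n_circ)
        pd = rng.permutation(A.n_diseases)
        Ap = AssociationMatrix(
            [A.disease_ids[i] for i in pd],
            [A.circ_ids[j] for j in pc],
            A.values[np.ix_(pd, pc)],
        )
        CSp = SimilarityMatrix([A.circ_ids[j] for j in pc], CS.values[np.ix_(pc, pc)])
        DSp = SimilarityMatrix([A.disease_ids[i] for i in pd], DS.values[np.ix_(pd, pd)])
        permuted = predict(Ap, CSp, DSp, config).values
        assert np.allclose(base[np.ix_(pd, pc)], permuted, atol=1e-12)
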