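"""Parcellation metrics: homogeneity, discreteness, composition matching,
agreement, probing, spatial contribution, markers, cross-animal presence."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nichescope.evaluation import (
    CompositionMatrix,
    clustering_agreement,
    composition_matrix,
    cross_animal_consistency,
    discreteness,
    linear_probe,
    match_compositions,
    prediction_correlation_report,
    rank_domain_markers,
    spatial_homogeneity,
)
from tests.test_neighborhoods import table_at


class TestHomogeneity:
    def test_single_label_gives_one_everywhere(self, small_table):
        res = spatial_homogeneity(small_table, np.zeros(small_table.n_cells, dtype=int), 10)
        assert np.all(res.per_cell == 1.0)
        assert res.dataset_mean == 1.0

    def test_all_unique_labels_give_zero_everywhere(self, small_table):
        res = spatial_homogeneity(small_table, np.arange(small_table.n_cells), 10)
        assert np.all(res.per_cell == 0.0)

    def test_matches_exact_brute_force_knn(self, rng):
        coords = rng.uniform(0, 100, size=(300, 2))
        t = table_at(coords)
        labels = rng.integers(0, 4, 300)
        res = spatial_homogeneity(t, labels, n_neighbors=10)
        d2 = ((coords[:, None] - coords[None, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        for i in range(300):
            nn = np.argsort(d2[i], kind="stable")[:10]
            assert res.per_cell[i] == pytest.approx((labels[nn] == labels[i]).mean())

    def test_restricted_to_same_section(self):
        # two sections stacked at identical coordinates: neighbors must not leak
        coords = [(0, 0), (1, 0), (2, 0)] * 2
        t = table_at(coords, sections=["a"] * 3 + ["b"] * 3)
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = spatial_homogeneity(t, labels, n_neighbors=2)
        assert np.all(res.per_cell == 1.0)

    def test_misaligned_labels_rejected(self, small_table):
        with pytest.raises(ValueError):
            spatial_homogeneity(small_table, np.zeros(3, dtype=int), 5)

    def test_relabeling_invariance(self, small_table, rng):
        labels = rng.integers(0, 5, small_table.n_cells)
        res1 = spatial_homogeneity(small_table, labels, 15)
        res2 = spatial_homogeneity(small_table, 4 - labels, 15)
        np.testing.assert_array_equal(res1.per_cell, res2.per_cell)


class TestDiscreteness:
    def test_percentile_zero_bound(self):
        ref = [0.2, 0.4, 0.6]
        frac, flags = discreteness([0.3, 0.5, 0.9], ref, percentile=0)
        assert frac == 1.0

    def test_self_comparison_at_20th_percentile(self):
        ref = np.linspace(0.1, 1.0, 10)
        frac, _ = discreteness(ref, ref, percentile=20)
        assert frac == pytest.approx(0.8, abs=0.1)  # ties at the threshold count as discrete

    def test_hand_worked_example(self):
        ref = np.arange(0.1, 1.05, 0.1)
        method = [0.15, 0.5, 0.9]
        frac, flags = discreteness(method, ref, percentile=20)
        threshold = np.percentile(ref, 20)  # 0.28
        np.testing.assert_array_equal(flags, np.array(method) >= threshold)
        assert frac == pytest.approx(2 / 3)


class TestComposition:
    def test_two_equal_types_give_half_half(self, rng):
        from tests.test_io_core import toy_table

        t = toy_table(n=4, g=3)
        t.cell_type = np.array([1, 2, 1, 2])
        comp = composition_matrix(np.zeros(4, dtype=int), t)
        np.testing.assert_allclose(comp.values, [[0.5, 0.5]])

    def test_rows_sum_to_one_random_inputs(self, small_table, rng):
        labels = rng.integers(0, 6, small_table.n_cells)
        comp = composition_matrix(labels, small_table)
        np.testing.assert_allclose(comp.values.sum(axis=1), 1.0, atol=1e-12)

    def test_twenty_cell_hand_tally(self):
        from tests.test_io_core import toy_table

        t = toy_table(n=20, g=3)
        t.cell_type = np.array([1] * 12 + [2] * 8)
        labels = np.array([0] * 10 + [1] * 10)
        comp = composition_matrix(labels, t)
        np.testing.assert_allclose(comp.values, [[1.0, 0.0], [0.2, 0.8]])


class TestMatching:
    def _comp(self, values, tag="d"):
        values = np.asarray(values, float)
        values = values / values.sum(axis=1, keepdims=True)
        return CompositionMatrix(
            values=values,
            domain_ids=list(range(len(values))),
            type_labels=[f"t{j}" for j in range(values.shape[1])],
        )

    def test_self_match_is_perfect_identity(self, rng):
        A = self._comp(rng.random((5, 7)) + 0.05)
        for mode in ("max", "assignment"):
            res = match_compositions(A, A, mode)
            assert res.mean_r == pytest.approx(1.0, abs=1e-12)
        assert match_compositions(A, A, "assignment").pairs == [(i, i) for i in range(5)]

    def test_max_mode_dominates_assignment_mode(self, rng):
        for _ in range(5):
            A = self._comp(rng.random((5, 6)) + 0.05)
            B = self._comp(rng.random((5, 6)) + 0.05)
            assert (
                match_compositions(A, B, "max").mean_r
                >= match_compositions(A, B, "assignment").mean_r - 1e-12
            )

    def test_assignment_equals_exhaustive_permutation_search(self, rng):
        A = self._comp(rng.random((5, 8)) + 0.05)
        B = self._comp(rng.random((5, 8)) + 0.05)
        res = match_compositions(A, B, "assignment")
        Za = (A.values - A.values.mean(1, keepdims=True)) / A.values.std(1, keepdims=True)
        Zb = (B.values - B.values.mean(1, keepdims=True)) / B.values.std(1, keepdims=True)
        R = Za @ Zb.T / 8
        best = max(np.mean([R[i, p[i]] for i in range(5)]) for p in itertools.permutations(range(5)))
        assert res.mean_r == pytest.approx(best, abs=1e-12)

    def test_constant_row_raises_naming_domain(self):
        A = self._comp([[1, 1, 1], [1, 2, 3]])
        B = self._comp([[1, 2, 3], [3, 2, 1]])
        with pytest.raises(ValueError, match="domain 0"):
            match_compositions(A, B, "max")

    def test_vocabulary_mismatch_rejected(self, rng):
        A = self._comp(rng.random((2, 3)) + 0.1)
        B = CompositionMatrix(
            values=A.values.copy(), domain_ids=[0, 1], type_labels=["x", "y", "z"]
        )
        with pytest.raises(ValueError, match="vocabular"):
            match_compositions(A, B, "max")

    def test_mean_r_invariant_under_simultaneous_row_permutation(self, rng):
        A = self._comp(rng.random((4, 6)) + 0.05)
        B = self._comp(rng.random((4, 6)) + 0.05)
        perm = rng.permutation(4)
        Ap = CompositionMatrix(A.values[perm], [A.domain_ids[i] for i in perm], A.type_labels)
        Bp = CompositionMatrix(B.values[perm], [B.domain_ids[i] for i in perm], B.type_labels)
        assert match_compositions(A, B, "assignment").mean_r == pytest.approx(
            match_compositions(Ap, Bp, "assignment").mean_r, abs=1e-12
        )


class TestAgreement:
    def test_identical_labelings_perfect_scores(self, rng):
        labels = rng.integers(0, 5, 100)
        nmi, ari = clustering_agreement(labels, labels.copy())
        assert nmi == pytest.approx(1.0)
        assert ari == pytest.approx(1.0)

    def test_constant_labeling_zero_information(self, rng):
        nmi, _ = clustering_agreement(np.zeros(50, dtype=int), rng.integers(0, 3, 50))
        assert nmi == 0.0

    def test_three_by_three_contingency_hand_computed(self):
        a = np.array([0] * 4 + [1] * 4 + [2] * 4)
        b = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2, 0])
        # hand-computed from the contingency table
        from math import log

        n = 12.0
        cont = np.zeros((3, 3))
        for i, j in zip(a, b):
            cont[i, j] += 1
        pij = cont / n
        pa = pij.sum(1)
        pb = pij.sum(0)
        mi = sum(
            pij[i, j] * log(pij[i, j] / (pa[i] * pb[j]))
            for i in range(3)
            for j in range(3)
            if pij[i, j] > 0
        )
        ha = -sum(p * log(p) for p in pa if p > 0)
        hb = -sum(p * log(p) for p in pb if p > 0)
        nmi, ari = clustering_agreement(a, b)
        assert nmi == pytest.approx(mi / ((ha + hb) / 2), abs=1e-12)
        # ARI from pair counts
        from scipy.special import comb

        sum_ij = sum(comb(int(x), 2) for x in cont.ravel())
        sum_a = sum(comb(int(x), 2) for x in cont.sum(1))
        sum_b = sum(comb(int(x), 2) for x in cont.sum(0))
        exp = sum_a * sum_b / comb(12, 2)
        assert ari == pytest.approx((sum_ij - exp) / ((sum_a + sum_b) / 2 - exp), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            clustering_agreement(np.zeros(3, dtype=int), np.zeros(4, dtype=int))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_independent_labelings_have_near_zero_mean_ari(self, seed):
        r = np.random.default_rng(seed)
        aris = [
            clustering_agreement(r.integers(0, 4, 200), r.integers(0, 4, 200))[1]
            for _ in range(10)
        ]
        assert abs(float(np.mean(aris))) < 0.05


class TestLinearProbe:
    def test_coordinates_exactly_recoverable_from_embedding(self, small_table, rng):
        emb = np.column_stack([small_table.x, small_table.y, rng.normal(size=(small_table.n_cells, 5))])
        res = linear_probe(emb, small_table, target="coordinates")
        assert res.median_abs_error <= 1e-8
        assert res.mean_abs_error <= 1e-8

    def test_planted_linear_map_recovered_matches_normal_equations(self, rng):
        from tests.test_neighborhoods import table_at

        X = rng.normal(size=(200, 8))
        W = rng.normal(size=(8, 2))
        Y = X @ W + rng.normal(0, 0.01, size=(200, 2))
        t = table_at(Y)
        res = linear_probe(X, t, target="coordinates")
        design = np.column_stack([X, np.ones(200)])
        coef = np.linalg.solve(design.T @ design, design.T @ Y)
        np.testing.assert_allclose(res.coefficients, coef, atol=1e-8)

    def test_linearly_separable_donors_classified_perfectly(self, rng):
        from tests.test_neighborhoods import table_at

        n = 60
        emb = np.vstack([rng.normal(-5, 0.3, (n, 4)), rng.normal(5, 0.3, (n, 4))])
        t = table_at(rng.uniform(0, 10, (2 * n, 2)))
        t.animal_id = np.array(["m1"] * n + ["m2"] * n, dtype=object)
        res = linear_probe(emb, t, target="donor")
        assert res.accuracy == 1.0
        assert res.per_group_accuracy == {"m1": 1.0, "m2": 1.0}


class TestSpatialContribution:
    def test_baseline_predictor_gives_zero_delta(self, rng):
        obs = rng.poisson(5.0, size=(30, 8)).astype(float)
        base = obs.mean(axis=0)
        types = rng.integers(1, 4, 30)
        df = prediction_correlation_report(obs, np.tile(base, (30, 1)), base, types)
        np.testing.assert_allclose(df["delta_r"], 0.0, atol=1e-12)

    def test_perfect_predictions_reach_unit_correlation(self, rng):
        obs = rng.poisson(5.0, size=(30, 8)).astype(float) + rng.random((30, 8))
        types = np.ones(30, dtype=int)
        df = prediction_correlation_report(obs, obs.copy(), obs.mean(axis=0), types)
        assert df.loc[0, "r_model"] == pytest.approx(1.0)
        assert df.loc[0, "delta_r"] == pytest.approx(1.0 - df.loc[0, "r_baseline"])

    def test_ten_cell_hand_set_predictions(self):
        obs = np.array([[1.0, 2.0, 3.0]] * 5 + [[3.0, 2.0, 1.0]] * 5)
        pred = np.array([[1.0, 2.0, 3.0]] * 5 + [[1.0, 2.0, 3.0]] * 5)
        base = np.array([2.0, 2.0, 2.0])  # constant: correlation undefined -> baseline r is nan-safe
        types = np.array([1] * 5 + [2] * 5)
        df = prediction_correlation_report(obs, pred, np.array([1.0, 2.0, 2.5]), types)
        assert df.loc[df.cell_type == 1, "r_model"].iloc[0] == pytest.approx(1.0)
        assert df.loc[df.cell_type == 2, "r_model"].iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_observations_skipped_and_counted(self):
        obs = np.array([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]])
        df = prediction_correlation_report(obs, obs, obs.mean(0), np.array([1, 1]))
        assert df.loc[0, "n_skipped"] == 1
        assert df.loc[0, "n_cells"] == 1


class TestMarkers:
    def _table(self, counts, labels):
        t = table_at(np.c_[np.arange(len(counts)), np.zeros(len(counts))])
        from scipy import sparse

        counts = np.asarray(counts)
        t.counts = sparse.csr_matrix(counts)
        t.gene_names = [f"g{j}" for j in range(counts.shape[1])]
        return t, np.asarray(labels)

    def test_exclusive_gene_reported_for_its_domain_only(self):
        counts = np.array([[50, 1], [60, 1], [0, 1], [0, 1]])
        t, labels = self._table(counts, [0, 0, 1, 1])
        markers = rank_domain_markers(t, labels)
        assert list(markers[0]["gene"]) == ["g0"]
        assert list(markers[1]["gene"]) == []

    def test_uniform_gene_never_a_marker(self):
        counts = np.full((6, 1), 7)
        t, labels = self._table(counts, [0, 0, 0, 1, 1, 1])
        markers = rank_domain_markers(t, labels)
        assert all(len(m) == 0 for m in markers.values())

    def test_three_domain_hand_computed_fold_changes(self):
        counts = np.array(
            [[8, 0, 2], [8, 0, 2], [0, 4, 2], [0, 4, 2], [0, 0, 2], [0, 0, 2]]
        )
        t, labels = self._table(counts, [0, 0, 1, 1, 2, 2])
        markers = rank_domain_markers(t, labels, min_log2fc=1.0, pseudocount=1.0)
        assert list(markers[0]["gene"]) == ["g0"]
        assert markers[0]["log2fc"].iloc[0] == pytest.approx(np.log2(9.0 / 1.0))
        assert list(markers[1]["gene"]) == ["g1"]
        assert markers[1]["log2fc"].iloc[0] == pytest.approx(np.log2(5.0 / 1.0))
        assert list(markers[2]["gene"]) == []


class TestCrossAnimal:
    def test_full_presence_gives_one(self, rng):
        labels = rng.integers(0, 3, 120)
        animals = np.repeat(["m1", "m2"], 60)
        frac, presence = cross_animal_consistency(labels, animals, min_cells=5)
        assert frac == 1.0
        assert presence.values.all()

    def test_domain_exclusive_to_one_animal_counted(self):
        labels = np.array([0] * 30 + [1] * 30 + [2] * 30 + [0] * 30 + [1] * 30)
        animals = np.array(["m1"] * 90 + ["m2"] * 60)
        frac, presence = cross_animal_consistency(labels, animals, min_cells=10)
        assert frac == pytest.approx(2 / 3)
        assert not presence.loc[2, "m2"]

    def test_three_animal_hand_tally(self):
        labels = np.array([0, 0, 1, 1] * 3 + [2] * 4 + [3] * 4)
        animals = np.array(
            ["a"] * 4 + ["b"] * 4 + ["c"] * 4 + ["a"] * 4 + ["b"] * 4
        )
        frac, presence = cross_animal_consistency(labels, animals, min_cells=2)
        assert presence.loc[0].tolist() == [True, True, True]
        assert presence.loc[2].tolist() == [True, False, False]
        assert presence.loc[3].tolist() == [False, True, False]
        assert frac == pytest.approx(2 / 4)

    def test_single_animal_rejected(self):
        with pytest.raises(ValueError):
            cross_animal_consistency(np.zeros(5, dtype=int), np.array(["m"] * 5))
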