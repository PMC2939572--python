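import numpy as np
import pytest

from mcnet import (
    CircularOrdering,
    Split,
    build_design_matrix,
    circular_splits,
    filter_splits,
    fit_nnls,
    fit_norm,
    fit_ols,
    kkt_residuals,
    weight_splits,
)
from mcnet.synthetic import random_circular_metric
from helpers import random_metric

KKT_TOL = 1e-8


def assert_kkt(design, dvec, weights):
    stat, dual = kkt_residuals(design, dvec, weights)
    assert stat <= KKT_TOL * max(1.0, np.abs(dvec).max())
    assert dual <= KKT_TOL * max(1.0, np.abs(dvec).max())


class TestSplit:
    def test_canonical_side_excludes_taxon_zero(self):
        s = Split.from_members([0, 1], 4)
        assert s.side == (2, 3)
        assert s == Split.from_members([2, 3], 4)

    def test_trivial_detection(self):
        assert Split.from_members([3], 5).is_trivial
        assert Split.from_members([1, 2, 3, 4], 5).is_trivial  # complement of {0}
        assert not Split.from_members([1, 2], 5).is_trivial

    def test_separates(self):
        s = Split.from_members([2, 3], 4)
        assert s.separates(0, 2)
        assert not s.separates(0, 1)
        assert not s.separates(2, 3)

    def test_degenerate_sides_rejected(self):
        with pytest.raises(ValueError):
            Split.from_members([0, 1, 2, 3], 4)


class TestCircularSplits:
    def test_four_taxa_enumeration(self):
        got = set(circular_splits(CircularOrdering((0, 1, 2, 3))))
        expect = {
            Split.from_members([1], 4), Split.from_members([2], 4),
            Split.from_members([3], 4), Split.from_members([0], 4),
            Split.from_members([0, 1], 4), Split.from_members([1, 2], 4),
        }
        assert got == expect

    @pytest.mark.parametrize("n", [4, 5, 7, 10])
    def test_count_is_n_choose_2_with_all_trivials(self, n):
        splits = circular_splits(CircularOrdering(tuple(range(n))))
        assert len(splits) == n * (n - 1) // 2
        assert len(set(splits)) == len(splits)
        assert sum(s.is_trivial for s in splits) == n

    def test_invariant_under_rotation_and_reversal(self):
        base = set(circular_splits(CircularOrdering((0, 1, 2, 3, 4))))
        assert set(circular_splits(CircularOrdering((2, 3, 4, 0, 1)))) == base
        assert set(circular_splits(CircularOrdering((4, 3, 2, 1, 0)))) == base


class TestDesignMatrix:
    def test_entries_are_separation_indicators(self):
        splits = [Split.from_members([2], 4)]
        A, pairs = build_design_matrix(splits, 4)
        col = dict(zip(pairs, A[:, 0]))
        assert col[(0, 1)] == 0.0
        assert col[(0, 2)] == 1.0
        assert col[(2, 3)] == 1.0

    def test_full_circular_system_is_square_full_rank(self):
        splits = circular_splits(CircularOrdering((0, 1, 2, 3)))
        A, _ = build_design_matrix(splits, 4)
        assert A.shape == (6, 6)
        assert np.linalg.matrix_rank(A) == 6

    @pytest.mark.parametrize("n", [5, 8])
    def test_trivial_columns_have_n_minus_1_ones(self, n):
        splits = circular_splits(CircularOrdering(tuple(range(n))))
        A, _ = build_design_matrix(splits, n)
        for k, s in enumerate(splits):
            if s.is_trivial:
                assert A[:, k].sum() == n - 1


class TestFitting:
    def quartet_system(self, quartet):
        sigma = CircularOrdering((0, 1, 2, 3))
        splits = circular_splits(sigma)
        A, _ = build_design_matrix(splits, 4)
        return splits, A, quartet.condensed()

    def test_ols_recovers_tree_weights_exactly(self, quartet):
        splits, A, dvec = self.quartet_system(quartet)
        w = fit_ols(A, dvec)
        expected = {s: (0.0 if s == Split.from_members([1, 2], 4) else 1.0)
                    for s in splits}
        for s, wi in zip(splits, w):
            assert wi == pytest.approx(expected[s], abs=1e-9)
        assert np.linalg.norm(A @ w - dvec) < 1e-9

    def test_ols_matches_normal_equation_closed_form(self):
        for seed in range(5):
            d = random_metric(6, seed)
            splits = circular_splits(CircularOrdering(tuple(range(6))))
            A, _ = build_design_matrix(splits, 6)
            dvec = d.condensed()
            w = fit_ols(A, dvec)
            closed = np.linalg.solve(A.T @ A, A.T @ dvec)
            np.testing.assert_allclose(w, closed, atol=1e-9)

    def test_ols_rejects_rank_deficient_design(self):
        splits = [Split.from_members([1], 4), Split.from_members([1], 4)]
        A, _ = build_design_matrix(splits, 4)
        with pytest.raises(np.linalg.LinAlgError):
            fit_ols(A, np.ones(6))

    def test_nnls_matches_ols_when_unconstrained_solution_is_feasible(self, quartet):
        splits, A, dvec = self.quartet_system(quartet)
        w_ols = fit_ols(A, dvec)
        w_nnls = fit_nnls(A, dvec)
        np.testing.assert_allclose(w_nnls, w_ols, atol=1e-9)
        assert_kkt(A, dvec, w_nnls)

    def test_nnls_recovers_consistent_nonnegative_systems(self):
        dm, cycle, truth = random_circular_metric(7, seed=2)
        system = weight_splits(dm, cycle)
        true = dict(truth)
        for s, w in zip(system.splits, system.weights):
            assert w == pytest.approx(true.get(s, 0.0), abs=1e-8)
        assert fit_norm(system) < 1e-8
        assert_kkt(system.design, system.dvec, system.weights)

    def test_nnls_clamps_negative_ols_weights_to_zero(self, quartet):
        # inflate one cross distance so OLS drives the AD|BC split negative
        v = quartet.values.copy()
        v[1, 2] += 1.0
        v[2, 1] += 1.0
        from mcnet import DistanceMatrix
        d = DistanceMatrix(quartet.labels, v)
        sigma = CircularOrdering((0, 1, 2, 3))
        splits = circular_splits(sigma)
        A, _ = build_design_matrix(splits, 4)
        dvec = d.condensed()
        w_ols = fit_ols(A, dvec)
        w_nnls = fit_nnls(A, dvec)
        assert w_ols.min() < -1e-9
        neg = w_ols < 0
        np.testing.assert_allclose(w_nnls[neg], 0.0, atol=1e-12)
        assert np.linalg.norm(A @ w_nnls - dvec) >= np.linalg.norm(A @ w_ols - dvec)
        assert_kkt(A, dvec, w_nnls)

    def test_nnls_optimum_matches_exhaustive_active_set_search(self, quartet):
        # on the 6-split quartet system, check NNLS against trying every
        # support: solve OLS on each subset of splits, keep feasible fits
        from itertools import combinations
        v = quartet.values.copy()
        v[1, 2] += 1.5
        v[2, 1] += 1.5
        from mcnet import DistanceMatrix
        dvec = DistanceMatrix(quartet.labels, v).condensed()
        splits = circular_splits(CircularOrdering((0, 1, 2, 3)))
        A, _ = build_design_matrix(splits, 4)
        best = np.inf
        for k in range(0, 7):
            for support in combinations(range(6), k):
                if not support:
                    resid = np.linalg.norm(dvec)
                else:
                    sub = A[:, support]
                    w, *_ = np.linalg.lstsq(sub, dvec, rcond=None)
                    if w.min() < -1e-12:
                        continue
                    resid = np.linalg.norm(sub @ w - dvec)
                best = min(best, resid)
        w_nnls = fit_nnls(A, dvec)
        assert np.linalg.norm(A @ w_nnls - dvec) == pytest.approx(best, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_nnls_residual_at_least_ols_residual(self, seed):
        d = random_metric(7, seed)
        splits = circular_splits(CircularOrdering(tuple(range(7))))
        A, _ = build_design_matrix(splits, 7)
        dvec = d.condensed()
        r_ols = np.linalg.norm(A @ fit_ols(A, dvec) - dvec)
        w = fit_nnls(A, dvec)
        r_nnls = np.linalg.norm(A @ w - dvec)
        assert r_nnls >= r_ols - 1e-12
        assert w.min() >= 0.0
        assert_kkt(A, dvec, w)


class TestFilterAndNorm:
    def test_quartet_keeps_five_splits(self, quartet):
        system = weight_splits(quartet, CircularOrdering((0, 1, 2, 3)))
        filtered = filter_splits(system)
        assert len(filtered.splits) == 5  # 2n-3 for the binary quartet tree
        assert all(w > 0 for w in filtered.weights)
        assert fit_norm(filtered) == pytest.approx(0.0, abs=1e-9)

    def test_threshold_above_max_weight_empties_the_system(self, quartet):
        system = weight_splits(quartet, CircularOrdering((0, 1, 2, 3)))
        empty = filter_splits(system, threshold=system.weights.max() + 1)
        assert len(empty.splits) == 0
        assert fit_norm(empty) == pytest.approx(np.linalg.norm(system.dvec))

    def test_all_above_threshold_is_identity(self, quartet):
        system = weight_splits(quartet, CircularOrdering((0, 1, 2, 3)))
        filtered = filter_splits(system, threshold=1e-10)
        again = filter_splits(filtered, threshold=1e-10)
        assert again.splits == filtered.splits
        np.testing.assert_array_equal(again.weights, filtered.weights)

    def test_phyletic_distances_are_nonnegative(self):
        for seed in range(5):
            d = random_metric(6, seed)
            system = weight_splits(d, CircularOrdering(tuple(range(6))))
            assert system.phyletic_distances().min() >= -1e-12

    def test_report_table_lists_every_split(self, quartet):
        system = filter_splits(weight_splits(quartet, CircularOrdering((0, 1, 2, 3))))
        table = system.to_table()
        assert table.count("\n") == len(system.splits) + 1
        assert "weight\tside" in table
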