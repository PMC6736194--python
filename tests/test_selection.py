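import numpy as np
import pytest

from scads import (
    CVTable,
    count_structures,
    eigenvector_cv,
    generate,
    one_se_rule,
    select_n_components,
    select_structure,
    sequential_select,
    template_to_mask,
    tune_lambda,
)
from scads.selection import _fold_indices


def noiseless_data(d1d2c, I=60, sizes=(8, 8), seed=5):
    return generate(I, sizes, d1d2c, (0.2, 0.2, 0.6), 0.0, seed=seed)


class TestFolds:
    def test_partition_covers_every_row_once(self):
        rng = np.random.default_rng(0)
        folds = _fold_indices(23, 5, rng)
        allidx = np.concatenate(folds)
        assert sorted(allidx) == list(range(23))
        assert len(folds) == 5

    def test_invalid_fold_counts(self, small_dataset):
        with pytest.raises(ValueError, match="n_folds"):
            eigenvector_cv(small_dataset.data, 2, n_folds=1)


class TestEigenvectorCV:
    def test_noiseless_low_rank_data_has_tiny_mpress(self, d1d2c):
        # raw scale: noiseless data may contain exactly-zero columns
        # (variables with all-zero loadings), so no standardization here
        ds = noiseless_data(d1d2c)
        res = eigenvector_cv(ds.data, 3, n_folds=10, seed=0, standardize=False,
                             tol=1e-12, max_iter=3000)
        assert res.mpress < 1e-6
        assert res.se >= 0

    def test_mpress_and_se_nonnegative(self, small_dataset):
        res = eigenvector_cv(small_dataset.data, 2, n_folds=5, seed=1)
        assert res.mpress >= 0
        assert res.se >= 0
        assert len(res.fold_press) == 5

    def test_own_entry_never_used_for_its_prediction(self, small_dataset):
        """Perturbing x_ij must not move the prediction of x_ij, nor any
        prediction for other rows of the same fold (whose fit excludes
        row i)."""
        data = small_dataset.data
        res = eigenvector_cv(data, 2, n_folds=5, seed=3,
                             return_predictions=True)
        i, j = 4, 7
        fold = res.fold_assignment[i]
        X2 = data.values.copy()
        X2[i, j] += 37.0
        res2 = eigenvector_cv(data.with_values(X2), 2, n_folds=5, seed=3,
                              return_predictions=True)
        same_fold = np.flatnonzero(res.fold_assignment == fold)
        assert res2.predictions[i, j] == pytest.approx(res.predictions[i, j], rel=1e-9)
        others = same_fold[same_fold != i]
        np.testing.assert_allclose(res2.predictions[others],
                                   res.predictions[others], rtol=1e-9)

    def test_deterministic_given_seed(self, small_dataset):
        a = eigenvector_cv(small_dataset.data, 2, n_folds=5, seed=11)
        b = eigenvector_cv(small_dataset.data, 2, n_folds=5, seed=11)
        assert a.mpress == b.mpress and a.se == b.se


class TestOneSERule:
    def _table(self, mpress, se, cx):
        t = CVTable.empty()
        for i, (m, s, c) in enumerate(zip(mpress, se, cx)):
            t.add(f"c{i}", m, s, c)
        return t

    def test_single_candidate_returned(self):
        assert one_se_rule(self._table([1.0], [0.1], [2])) == 0

    def test_least_complex_within_one_se_wins(self):
        # best 0.90 with se 0.10: candidate 1 (0.95) is inside, candidate
        # 2 (1.20) is outside, so the simpler candidate 1 is chosen
        idx = one_se_rule(self._table([0.90, 0.95, 1.20], [0.10, 0.2, 0.2], [3, 2, 1]))
        assert idx == 1

    def test_all_tied_returns_least_complex(self):
        idx = one_se_rule(self._table([1.0, 1.0, 1.0], [0.1, 0.1, 0.1], [3, 1, 2]))
        assert idx == 1

    def test_never_exceeds_threshold(self):
        mpress = [0.5, 0.45, 0.61, 0.7]
        se = [0.05, 0.1, 0.02, 0.02]
        idx = one_se_rule(self._table(mpress, se, [4, 3, 2, 1]))
        assert mpress[idx] <= 0.45 + 0.1


class TestSelectNComponents:
    def test_recovers_true_rank_of_noiseless_data(self, d1d2c):
        ds = noiseless_data(d1d2c)
        q, table = select_n_components(ds.data, 6, n_folds=10, seed=0,
                                       standardize=False)
        assert q == 3
        assert len(table) == 6

    def test_qmax_one(self, small_dataset):
        q, _ = select_n_components(small_dataset.data, 1, n_folds=5, seed=0)
        assert q == 1

    def test_never_more_complex_than_minimum_mpress(self, small_dataset):
        q, table = select_n_components(small_dataset.data, 5, n_folds=5, seed=2)
        assert q <= table.payload[int(np.argmin(table.mpress))]


class TestSelectStructure:
    def test_single_block_shortcut(self, rng):
        from scads import MultiBlockData
        from scads.data import Block
        X = rng.standard_normal((30, 6))
        mbd = MultiBlockData(X, (Block("only", 0, 6),))
        t, table = select_structure(mbd, 2, n_folds=5, seed=0)
        assert t.components == ((1,), (1,))
        assert len(table) == 1

    def test_table_has_one_row_per_candidate_structure(self, small_dataset):
        _, table = select_structure(small_dataset.data, 3, n_folds=5, seed=0)
        assert len(table) == count_structures(2, 3) == 10

    def test_selected_within_one_se_and_not_more_complex_than_best(self, small_dataset):
        t, table = select_structure(small_dataset.data, 3, n_folds=5, seed=0)
        idx = table.payload.index(t)
        best = int(np.argmin(table.mpress))
        assert table.mpress[idx] <= table.mpress[best] + table.se[best]
        assert table.complexity[idx] <= table.complexity[best]

    def test_candidate_cap(self, small_dataset):
        with pytest.raises(ValueError, match="cap"):
            select_structure(small_dataset.data, 3, candidate_cap=5)


class TestTuneLambda:
    def test_singleton_grid_returns_it(self, small_dataset):
        mask = template_to_mask(small_dataset.template, small_dataset.data)
        lam, _ = tune_lambda(small_dataset.data, 3, mask, [0.0], n_folds=5, seed=0)
        assert lam == 0.0

    def test_pure_noise_selects_largest_lasso(self, rng):
        from scads import MultiBlockData
        from scads.data import Block
        X = rng.standard_normal((40, 8))
        mbd = MultiBlockData(X, (Block("a", 0, 4), Block("b", 4, 8)))
        lam, table = tune_lambda(mbd, 2, None, [0.0, 20.0, 200.0, 2000.0],
                                 n_folds=5, seed=0)
        assert lam == 2000.0

    def test_selected_at_least_minimum_mpress_lambda(self, small_dataset):
        grid = [0.0, 0.05, 0.2, 0.8]
        lam, table = tune_lambda(small_dataset.data, 3, None, grid,
                                 n_folds=5, seed=0)
        assert lam >= table.payload[int(np.argmin(table.mpress))]


class TestSequential:
    def test_deterministic_and_complete(self, d1d2c):
        ds = generate(50, (6, 6), d1d2c, (0.2, 0.2, 0.5), 0.10, seed=3)
        a = sequential_select(ds.data, Q_max=4, n_folds=5, seed=9, lasso_grid_size=4)
        b = sequential_select(ds.data, Q_max=4, n_folds=5, seed=9, lasso_grid_size=4)
        assert a.Q == b.Q
        assert a.template == b.template
        assert a.lambda1 == b.lambda1 and a.lambda2 == b.lambda2
        np.testing.assert_array_equal(a.model.weights, b.model.weights)
        # I > J here, so the ridge step is skipped
        assert a.ridge_table is None and a.lambda2 == 0.0

    def test_ridge_tuned_when_wide(self, d1d2c):
        ds = generate(20, (12, 12), d1d2c, (0.2, 0.2, 0.5), 0.10, seed=4)
        sel = sequential_select(ds.data, Q_max=3, n_folds=4, seed=1,
                                lasso_grid_size=3)
        assert sel.ridge_table is not None
        assert sel.lambda2 > 0
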