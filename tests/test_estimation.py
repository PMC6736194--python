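import numpy as np
import pytest

from scads import (
    fit_scads,
    fit_sparse_pca,
    lambda_max,
    objective,
    predict_scores,
    template_to_mask,
    tune_lasso_to_cardinality,
    update_loadings,
    update_weights,
)


from _oracles import grid_search_coordinate, random_orthonormal  # noqa: E402


class TestObjective:
    def test_zero_weights_give_data_sum_of_squares(self, rng):
        X = rng.standard_normal((8, 5))
        P = random_orthonormal(rng, 5, 2)
        assert objective(X, np.zeros((5, 2)), P) == pytest.approx(np.sum(X * X))

    def test_perfect_reconstruction_gives_zero(self, rng):
        # build X = T Pᵀ with X W = T, so X W Pᵀ = X exactly
        P = random_orthonormal(rng, 6, 2)
        T = rng.standard_normal((9, 2))
        X = T @ P.T
        W = P @ np.linalg.inv(P.T @ P)   # Pᵀ W = I on the span
        assert objective(X, W, P) == pytest.approx(0.0, abs=1e-18)

    def test_hand_computed_value(self):
        X = np.array([[1.0, 2.0], [0.0, 1.0], [2.0, 0.0]])
        W = np.array([[1.0, 0.0], [0.5, -1.0]])
        P = np.array([[1.0, 0.0], [0.0, 1.0]])
        # independent elementwise arithmetic
        recon = X @ W @ P.T
        expected = float(((X - recon) ** 2).sum()) + 1.0 * 2.5 + 2.0 * 2.25
        assert objective(X, W, P, lambda1=1.0, lambda2=2.0) == pytest.approx(expected)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            objective(rng.standard_normal((4, 3)), np.ones((2, 2)), np.ones((2, 2)))


class TestUpdateLoadings:
    def test_identity_data_returns_weights(self, rng):
        W = random_orthonormal(rng, 5, 3)
        P = update_loadings(np.eye(5), W)
        np.testing.assert_allclose(P, W, atol=1e-10)

    def test_orthonormal_columns(self, rng):
        X = rng.standard_normal((12, 7))
        W = rng.standard_normal((7, 3))
        P = update_loadings(X, W)
        np.testing.assert_allclose(P.T @ P, np.eye(3), atol=1e-10)

    def test_minimizes_over_random_orthonormal_competitors(self, rng):
        X = rng.standard_normal((20, 6))
        W = rng.standard_normal((6, 2))
        P_star = update_loadings(X, W)
        f_star = objective(X, W, P_star)
        for _ in range(1000):
            P = random_orthonormal(rng, 6, 2)
            assert f_star <= objective(X, W, P) + 1e-9

    def test_all_zero_weights_raise(self, rng):
        with pytest.raises(ValueError, match="no active components"):
            update_loadings(rng.standard_normal((5, 4)), np.zeros((4, 2)))


class TestUpdateWeights:
    def test_huge_lasso_zeroes_all_free_weights(self, rng):
        X = rng.standard_normal((10, 6))
        P = random_orthonormal(rng, 6, 2)
        W = rng.standard_normal((6, 2))
        out = update_weights(X, P, 1e9, 0.0, None, W)
        np.testing.assert_array_equal(out, 0.0)

    def test_masked_positions_stay_exactly_zero(self, rng):
        X = rng.standard_normal((10, 6))
        P = random_orthonormal(rng, 6, 3)
        mask = rng.random((6, 3)) > 0.4
        mask[0, :] = True  # keep no all-zero columns
        W = rng.standard_normal((6, 3))
        out = W
        for _ in range(5):
            out = update_weights(X, P, 0.3, 0.1, mask, out)
        assert np.all(out[~mask] == 0.0)

    def test_non_orthonormal_loadings_rejected(self, rng):
        X = rng.standard_normal((8, 4))
        P = np.ones((4, 2))
        with pytest.raises(ValueError, match="orthonormal"):
            update_weights(X, P, 0.0, 0.0, None, np.zeros((4, 2)))

    def test_single_coordinate_matches_grid_search(self, rng):
        # the sweep visits (j=0, q=0) first, so at that point every other
        # weight still holds its input value: a clean 1-D comparison
        X = rng.standard_normal((5, 3))
        P = random_orthonormal(rng, 3, 2)
        W = rng.standard_normal((3, 2)) * 0.5
        lam1, lam2 = 0.7, 0.3
        out = update_weights(X, P, lam1, lam2, None, W)
        expected = grid_search_coordinate(X, W, P, lam1, lam2, 0, 0)
        assert out[0, 0] == pytest.approx(expected, abs=2e-4)

    def test_coordinate_updates_match_grid_oracle_across_many_instances(self):
        """The first coordinate update of a sweep is the exact univariate
        minimizer, checked against a dense grid search on 100 random
        small instances."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((6, 4))
            P = random_orthonormal(rng, 4, 2)
            W = rng.standard_normal((4, 2))
            lam1 = float(rng.uniform(0, 3))
            lam2 = float(rng.uniform(0, 2))
            out = update_weights(X, P, lam1, lam2, None, W)
            expected = grid_search_coordinate(X, W, P, lam1, lam2, 0, 0)
            assert out[0, 0] == pytest.approx(expected, abs=2e-4), f"seed {seed}"


class TestFitScads:
    def test_loss_trace_never_increases(self, rng):
        X = rng.standard_normal((40, 15))
        model = fit_scads(X, 4, lambda1=0.8, lambda2=0.2, tol=0.0, max_iter=60, seed=0)
        assert len(model.loss_trace) >= 50
        diffs = np.diff(model.loss_trace)
        assert np.all(diffs <= 1e-10)

    def test_pca_limit_matches_truncated_svd(self, rng):
        X = rng.standard_normal((20, 8))
        X = X - X.mean(0)
        model = fit_scads(X, 3, tol=1e-12, max_iter=2000)
        resid = np.sum((X - X @ model.weights @ model.loadings.T) ** 2)
        s = np.linalg.svd(X, compute_uv=False)
        svd_resid = float(np.sum(s[3:] ** 2))
        assert resid == pytest.approx(svd_resid, rel=1e-6, abs=1e-9)

    def test_mask_zero_cells_are_bitwise_zero(self, small_dataset):
        mask = template_to_mask(small_dataset.template, small_dataset.data).mask
        model = fit_scads(small_dataset.data.values, 3, lambda1=0.01,
                          lambda2=0.01, mask=mask, seed=1)
        assert np.all(model.weights[~mask] == 0.0)

    def test_gram_and_streaming_kernels_agree(self, rng):
        for shape in [(15, 8), (8, 15)]:
            X = rng.standard_normal(shape)
            Q = 3
            kw = dict(lambda1=0.4, lambda2=0.1, tol=1e-10, max_iter=200)
            a = fit_scads(X, Q, method="gram", **kw)
            b = fit_scads(X, Q, method="tall", **kw)
            np.testing.assert_allclose(a.weights, b.weights, atol=1e-9)
            np.testing.assert_allclose(a.loadings, b.loadings, atol=1e-9)

    def test_multiple_starts_return_best_loss(self, rng):
        X = rng.standard_normal((25, 10))
        m1 = fit_scads(X, 3, lambda1=1.0, n_starts=1, seed=3)
        m5 = fit_scads(X, 3, lambda1=1.0, n_starts=5, seed=3)
        assert m5.loss_trace[-1] <= m1.loss_trace[-1] + 1e-12

    def test_q_too_large_raises(self, rng):
        with pytest.raises(ValueError, match="Q"):
            fit_scads(rng.standard_normal((5, 4)), 5)

    def test_sign_convention_largest_weight_positive(self, rng):
        X = rng.standard_normal((30, 8))
        model = fit_scads(X, 3, lambda1=0.2, seed=0)
        for q in range(3):
            col = model.weights[:, q]
            assert col[np.argmax(np.abs(col))] >= 0


class TestSparsePCA:
    def test_equals_fit_scads_with_all_ones_mask(self, rng):
        X = rng.standard_normal((20, 9))
        a = fit_sparse_pca(X, 2, lambda1=0.5, lambda2=0.1, seed=4)
        b = fit_scads(X, 2, lambda1=0.5, lambda2=0.1,
                      mask=np.ones((9, 2), dtype=bool), seed=4)
        np.testing.assert_array_equal(a.weights, b.weights)
        np.testing.assert_array_equal(a.loadings, b.loadings)
        assert a.start_id == b.start_id

    def test_no_lasso_gives_dense_weights(self, rng):
        X = rng.standard_normal((20, 6))
        model = fit_sparse_pca(X, 2, lambda1=0.0, lambda2=0.01)
        assert np.all(model.weights != 0)


class TestCardinalityTuning:
    def test_full_target_returns_near_zero_lasso(self, small_dataset):
        X = small_dataset.data.values
        mask = template_to_mask(small_dataset.template, small_dataset.data).mask
        res = tune_lasso_to_cardinality(X, 3, mask, 1e-6, int(mask.sum()))
        assert res.exact
        assert res.n_nonzero == int(mask.sum())
        assert np.all(res.lambda1 < 1e-6 * lambda_max(X, 3, mask) + 1e-30)

    def test_zero_target_returns_lambda_max_and_empty_model(self, small_dataset):
        X = small_dataset.data.values
        res = tune_lasso_to_cardinality(X, 3, None, 1e-6, 0)
        np.testing.assert_allclose(res.lambda1, lambda_max(X, 3, None))
        assert res.n_nonzero == 0

    def test_sparse_target_hits_count_or_nearest(self, small_dataset):
        X = small_dataset.data.values
        mask = template_to_mask(small_dataset.template, small_dataset.data).mask
        target = int(round(0.4 * mask.sum()))
        res = tune_lasso_to_cardinality(X, 3, mask, 1e-3, target)
        # within the stated tolerance, or the closest achievable count
        assert abs(res.n_nonzero - target) <= max(1e-4 * target, 2)

    def test_per_component_targets(self, small_dataset):
        X = small_dataset.data.values
        targets = np.array([6, 6, 10])
        res = tune_lasso_to_cardinality(X, 3, None, 1e-3, targets)
        # exact counts, or off by at most one where the count function
        # jumps over the target (nearest achievable bracket endpoint)
        counts = res.model.nonzero_per_component()
        assert np.all(np.abs(counts - targets) <= 1)
        if res.exact:
            np.testing.assert_array_equal(counts, targets)


class TestPredictScores:
    def test_training_scores_reproduced(self, rng):
        X = rng.standard_normal((15, 6))
        model = fit_scads(X, 2, lambda1=0.3, seed=0)
        np.testing.assert_allclose(predict_scores(X, model), X @ model.weights)

    def test_zero_row_gives_zero_scores(self, rng):
        model = fit_scads(rng.standard_normal((15, 6)), 2, seed=0)
        np.testing.assert_array_equal(predict_scores(np.zeros((1, 6)), model), 0.0)

    def test_scores_ignore_zero_weight_variables(self, small_dataset):
        X = small_dataset.data.values
        mask = template_to_mask(small_dataset.template, small_dataset.data).mask
        model = fit_scads(X, 3, lambda1=0.05, lambda2=0.01, mask=mask, seed=0)
        zero_var = int(np.flatnonzero(model.weights[:, 0] == 0)[0])
        X2 = X.copy()
        X2[:, zero_var] += 100.0
        t1 = predict_scores(X, model)[:, 0]
        t2 = predict_scores(X2, model)[:, 0]
        np.testing.assert_allclose(t1, t2)

    def test_column_mismatch_raises(self, rng):
        model = fit_scads(rng.standard_normal((10, 5)), 2)
        with pytest.raises(ValueError, match="columns"):
            predict_scores(np.zeros((2, 4)), model)
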