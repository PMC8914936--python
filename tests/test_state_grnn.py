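import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import limbintent as li
from limbintent.state_grnn import FEATURE_COLUMNS, fold_indices


def toy_data(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 4))
    y = rng.choice([-1, 0, 1], size=n).astype(float)
    return X, y


class TestStateFeatures:
    def test_constant_window_is_static_signature(self):
        np.testing.assert_allclose(li.state_features([3.0] * 10), [0, 0, 3, 3])

    def test_increasing_window_has_positive_diff(self):
        row = li.state_features(np.linspace(0, 9, 10))
        assert row[1] > 0

    def test_example_row(self):
        e = [0, 1, 2, 1]
        expected_var = sum((x - 1.0) ** 2 for x in e) / 3  # Bessel-corrected
        np.testing.assert_allclose(li.state_features(e), [expected_var, 1, 2, 0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            li.state_features([1.0])


class TestGrnnPredict:
    def test_single_training_row_returns_its_target(self):
        model = li.train_state_model([[0, 0, 0, 0]], [1.0], sigma=0.5)
        assert li.grnn_predict(model, [5, 5, 5, 5]) == pytest.approx(1.0)

    def test_equidistant_symmetric_targets_average_to_zero(self):
        model = li.train_state_model([[1, 0, 0, 0], [-1, 0, 0, 0]], [1.0, -1.0], 0.5)
        assert li.grnn_predict(model, [0, 0, 0, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_small_sigma_limit_is_nearest_neighbour(self):
        X, y = toy_data()
        model = li.train_state_model(X, y, sigma=1e-3)
        for i in [0, 7, 23]:
            assert li.grnn_predict(model, X[i]) == pytest.approx(y[i], abs=1e-6)

    def test_large_sigma_limit_is_target_mean(self):
        X, y = toy_data()
        model = li.train_state_model(X, y, sigma=1e6)
        assert li.grnn_predict(model, X[3]) == pytest.approx(np.mean(y), abs=1e-6)

    def test_predictions_bounded_by_targets(self):
        X, y = toy_data(60, seed=2)
        model = li.train_state_model(X, y, sigma=0.7)
        preds = li.grnn_predict(model, np.random.default_rng(5).normal(size=(200, 4)))
        assert np.all(preds >= -1 - 1e-12) and np.all(preds <= 1 + 1e-12)

    def test_permutation_invariance(self):
        X, y = toy_data()
        perm = np.random.default_rng(1).permutation(len(y))
        m1 = li.train_state_model(X, y, 0.7)
        m2 = li.train_state_model(X[perm], y[perm], 0.7)
        q = np.random.default_rng(2).normal(size=(20, 4))
        np.testing.assert_allclose(li.grnn_predict(m1, q), li.grnn_predict(m2, q),
                                   atol=1e-10)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            li.train_state_model([[0, 0, 0, 0]], [1.0], sigma=0.0)

    def test_json_round_trip_is_bit_identical(self, tmp_path):
        X, y = toy_data()
        model = li.train_state_model(X, y, 0.7)
        path = tmp_path / "model.json"
        model.save(path)
        reloaded = li.GrnnModel.load(path)
        q = np.random.default_rng(9).normal(size=(50, 4))
        np.testing.assert_array_equal(li.grnn_predict(model, q),
                                      li.grnn_predict(reloaded, q))

    def test_training_rows_reproduced_at_tiny_sigma(self):
        X, y = toy_data(30, seed=4)
        model = li.train_state_model(X, y, sigma=0.01)
        decoded = li.decode_state(li.grnn_predict(model, X))
        np.testing.assert_array_equal(decoded, y.astype(int))


class TestDecodeState:
    @pytest.mark.parametrize(
        "yhat,expected",
        [(0.9, 1), (-0.6, -1), (0.5, 0), (-0.5, 0), (0.0, 0), (1.0, 1), (-2.0, -1)],
    )
    def test_nearest_label_with_static_midpoints(self, yhat, expected):
        assert li.decode_state(yhat) == expected

    def test_vectorized(self):
        np.testing.assert_array_equal(li.decode_state([0.9, -0.6, 0.2]), [1, -1, 0])

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            li.decode_state(float("nan"))


class TestCrossValidation:
    def test_single_candidate_selected(self):
        X, y = toy_data()
        cv = li.cross_validate_sigma(X, y, [0.7], folds=5, seed=1)
        assert cv.selected_sigma == 0.7

    def test_fold_partition(self):
        folds = fold_indices(47, 10, seed=3)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1
        all_idx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_idx, np.arange(47))

    def test_deterministic_under_fixed_seed(self):
        X, y = toy_data(50, seed=6)
        grid = [0.3, 0.7, 1.1]
        cv1 = li.cross_validate_sigma(X, y, grid, seed=9)
        cv2 = li.cross_validate_sigma(X, y, grid, seed=9)
        assert cv1.selected_sigma == cv2.selected_sigma
        np.testing.assert_array_equal(cv1.mse_per_sigma, cv2.mse_per_sigma)

    def test_rejects_fewer_samples_than_folds(self):
        X, y = toy_data(8)
        with pytest.raises(ValueError):
            li.cross_validate_sigma(X, y, [0.7], folds=10)

    def test_matches_naive_recomputation_small(self):
        df = li.generate_state_dataset(120, seed=13)
        X = df[list(FEATURE_COLUMNS)].to_numpy()
        y = df["state"].to_numpy(dtype=float)
        grid = [0.2, 0.5, 0.8, 1.2]
        cv = li.cross_validate_sigma(X, y, grid, folds=10, seed=5)
        naive = naive_cv_mse(X, y, grid, folds=10, seed=5)
        np.testing.assert_allclose(cv.mse_per_sigma, naive, atol=1e-9)
        assert cv.selected_sigma == grid[int(np.argmin(naive))]


def naive_cv_mse(X, y, grid, folds, seed):
    """Independent re-implementation: explicit loops, textbook formulas."""
    perm = np.random.default_rng(seed).permutation(len(y))
    test_folds = np.array_split(perm, folds)
    out = []
    for sigma in grid:
        fold_mses = []
        for test_idx in test_folds:
            train_idx = np.setdiff1d(perm, test_idx)
            Xtr, ytr = X[train_idx], y[train_idx]
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd == 0] = 1.0
            Ztr = (Xtr - mu) / sd
            errs = []
            for xi, yi in zip(X[test_idx], y[test_idx]):
                z = (xi - mu) / sd
                d2 = np.sum((Ztr - z) ** 2, axis=1)
                w = np.exp(-(d2 - d2.min()) / (2 * sigma**2))
                errs.append((float(np.sum(w * ytr) / np.sum(w)) - yi) ** 2)
            fold_mses.append(float(np.mean(errs)))
        out.append(float(np.mean(fold_mses)))
    return out
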