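"""Tests of the from-scratch gradient-boosted regression-tree engine."""

import numpy as np
import pandas as pd
import pytest

from greenaccess.gbdt import (
    GBDTHyperparams,
    GBDTResults,
    GradientBoostedTrees,
    cross_validate,
    fit_tree,
)


@pytest.fixture(scope="module")
def nonlinear_data():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(500, 6))
    y = np.sin(X[:, 0]) + 0.5 * X[:, 1] ** 2 + X[:, 2] + rng.normal(0, 0.2, 500)
    return X, y


class TestFitTree:
    def test_constant_response_single_leaf(self):
        X = np.arange(20, dtype=float).reshape(-1, 1)
        tree = fit_tree(X, np.full(20, 4.2))
        assert tree.n_nodes == 1
        assert tree.value[0] == pytest.approx(4.2)

    def test_step_function_split_at_gap_midpoint(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([0.0, 0.0, 0.0, 5.0, 5.0, 5.0])
        tree = fit_tree(X, y, max_depth=1, min_leaf=1)
        assert tree.threshold[0] == pytest.approx(6.0)  # midpoint of 2 and 10
        assert sorted(tree.value[tree.feature == -1]) == [0.0, 5.0]
        # recorded improvement equals the full SSE removed
        assert tree.improvement[0] == pytest.approx(((y - y.mean()) ** 2).sum())

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 3))
        y = rng.normal(size=60)
        perm = rng.permutation(60)
        a, b = fit_tree(X, y), fit_tree(X[perm], y[perm])
        np.testing.assert_array_equal(a.feature, b.feature)
        np.testing.assert_allclose(a.threshold, b.threshold)
        np.testing.assert_allclose(np.sort(a.value), np.sort(b.value))

    def test_constant_features_nonconstant_y_is_single_leaf(self):
        X = np.ones((20, 2))
        y = np.arange(20, dtype=float)
        tree = fit_tree(X, y)
        assert tree.n_nodes == 1 and tree.value[0] == pytest.approx(y.mean())

    def test_depth_and_min_leaf_respected(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(200, 2)), rng.normal(size=200)
        tree = fit_tree(X, y, max_depth=2, min_leaf=10)
        assert tree.n_leaves <= 4
        counts = np.bincount(
            np.searchsorted(np.sort(np.unique(tree.predict(X))), tree.predict(X))
        )
        assert counts[counts > 0].min() >= 10


class TestBoosting:
    def test_constant_response(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        res = GradientBoostedTrees(np.full(30, 7.0), X).fit(n_trees=5, learning_rate=1.0)
        assert res.f0 == pytest.approx(7.0)
        np.testing.assert_allclose(res.predict(X), 7.0)

    def test_one_tree_full_rate_equals_cart_on_centered_response(self, nonlinear_data):
        X, y = nonlinear_data
        boosted = GradientBoostedTrees(y, X).fit(n_trees=1, learning_rate=1.0)
        cart = fit_tree(X, y - y.mean())
        np.testing.assert_allclose(
            boosted.predict(X), y.mean() + cart.predict(X), rtol=1e-12
        )

    def test_training_loss_monotone_nonincreasing(self, nonlinear_data):
        X, y = nonlinear_data
        res = GradientBoostedTrees(y, X).fit(n_trees=80, learning_rate=0.1)
        assert np.all(np.diff(res.train_loss) <= 1e-12)

    def test_deep_unshrunk_fit_drives_training_mse_to_zero(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 2))  # distinct values almost surely
        y = rng.normal(size=40)
        res = GradientBoostedTrees(y, X).fit(
            n_trees=150, learning_rate=1.0, max_depth=8, min_leaf=1
        )
        assert res.train_loss[-1] < 1e-8

    def test_prediction_is_f0_plus_shrunk_tree_sum(self, nonlinear_data):
        X, y = nonlinear_data
        res = GradientBoostedTrees(y, X).fit(n_trees=20, learning_rate=0.1)
        manual = np.full(len(X), res.f0)
        for tree in res.trees:
            manual += res.params.learning_rate * tree.predict(X)
        np.testing.assert_allclose(res.predict(X), manual, rtol=1e-12)

    def test_agreement_with_reference_implementation(self, nonlinear_data):
        """Matched hyperparameters reproduce an established library's fit."""
        sklearn = pytest.importorskip("sklearn")
        from sklearn.ensemble import GradientBoostingRegressor
        from sklearn.metrics import r2_score

        X, y = nonlinear_data
        hp = GBDTHyperparams(n_trees=100, learning_rate=0.1, max_depth=3, min_leaf=5)
        ours = GradientBoostedTrees(y, X).fit(hp).predict(X)
        ref = GradientBoostingRegressor(
            n_estimators=100, learning_rate=0.1, max_depth=3, min_samples_leaf=5,
            random_state=0,
        ).fit(X, y).predict(X)
        assert r2_score(ours, ref) > 0.99

    def test_non_finite_inputs_rejected(self):
        X = np.ones((12, 2))
        y = np.ones(12)
        y[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            GradientBoostedTrees(y, X)

    def test_missing_feature_named_at_predict(self, nonlinear_data):
        X, y = nonlinear_data
        df = pd.DataFrame(X, columns=[f"f{j}" for j in range(6)])
        res = GradientBoostedTrees(y, df).fit(n_trees=3, learning_rate=0.5)
        with pytest.raises(KeyError, match="f5"):
            res.predict(df.drop(columns="f5"))


class TestImportance:
    def test_sums_to_100_when_splits_exist(self, nonlinear_data):
        X, y = nonlinear_data
        res = GradientBoostedTrees(y, X).fit(n_trees=30, learning_rate=0.1)
        assert res.feature_importance().sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_informative_feature_dominates(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(300, 5))
        y = 3.0 * X[:, 1]
        res = GradientBoostedTrees(y, X).fit(n_trees=100, learning_rate=0.1)
        imp = res.feature_importance()
        assert imp.iloc[1] > 95.0

    def test_irrelevant_duplicate_feature_near_zero(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(300, 4))
        X[:, 3] = rng.normal(size=300)  # pure noise
        y = np.sin(X[:, 0])
        res = GradientBoostedTrees(y, X).fit(n_trees=100, learning_rate=0.1)
        assert res.feature_importance().iloc[3] < 2.0

    def test_no_split_model_warns_with_zeros(self):
        X = np.ones((20, 2))
        res = GradientBoostedTrees(np.ones(20), X).fit(n_trees=2, learning_rate=0.5)
        with pytest.warns(UserWarning, match="no splits"):
            imp = res.feature_importance()
        assert (imp == 0).all()


class TestCrossValidation:
    def test_noiseless_linear_recovery(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(300, 3))
        y = 2.0 * X[:, 0] - X[:, 1]
        cv = cross_validate(X, y, n_trees=200, learning_rate=0.1, seed=0)
        assert cv.mean_r2 >= 0.9

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(300, 3))
        y = rng.normal(size=300)
        cv = cross_validate(X, y, n_trees=50, learning_rate=0.05, seed=0)
        assert cv.mean_r2 < 0.15  # may be <= 0 by the 1 - SS ratio convention

    def test_seeded_determinism(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(80, 3))
        y = rng.normal(size=80)
        a = cross_validate(X, y, n_trees=10, learning_rate=0.1, seed=5)
        b = cross_validate(X, y, n_trees=10, learning_rate=0.1, seed=5)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
        assert a.fold_r2 == b.fold_r2

    def test_too_many_folds_rejected(self):
        X, y = np.ones((4, 2)), np.ones(4)
        with pytest.raises(ValueError, match="folds"):
            cross_validate(X, y, n_trees=1, n_folds=5)


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, nonlinear_data, tmp_path):
        X, y = nonlinear_data
        df = pd.DataFrame(X, columns=[f"f{j}" for j in range(6)])
        res = GradientBoostedTrees(y, df).fit(n_trees=15, learning_rate=0.2)
        path = tmp_path / "model.json"
        res.to_json(path)
        loaded = GBDTResults.from_json(path.read_text())
        np.testing.assert_allclose(loaded.predict(df), res.predict(df), rtol=1e-12)
        assert loaded.feature_names == res.feature_names


class TestHyperparams:
    @pytest.mark.parametrize(
        "kwargs", [dict(n_trees=0), dict(learning_rate=0.0),
                   dict(learning_rate=1.5), dict(n_folds=1)]
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GBDTHyperparams(**kwargs)
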