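"""Effect analysis: partial dependence, smoothing, key variables, OLS."""

import numpy as np
import pandas as pd
import pytest

from greenaccess.effects import (
    compare_models,
    ols_fit,
    partial_dependence,
    select_key_variables,
    smooth_curve,
)
from greenaccess.gbdt import GradientBoostedTrees, cross_validate


@pytest.fixture(scope="module")
def linear_fit():
    rng = np.random.default_rng(21)
    X = pd.DataFrame(
        {"x1": rng.uniform(0, 10, 400), "x2": rng.normal(size=400)}
    )
    y = 2.0 * X["x1"].to_numpy()
    res = GradientBoostedTrees(y, X).fit(n_trees=400, learning_rate=0.1)
    return X, y, res


class TestPartialDependence:
    def test_ignored_feature_gives_flat_curve(self, linear_fit):
        X, _, res = linear_fit
        curve = partial_dependence(res, X, "x2")
        assert np.ptp(curve.raw) < 0.05 * 20.0  # response spans ~20 units

    def test_linear_effect_slope_recovered(self, linear_fit):
        X, _, res = linear_fit
        curve = partial_dependence(res, X, "x1")
        interior = slice(5, -5)
        slope = np.polyfit(curve.grid[interior], curve.smoothed[interior], 1)[0]
        assert slope == pytest.approx(2.0, rel=0.1)

    def test_grid_confined_to_quantile_range(self, linear_fit):
        X, _, res = linear_fit
        curve = partial_dependence(res, X, "x1", quantile_range=(0.1, 0.9))
        lo, hi = np.quantile(X["x1"], [0.1, 0.9])
        assert curve.grid[0] >= lo - 1e-9 and curve.grid[-1] <= hi + 1e-9
        assert np.all(np.diff(curve.grid) > 0)

    def test_constant_feature_single_point_with_warning(self, linear_fit):
        X, y, res = linear_fit
        Xc = X.copy()
        Xc["x2"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            curve = partial_dependence(res, Xc, "x2")
        assert len(curve.grid) == 1

    def test_additivity_pd_independent_of_other_features(self):
        """PD of an additive model in one feature does not depend on the
        distribution of the others."""
        rng = np.random.default_rng(22)
        X1 = pd.DataFrame({"a": rng.uniform(0, 1, 300), "b": rng.normal(0, 1, 300)})
        X2 = X1.copy()
        X2["b"] = rng.normal(5, 3, 300)  # shifted other-feature distribution
        y1 = 3 * X1["a"].to_numpy()
        # depth-1 stumps give an exactly additive fitted function
        res = GradientBoostedTrees(y1, X1).fit(
            n_trees=200, learning_rate=0.1, max_depth=1
        )
        c1 = partial_dependence(res, X1, "a", n_grid=20)
        c2 = partial_dependence(res, X2, "a", n_grid=20)
        # the other feature's distribution only shifts the curve by the
        # constant mean of its own additive term; the shape is unchanged
        np.testing.assert_allclose(
            c1.raw - c1.raw.mean(), c2.raw - c2.raw.mean(), atol=1e-9
        )


class TestSmoothCurve:
    def test_linear_input_reproduced_exactly(self):
        y = np.linspace(0, 5, 30)
        np.testing.assert_allclose(smooth_curve(y), y, atol=1e-9)

    def test_spike_attenuated_below_half(self):
        y = np.zeros(25)
        y[12] = 1.0
        smoothed = smooth_curve(y)
        assert abs(smoothed[12]) < 0.5

    def test_length_preserved_and_endpoints_estimated(self):
        y = np.sin(np.linspace(0, 3, 40))
        out = smooth_curve(y, span=0.3)
        assert len(out) == 40
        assert np.all(np.isfinite(out))

    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            smooth_curve(np.zeros(10), span=0.0)
        with pytest.raises(ValueError, match="span"):
            smooth_curve(np.zeros(10), span=1.5)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5"):
            smooth_curve(np.zeros(4))

    def test_density_weights_downweight_sparse_bins(self):
        y = np.zeros(21)
        y[10] = 1.0  # spike sits in a low-density bin
        w = np.ones(21)
        w[10] = 1e-6
        assert abs(smooth_curve(y, weights=w)[10]) < abs(smooth_curve(y)[10])


class TestKeyVariables:
    def test_all_above_threshold_selected_descending(self):
        imp = {"a": 50.0, "b": 40.0, "c": 10.0}
        assert select_key_variables(imp) == ["a", "b", "c"]

    def test_boundary_is_strict(self):
        assert select_key_variables({"a": 93.0, "b": 7.0}) == ["a"]

    def test_idempotent_and_order_independent(self):
        imp = pd.Series({"c": 10.0, "a": 50.0, "b": 40.0})
        first = select_key_variables(imp)
        assert select_key_variables(imp.sort_values()) == first
        assert select_key_variables(imp.sample(frac=1, random_state=0)) == first
        assert select_key_variables(imp) == first

    def test_five_element_key_set(self):
        imp = {"PD": 20.86, "IFA": 17.35, "PI": 14.43, "GDP": 13.75, "RCG": 12.87,
               "SAD": 4.18, "P-NDVI": 4.74, "LUM": 3.42, "PC": 2.32, "PCAR": 1.88,
               "RI": 1.88, "PR": 1.32, "PFBR": 0.51, "RD": 0.45, "PTN": 0.04}
        key = select_key_variables(imp, 7.0)
        assert key == ["PD", "IFA", "PI", "GDP", "RCG"]

    def test_rejects_unnormalised_table(self):
        with pytest.raises(ValueError, match="100"):
            select_key_variables({"a": 5.0, "b": 5.0})


class TestOLS:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(30)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        y = 1.0 + 2.0 * X["a"] - 0.5 * X["c"]
        res = ols_fit(X, y)
        assert res.r_squared == pytest.approx(1.0)
        assert res.intercept == pytest.approx(1.0, abs=1e-8)
        assert res.coefficients["a"] == pytest.approx(2.0, abs=1e-8)
        assert res.coefficients["b"] == pytest.approx(0.0, abs=1e-8)

    def test_orthogonal_noise_r2_near_zero(self):
        rng = np.random.default_rng(31)
        X = pd.DataFrame(rng.normal(size=(500, 3)))
        y = rng.normal(size=500)
        assert ols_fit(X, y).r_squared < 0.05

    def test_matches_normal_equations_oracle_10x3(self):
        rng = np.random.default_rng(32)
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        design = np.column_stack([np.ones(10), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        res = ols_fit(pd.DataFrame(X, columns=["a", "b", "c"]), y)
        np.testing.assert_allclose(
            np.r_[res.intercept, res.coefficients.to_numpy()], beta, atol=1e-8
        )

    def test_rank_deficiency_reports_collinear_columns(self):
        rng = np.random.default_rng(33)
        X = pd.DataFrame({"a": rng.normal(size=20)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="collinear"):
            ols_fit(X, rng.normal(size=20))

    def test_r2_never_decreases_with_added_predictor(self):
        rng = np.random.default_rng(34)
        X = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        y = X["a"] + rng.normal(size=100)
        r2 = [ols_fit(X[list("abcd")[: k + 1]], y).r_squared for k in range(4)]
        assert all(r2[k + 1] >= r2[k] - 1e-12 for k in range(3))


class TestCompareModels:
    def test_nonlinear_data_favours_gbdt(self):
        rng = np.random.default_rng(35)
        X = pd.DataFrame({"a": rng.uniform(-3, 3, 400), "b": rng.normal(size=400)})
        y = np.sin(2 * X["a"].to_numpy()) + rng.normal(0, 0.1, 400)
        cv = cross_validate(X, y, n_trees=150, learning_rate=0.1, seed=1)
        cmp = compare_models(ols_fit(X, y), cv)
        assert cmp.gbdt_r2 > cmp.ols_r2
        assert cmp.difference == pytest.approx(cmp.gbdt_r2 - cmp.ols_r2)

    def test_linear_data_difference_small(self):
        rng = np.random.default_rng(36)
        X = pd.DataFrame({"a": rng.normal(size=400), "b": rng.normal(size=400)})
        y = X["a"].to_numpy() + rng.normal(0, 0.1, 400)
        cv = cross_validate(X, y, n_trees=200, learning_rate=0.1, seed=1)
        cmp = compare_models(ols_fit(X, y), cv)
        assert abs(cmp.difference) < 0.1

    def test_deterministic_report(self):
        rng = np.random.default_rng(37)
        X = pd.DataFrame(rng.normal(size=(100, 2)), columns=["a", "b"])
        y = X["a"].to_numpy()
        a = compare_models(ols_fit(X, y), cross_validate(X, y, n_trees=20,
                                                         learning_rate=0.1, seed=2))
        b = compare_models(ols_fit(X, y), cross_validate(X, y, n_trees=20,
                                                         learning_rate=0.1, seed=2))
        assert a.to_dict() == b.to_dict()
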