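import numpy as np
import pandas as pd
import pytest

from mossar import brt

N = 60


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="module")
def X(rng):
    return pd.DataFrame({f"x{i}": rng.normal(size=N) for i in range(5)})


def quick_config(**kw):
    defaults = dict(tree_complexity=2, learning_rate=0.05, bag_fraction=0.75,
                    max_trees=300, step_size=25)
    defaults.update(kw)
    return brt.BRTConfig(**defaults)


def tiny_grid():
    return [
        brt.BRTConfig(tc, lr, 0.75, max_trees=300, step_size=25)
        for tc in (1, 2)
        for lr in (0.01, 0.05)
    ]


class TestGrid:
    def test_default_grid_has_360_points(self):
        grid = brt.default_grid()
        assert len(grid) == 360
        assert len({(c.tree_complexity, c.learning_rate, c.bag_fraction) for c in grid}) == 360

    def test_bad_bag_fraction_rejected(self):
        with pytest.raises(ValueError):
            brt.BRTConfig(2, 0.01, 0.0)


class TestTuneBrt:
    def test_learnable_step_function(self, X):
        y = np.where(X["x0"] > 0, 5.0, -5.0)
        model = brt.fit_at_config(X, y, quick_config(), seed=0)
        assert model.pseudo_r2 > 0.95

    def test_null_data_no_hallucinated_signal(self, X):
        rng = np.random.default_rng(10)
        corrs = []
        for seed in range(8):
            y = rng.normal(size=N)
            model = brt.tune_brt(X, y, grid=tiny_grid(), seed=seed)
            corrs.append(model.cv_correlation)
        assert np.median(corrs) < 0.35

    def test_constant_response_rejected(self, X):
        with pytest.raises(ValueError, match="constant"):
            brt.fit_at_config(X, np.ones(N), quick_config())

    def test_fewer_rows_than_folds_rejected(self, X):
        with pytest.raises(ValueError):
            brt.fit_at_config(X.head(5), np.arange(5.0), quick_config(cv_folds=10))

    def test_deterministic_given_seed(self, X):
        y = 2 * X["x1"].to_numpy() + np.random.default_rng(3).normal(0, 0.5, N)
        a = brt.fit_at_config(X, y, quick_config(), seed=5)
        b = brt.fit_at_config(X, y, quick_config(), seed=5)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))
        assert a.n_trees_opt == b.n_trees_opt


class TestPerformance:
    def test_perfect_predictions(self, X):
        y = np.where(X["x0"] > 0, 5.0, -5.0)
        model = brt.fit_at_config(X, y, quick_config(max_trees=600), seed=0)
        perf = brt.performance(model, X, y)
        assert perf["rmse"] < 0.5 and perf["r2"] > 0.99

    def test_r2_zero_for_mean_prediction(self):
        # direct check of the definitions on a hand-built case
        y = np.array([1.0, 2.0, 3.0])
        pred = np.full(3, 2.0)
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot == pytest.approx(0.0)

    def test_heldout_recovery_strong_signal(self):
        rng = np.random.default_rng(11)
        n = 300
        X = pd.DataFrame({f"x{i}": rng.normal(size=n) for i in range(4)})
        y = np.sin(2 * X["x0"]) * 3 + X["x1"] + rng.normal(0, 0.5, n)
        train = np.arange(n) < 200
        model = brt.fit_at_config(X[train], y[train], quick_config(max_trees=500), seed=0)
        pred = model.predict(X[~train])
        resid = y[~train] - pred
        r2 = 1 - np.sum(resid**2) / np.sum((y[~train] - y[~train].mean()) ** 2)
        assert r2 >= 0.6


class TestConditionalImportance:
    @pytest.fixture(scope="class")
    def single_driver(self, X):
        y = 3 * X["x1"].to_numpy() + np.random.default_rng(1).normal(0, 0.3, N)
        model = brt.fit_at_config(X, y, quick_config(), seed=0)
        return model, y

    def test_sums_to_100(self, X, single_driver):
        model, y = single_driver
        ri = brt.conditional_importance(model, X, y, seed=0)
        assert ri["ri"].sum() == pytest.approx(100.0, abs=1e-6)
        assert (ri["ri"] >= 0).all()

    def test_planted_driver_dominates(self, X, single_driver):
        model, y = single_driver
        ri = brt.conditional_importance(model, X, y, seed=0)
        assert ri["ri"].idxmax() == "x1"
        assert ri.loc["x1", "ri"] > 50

    def test_unused_predictor_small(self, X, single_driver):
        model, y = single_driver
        ri = brt.conditional_importance(model, X, y, seed=0)
        assert (ri["ri"].drop("x1") < 5).all()

    def test_invariant_to_affine_y_rescale(self, X):
        rng = np.random.default_rng(2)
        y = 2 * X["x0"].to_numpy() + X["x2"].to_numpy() + rng.normal(0, 0.2, N)
        m1 = brt.fit_at_config(X, y, quick_config(), seed=0)
        m2 = brt.fit_at_config(X, 10 * y + 3, quick_config(), seed=0)
        ri1 = brt.conditional_importance(m1, X, y, seed=0)["ri"]
        ri2 = brt.conditional_importance(m2, X, 10 * y + 3, seed=0)["ri"]
        assert (ri1 - ri2).abs().max() < 5.0


class TestPartialDependence:
    def test_curve_mean_zero(self, X):
        y = np.sin(X["x0"].to_numpy() * 2) * 3
        model = brt.fit_at_config(X, y, quick_config(), seed=0)
        pdp = brt.partial_dependence(model, X, "x0")
        assert pdp["effect"].mean() == pytest.approx(0.0, abs=1e-10)

    def test_additive_shape_recovered(self, X):
        rng = np.random.default_rng(4)
        shape = np.tanh
        y = 4 * shape(X["x0"].to_numpy()) + rng.normal(0, 0.1, N)
        model = brt.fit_at_config(X, y, quick_config(max_trees=500), seed=0)
        pdp = brt.partial_dependence(model, X, "x0", n_grid=30)
        target = 4 * shape(pdp["value"].to_numpy())
        target -= target.mean()
        corr = np.corrcoef(pdp["effect"], target)[0, 1]
        assert corr > 0.95

    def test_unused_predictor_flat(self, X):
        y = np.where(X["x0"] > 0, 5.0, -5.0)
        model = brt.fit_at_config(X, y, quick_config(), seed=0)
        pdp = brt.partial_dependence(model, X, "x4")
        assert pdp["effect"].abs().max() < 0.5  # vs signal swing of 10


class TestInteractions:
    def test_additive_has_weak_interactions(self, X):
        rng = np.random.default_rng(5)
        y = 2 * X["x0"].to_numpy() + 2 * X["x1"].to_numpy() + rng.normal(0, 0.1, N)
        model = brt.fit_at_config(X, y, quick_config(tree_complexity=3), seed=0)
        mat = brt.interaction_strength(model, X)
        planted = brt.interaction_strength(
            brt.fit_at_config(
                X, 3 * X["x0"].to_numpy() * X["x1"].to_numpy() + rng.normal(0, 0.1, N),
                quick_config(tree_complexity=3), seed=0,
            ),
            X,
        )
        assert mat.to_numpy().max() < planted.loc["x0", "x1"]

    def test_planted_pair_is_top(self, X):
        rng = np.random.default_rng(6)
        y = 3 * X["x0"].to_numpy() * X["x1"].to_numpy() + rng.normal(0, 0.2, N)
        model = brt.fit_at_config(X, y, quick_config(tree_complexity=3), seed=0)
        mat = brt.interaction_strength(model, X)
        top = brt.top_interactions(mat, 1)[0]
        assert {top[0], top[1]} == {"x0", "x1"}

    def test_symmetric_zero_diagonal(self, X):
        rng = np.random.default_rng(7)
        y = X["x0"].to_numpy() * X["x1"].to_numpy() + rng.normal(0, 0.2, N)
        model = brt.fit_at_config(X, y, quick_config(tree_complexity=2), seed=0)
        mat = brt.interaction_strength(model, X)
        np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T)
        assert (np.diag(mat.to_numpy()) == 0).all()

    def test_depth_one_empty_with_notice(self, X):
        y = 2 * X["x0"].to_numpy()
        model = brt.fit_at_config(X, y, quick_config(tree_complexity=1), seed=0)
        with pytest.warns(UserWarning, match="tree_complexity"):
            mat = brt.interaction_strength(model, X)
        assert mat.empty


class TestResidualSpatialCheck:
    def test_random_residuals_usually_nonsignificant(self, X, transect_coords):
        rng = np.random.default_rng(8)
        y = 2 * X["x0"].to_numpy()[:56] + rng.normal(0, 0.5, 56)
        model = brt.fit_at_config(X.head(56), y, quick_config(), seed=0)
        ps = [
            brt.residual_spatial_check(model, X.head(56), y, transect_coords, seed=s).p_perm
            for s in range(5)
        ]
        assert np.median(ps) > 0.05

    def test_spatial_gradient_in_residuals_detected(self, X, transect_coords):
        gradient = np.linspace(-3, 3, 56)
        y = 2 * X["x0"].to_numpy()[:56] + gradient
        model = brt.fit_at_config(X.head(56), y, quick_config(learning_rate=0.001, max_trees=50), seed=0)
        res = brt.residual_spatial_check(model, X.head(56), y, transect_coords, seed=0)
        assert res.p_perm <= 0.05

    def test_constant_residuals_error(self, X, transect_coords):
        # lr=1, no bagging: a single depth-1 split fits the step exactly,
        # leaving identically-zero residuals
        y = np.where(X["x0"].to_numpy()[:56] > 0, 5.0, -5.0)
        model = brt.fit_at_config(
            X.head(56), y,
            quick_config(tree_complexity=1, learning_rate=1.0, bag_fraction=1.0,
                         max_trees=50, step_size=10),
            seed=0,
        )
        assert np.allclose(model.predict(X.head(56)), y)
        with pytest.raises(ValueError, match="zero variance|constant"):
            brt.residual_spatial_check(model, X.head(56), y, transect_coords)
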