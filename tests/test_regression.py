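import numpy as np
import pandas as pd
import pytest

from oilnmr.regression_models import (
    PLSRegressor,
    durbin_watson,
    fit_plsr,
    fit_svr,
    quantify_pipeline,
    regression_metrics,
    rmsecv_curve,
    select_latent_variables,
    _stratified_folds,
)
from oilnmr.relaxometry import FEATURE_COLUMNS


@pytest.fixture(scope="module")
def so_series(study_features):
    return study_features[study_features["label"].isin({"AO", "AO-SO", "SO"})]


class TestPlsr:
    def test_single_latent_variable_recovers_exactly_linear_response(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(30, 5))
        X, _ = np.linalg.qr(raw - raw.mean(axis=0))  # centred orthogonal columns
        y = 3.0 * X[:, 2]
        model = fit_plsr(X, y, 1)
        resid = y - model.predict(X)
        assert np.sqrt(np.mean(resid**2)) < 1e-8

    def test_full_rank_equals_ordinary_least_squares(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        model = fit_plsr(X, y, 6)
        # normal-equations oracle with intercept
        Xd = np.column_stack([np.ones(40), X])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        np.testing.assert_allclose(model.predict(X), Xd @ beta, atol=1e-8)

    def test_rank_deficiency_rejected(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])  # rank 3, 4 columns
        with pytest.raises(ValueError):
            fit_plsr(X, rng.normal(size=20), 4)

    def test_trend_features_carry_largest_standardized_coefficients(self, so_series):
        report = quantify_pipeline(so_series, adulterant="SO", seed=0)
        coef = report.standardized_coefficients.abs().sort_values(ascending=False)
        trend = {"T2W", "T22S", "T22P", "T23P", "T23E", "P22", "P23"}
        assert len(set(coef.index[:5]) & trend) >= 2


class TestRmsecv:
    def test_noiseless_linear_response_needs_one_latent_variable(self):
        # a single latent direction drives all features and the response, so
        # the feasible curve has one entry, already at (numerical) zero
        rng = np.random.default_rng(3)
        t = rng.normal(size=35)
        X = np.outer(t, rng.uniform(0.5, 2.0, size=5))
        with pytest.warns(UserWarning, match="truncated"):
            curve = rmsecv_curve(X, t, max_latent=4, folds=7, seed=0)
        assert len(curve) == 1
        assert curve[0] < 1e-8
        assert select_latent_variables(curve) == 1

    def test_curve_has_requested_length_when_feasible(self):
        rng = np.random.default_rng(30)
        X = rng.normal(size=(40, 5))
        y = X @ [1.0, 0.3, 0.0, -0.5, 0.1] + 0.05 * rng.normal(size=40)
        assert len(rmsecv_curve(X, y, max_latent=4, folds=7, seed=0)) == 4

    def test_curve_truncated_with_warning_when_rank_limited(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 3))
        y = X @ [1.0, -1.0, 0.5] + 0.01 * rng.normal(size=15)
        with pytest.warns(UserWarning, match="truncated"):
            curve = rmsecv_curve(X, y, max_latent=10, folds=5, seed=0)
        assert len(curve) == 3

    def test_matches_literal_fold_loop(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        y = X @ [1.0, 0.5, -0.2, 0.0] + 0.1 * rng.normal(size=30)
        folds, seed, max_latent = 7, 2, 3
        curve = rmsecv_curve(X, y, max_latent=max_latent, folds=folds, seed=seed)
        assignment = _stratified_folds(y, folds, seed)
        for a in range(1, max_latent + 1):
            sq = []
            for f in range(folds):
                tr, te = assignment != f, assignment == f
                model = PLSRegressor(n_components=a).fit(X[tr], y[tr])
                sq.extend((model.predict(X[te]) - y[te]) ** 2)
            assert curve[a - 1] == pytest.approx(np.sqrt(np.mean(sq)), abs=1e-12)


class TestLatentVariableSelection:
    @pytest.mark.parametrize("curve, expected", [
        ([0.1, 0.1, 0.1], 1),                  # flat -> simplest model
        ([0.20, 0.10, 0.099, 0.0985], 2),      # plateau after the second LV
        ([0.30, 0.20, 0.10], 3),               # keeps improving to the end
        ([0.10, 0.12, 0.08], 1),               # an increase counts as plateau
    ])
    def test_plateau_rule(self, curve, expected):
        assert select_latent_variables(curve) == expected

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            select_latent_variables([])


class TestRegressionMetrics:
    def test_perfect_predictions(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 3))
        y = X @ [1.0, 2.0, -1.0]
        model = fit_plsr(X, y, 3)
        m = regression_metrics(model, (X, y), (X, y))
        assert m.rmsep < 1e-8 and m.r2p == pytest.approx(1.0)

    def test_hand_computed_pearson_r_squared(self):
        class Identity:
            def predict(self, X):
                return np.asarray(X, float).ravel()

        obs = np.array([0.0, 1.0, 2.0, 4.0])
        pred = np.array([0.5, 0.9, 2.5, 3.6])
        m = regression_metrics(Identity(), (pred, obs), (pred, obs))
        # hand Pearson: r = cov / (sd_x sd_y)
        r = np.sum((obs - obs.mean()) * (pred - pred.mean())) / np.sqrt(
            np.sum((obs - obs.mean()) ** 2) * np.sum((pred - pred.mean()) ** 2))
        assert m.r2c == pytest.approx(r**2, abs=1e-12)

    def test_constant_shift_leaves_r2_and_raises_rmse(self):
        class Shifted:
            def predict(self, X):
                return np.asarray(X, float).ravel() + 0.5

        obs = np.array([0.0, 0.2, 0.4, 0.8, 1.0])
        m = regression_metrics(Shifted(), (obs, obs), (obs, obs))
        assert m.r2c == pytest.approx(1.0)
        assert m.rmsec == pytest.approx(0.5)

    def test_constant_observations_have_undefined_r2(self):
        class Zero:
            def predict(self, X):
                return np.zeros(len(X))

        obs = np.ones(5)
        m = regression_metrics(Zero(), (obs, obs), (obs, obs))
        assert m.r2c is None


class TestDurbinWatson:
    def test_constant_residuals_give_zero(self):
        stat, _ = durbin_watson(np.full(10, 1.3), n_permutations=100, seed=0)
        assert stat == 0.0

    def test_alternating_signs_n4_give_three(self):
        stat, _ = durbin_watson([1.0, -1.0, 1.0, -1.0], n_permutations=100, seed=0)
        assert stat == pytest.approx(3.0, abs=1e-12)

    def test_white_noise_near_two(self):
        rng = np.random.default_rng(7)
        stat, p = durbin_watson(rng.normal(size=1000), n_permutations=200, seed=0)
        assert 1.8 < stat < 2.2
        assert p > 0.05

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        e = rng.normal(size=50)
        s1, _ = durbin_watson(e, n_permutations=10, seed=0)
        s2, _ = durbin_watson(1e6 * e, n_permutations=10, seed=0)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_structured_residuals_detected(self):
        # strongly positively autocorrelated residuals: DW << 2, small p
        t = np.linspace(0, 1, 60)
        e = np.sin(2 * np.pi * t)
        stat, p = durbin_watson(e, n_permutations=2000, seed=1)
        assert stat < 1.0 and p < 0.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            durbin_watson([0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            durbin_watson([1.0, 2.0])


class TestSvr:
    def test_linear_noiseless_response_fits_tightly(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 4))
        y = 0.1 + 0.2 * X[:, 0] - 0.1 * X[:, 1]
        model = fit_svr(X, y, seed=0)
        assert model.cv_rmse_ < 0.02

    def test_same_seed_and_grid_reproduce_hyperparameters(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(50, 3))
        y = np.tanh(X[:, 0]) + 0.05 * rng.normal(size=50)
        m1 = fit_svr(X, y, seed=4)
        m2 = fit_svr(X, y, seed=4)
        assert (m1.C_, m1.gamma_, m1.epsilon_) == (m2.C_, m2.gamma_, m2.epsilon_)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))

    def test_degenerate_response_rejected(self):
        with pytest.raises(ValueError):
            fit_svr(np.random.default_rng(0).normal(size=(20, 3)), np.ones(20))


class TestQuantifyPipeline:
    def test_linear_system_routes_to_plsr(self):
        rng = np.random.default_rng(12)
        levels = np.repeat([0.0, 0.1, 0.2, 0.3, 0.4, 0.6, 0.8, 1.0], 8)
        X = np.column_stack([levels + 0.01 * rng.normal(size=levels.size)
                             for _ in range(len(FEATURE_COLUMNS))])
        table = pd.DataFrame(X, columns=FEATURE_COLUMNS)
        table["label"] = "AO-SO"
        table["level"] = levels
        report = quantify_pipeline(table, adulterant="SO", max_latent=3, seed=0)
        assert report.route == "PLSR"
        assert report.dw_p_value >= 0.05

    def test_deliberately_nonlinear_system_routes_to_svr(self):
        rng = np.random.default_rng(13)
        levels = np.repeat([0.0, 0.1, 0.2, 0.3, 0.4, 0.6, 0.8, 1.0], 8)
        base = levels**2  # strongly curved level-feature map
        X = np.column_stack([base + 0.005 * rng.normal(size=levels.size)
                             for _ in range(len(FEATURE_COLUMNS))])
        table = pd.DataFrame(X, columns=FEATURE_COLUMNS)
        table["label"] = "AO-RO"
        table["level"] = levels
        report = quantify_pipeline(table, adulterant="RO", max_latent=3, seed=0)
        assert report.dw_p_value < 0.05
        assert report.route == "SVR"
        assert report.svr is not None

    def test_pooled_report_contains_both_model_families(self, study_features):
        report = quantify_pipeline(study_features, adulterant="pooled", seed=0,
                                   always_fit_svr=True)
        rows = report.as_rows()
        assert set(rows["model"]) == {"PLSR", "SVR"}
        for col in ("RMSEC", "RMSECV", "RMSEP", "R2C", "R2P"):
            assert rows[col].notna().all()

    def test_unknown_series_rejected(self, study_features):
        with pytest.raises(ValueError):
            quantify_pipeline(study_features[study_features["label"] == "AO"],
                              adulterant="SO", seed=0)
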