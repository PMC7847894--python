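import numpy as np
import pandas as pd
import pytest

from edamame.model_selection import (
    ModelSelectionError,
    fit_neural,
    stepwise_select,
    variable_importance,
)


def noise_candidates(rng, n=200, k=5):
    return pd.DataFrame(
        rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(1, k + 1)]
    )


class TestStepwise:
    def test_strong_predictor_enters_with_correct_coefficient(self):
        rng = np.random.default_rng(0)
        X = noise_candidates(rng)
        y = 2.0 * X["x1"] + rng.normal(0, 0.1, len(X))
        result = stepwise_select(y, X)
        assert "x1" in result.selected_terms
        assert result.coefficients["x1"] == pytest.approx(2.0, abs=0.05)
        assert result.aic == min(result.aic_path)

    def test_invariant_to_candidate_column_order(self):
        rng = np.random.default_rng(1)
        X = noise_candidates(rng)
        y = X["x2"] - 0.5 * X["x4"] + rng.normal(0, 0.3, len(X))
        r1 = stepwise_select(y, X)
        r2 = stepwise_select(y, X[list(reversed(X.columns))])
        assert set(r1.selected_terms) == set(r2.selected_terms)
        for term, coef in r1.coefficients.items():
            assert r2.coefficients[term] == pytest.approx(coef, rel=1e-9)

    def test_zero_thresholds_give_intercept_only(self):
        rng = np.random.default_rng(2)
        X = noise_candidates(rng)
        y = 3.0 * X["x1"] + rng.normal(0, 0.1, len(X))
        result = stepwise_select(y, X, entry_p=1e-300, stay_p=1e-300)
        assert result.selected_terms == ()
        assert list(result.coefficients) == ["intercept"]

    def test_unit_thresholds_visit_full_model(self):
        """With entry/stay thresholds of 1 every candidate enters and none
        leaves, so the search path terminates at the full model; the
        returned model is the minimum-AIC subset along that path."""
        rng = np.random.default_rng(3)
        X = noise_candidates(rng)
        y = X["x1"] + rng.normal(0, 1.0, len(X))
        result = stepwise_select(y, X, entry_p=1.0, stay_p=1.0)
        assert len(result.aic_path) == len(X.columns) + 1  # intercept + 5 entries
        assert result.aic == min(result.aic_path)
        assert set(result.selected_terms) <= set(X.columns)

    def test_perfect_fit_guarded_aic_floor(self):
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(size=100))
        X = pd.DataFrame({"x1": y})
        result = stepwise_select(y, X)
        assert result.selected_terms == ("x1",)
        assert result.coefficients["x1"] == pytest.approx(1.0, abs=1e-9)
        assert np.isfinite(result.aic)

    def test_collinear_candidates_raise_in_strict_mode(self):
        rng = np.random.default_rng(5)
        X = noise_candidates(rng, k=3)
        X["x_sum"] = X["x1"] + X["x2"]
        y = pd.Series(rng.normal(size=len(X)))
        with pytest.raises(ModelSelectionError, match="collinear"):
            stepwise_select(y, X)

    def test_collinear_candidates_tolerated_when_not_strict(self):
        rng = np.random.default_rng(6)
        X = noise_candidates(rng, k=3)
        X["x_sum"] = X["x1"] + X["x2"]
        y = 1.5 * X["x1"] + 0.8 * X["x2"] + rng.normal(0, 0.1, len(X))
        result = stepwise_select(y, X, strict=False)
        # the redundant alias never enters alongside both parents
        assert not {"x1", "x2", "x_sum"} <= set(result.selected_terms)

    def test_too_few_observations_rejected(self):
        rng = np.random.default_rng(7)
        X = noise_candidates(rng, n=5, k=5)
        with pytest.raises(ModelSelectionError):
            stepwise_select(pd.Series(rng.normal(size=5)), X)

    def test_retained_terms_significant_at_stay_threshold(self):
        rng = np.random.default_rng(8)
        X = noise_candidates(rng)
        y = X["x1"] + 0.5 * X["x3"] + rng.normal(0, 0.5, len(X))
        result = stepwise_select(y, X)
        assert all(p <= 0.15 for p in result.pvalues.values())


class TestNeural:
    def test_recovers_tanh_generated_response(self):
        rng = np.random.default_rng(42)
        n = 2000
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        W = rng.normal(size=(3, 3))
        y = np.tanh(X.to_numpy() @ W) @ np.array([1.5, -2.0, 1.0])
        y = y + rng.normal(0, 0.05, n)
        model = fit_neural(y, X, n_nodes=5, penalty_strength=1e-4,
                           n_restarts=3, seed=0)
        assert model.val_r2 >= 0.9

    def test_approximates_linear_response(self):
        rng = np.random.default_rng(43)
        X = pd.DataFrame(rng.normal(size=(500, 3)), columns=list("abc"))
        model = fit_neural(X["a"].to_numpy(), X, n_nodes=5,
                           penalty_strength=1e-4, n_restarts=2, seed=1)
        assert model.val_r2 >= 0.95

    def test_more_restarts_never_worse_on_validation(self):
        rng = np.random.default_rng(44)
        X = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
        y = np.sin(3 * X["a"]) * np.cos(2 * X["b"]) + 0.1 * rng.normal(size=300)
        kw = dict(n_nodes=6, penalty_strength=1e-3, seed=5, max_iter=80)
        best1 = fit_neural(y, X, n_restarts=1, **kw).val_rmse
        best5 = fit_neural(y, X, n_restarts=5, **kw).val_rmse
        assert best5 <= best1 + 1e-12

    def test_training_loss_non_increasing(self):
        rng = np.random.default_rng(45)
        X = pd.DataFrame(rng.normal(size=(200, 2)), columns=list("ab"))
        y = X["a"] ** 2 + rng.normal(0, 0.1, 200)
        model = fit_neural(y, X, n_nodes=4, penalty_strength=1e-3,
                           n_restarts=1, seed=2)
        trace = np.asarray(model.loss_trace)
        assert len(trace) > 1
        assert np.all(np.diff(trace) <= 1e-9)

    def test_constant_response_rejected(self):
        rng = np.random.default_rng(46)
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=list("ab"))
        with pytest.raises(ModelSelectionError):
            fit_neural(np.ones(50), X, n_restarts=1, seed=0)

    def test_predictions_on_original_scale(self):
        rng = np.random.default_rng(47)
        X = pd.DataFrame(rng.normal(size=(200, 2)), columns=list("ab"))
        y = 5.0 + 3.0 * X["a"] + rng.normal(0, 0.05, 200)
        model = fit_neural(y, X, n_nodes=4, penalty_strength=1e-4,
                           n_restarts=2, seed=3)
        assert model.predict(X).mean() == pytest.approx(5.0, abs=0.3)


@pytest.fixture(scope="module")
def single_factor_model():
    rng = np.random.default_rng(50)
    X = pd.DataFrame(rng.normal(size=(600, 3)), columns=list("abc"))
    y = np.tanh(2 * X["a"]) + rng.normal(0, 0.02, 600)
    model = fit_neural(y, X, n_nodes=4, penalty_strength=1e-4,
                       n_restarts=2, seed=4)
    return model, X


class TestVariableImportance:
    def test_single_driver_dominates(self, single_factor_model):
        model, X = single_factor_model
        imp = variable_importance(model, X, n_permutations=10, seed=0)
        imp = imp.set_index("predictor")
        assert imp.loc["a", "main_effect"] == pytest.approx(1.0, abs=0.05)
        assert imp.loc["b", "total_effect"] == pytest.approx(0.0, abs=0.05)
        assert imp.loc["c", "total_effect"] == pytest.approx(0.0, abs=0.05)

    def test_symmetric_predictors_share_importance(self):
        rng = np.random.default_rng(51)
        X = pd.DataFrame(rng.normal(size=(600, 2)), columns=list("ab"))
        y = X["a"] + X["b"] + rng.normal(0, 0.05, 600)
        model = fit_neural(y, X, n_nodes=4, penalty_strength=1e-4,
                           n_restarts=2, seed=6)
        imp = variable_importance(model, X, n_permutations=10, seed=1)
        imp = imp.set_index("predictor")
        assert imp.loc["a", "main_effect"] == pytest.approx(
            imp.loc["b", "main_effect"], abs=0.05
        )

    def test_total_effect_at_least_main_and_in_unit_interval(self, single_factor_model):
        model, X = single_factor_model
        imp = variable_importance(model, X, n_permutations=5, seed=2)
        assert (imp["total_effect"] >= imp["main_effect"]).all()
        assert imp["main_effect"].between(0, 1).all()
        assert imp["total_effect"].between(0, 1).all()
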