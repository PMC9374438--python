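"""Regression: linear baseline, KRR closed form, hyperparameter tuning,
the chi error and feature-set evaluation."""

import numpy as np
import pytest
from scipy.optimize import minimize

from plumeloc import (
    chi_error,
    krr_fit,
    krr_predict,
    linear_fit,
    random_predictions,
    trivial_predictions,
    tune_hyperparameters,
)
from plumeloc.cone import RegressionDataset
from plumeloc.regression import evaluate_feature_sets, fit_evaluate
import pandas as pd


class TestChiError:
    def test_exact_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 5.0])
        assert chi_error(y, y) == 0.0

    def test_trivial_predictor_scores_one(self):
        rng = np.random.default_rng(0)
        y = rng.random(500)
        assert chi_error(y, trivial_predictions(y)) == pytest.approx(1.0)

    def test_random_guessing_scores_two_in_expectation(self):
        rng = np.random.default_rng(1)
        y = rng.exponential(size=800)
        chis = [chi_error(y, random_predictions(y, rng)) for _ in range(200)]
        assert np.mean(chis) == pytest.approx(2.0, abs=0.05)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            chi_error(np.array([1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            chi_error(np.array([2.0, 2.0]), np.array([1.0, 3.0]))
        with pytest.raises(ValueError):
            chi_error(np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0]))


class TestLinearFit:
    def test_exact_linear_data(self):
        m = linear_fit(np.array([[1.0], [2.0], [3.0]]), np.array([2.0, 4.0, 6.0]))
        assert m.weights[0] == pytest.approx(2.0)
        assert m.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_output(self):
        m = linear_fit(np.array([[1.0], [2.0], [3.0]]), np.array([5.0, 5.0, 5.0]))
        assert m.weights[0] == pytest.approx(0.0, abs=1e-12)
        assert m.intercept == pytest.approx(5.0)

    def test_matches_gradient_descent_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        m = linear_fit(X, y)
        A = np.column_stack([np.ones(40), X])

        def obj(w):
            return np.sum((A @ w - y) ** 2) / 40

        res = minimize(obj, np.zeros(3), jac=lambda w: (2 / 40) * A.T @ (A @ w - y),
                       method="CG", tol=1e-14)
        np.testing.assert_allclose(
            res.x, np.concatenate([[m.intercept], m.weights]), atol=1e-6
        )

    def test_singular_design_raises(self):
        X = np.ones((5, 2))  # duplicated constant columns
        with pytest.raises(np.linalg.LinAlgError, match="regularized"):
            linear_fit(X, np.arange(5.0))

    def test_underdetermined_raises(self):
        with pytest.raises(ValueError):
            linear_fit(np.ones((2, 3)), np.array([1.0, 2.0]))


class TestKRR:
    def test_single_training_point_scalar_case(self):
        m = krr_fit(np.array([[0.3]]), np.array([2.0]), sigma=1.0, lam=0.5)
        assert m.coef[0] == pytest.approx(2.0 / 1.5)
        assert krr_predict(m, np.array([[0.3]]))[0] == pytest.approx(2.0 / 1.5)

    def test_interpolation_limit_at_zero_regularization(self):
        X = np.linspace(0, 1, 12)[:, None]
        y = np.cos(3 * X).ravel()
        m = krr_fit(X, y, sigma=0.5, lam=0.0)
        pred = krr_predict(m, X)
        assert np.abs(pred - y).max() / np.abs(y).max() < 1e-6

    def test_far_point_predicts_zero(self):
        X = np.linspace(0, 1, 8)[:, None]
        m = krr_fit(X, np.ones(8), sigma=0.2, lam=1e-6)
        assert abs(krr_predict(m, np.array([[50.0]]))[0]) < 1e-8

    def test_training_point_recovered_at_zero_regularization(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(size=(10, 2)) * 4
        y = rng.normal(size=10)
        m = krr_fit(X, y, sigma=0.4, lam=0.0)
        assert krr_predict(m, X[3:4])[0] == pytest.approx(y[3], rel=1e-6)

    def test_infinite_width_gives_constant_predictions(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 1))
        y = rng.normal(size=30)
        m = krr_fit(X, y, sigma=1e6, lam=1e-3)
        pred = krr_predict(m, rng.normal(size=(50, 1)))
        assert pred.std() < 1e-6

    def test_invalid_hyperparameters_rejected(self):
        X, y = np.ones((3, 1)), np.ones(3)
        with pytest.raises(ValueError):
            krr_fit(X, y, sigma=0.0, lam=0.1)
        with pytest.raises(ValueError):
            krr_fit(X, y, sigma=1.0, lam=-0.1)

    def test_duplicate_points_at_zero_regularization_raise(self):
        X = np.array([[1.0], [1.0], [2.0]])
        with pytest.raises(np.linalg.LinAlgError):
            krr_fit(X, np.array([1.0, 2.0, 3.0]), sigma=1.0, lam=0.0)

    def test_dimension_mismatch_rejected(self):
        m = krr_fit(np.ones((4, 2)), np.ones(4), sigma=1.0, lam=0.1)
        with pytest.raises(ValueError):
            krr_predict(m, np.ones((3, 3)))

    def test_closed_form_matches_objective_minimizer(self, oracle_gap):
        """Spot check of the optimizer-oracle equivalence (the acceptance
        suite runs the full 20-instance sweep)."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = int(rng.integers(5, 30))
            X = rng.normal(size=(n, int(rng.integers(1, 4))))
            y = rng.normal(size=n)
            gap = oracle_gap(X, y, float(rng.uniform(0.3, 1.0)),
                             float(10 ** rng.uniform(-2, 0)))
            assert gap < 1e-6


class TestTuning:
    def test_noiseless_monotone_selects_weak_regularization(self):
        X = np.linspace(0, 1, 160)[:, None]
        y = (X**3).ravel()
        cv = tune_hyperparameters(X, y, seed=0)
        assert cv.lam <= cv.lam_grid[2]

    def test_pure_noise_cannot_beat_trivial(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(160, 1))
        y = rng.normal(size=160)
        cv = tune_hyperparameters(X, y, seed=1)
        assert cv.refined_errors.min() == pytest.approx(1.0, abs=0.2)

    def test_determinism(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(60, 1)), rng.normal(size=60)
        a = tune_hyperparameters(X, y, seed=3)
        b = tune_hyperparameters(X, y, seed=3)
        assert (a.lam, a.sigma) == (b.lam, b.sigma)

    def test_selected_pair_minimizes_refined_grid(self):
        rng = np.random.default_rng(4)
        X = np.linspace(0, 2, 80)[:, None]
        y = np.sin(X).ravel() + 0.1 * rng.normal(size=80)
        cv = tune_hyperparameters(X, y, seed=4)
        i, j = np.unravel_index(np.argmin(cv.refined_errors),
                                cv.refined_errors.shape)
        assert cv.lam == cv.refined_lam_grid[i]
        assert cv.sigma == cv.refined_sigma_grid[j]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            tune_hyperparameters(np.ones((6, 1)), np.arange(6.0))


def _toy_dataset(seed=0, n=240, nt=240):
    """y depends on x1 below the midpoint and on x5 above it, so the two
    features are complementary."""
    rng = np.random.default_rng(seed)
    y = rng.uniform(0, 2, size=n + nt)
    noise = lambda: rng.normal(scale=0.05, size=n + nt)
    x1 = np.where(y < 1, y, 1.0) + noise()
    x5 = np.where(y >= 1, y, 1.0) + noise()
    table = pd.DataFrame(
        {
            "x1": x1, "x2": rng.normal(size=n + nt), "x3": rng.normal(size=n + nt),
            "x4": rng.normal(size=n + nt), "x5": x5, "y": y,
            "z1": y, "z2": 0.0, "t0": 0.0,
            "role": ["train"] * n + ["test"] * nt,
        }
    )
    return RegressionDataset(table=table, output_axis="downwind", memory=1,
                             dt=1.0, cone_R=2.0, seed=seed)


class TestEvaluateFeatureSets:
    def test_complementary_pair_beats_both_singles(self):
        ds = _toy_dataset()
        reports = evaluate_feature_sets(
            ds, [("x1",), ("x5",), ("x1", "x5")], seed=0
        )
        pair = reports[("x1", "x5")]
        assert pair.chi < min(reports[("x1",)].chi, reports[("x5",)].chi)
        assert pair.improvement is not None and pair.improvement > 0

    def test_duplicated_feature_pair_matches_single(self):
        ds = _toy_dataset(seed=1)
        reports = evaluate_feature_sets(ds, [("x1",), ("x1", "x1")], seed=1)
        assert reports[("x1", "x1")].chi == pytest.approx(
            reports[("x1",)].chi, abs=0.1
        )

    def test_noiseless_single_feature_is_accurate(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(0.2, 2, size=400)
        X = (y**2)[:, None]
        rep = fit_evaluate(X[:200], y[:200], X[200:], y[200:], seed=2)
        assert rep.chi < 0.05

    def test_rejects_unsupported_subset_size(self):
        ds = _toy_dataset(seed=3)
        with pytest.raises(ValueError):
            evaluate_feature_sets(ds, [("x1", "x2", "x3")], seed=3)

    def test_report_percentiles_consistent(self):
        ds = _toy_dataset(seed=4)
        rep = evaluate_feature_sets(ds, [("x1",)], seed=4)[("x1",)]
        assert rep.chi == pytest.approx(rep.per_point.mean())
        assert rep.median <= rep.p95
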