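import math

import numpy as np
import pytest

from metsig.enet_model import (
    ElasticNetConfig,
    ModelFit,
    PenaltyPath,
    aic_prime,
    aicc_prime,
    fit_null_model,
    fit_and_select,
    fit_penalty_path,
    predict_probabilities,
    select_by_criterion,
)
from metsig.preprocessing_io import InputValidationError

from conftest import make_matrix, make_outcome


def _fit(lambda_, loglik, null_loglik, k, n=50):
    coef = np.zeros(5)
    coef[:k] = 1.0
    return ModelFit(
        intercept=0.0,
        coefficients=coef,
        gene_ids=tuple(f"g{j}" for j in range(5)),
        lambda_=lambda_,
        n=n,
        loglik=loglik,
        null_loglik=null_loglik,
    )


class TestAicPrime:
    @pytest.mark.parametrize(
        "loglik, null, k, expected",
        [(-50.0, -50.0, 0, 0.0), (-40.0, -50.0, 10, 0.0), (-30.0, -50.0, 5, 30.0)],
    )
    def test_hand_values(self, loglik, null, k, expected):
        assert aic_prime(loglik, null, k) == pytest.approx(expected, abs=1e-12)

    def test_negative_k_rejected(self):
        with pytest.raises(InputValidationError):
            aic_prime(-10.0, -20.0, -1)

    def test_model_must_nest_null(self):
        with pytest.raises(InputValidationError):
            aic_prime(-21.0, -20.0, 1)

    def test_aicc_undefined_at_saturation(self):
        assert aicc_prime(-10.0, -20.0, 49, 50) == -math.inf
        # below saturation it equals aic' minus the extra small-sample penalty
        assert aicc_prime(-10.0, -20.0, 5, 50) == pytest.approx(
            20.0 - 10.0 - 2 * 5 * 6 / 44
        )


class TestNullModel:
    def test_quarter_prevalence_intercept(self):
        y = make_outcome([1] * 22 + [0] * 66)
        fit = fit_null_model(y)
        assert fit.intercept == pytest.approx(math.log(0.25 / 0.75), abs=1e-12)
        assert fit.k == 0
        assert fit.aic_prime == 0.0

    def test_balanced_two_samples_give_zero_intercept(self):
        fit = fit_null_model(make_outcome([0, 1]))
        assert fit.intercept == 0.0

    def test_bernoulli_loglik_closed_form(self):
        y = make_outcome([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        fit = fit_null_model(y)
        assert fit.loglik == pytest.approx(3 * math.log(0.3) + 7 * math.log(0.7))

    def test_single_class_rejected(self):
        with pytest.raises(InputValidationError):
            fit_null_model(make_outcome([1, 1, 1]))


@pytest.fixture(scope="module")
def fitted(signal_dataset):
    ds = signal_dataset
    return ds, fit_penalty_path(ds.X, ds.y)


class TestPenaltyPath:

    def test_lambda_max_fit_is_null(self, fitted):
        _, path = fitted
        first = path.fits[0]
        assert first.k == 0
        assert first.aic_prime == 0.0
        assert np.all(np.diff(path.lambdas) < 0)

    def test_lambda_max_predicts_prevalence(self, fitted):
        ds, path = fitted
        p = predict_probabilities(path.fits[0], ds.X)
        np.testing.assert_allclose(p, ds.y.values.mean(), atol=1e-6)

    def test_loglik_never_below_null(self, fitted):
        _, path = fitted
        for fit in path.fits:
            assert fit.loglik >= fit.null_loglik - 1e-8

    def test_selected_set_recovers_true_support(self, fitted):
        ds, path = fitted
        fit, selected = select_by_criterion(path)
        assert fit.k > 0
        assert len(set(selected.gene_ids) & ds.true_support_ids) >= 4

    def test_duplicated_columns_share_coefficients(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((80, 4))
        X = make_matrix(np.column_stack([base, base[:, 0]]))
        eta = 1.5 * base[:, 0] - base[:, 1]
        y = make_outcome(rng.binomial(1, 1 / (1 + np.exp(-eta))))
        # the only curvature along the duplicated-column direction is the
        # ridge term lambda*(1-alpha), so the grid keeps lambda_min large
        # enough for coordinate descent to close the symmetry gap
        cfg = ElasticNetConfig(tol=1e-20, max_iter=200_000,
                               lambda_min_ratio=0.05, n_lambda=40)
        path = fit_penalty_path(X, y, cfg)
        for fit in path.fits:
            # strict convexity of the ridge component forces symmetry
            assert fit.coefficients[0] == pytest.approx(
                fit.coefficients[4], abs=1e-6
            )

    def test_column_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((100, 8))
        eta = X[:, 0] - 0.8 * X[:, 3]
        yv = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        y = make_outcome(yv)
        c = 7.5
        Xs = X.copy()
        Xs[:, 0] *= c
        fit_a, _ = fit_and_select(make_matrix(X), y)
        fit_b, _ = fit_and_select(make_matrix(Xs), y)
        assert fit_b.coefficients[0] == pytest.approx(
            fit_a.coefficients[0] / c, abs=1e-6
        )
        pa = predict_probabilities(fit_a, make_matrix(X))
        pb = predict_probabilities(fit_b, make_matrix(Xs))
        np.testing.assert_allclose(pa, pb, atol=1e-6)

    def test_matches_saga_reference_solver(self):
        """Independent-solver oracle: coefficients agree with scikit-learn's
        saga elastic-net on the standardized problem."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(5)
        n, p = 60, 10
        X = rng.standard_normal((n, p))
        eta = 1.2 * X[:, 0] - 0.8 * X[:, 1]
        yv = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        path = fit_penalty_path(
            make_matrix(X), make_outcome(yv), ElasticNetConfig(tol=1e-12)
        )
        mean, sd = X.mean(0), X.std(0)
        Xstd = (X - mean) / sd
        for li in (25, 60, 95):
            lam = path.lambdas[li]
            ref = LogisticRegression(
                l1_ratio=0.5, C=1.0 / (n * lam), solver="saga",
                max_iter=200_000, tol=1e-10,
            ).fit(Xstd, yv)
            ours_std = path.fits[li].coefficients * sd
            np.testing.assert_allclose(ours_std, ref.coef_[0], atol=2e-4)

    def test_too_few_samples_rejected(self):
        X = make_matrix(np.zeros((3, 2)))
        with pytest.raises(InputValidationError):
            fit_penalty_path(X, make_outcome([0, 1, 0]))


class TestSelection:
    def test_all_nonpositive_criterion_selects_null(self):
        null = _fit(1.0, -50.0, -50.0, 0)
        worse = _fit(0.5, -49.5, -50.0, 3)  # aic' = 1 - 6 = -5
        path = PenaltyPath(np.array([1.0, 0.5]), (null, worse), 0)
        fit, selected = select_by_criterion(path)
        assert fit.k == 0
        assert len(selected) == 0

    def test_ties_break_toward_larger_lambda(self):
        a = _fit(0.5, -49.0, -50.0, 1)  # aic' = 0
        b = _fit(0.1, -48.0, -50.0, 2)  # aic' = 0
        path = PenaltyPath(np.array([0.5, 0.1]), (a, b), 0)
        fit, _ = select_by_criterion(path)
        assert fit.lambda_ == 0.5

    def test_agrees_with_brute_force_argmax(self, signal_dataset):
        ds = signal_dataset
        path = fit_penalty_path(ds.X, ds.y)
        brute = int(np.argmax(
            [2 * (f.loglik - f.null_loglik) - 2 * f.k for f in path.fits]
        ))
        assert path.selected_index == brute


class TestPredict:
    def test_intercept_only_closed_forms(self):
        X = make_matrix(np.zeros((3, 2)))
        for b0, expected in [(0.0, 0.5), (math.log(3), 0.75)]:
            fit = _fit(1.0, -1.0, -1.0, 0)
            fit = ModelFit(b0, np.zeros(2), X.gene_ids, 1.0, 3, -1.0, -1.0)
            np.testing.assert_allclose(predict_probabilities(fit, X), expected)

    def test_single_slope_hand_value(self):
        X = make_matrix([[2.0]])
        fit = ModelFit(0.0, np.array([1.0]), X.gene_ids, 1.0, 1, -1.0, -1.0)
        assert predict_probabilities(fit, X)[0] == pytest.approx(
            1 / (1 + math.exp(-2)), abs=1e-12
        )

    def test_gene_mismatch_rejected(self):
        X = make_matrix(np.zeros((2, 2)))
        fit = ModelFit(0.0, np.zeros(2), ("other1", "other2"), 1.0, 2, -1.0, -1.0)
        with pytest.raises(InputValidationError):
            predict_probabilities(fit, X)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 1.5},
            {"lambda_min_ratio": 0.0},
            {"n_lambda": 1},
            {"criterion": "bic"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InputValidationError):
            ElasticNetConfig(**kwargs)
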