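"""Penalized logistic regression: likelihood oracles, shrinkage, CV contract."""

import numpy as np
import pytest
from scipy.special import expit, logit

from itakit.penalized import (
    PenalizedLogisticRegression,
    cross_validate_lambda,
    fit_penalized_logistic,
    lambda_grid,
    logistic_loglik,
)


def naive_loglik(X, y, theta, intercept=0.0):
    """Per-row Bernoulli probability product, evaluated the slow direct way.

    Uses extended precision so the oracle itself stays accurate when a row
    probability approaches 1 (log(1-p) cancellation at |eta| ~ 18 costs ~1e-8
    in double precision, far above the 1e-10 agreement this oracle certifies).
    """
    eta = (np.asarray(X, dtype=np.longdouble) @ np.asarray(theta, np.longdouble)
           + np.longdouble(intercept))
    p = 1.0 / (1.0 + np.exp(-eta))
    return float(np.sum(np.where(np.asarray(y) == 1, np.log(p), np.log1p(-p))))


class TestLoglik:
    def test_symmetric_null(self):
        X = np.random.default_rng(0).standard_normal((17, 3))
        y = np.random.default_rng(1).integers(0, 2, 17)
        assert logistic_loglik(X, y, np.zeros(3), 0.0) == pytest.approx(
            17 * np.log(0.5)
        )

    def test_single_row_at_zero_eta(self):
        assert logistic_loglik(np.zeros((1, 2)), [1], np.zeros(2)) == pytest.approx(
            np.log(0.5)
        )

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n, p = int(rng.integers(5, 51)), int(rng.integers(1, 4))
            X = rng.standard_normal((n, p))
            y = rng.integers(0, 2, n)
            theta = rng.normal(0, 1.5, p)
            b = float(rng.normal())
            assert logistic_loglik(X, y, theta, b) == pytest.approx(
                naive_loglik(X, y, theta, b), abs=1e-10
            )

    def test_overflow_safe_at_extreme_eta(self):
        X = np.array([[1.0], [-1.0]])
        val = logistic_loglik(X, [1, 0], np.array([2000.0]))
        assert np.isfinite(val) and val == pytest.approx(0.0, abs=1e-8)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            logistic_loglik(np.ones((2, 1)), [0, 1], [np.inf])


class TestFit:
    def test_unpenalized_matches_newton_mle(self, logistic_instance):
        import statsmodels.api as sm

        X, y = logistic_instance
        mle = sm.Logit(y, sm.add_constant(X)).fit(method="newton", disp=0)
        model = fit_penalized_logistic(X, y, "l1", 0.0)
        ours = np.r_[model.intercept_, model.coef_]
        assert np.abs(ours - mle.params).max() < 1e-4

    def test_total_shrinkage_limit(self, logistic_instance):
        X, y = logistic_instance
        model = fit_penalized_logistic(X, y, "l1", 1e6 * len(y))
        assert len(model.support_) == 0
        assert model.intercept_ == pytest.approx(logit(y.mean()), abs=1e-6)

    def test_ridge_norm_nonincreasing_in_lam(self, logistic_instance):
        X, y = logistic_instance
        lams = np.logspace(-2, 3, 10)
        norms = [
            np.linalg.norm(fit_penalized_logistic(X, y, "l2", lam).coef_std_)
            for lam in lams
        ]
        assert all(b <= a + 1e-9 for a, b in zip(norms, norms[1:]))

    def test_l1_sparsity_nonincreasing_in_lam(self, logistic_instance):
        X, y = logistic_instance
        lams = np.logspace(-1, 2.5, 8)
        nnz = [
            len(fit_penalized_logistic(X, y, "l1", lam).support_) for lam in lams
        ]
        assert all(b <= a for a, b in zip(nnz, nnz[1:]))

    def test_objective_matches_direct_evaluation(self, logistic_instance):
        X, y = logistic_instance
        for penalty, lam in (("l1", 3.0), ("l2", 2.0)):
            model = fit_penalized_logistic(X, y, penalty, lam)
            Xs = (X - model.scaler_mean_) / model.scaler_scale_
            pen = (lam * np.abs(model.coef_std_).sum() if penalty == "l1"
                   else lam * np.square(model.coef_std_).sum())
            direct = naive_loglik(Xs, y, model.coef_std_, model.intercept_std_) - pen
            assert model.objective_value_ == pytest.approx(direct, abs=1e-8)

    def test_objective_beats_null_model(self, logistic_instance):
        X, y = logistic_instance
        model = fit_penalized_logistic(X, y, "l1", 2.0)
        Xs = (X - model.scaler_mean_) / model.scaler_scale_
        at_null = logistic_loglik(Xs, y, np.zeros(X.shape[1]), logit(y.mean()))
        assert model.objective_value_ >= at_null

    def test_raw_scale_backtransform_consistent(self, logistic_instance):
        X, y = logistic_instance
        model = fit_penalized_logistic(X, y, "l2", 1.0)
        Xs = (X - model.scaler_mean_) / model.scaler_scale_
        eta_std = Xs @ model.coef_std_ + model.intercept_std_
        assert np.allclose(model.decision_function(X), eta_std, atol=1e-10)

    def test_input_validation(self, logistic_instance):
        X, y = logistic_instance
        with pytest.raises(ValueError):
            fit_penalized_logistic(X, np.ones_like(y), "l1", 1.0)  # one class
        with pytest.raises(ValueError):
            fit_penalized_logistic(X, y, "l1", -1.0)
        with pytest.raises(ValueError):
            fit_penalized_logistic(X, y, "elastic", 1.0)
        with pytest.raises(ValueError):
            Xbad = X.copy()
            Xbad[0, 0] = np.nan
            fit_penalized_logistic(Xbad, y, "l1", 1.0)


class TestPredict:
    def test_null_model_predicts_half(self):
        m = PenalizedLogisticRegression("l2", 1.0)
        m.fit(np.random.default_rng(0).standard_normal((50, 2)),
              np.r_[np.ones(25, int), np.zeros(25, int)])
        m.coef_ = np.zeros(2)
        m.intercept_ = 0.0
        assert np.allclose(m.predict_proba(np.ones((3, 2)))[:, 1], 0.5)

    def test_probabilities_stay_in_open_interval(self, logistic_instance):
        X, y = logistic_instance
        m = fit_penalized_logistic(X, y, "l2", 0.1)
        p = m.predict_proba(X * 1e6)[:, 1]
        assert np.all((p > 0) & (p < 1))

    def test_hand_computed_three_rows(self, logistic_instance):
        X, y = logistic_instance
        m = fit_penalized_logistic(X, y, "l2", 1.0)
        rows = X[:3]
        expected = expit(rows @ m.coef_ + m.intercept_)
        assert np.allclose(m.predict_proba(rows)[:, 1], expected, atol=1e-12)

    def test_feature_name_alignment_error(self, logistic_instance):
        import pandas as pd

        X, y = logistic_instance
        df = pd.DataFrame(X, columns=[f"v{i}" for i in range(X.shape[1])])
        m = PenalizedLogisticRegression("l2", 1.0).fit(df, y)
        wrong = df.rename(columns={"v0": "other"})
        with pytest.raises(ValueError, match="features"):
            m.predict_proba(wrong)


class TestCrossValidation:
    def test_single_candidate_grid(self, logistic_instance):
        X, y = logistic_instance
        cv = cross_validate_lambda(X, y, "l1", grid=[2.5], k=3, seed=0)
        assert cv.lambda_star == 2.5

    def test_five_fold_sizes_exact(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((1000, 4))
        y = (rng.random(1000) < 0.3).astype(int)
        cv = cross_validate_lambda(X, y, "l2", grid=[1.0, 0.1], k=5, seed=0)
        sizes = np.bincount(cv.fold_assignments)[1:]
        assert list(sizes) == [200] * 5

    def test_lambda_star_attains_grid_maximum(self, logistic_instance):
        X, y = logistic_instance
        cv = cross_validate_lambda(X, y, "l1", k=5, seed=1, n_lambda=12,
                                   ratio=1e-2, patience=None)
        star = np.argmin(np.abs(cv.grid - cv.lambda_star))
        assert cv.heldout_loglik[star] == cv.heldout_loglik.max()

    def test_cv_l1_beats_unpenalized_on_sparse_truth(self):
        rng = np.random.default_rng(21)
        n, p_signal, p_noise = 3000, 5, 60
        X = rng.standard_normal((n, p_signal + p_noise))
        beta = np.r_[rng.uniform(0.8, 1.2, p_signal), np.zeros(p_noise)]
        make_y = lambda rng_: rng_.binomial(1, expit(X @ beta - 2.0))
        y = make_y(np.random.default_rng(22))
        y_rep = make_y(np.random.default_rng(23))  # independent replicate
        cv = cross_validate_lambda(X, y, "l1", k=5, seed=2, n_lambda=12, ratio=1e-3)
        tuned = fit_penalized_logistic(X, y, "l1", cv.lambda_star)
        loose = fit_penalized_logistic(X, y, "l1", 1e-4)  # essentially the MLE
        ll_tuned = logistic_loglik(X, y_rep, tuned.coef_, tuned.intercept_)
        ll_loose = logistic_loglik(X, y_rep, loose.coef_, loose.intercept_)
        assert ll_tuned >= ll_loose

    def test_stratification_failure_reported(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((60, 3))
        y = np.zeros(60, int)
        y[:3] = 1  # 3 positives cannot stratify into 5 folds
        with pytest.raises(ValueError, match="stratification|least populated"):
            cross_validate_lambda(X, y, "l1", grid=[1.0], k=5, seed=0)

    def test_lambda_grid_spans_requested_ratio(self, logistic_instance):
        X, y = logistic_instance
        grid = lambda_grid(X, y, num=50, ratio=1e-4)
        assert len(grid) == 50
        assert grid[0] / grid[-1] == pytest.approx(1e4)
        # lam_max zeroes the lasso, one notch below does not
        assert len(fit_penalized_logistic(X, y, "l1", grid[0] * 1.001).support_) == 0
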