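import numpy as np
import pytest
from scipy import integrate, optimize, stats

from earlychange.grids import build_loading_matrix, early_change_grid
from earlychange.mixture import (
    PiecewiseGrowthMixture,
    classify_subjects,
    em_fit,
    information_criteria,
    marginal_loglik_subject,
    relative_entropy,
)

LAM = build_loading_matrix(early_change_grid())


class TestMarginalLoglik:
    def test_single_standard_normal_observation(self):
        # one observed coordinate, psi=0, theta=1, mean == observation
        mu = np.array([5.0, 0.0, 0.0])
        y = np.array([5.0, np.nan, np.nan, np.nan])
        mask = ~np.isnan(y)
        ll = marginal_loglik_subject(np.nan_to_num(y), mask, mu, 0.0, 1.0, LAM)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_fully_observed_matches_dense_mvn_oracle(self):
        mu = np.array([10.0, -1.0, -2.0])
        psi, theta = 2.0, 1.5
        mean = LAM.values @ mu
        cov = psi * np.ones((4, 4)) + theta * np.eye(4)
        y = np.array([11.0, 9.5, 8.0, 7.0])
        oracle = stats.multivariate_normal(mean, cov).logpdf(y)
        ll = marginal_loglik_subject(y, np.ones(4, bool), mu, psi, theta, LAM)
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_one_missing_matches_quadrature_oracle(self):
        # integrate the full 3-occasion density over the missing coordinate
        lam3 = LAM.values[:3]
        mu = np.array([9.0, -0.8, -1.5])
        psi, theta = 1.3, 0.9
        mean = lam3 @ mu
        cov = psi * np.ones((3, 3)) + theta * np.eye(3)
        full = stats.multivariate_normal(mean, cov)
        y_obs = np.array([9.6, 7.9])

        def dens(z):
            return full.pdf(np.array([y_obs[0], z, y_obs[1]]))

        integral, err = integrate.quad(dens, mean[1] - 12, mean[1] + 12, limit=200)
        ll = marginal_loglik_subject(
            np.array([9.6, 0.0, 7.9]),
            np.array([True, False, True]),
            mu,
            psi,
            theta,
            lam3,
        )
        assert ll == pytest.approx(np.log(integral), abs=1e-6)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="observed"):
            marginal_loglik_subject(
                np.zeros(4), np.zeros(4, bool), np.zeros(3), 1.0, 1.0, LAM
            )

    def test_invalid_variances_rejected(self):
        y, m = np.ones(4), np.ones(4, bool)
        with pytest.raises(ValueError):
            marginal_loglik_subject(y, m, np.zeros(3), 1.0, 0.0, LAM)
        with pytest.raises(ValueError):
            marginal_loglik_subject(y, m, np.zeros(3), -0.5, 1.0, LAM)


class TestInformationCriteria:
    def test_formula_values(self):
        bic, sabic, aic = information_criteria(-100.0, 5, 50)
        assert bic == pytest.approx(200 + 5 * np.log(50), abs=1e-9)
        assert round(bic, 3) == 219.560
        assert aic == pytest.approx(210.0)
        assert sabic == pytest.approx(200 + 5 * np.log(52 / 24), abs=1e-9)

    def test_zero_limit(self):
        assert information_criteria(0.0, 0, 10) == (0.0, 0.0, 0.0)

    def test_parameter_count_three_classes(self, early_scores):
        # (K-1) mixing + 3K means + psi + theta = 13 for K=3
        fit = em_fit(early_scores[:80], n_classes=3, loading_matrix=LAM, n_starts=4, seed=0)
        assert fit.n_parameters_ == 13
        assert fit.bic_ == pytest.approx(
            -2 * fit.log_likelihood_ + 13 * np.log(fit.n_subjects_)
        )


class TestRelativeEntropy:
    def test_one_hot_and_uniform(self):
        onehot = np.eye(3)[np.array([0, 1, 2, 0])]
        assert relative_entropy(onehot) == pytest.approx(1.0)
        uniform = np.full((5, 3), 1 / 3)
        assert relative_entropy(uniform) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_subject_value(self):
        post = np.array([[0.9, 0.1], [0.6, 0.4]])
        assert relative_entropy(post) == pytest.approx(0.2800, abs=5e-4)

    def test_single_class_flagged_nan(self):
        assert np.isnan(relative_entropy(np.ones((4, 1))))


class TestClassification:
    def test_modal_and_tie_break(self):
        post = np.array([[0.7, 0.2, 0.1], [0.5, 0.5, 0.0]])
        np.testing.assert_array_equal(classify_subjects(post), [0, 0])


class TestEMFit:
    def test_single_class_matches_direct_maximizer(self, rng):
        # K=1, complete data: EM against a generic numerical optimizer of
        # the identical marginal likelihood
        n = 60
        b = rng.normal(0, 1.2, n)
        mu_true = np.array([10.0, -1.0, -2.0])
        X = (LAM.values @ mu_true)[None, :] + b[:, None] + rng.normal(0, 1.0, (n, 4))
        fit = PiecewiseGrowthMixture(
            n_classes=1, loading_matrix=LAM, tol=1e-12, max_iter=3000, random_state=0
        ).fit(X)

        mask = np.ones(4, bool)

        def negll(params):
            mu, lpsi, lth = params[:3], params[3], params[4]
            return -sum(
                marginal_loglik_subject(X[i], mask, mu, np.exp(lpsi), np.exp(lth), LAM)
                for i in range(n)
            )

        res = optimize.minimize(
            negll,
            np.array([9.0, 0.0, 0.0, 0.0, 0.0]),
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 20000, "maxfev": 20000},
        )
        assert fit.log_likelihood_ == pytest.approx(-res.fun, abs=1e-4)
        np.testing.assert_allclose(fit.means_[0], res.x[:3], atol=1e-3)
        assert fit.intercept_var_ == pytest.approx(np.exp(res.x[3]), abs=1e-3)
        assert fit.residual_var_ == pytest.approx(np.exp(res.x[4]), abs=1e-3)

    def test_two_class_recovery(self, rng):
        # intercept means 6 and 14, psi = theta = 1, n = 400
        n = 400
        cls = rng.random(n) < 0.5
        mu = np.where(cls[:, None], [14.0, 0.0, -1.0], [6.0, 0.0, 1.0])
        b = rng.normal(0, 1.0, n)
        X = mu @ LAM.values.T + b[:, None] + rng.normal(0, 1.0, (n, 4))
        fit = em_fit(X, n_classes=2, loading_matrix=LAM, seed=3)
        # classes ordered by descending intercept
        assert abs(fit.weights_[0] - cls.mean()) < 0.05
        assert abs(fit.means_[0, 0] - 14.0) < 0.5
        assert abs(fit.means_[1, 0] - 6.0) < 0.5

    def test_posterior_normalization_and_weights(self, early_scores):
        fit = em_fit(early_scores, n_classes=3, loading_matrix=LAM, n_starts=6, seed=1)
        np.testing.assert_allclose(fit.posterior_.sum(axis=1), 1.0, atol=1e-10)
        assert fit.weights_.sum() == pytest.approx(1.0, abs=1e-12)
        assert (fit.weights_ >= 0).all()
        assert 0.0 <= fit.entropy_ <= 1.0

    def test_em_monotone_loglik(self, early_scores):
        fit = em_fit(early_scores, n_classes=3, loading_matrix=LAM, n_starts=4, seed=5)
        diffs = np.diff(fit.loglik_trace_)
        assert (diffs > -1e-8).all()

    def test_label_permutation_leaves_likelihood_unchanged(self, early_scores):
        fit = em_fit(early_scores[:150], n_classes=3, loading_matrix=LAM, n_starts=4, seed=2)
        ll_orig = fit.score(early_scores[:150])
        perm = np.array([2, 0, 1])
        fit.weights_ = fit.weights_[perm]
        fit.means_ = fit.means_[perm]
        assert fit.score(early_scores[:150]) == pytest.approx(ll_orig, abs=1e-8)

    def test_fiml_equals_complete_likelihood_on_full_mask(self, rng):
        # complete data: the per-subject marginal equals the dense MVN
        n = 30
        X = (np.array([9.0, -0.5, -1.0]) @ LAM.values.T)[None, :] + rng.normal(0, 1.5, (n, 4))
        fit = PiecewiseGrowthMixture(n_classes=1, loading_matrix=LAM, random_state=0).fit(X)
        mean = fit.means_[0] @ LAM.values.T
        cov = fit.intercept_var_ * np.ones((4, 4)) + fit.residual_var_ * np.eye(4)
        oracle = stats.multivariate_normal(mean, cov).logpdf(X).sum()
        assert fit.log_likelihood_ == pytest.approx(oracle, abs=1e-10)

    def test_deterministic_given_seed(self, early_scores):
        a = em_fit(early_scores, n_classes=3, loading_matrix=LAM, n_starts=5, seed=42)
        b = em_fit(early_scores, n_classes=3, loading_matrix=LAM, n_starts=5, seed=42)
        assert a.fit_summary().to_dict() == b.fit_summary().to_dict()
        np.testing.assert_array_equal(a.posterior_, b.posterior_)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            em_fit(np.ones((5, 4)), n_classes=2, loading_matrix=LAM)
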