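"""GP surrogate: kernel, fitting, prediction, marginal likelihood."""

import numpy as np
import pytest
from scipy import stats

from pipeopt.gp import (
    JITTER,
    GPHyperparams,
    GPSurrogate,
    kernel,
    kernel_matrix,
    log_marginal_likelihood,
    optimise_hyperparams,
)

THETA = GPHyperparams(sigma_n=0.2, sigma_f=1.5, sigma_l=0.7)


def gp_oracle(X, y, theta, x_star, center=False):
    """Naive direct-inverse posterior, independent of the Cholesky path."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    mu0 = y.mean() if (center and y.size) else 0.0
    K = kernel_matrix(X, X, theta) + (theta.sigma_n + JITTER) * np.eye(len(y))
    K_inv = np.linalg.inv(K)
    ks = kernel_matrix(np.atleast_2d(x_star), X, theta).ravel()
    mean = ks @ K_inv @ (y - mu0) + mu0
    var = theta.sigma_f + theta.sigma_n - ks @ K_inv @ ks
    return float(mean), float(var)


class TestKernel:
    def test_zero_distance_gives_signal_variance(self):
        u = np.array([0.2, 0.7])
        assert kernel(u, u, THETA) == pytest.approx(THETA.sigma_f)

    def test_distance_sq_two_sigma_l_gives_sigma_f_over_e(self):
        d = np.sqrt(2 * THETA.sigma_l)
        assert kernel(np.array([0.0]), np.array([d]), THETA) == pytest.approx(
            THETA.sigma_f * np.exp(-1), rel=1e-12
        )

    def test_monotone_decay_to_zero(self):
        dists = np.linspace(0, 50, 200)
        vals = [kernel(np.array([0.0]), np.array([d]), THETA) for d in dists]
        assert np.all(np.diff(vals) <= 0)
        assert vals[-1] < 1e-10
        # strictly positive wherever exp does not underflow
        assert all(v > 0 for d, v in zip(dists, vals) if d < 10)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            kernel(np.array([0.0]), np.array([0.0, 1.0]), THETA)

    def test_kernel_matrix_positive_semidefinite(self, rng):
        for _ in range(20):
            X = rng.uniform(0, 1, (rng.integers(2, 12), rng.integers(1, 5)))
            K = kernel_matrix(X, X, THETA)
            assert np.allclose(K, K.T)
            assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestFitPredict:
    def test_prior_only_state_with_no_data(self):
        gp = GPSurrogate(**THETA._asdict(), optimizer=None).fit(
            np.empty((0, 2)), np.empty(0)
        )
        mean, var = gp.predict(np.array([[0.3, 0.4]]), return_var=True)
        assert mean[0] == pytest.approx(0.0)
        assert var[0] == pytest.approx(THETA.sigma_f + THETA.sigma_n)

    def test_refit_is_deterministic(self, rng):
        X = rng.uniform(0, 1, (6, 2))
        y = rng.uniform(1, 10, 6)
        xs = rng.uniform(0, 1, (4, 2))
        p1 = GPSurrogate(optimizer=None).fit(X, y).predict(xs, return_var=True)
        p2 = GPSurrogate(optimizer=None).fit(X, y).predict(xs, return_var=True)
        assert np.array_equal(p1[0], p2[0]) and np.array_equal(p1[1], p2[1])

    def test_duplicate_training_points_factorise_with_noise(self):
        X = np.array([[0.5], [0.5]])
        gp = GPSurrogate(sigma_n=0.1, optimizer=None).fit(X, np.array([4.0, 6.0]))
        mean = gp.predict(np.array([[0.5]]))
        assert np.isfinite(mean).all()

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            GPSurrogate(optimizer=None).fit(np.array([[0.1]]), np.array([np.nan]))

    def test_single_point_posterior_mean_closed_form(self):
        # predictive mean at the training point: y * sigma_f / (sigma_f + sigma_n)
        gp = GPSurrogate(**THETA._asdict(), center_y=False, optimizer=None)
        gp.fit(np.array([[0.4, 0.9]]), np.array([5.0]))
        mean = gp.predict(np.array([[0.4, 0.9]]))
        expected = 5.0 * THETA.sigma_f / (THETA.sigma_f + THETA.sigma_n)
        assert mean[0] == pytest.approx(expected, abs=1e-6)

    def test_noise_free_limit_interpolates(self):
        gp = GPSurrogate(
            sigma_n=0.0, sigma_f=2.0, sigma_l=0.5, center_y=False, optimizer=None
        ).fit(np.array([[0.2]]), np.array([7.0]))
        mean, var = gp.predict(np.array([[0.2]]), return_var=True)
        assert mean[0] == pytest.approx(7.0, abs=1e-6)
        assert var[0] < 1e-6

    @pytest.mark.parametrize("center", [False, True])
    def test_matches_direct_inverse_oracle(self, center, rng):
        for _ in range(30):
            n, d = rng.integers(1, 6), rng.integers(1, 4)
            X = rng.uniform(0, 1, (n, d))
            y = rng.uniform(1, 10, n)
            xs = rng.uniform(0, 1, d)
            gp = GPSurrogate(**THETA._asdict(), center_y=center, optimizer=None).fit(X, y)
            mean, var = gp.predict(xs[None, :], return_var=True)
            mo, vo = gp_oracle(X, y, THETA, xs, center=center)
            assert mean[0] == pytest.approx(mo, abs=1e-8)
            assert var[0] == pytest.approx(max(vo, 0.0), abs=1e-8)

    def test_predictive_variance_bounded_by_prior(self, rng):
        X = rng.uniform(0, 1, (8, 3))
        y = rng.uniform(1, 10, 8)
        gp = GPSurrogate(**THETA._asdict(), optimizer=None).fit(X, y)
        _, var = gp.predict(X, return_var=True)
        assert np.all(var >= 0)
        assert np.all(var <= THETA.sigma_f + THETA.sigma_n + 1e-9)

    def test_reversion_to_prior_far_from_data(self):
        gp = GPSurrogate(**THETA._asdict(), center_y=False, optimizer=None)
        gp.fit(np.array([[0.0, 0.0]]), np.array([9.0]))
        mean, var = gp.predict(np.array([[50.0, 50.0]]), return_var=True)
        assert abs(mean[0]) < 1e-6
        assert var[0] == pytest.approx(THETA.sigma_f + THETA.sigma_n, abs=1e-6)

    def test_prediction_dimension_mismatch_rejected(self):
        gp = GPSurrogate(optimizer=None).fit(np.array([[0.1, 0.2]]), np.array([5.0]))
        with pytest.raises(ValueError, match="dimension"):
            gp.predict(np.array([[0.1]]))


class TestLogMarginalLikelihood:
    def test_univariate_closed_form(self):
        y = 4.2
        got = log_marginal_likelihood(np.array([[0.5]]), np.array([y]), THETA)
        s2 = THETA.sigma_f + THETA.sigma_n
        expected = -0.5 * (np.log(2 * np.pi * s2) + y**2 / s2)
        assert got == pytest.approx(expected, abs=1e-7)

    def test_invariant_under_training_order_permutation(self, rng):
        X = rng.uniform(0, 1, (5, 2))
        y = rng.uniform(1, 10, 5)
        perm = rng.permutation(5)
        assert log_marginal_likelihood(X, y, THETA) == pytest.approx(
            log_marginal_likelihood(X[perm], y[perm], THETA), abs=1e-9
        )

    def test_matches_multivariate_normal_density(self, rng):
        X = rng.uniform(0, 1, (4, 2))
        y = rng.uniform(1, 10, 4)
        K = kernel_matrix(X, X, THETA) + (THETA.sigma_n + JITTER) * np.eye(4)
        expected = stats.multivariate_normal(np.zeros(4), K).logpdf(y)
        assert log_marginal_likelihood(X, y, THETA) == pytest.approx(expected, abs=1e-8)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="N >= 1"):
            log_marginal_likelihood(np.empty((0, 1)), np.empty(0), THETA)


class TestOptimiseHyperparams:
    def test_never_worsens_the_start_point(self, rng):
        X = rng.uniform(0, 1, (10, 2))
        y = rng.uniform(1, 10, 10)
        theta0 = GPHyperparams(0.5, 2.0, 1.0)
        theta = optimise_hyperparams(X, y, theta0, seed=0)
        assert log_marginal_likelihood(X, y, theta) >= (
            log_marginal_likelihood(X, y, theta0) - 1e-9
        )

    def test_degenerate_bounds_pin_to_start(self, rng):
        X = rng.uniform(0, 1, (5, 1))
        y = rng.uniform(1, 10, 5)
        theta0 = GPHyperparams(0.3, 1.2, 0.8)
        bounds = {
            "sigma_n": (0.3, 0.3),
            "sigma_f": (1.2, 1.2),
            "sigma_l": (0.8, 0.8),
        }
        theta = optimise_hyperparams(X, y, theta0, bounds=bounds, seed=0)
        assert np.allclose(theta, theta0)

    def test_requires_at_least_two_points(self):
        with pytest.raises(ValueError, match="N >= 2"):
            optimise_hyperparams(
                np.array([[0.1]]), np.array([5.0]), GPHyperparams(0.1, 1.0, 1.0)
            )

    def test_length_scale_recovery_from_simulated_gp(self):
        """sigma_l recovered within a factor of 3 in >= 80% of 20 replicates
        of 40 points drawn from a known GP (sigma_l = 0.1)."""
        true = GPHyperparams(sigma_n=0.05, sigma_f=1.0, sigma_l=0.1)
        theta0 = GPHyperparams(0.1, 1.0, 1.0)
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            X = rng.uniform(0, 1, (40, 2))
            K = kernel_matrix(X, X, true) + true.sigma_n * np.eye(40)
            y = rng.multivariate_normal(np.zeros(40), K)
            theta = optimise_hyperparams(X, y, theta0, seed=rep)
            hits += true.sigma_l / 3 <= theta.sigma_l <= true.sigma_l * 3
        assert hits >= 16
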