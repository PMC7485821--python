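"""Gaussian-process regression surrogate for quality scores.

The surrogate maps an encoded pipeline configuration ``x`` in ``[0,1]^d`` to
the quality score ``y`` on the 1-10 scale.  The model is a zero-mean GP with
Gaussian observation noise and the squared-exponential covariance

    k(x, x') = sigma_f * exp(-||x - x'||^2 / (2 * sigma_l))

with hyperparameters theta = {sigma_n, sigma_f, sigma_l}.  Note that
``sigma_l`` divides the squared distance directly, so it plays the role of a
*squared* length-scale, and ``sigma_n`` and ``sigma_f`` are variances.  The
predictive distribution is that of the *observable noisy score* y*, so the
predictive variance includes ``sigma_n``.

Hyperparameters carry no priors; they are set by multi-start bounded
maximisation of the log marginal likelihood in log-space.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Optional, Tuple

import numpy as np
from scipy import linalg, optimize
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "GPHyperparams",
    "DEFAULT_BOUNDS",
    "JITTER",
    "kernel",
    "kernel_matrix",
    "log_marginal_likelihood",
    "optimise_hyperparams",
    "GPSurrogate",
]

#: Unconditional diagonal jitter for numerical stability with duplicate points.
JITTER = 1e-8

#: Default hyperparameter search bounds (variances, not standard deviations).
#: The sigma_l floor corresponds to a length-scale of 0.1 on the unit
#: hypercube; anything shorter degenerates into a white-noise fit on the
#: few dozen observations a run collects, which starves the acquisition
#: step of gradient information.
DEFAULT_BOUNDS: dict = {
    "sigma_n": (1e-6, 4.0),
    "sigma_f": (1e-3, 100.0),
    "sigma_l": (1e-2, 10.0),
}


class GPHyperparams(NamedTuple):
    """theta = {sigma_n, sigma_f, sigma_l}: noise variance, signal variance,
    squared length-scale."""

    sigma_n: float
    sigma_f: float
    sigma_l: float

    def validate(self) -> "GPHyperparams":
        if not self.sigma_f > 0:
            raise ValueError("sigma_f must be > 0")
        if not self.sigma_l > 0:
            raise ValueError("sigma_l must be > 0")
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be >= 0")
        return self


def kernel(u: np.ndarray, v: np.ndarray, theta: GPHyperparams) -> float:
    """Covariance between two encoded points."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    sq = float(np.sum((u - v) ** 2))
    return float(theta.sigma_f * np.exp(-sq / (2.0 * theta.sigma_l)))


def kernel_matrix(U: np.ndarray, V: np.ndarray, theta: GPHyperparams) -> np.ndarray:
    """Cross-covariance matrix between two point sets (rows are points)."""
    U = np.atleast_2d(np.asarray(U, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if U.shape[1] != V.shape[1]:
        raise ValueError(f"dimension mismatch: {U.shape[1]} vs {V.shape[1]}")
    sq = (
        np.sum(U**2, axis=1)[:, None]
        + np.sum(V**2, axis=1)[None, :]
        - 2.0 * U @ V.T
    )
    np.maximum(sq, 0.0, out=sq)
    return theta.sigma_f * np.exp(-sq / (2.0 * theta.sigma_l))


def _factorise(X: np.ndarray, theta: GPHyperparams) -> np.ndarray:
    """Lower Cholesky factor of K + (sigma_n + jitter) I."""
    K = kernel_matrix(X, X, theta)
    K[np.diag_indices_from(K)] += theta.sigma_n + JITTER
    try:
        return linalg.cholesky(K, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise linalg.LinAlgError(
            "covariance factorisation failed; increase sigma_n or the jitter"
        ) from exc


def log_marginal_likelihood(
    X: np.ndarray, y: np.ndarray, theta: GPHyperparams, center: bool = False
) -> float:
    """log N(y | 0, K + sigma_n I), optionally after centring y.

    Requires at least one observation.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n == 0:
        raise ValueError("log marginal likelihood requires N >= 1")
    if not np.all(np.isfinite(y)):
        raise ValueError("scores must be finite")
    if center:
        y = y - y.mean()
    theta.validate()
    L = _factorise(X, theta)
    alpha = linalg.cho_solve((L, True), y)
    return float(
        -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * np.log(2.0 * np.pi)
    )


def optimise_hyperparams(
    X: np.ndarray,
    y: np.ndarray,
    theta0: GPHyperparams,
    bounds: Optional[dict] = None,
    n_restarts: int = 5,
    seed: Optional[int] = None,
    center: bool = False,
) -> GPHyperparams:
    """Multi-start bounded LML maximisation over log(sigma_n, sigma_f, sigma_l).

    The returned theta never has a lower LML than ``theta0`` (the start point
    is always kept as a candidate).  Requires N >= 2 observations.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("hyperparameter optimisation requires N >= 2 (bootstrap incomplete)")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    log_bounds = [
        (np.log(b["sigma_n"][0]), np.log(b["sigma_n"][1])),
        (np.log(b["sigma_f"][0]), np.log(b["sigma_f"][1])),
        (np.log(b["sigma_l"][0]), np.log(b["sigma_l"][1])),
    ]

    def neg_lml(log_theta: np.ndarray) -> float:
        th = GPHyperparams(*np.exp(log_theta))
        try:
            return -log_marginal_likelihood(X, y, th, center=center)
        except linalg.LinAlgError:
            return 1e25

    lows = np.array([b["sigma_n"][0], b["sigma_f"][0], b["sigma_l"][0]])
    highs = np.array([b["sigma_n"][1], b["sigma_f"][1], b["sigma_l"][1]])
    start0 = np.log(np.clip(np.array(theta0, dtype=float), lows, highs))
    rng = np.random.default_rng(seed)
    starts = [start0] + [
        np.array([rng.uniform(lo, hi) for lo, hi in log_bounds])
        for _ in range(n_restarts)
    ]

    best_theta, best_val = theta0, -neg_lml(np.log(np.array(theta0, dtype=float)))
    for s in starts:
        res = optimize.minimize(
            neg_lml, s, method="L-BFGS-B", bounds=log_bounds
        )
        if np.isfinite(res.fun) and -res.fun > best_val + 1e-12:
            best_val = -res.fun
            best_theta = GPHyperparams(*np.exp(res.x))
    return best_theta


class GPSurrogate(RegressorMixin, BaseEstimator):
    """GP-regression surrogate with the squared-exponential kernel.

    Parameters
    ----------
    sigma_n, sigma_f, sigma_l : float
        Initial (or fixed) hyperparameters: noise variance, signal variance,
        squared length-scale.
    center_y : bool, default True
        Subtract the training-score mean before fitting and add it back to
        predictions.  With quality scores on the 1-10 scale a zero-mean prior
        would otherwise bias predictions low far from the data.
    optimizer : {"lbfgs", None}, default "lbfgs"
        If "lbfgs" and N >= 2, hyperparameters are re-estimated on ``fit`` by
        marginal-likelihood maximisation; ``None`` keeps them fixed.
    n_restarts : int
        Number of random restarts in addition to the initial theta.
    bounds : dict or None
        Per-hyperparameter ``(low, high)`` search bounds; defaults to
        :data:`DEFAULT_BOUNDS`.
    random_state : int or None
        Seed for the optimiser restarts.

    Attributes
    ----------
    X_train_ : ndarray of shape (n, d)
    y_train_ : ndarray of shape (n,)
    theta_ : GPHyperparams in force after fitting.
    L_ : lower Cholesky factor of K + (sigma_n + jitter) I.
    alpha_ : solve of the factorisation against the (centred) scores.
    y_mean_ : the centring offset (0 when ``center_y=False`` or N = 0).
    """

    def __init__(
        self,
        sigma_n: float = 0.1,
        sigma_f: float = 1.0,
        sigma_l: float = 1.0,
        center_y: bool = True,
        optimizer: Optional[str] = "lbfgs",
        n_restarts: int = 5,
        bounds: Optional[dict] = None,
        random_state: Optional[int] = None,
    ):
        self.sigma_n = sigma_n
        self.sigma_f = sigma_f
        self.sigma_l = sigma_l
        self.center_y = center_y
        self.optimizer = optimizer
        self.n_restarts = n_restarts
        self.bounds = bounds
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _initial_theta(self) -> GPHyperparams:
        return GPHyperparams(self.sigma_n, self.sigma_f, self.sigma_l).validate()

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GPSurrogate":
        """Fit on encoded configurations X (n x d) and scores y (n,).

        N = 0 is permitted and yields the prior-only state.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.size == 0:
            X = X.reshape(0, max(1, X.shape[-1] if X.ndim > 1 else 1))
        else:
            X = np.atleast_2d(X)
        if X.shape[0] != y.size:
            raise ValueError(f"X has {X.shape[0]} rows but y has {y.size} scores")
        if y.size and not np.all(np.isfinite(y)):
            raise ValueError("scores must be finite")

        theta = self._initial_theta()
        y_mean = float(y.mean()) if (self.center_y and y.size) else 0.0
        yc = y - y_mean
        if self.optimizer == "lbfgs" and y.size >= 2:
            theta = optimise_hyperparams(
                X,
                yc,
                theta,
                bounds=self.bounds,
                n_restarts=self.n_restarts,
                seed=self.random_state,
                center=False,
            )
        self.X_train_ = X
        self.y_train_ = y
        self.y_mean_ = y_mean
        self.theta_ = theta
        if y.size:
            self.L_ = _factorise(X, theta)
            self.alpha_ = linalg.cho_solve((self.L_, True), yc)
        else:
            self.L_ = np.zeros((0, 0))
            self.alpha_ = np.zeros(0)
        return self

    def predict(
        self, X: np.ndarray, return_var: bool = False
    ) -> "np.ndarray | Tuple[np.ndarray, np.ndarray]":
        """Posterior predictive mean (and variance) of the noisy score y*.

        Variance is ``sigma_f + sigma_n - k*^T (K + sigma_n I)^{-1} k*``,
        clipped into ``[0, sigma_f + sigma_n]``.
        """
        if not hasattr(self, "theta_"):
            raise RuntimeError("GPSurrogate is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        th = self.theta_
        prior_var = th.sigma_f + th.sigma_n
        if self.y_train_.size == 0:
            mean = np.full(X.shape[0], self.y_mean_)
            var = np.full(X.shape[0], prior_var)
        else:
            if X.shape[1] != self.X_train_.shape[1]:
                raise ValueError(
                    f"dimension mismatch: {X.shape[1]} vs {self.X_train_.shape[1]}"
                )
            Ks = kernel_matrix(X, self.X_train_, th)
            mean = Ks @ self.alpha_ + self.y_mean_
            v = linalg.solve_triangular(self.L_, Ks.T, lower=True)
            var = prior_var - np.sum(v**2, axis=0)
            var = np.clip(var, 0.0, prior_var)
        if return_var:
            return mean, var
        return mean

    def log_marginal_likelihood(self, theta: Optional[GPHyperparams] = None) -> float:
        """LML of the training data under ``theta`` (default: the fitted theta)."""
        if not hasattr(self, "theta_"):
            raise RuntimeError("GPSurrogate is not fitted")
        th = theta if theta is not None else self.theta_
        return log_marginal_likelihood(
            self.X_train_, self.y_train_ - self.y_mean_, th, center=False
        )
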