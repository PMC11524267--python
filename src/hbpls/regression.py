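"""Huber-Berhu penalized regression via accelerated proximal gradient descent.

Minimizes

    f(beta) = sum_i H_M(y_i - beta0 - x_i' beta) + lam * sum_j B_M(beta_j)

where ``H_M`` is the Huber loss and ``B_M`` the Berhu penalty (see
:mod:`hbpls.losses`).  The smooth Huber part is handled by gradient steps with
a backtracking (halving) line search; the non-smooth Berhu part by its
closed-form proximal operator.  Momentum weight ``k/(k+3)`` at outer iteration
``k`` gives the accelerated O(1/k^2) rate.

The intercept is handled by mean-centering: ``y`` is centered and columns of
``X`` standardized, the solver runs with the intercept fixed at zero in the
centered space, and ``beta0 = ybar - xbar' beta`` is recovered on output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .losses import (
    berhu_value,
    default_shape_parameter,
    huber_gradient,
    huber_value,
    prox_berhu,
)

__all__ = [
    "RegressionProblem",
    "HBFit",
    "hb_objective",
    "lambda_max",
    "fit_hb_regression",
    "predict",
]


@dataclass
class RegressionProblem:
    """A Huber-Berhu regression instance.

    Parameters
    ----------
    X : (n, p) design matrix.
    y : (n,) response vector.
    lam : nonnegative penalty weight.
    M : shape parameter; ``None`` selects IQR(y - ybar)/10.
    max_iter, tol : outer-iteration cap and relative-change convergence
        tolerance on the coefficient vector.
    """

    X: np.ndarray
    y: np.ndarray
    lam: float
    M: float | None = None
    max_iter: int = 1000
    tol: float = 1e-6

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n, p = self.X.shape
        if self.y.shape[0] != n:
            raise ValueError(f"X has {n} rows but y has {self.y.shape[0]} entries")
        if n < 2 or p < 1:
            raise ValueError("need n >= 2 samples and p >= 1 predictors")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("X and y must be finite")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter must be >= 1 and tol > 0")


@dataclass
class HBFit:
    """A fitted Huber-Berhu regression."""

    beta0: float
    beta: np.ndarray
    lam: float
    M: float
    n_iter: int
    converged: bool
    objective_trace: np.ndarray = field(repr=False)


def hb_objective(X, y, beta0, beta, lam, M) -> float:
    """Evaluate the Huber-Berhu objective at ``(beta0, beta)``.

    The intercept is not penalized.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    beta = np.asarray(beta, dtype=float).ravel()
    if X.shape[1] != beta.shape[0]:
        raise ValueError("beta length does not match number of predictors")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on sample count")
    r = y - beta0 - X @ beta
    return float(np.sum(huber_value(r, M)) + lam * np.sum(berhu_value(beta, M)))


def lambda_max(X, y, M) -> float:
    """Smallest penalty at which the zero vector is stationary.

    The zero vector minimizes the objective iff every coordinate of the
    Huber-loss gradient at beta = 0 lies within the Berhu subdifferential
    ``lam * [-1, 1]`` at zero, i.e. ``lam >= max_j |X_j' H'_M(y)|``.
    ``X`` and ``y`` should be on the scale the solver will see (centered).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    return float(np.max(np.abs(X.T @ huber_gradient(y, M))))


def _apg(X, y, lam, M, max_iter, tol):
    """Accelerated proximal gradient on the no-intercept problem.

    Step size starts at 1 and is only ever halved (kept across outer
    iterations); each outer iteration backtracks until the standard
    quadratic-upper-bound sufficient-decrease test holds at the step.
    """
    n, p = X.shape
    beta = np.zeros(p)
    beta_prev = np.zeros(p)
    t = 1.0
    trace = [hb_objective(X, y, 0.0, beta, lam, M)]
    converged = False
    k_done = 0
    for k in range(1, max_iter + 1):
        v = beta + (k / (k + 3.0)) * (beta - beta_prev)
        r_v = y - X @ v
        g_v = float(np.sum(huber_value(r_v, M)))
        grad = -(X.T @ huber_gradient(r_v, M))
        while True:
            p2 = prox_berhu(v - t * grad, t, lam, M)
            d = p2 - v
            g_new = float(np.sum(huber_value(y - X @ p2, M)))
            bound = g_v + float(grad @ d) + float(d @ d) / (2.0 * t)
            if g_new <= bound + 1e-12 * max(abs(bound), 1.0):
                break
            t *= 0.5
            if t < 1e-16:  # numerically degenerate; accept the step
                break
        beta_prev = beta
        beta = p2
        trace.append(hb_objective(X, y, 0.0, beta, lam, M))
        k_done = k
        step = np.linalg.norm(beta - beta_prev)
        if step <= tol * max(np.linalg.norm(beta_prev), 1e-12):
            converged = True
            break
    return beta, k_done, converged, np.asarray(trace)


def fit_hb_regression(problem: RegressionProblem, standardize: bool = True) -> HBFit:
    """Fit the Huber-Berhu regression by accelerated proximal gradient.

    With ``standardize=True`` (default) the response is mean-centered and the
    predictor columns standardized before solving; coefficients are returned
    on the original scale with the recovered intercept.  With
    ``standardize=False`` the problem is solved as given with the intercept
    fixed at zero (useful when the data are already centered).

    Non-convergence within ``max_iter`` produces a warning and a fit flagged
    ``converged=False``, not an exception.
    """
    X, y = problem.X, problem.y
    if standardize:
        x_mean = X.mean(axis=0)
        x_sd = X.std(axis=0)
        if np.any(x_sd <= 0):
            raise ValueError("constant predictor columns cannot be standardized")
        y_mean = y.mean()
        Xw = (X - x_mean) / x_sd
        yw = y - y_mean
    else:
        Xw, yw = X, y

    M = problem.M if problem.M is not None else default_shape_parameter(yw - yw.mean())
    beta_w, n_iter, converged, trace = _apg(
        Xw, yw, problem.lam, M, problem.max_iter, problem.tol
    )
    if not converged:
        warnings.warn(
            f"proximal gradient did not converge in {problem.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )

    if standardize:
        beta = beta_w / x_sd
        beta0 = float(y_mean - x_mean @ beta)
    else:
        beta = beta_w
        beta0 = 0.0
    return HBFit(
        beta0=beta0,
        beta=beta,
        lam=problem.lam,
        M=M,
        n_iter=n_iter,
        converged=converged,
        objective_trace=trace,
    )


def predict(fit: HBFit, Xnew) -> np.ndarray:
    """Linear predictions ``beta0 + Xnew @ beta`` on the original scale."""
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.ndim != 2 or Xnew.shape[1] != fit.beta.shape[0]:
        raise ValueError("Xnew must have the same number of columns as training X")
    return fit.beta0 + Xnew @ fit.beta
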