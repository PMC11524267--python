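"""Hyperparameter tuning: k-fold CV for the penalty and Q2 for the dimension.

The penalty weight lambda is chosen on a descending grid by minimizing the
mean held-out squared prediction error of the full HB-PLS fit; ties prefer
the larger (sparser) lambda.  The number of latent components is chosen by
the Q2 criterion

    Q2_h = 1 - (sum_k PRESS_h^k) / (sum_k RSS_h^k)

where PRESS_h^k sums squared held-out prediction errors of the h-component
model over cross-validation folds and RSS_h^k sums in-sample residuals of the
h-component model fitted on all data.  A component is retained when
Q2_h >= 1 - 0.95^2 = 0.0975.  Because PRESS compares held-out to in-sample
error at the same h, the criterion is conservative; at least one component is
always kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .losses import default_shape_parameter, huber_gradient
from .pls import cross_product, fit_hb_pls, initialize_weights, standardize

__all__ = [
    "Q2_THRESHOLD",
    "CVPlan",
    "QSquared",
    "pls_lambda_max",
    "default_lambda_grid",
    "make_folds",
    "cv_tune_lambda",
    "q_squared_path",
    "select_n_components",
]

# Retain a component when it explains at least 1 - 0.95^2 of what is left.
Q2_THRESHOLD = 1.0 - 0.95**2


@dataclass
class CVPlan:
    """Cross-validation layout and search grid."""

    n_folds: int = 5
    lambda_grid: np.ndarray | None = None  # descending; None -> data-derived
    seed: int = 0
    K_max: int = 2
    leave_one_out: bool = False

    def resolved_folds(self, n: int) -> int:
        # leave-one-out for small samples, per standard PLS practice
        if self.leave_one_out or n < 30:
            return n
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        return min(self.n_folds, n)


@dataclass
class QSquared:
    """Per-component PRESS/RSS/Q2 table."""

    per_component: pd.DataFrame  # columns: h, PRESS, RSS, Q2
    threshold: float = Q2_THRESHOLD


def pls_lambda_max(X, Y) -> float:
    """Penalty level at which the first component's weights shrink to zero.

    Computed from the stationarity condition of the Berhu-penalized Huber
    rank-one problem at the SVD initialization: the largest coordinate of the
    Huber-loss gradient of either weight vector evaluated at zero.
    """
    Xs, Ys, _ = standardize(X, Y)
    Mmat = cross_product(Xs, Ys)
    M = default_shape_parameter(Mmat.ravel())
    u0, v0 = initialize_weights(Mmat)
    grad_u0 = -(huber_gradient(Mmat, M) @ v0)  # d/du at u = 0, v = v0
    grad_v0 = -(huber_gradient(Mmat, M).T @ u0)  # d/dv at v = 0, u = u0
    return float(max(np.max(np.abs(grad_u0)), np.max(np.abs(grad_v0))))


def default_lambda_grid(X, Y, n_values: int = 20) -> np.ndarray:
    """Descending log-spaced grid from lambda_max down to lambda_max/1000."""
    lmax = pls_lambda_max(X, Y)
    return np.geomspace(lmax, lmax / 1000.0, n_values)


def make_folds(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Contiguous blocks of a seeded random permutation of the samples."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(block) for block in np.array_split(perm, n_folds)]


def _fit_or_null(Xtr, Ytr, lam, K, **kw):
    """Fit HB-PLS; an over-penalized (all-zero) model degrades to the mean."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            return fit_hb_pls(Xtr, Ytr, lam, K, **kw)
        except ValueError:
            return None


def _holdout_predictions(model, Xte, Ytr_mean, n_components=None):
    if model is None:
        return np.broadcast_to(Ytr_mean, (Xte.shape[0], Ytr_mean.shape[0]))
    if n_components is not None:
        n_components = min(n_components, model.n_components)
    return model.predict(Xte, n_components=n_components)


def cv_tune_lambda(X, Y, plan: CVPlan):
    """Choose lambda by k-fold CV on held-out squared prediction error.

    Returns ``(best_lambda, table)`` where the table has one row per grid
    value with per-fold errors, their mean, standard error, and a flag for
    grid points where every fold degenerated to the null (mean) model.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    grid = plan.lambda_grid if plan.lambda_grid is not None else default_lambda_grid(X, Y)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    if np.any(np.diff(grid) > 0):
        grid = np.sort(grid)[::-1]
    folds = make_folds(n, plan.resolved_folds(n), plan.seed)

    rows = []
    best_lam, best_err = None, np.inf
    for lam in grid:
        fold_errs, all_null = [], True
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            Xtr, Ytr = X[train_idx], Y[train_idx]
            if np.all(Xtr.std(axis=0) == 0) or np.all(Ytr.std(axis=0) == 0):
                warnings.warn("skipping degenerate fold (constant data)", RuntimeWarning)
                continue
            model = _fit_or_null(Xtr, Ytr, lam, plan.K_max)
            if model is not None:
                all_null = False
            pred = _holdout_predictions(model, X[test_idx], Ytr.mean(axis=0))
            fold_errs.append(float(np.mean((Y[test_idx] - pred) ** 2)))
        if not fold_errs:
            continue
        mean_err = float(np.mean(fold_errs))
        se = float(np.std(fold_errs, ddof=1) / np.sqrt(len(fold_errs))) if len(fold_errs) > 1 else 0.0
        rows.append(
            {
                "lambda": float(lam),
                "mean_error": mean_err,
                "se": se,
                "null_model": all_null,
                **{f"fold{i}": e for i, e in enumerate(fold_errs)},
            }
        )
        # grid is descending, so strict improvement keeps the larger lambda on ties
        if mean_err < best_err:
            best_err, best_lam = mean_err, float(lam)
    if best_lam is None:
        raise ValueError("cross-validation failed on every fold")
    return best_lam, pd.DataFrame(rows)


def q_squared_path(X, Y, lam, K_max, plan: CVPlan) -> QSquared:
    """PRESS/RSS/Q2 for models with 1..K_max components at a fixed lambda."""
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]

    full = _fit_or_null(X, Y, lam, K_max)
    if full is None:
        raise ValueError("model has no usable components at this lambda")
    K_eff = full.n_components

    folds = make_folds(n, plan.resolved_folds(n), plan.seed)
    fold_models = []
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        fold_models.append(
            (test_idx, _fit_or_null(X[train_idx], Y[train_idx], lam, K_max), Y[train_idx].mean(axis=0))
        )

    rows = []
    for h in range(1, K_eff + 1):
        rss = float(np.sum((Y - full.predict(X, n_components=h)) ** 2))
        press = 0.0
        for test_idx, model, ytr_mean in fold_models:
            pred = _holdout_predictions(model, X[test_idx], ytr_mean, n_components=h)
            press += float(np.sum((Y[test_idx] - pred) ** 2))
        if rss == 0.0:
            q2 = 1.0  # perfect in-sample fit
        else:
            q2 = 1.0 - press / rss
        rows.append({"h": h, "PRESS": press, "RSS": rss, "Q2": q2})
    return QSquared(per_component=pd.DataFrame(rows))


def select_n_components(qs: QSquared, K_max: int = 5) -> int:
    """Largest prefix of components all meeting the Q2 threshold (min 1)."""
    q2 = qs.per_component["Q2"].to_numpy()
    k = 0
    for val in q2[:K_max]:
        if val >= qs.threshold:
            k += 1
        else:
            break
    return max(k, 1)
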