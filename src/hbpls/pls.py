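"""Huber-Berhu partial least squares (HB-PLS).

PLS extracts latent components xi = X u that maximize covariance with linear
combinations of the responses Y v.  On standardized data this is equivalent to
a rank-one approximation of the cross-product matrix Mmat = X'Y, which plain
PLS obtains from the leading singular pair.  HB-PLS replaces the squared-error
rank-one fit with a Huber loss on the cells of Mmat and adds a Berhu penalty
on both weight vectors:

    min_{u,v}  sum_ij H_M(m_ij - u_i v_j) + lam * sum_i B_M(u_i)
                                          + lam * sum_j B_M(v_j)

solved by alternating single proximal-gradient steps on u and v (each
subproblem is convex and separable across coordinates).  After a component is
extracted, X and Y are deflated by its rank-one contribution and the
regression coefficient matrix A (TFs x pathway genes) is accumulated so that
X A reproduces the sum of the per-component predictions.

The shape parameter for each component's inner problem is one tenth of the
interquartile range of the entries of the current (deflated) cross-product
matrix.
"""

from __future__ import annotations

import json
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
    "Standardizer",
    "PLSComponent",
    "HBPLSModel",
    "standardize",
    "cross_product",
    "initialize_weights",
    "update_u",
    "update_v",
    "inner_objective",
    "solve_weights",
    "extract_component",
    "accumulate",
    "deflate",
    "fit_hb_pls",
    "save_model",
    "load_model",
]


@dataclass
class Standardizer:
    """Column means/SDs of X and Y plus the retained-column masks."""

    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    x_kept: np.ndarray  # boolean mask over original X columns
    y_kept: np.ndarray

    def transform_x(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.x_kept]
        return (X - self.x_mean) / self.x_sd

    def inverse_transform_y(self, Ys) -> np.ndarray:
        return np.asarray(Ys, dtype=float) * self.y_sd + self.y_mean


@dataclass
class PLSComponent:
    """One latent dimension: weights, score, and loadings."""

    u: np.ndarray
    v: np.ndarray
    xi: np.ndarray
    c: np.ndarray
    d: np.ndarray
    n_alternations: int = 0
    converged: bool = True


@dataclass
class HBPLSModel:
    """Fitted HB-PLS model.

    ``A`` is the accumulated p x q coefficient matrix on the standardized
    scale: standardized predictions are ``Xs @ A``.  ``A_path[h]`` is the
    coefficient matrix of the (h+1)-component truncation, so prediction with
    fewer components needs no refit.
    """

    components: list[PLSComponent]
    A: np.ndarray
    lam: float
    K: int
    tf_ids: list[str]
    gene_ids: list[str]
    scaler: Standardizer
    A_path: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        """Predict responses on the original scale from original-scale X."""
        A = self.A if n_components is None else self.A_path[n_components - 1]
        Xs = self.scaler.transform_x(X)
        return self.scaler.inverse_transform_y(Xs @ A)


def standardize(X, Y, x_ids=None, y_ids=None):
    """Center and scale columns of X and Y to mean 0, SD 1.

    Constant columns carry no correlation information and cannot be scaled;
    they are dropped with a warning and recorded in the returned
    :class:`Standardizer`.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("X and Y must be 2-D")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of samples (rows)")

    def _prep(A, label):
        sd = A.std(axis=0)
        kept = sd > 0
        if not np.any(kept):
            raise ValueError(f"all columns of {label} are constant")
        if not np.all(kept):
            warnings.warn(
                f"dropping {int((~kept).sum())} constant column(s) of {label}",
                RuntimeWarning,
                stacklevel=3,
            )
        A = A[:, kept]
        mean = A.mean(axis=0)
        sd = A.std(axis=0)
        return (A - mean) / sd, mean, sd, kept

    Xs, x_mean, x_sd, x_kept = _prep(X, "X")
    Ys, y_mean, y_sd, y_kept = _prep(Y, "Y")
    scaler = Standardizer(x_mean, x_sd, y_mean, y_sd, x_kept, y_kept)
    return Xs, Ys, scaler


def cross_product(Xs, Ys) -> np.ndarray:
    """Cross-product matrix X'Y of standardized data (p x q)."""
    Xs = np.asarray(Xs, dtype=float)
    Ys = np.asarray(Ys, dtype=float)
    if Xs.shape[0] != Ys.shape[0]:
        raise ValueError("sample-count mismatch between X and Y")
    return Xs.T @ Ys


def initialize_weights(Mmat):
    """Initial (u, v) from the leading singular triplet of the cross-product.

    u is the first left singular vector (unit norm); v is the first right
    singular vector scaled by the first singular value, so that u v' is the
    best rank-one approximation.  Signs are flipped jointly so the
    largest-magnitude entry of u is positive.
    """
    Mmat = np.asarray(Mmat, dtype=float)
    if not np.any(Mmat):
        raise ValueError("no remaining covariance structure (cross-product is zero)")
    U, s, Vt = np.linalg.svd(Mmat, full_matrices=False)
    u = U[:, 0].copy()
    v = (s[0] * Vt[0, :]).copy()
    if u[np.argmax(np.abs(u))] < 0:
        u, v = -u, -v
    return u, v


def _huber_grad_u(Mmat, u, v, M):
    """Gradient of sum_ij H_M(m_ij - u_i v_j) with respect to u."""
    R = Mmat - np.outer(u, v)
    return -(huber_gradient(R, M) @ v)


def _huber_grad_v(Mmat, u, v, M):
    R = Mmat - np.outer(u, v)
    return -(huber_gradient(R, M).T @ u)


def _huber_sum(Mmat, u, v, M):
    return float(np.sum(huber_value(Mmat - np.outer(u, v), M)))


def inner_objective(Mmat, u, v, lam, M) -> float:
    """Huber rank-one misfit plus Berhu penalties on both weight vectors."""
    return _huber_sum(Mmat, u, v, M) + float(
        lam * (np.sum(berhu_value(u, M)) + np.sum(berhu_value(v, M)))
    )


def _prox_step(x, grad_fn, smooth_fn, lam, M, t):
    """One backtracked proximal-gradient step shared across coordinates.

    Returns the updated vector and the (possibly halved) step size.
    """
    g0 = smooth_fn(x)
    grad = grad_fn(x)
    while True:
        x_new = prox_berhu(x - t * grad, t, lam, M)
        d = x_new - x
        bound = g0 + float(grad @ d) + float(d @ d) / (2.0 * t)
        if smooth_fn(x_new) <= bound + 1e-12 * max(abs(bound), 1.0):
            return x_new, t
        t *= 0.5
        if t < 1e-16:
            return x, t


def update_u(Mmat, u, v, lam, M, t=1.0):
    """One proximal-gradient step on u with v fixed."""
    u_new, t = _prox_step(
        np.asarray(u, dtype=float),
        lambda w: _huber_grad_u(Mmat, w, v, M),
        lambda w: _huber_sum(Mmat, w, v, M),
        lam,
        M,
        t,
    )
    return u_new, t

def update_v(Mmat, u, v, lam, M, t=1.0):
    """One proximal-gradient step on v with u fixed."""
    v_new, t = _prox_step(
        np.asarray(v, dtype=float),
        lambda w: _huber_grad_v(Mmat, u, w, M),
        lambda w: _huber_sum(Mmat, u, w, M),
        lam,
        M,
        t,
    )
    return v_new, t


def solve_weights(Mmat, lam, M=None, inner_tol: float = 1e-5, inner_max_iter: int = 500):
    """Alternating one-step proximal solver for the penalized rank-one fit.

    Starts from the SVD initialization and alternates single backtracked
    proximal steps on u and v until the relative change of both falls below
    ``inner_tol``.  Returns ``(u, v, n_alternations, converged)``.
    """
    Mmat = np.asarray(Mmat, dtype=float)
    if M is None:
        M = default_shape_parameter(Mmat.ravel())
    u, v = initialize_weights(Mmat)
    t_u = t_v = 1.0
    converged = False
    n_alt = 0
    for n_alt in range(1, inner_max_iter + 1):
        u_new, t_u = update_u(Mmat, u, v, lam, M, t_u)
        v_new, t_v = update_v(Mmat, u_new, v, lam, M, t_v)
        du = np.linalg.norm(u_new - u) / max(np.linalg.norm(u), 1e-12)
        dv = np.linalg.norm(v_new - v) / max(np.linalg.norm(v), 1e-12)
        u, v = u_new, v_new
        if max(du, dv) < inner_tol:
            converged = True
            break
    return u, v, n_alt, converged


def extract_component(
    Xd,
    Yd,
    lam,
    M=None,
    inner_tol: float = 1e-5,
    inner_max_iter: int = 500,
):
    """Extract one HB-PLS component from the (deflated) matrices.

    Returns ``None`` when the penalty annihilates u or the score has zero
    norm, which callers treat as "stop extracting".
    """
    Mmat = cross_product(Xd, Yd)
    if not np.any(Mmat):
        return None
    u, v, n_alt, converged = solve_weights(
        Mmat, lam, M=M, inner_tol=inner_tol, inner_max_iter=inner_max_iter
    )
    if not np.any(u):
        return None
    xi = Xd @ u
    ss = float(xi @ xi)
    if ss <= 0:
        return None
    c = Xd.T @ xi / ss
    d = Yd.T @ xi / ss
    if u[np.argmax(np.abs(u))] < 0:
        u, v, xi, c, d = -u, -v, -xi, -c, -d
    return PLSComponent(u=u, v=v, xi=xi, c=c, d=d, n_alternations=n_alt, converged=converged)


def accumulate(A, cF, u, c, d):
    """Coefficient-matrix and weight-map updates after one component.

    ``A <- A + cF u d'`` maps the component's contribution back to original-X
    coordinates; ``cF <- cF (I - u c')`` composes the deflation so the next
    component's weights are expressed in the same coordinates.  Applied in
    this order.
    """
    A = np.asarray(A, dtype=float)
    cF = np.asarray(cF, dtype=float)
    u = np.asarray(u, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    p = cF.shape[0]
    if cF.shape != (p, p) or u.shape[0] != p or c.shape[0] != p or A.shape[0] != p:
        raise ValueError("nonconformable dimensions in accumulate")
    if A.shape[1] != d.shape[0]:
        raise ValueError("A and d disagree on the number of responses")
    A_new = A + np.outer(cF @ u, d)
    cF_new = cF @ (np.eye(p) - np.outer(u, c))
    return A_new, cF_new


def deflate(Xd, Yd, component: PLSComponent):
    """Remove the component's rank-one contribution from X and Y.

    The loadings are recomputed from the matrices being deflated, making the
    operation the projection of the columns onto the orthocomplement of the
    score; right after extraction they equal the component's stored ``c`` and
    ``d``, and deflating twice with the same component is a no-op.
    """
    xi = component.xi
    ss = float(xi @ xi)
    if ss <= 0:
        raise ValueError("component has a zero-norm score")
    c = Xd.T @ xi / ss
    d = Yd.T @ xi / ss
    return Xd - np.outer(xi, c), Yd - np.outer(xi, d)


def fit_hb_pls(
    X,
    Y,
    lam,
    K,
    tf_ids=None,
    gene_ids=None,
    M=None,
    inner_tol: float = 1e-5,
    inner_max_iter: int = 500,
) -> HBPLSModel:
    """Fit a K-component HB-PLS model.

    Standardizes X and Y, then repeats {cross-product, SVD initialization,
    alternating proximal extraction, accumulation, deflation} K times.  A
    rejected component (all-zero weights under the penalty, or a zero-norm
    score) truncates the model with a warning rather than raising, so tuning
    loops stay robust.

    ``M=None`` (default) recomputes the shape parameter per component from
    the current cross-product matrix; passing a number fixes it globally.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if tf_ids is None:
        tf_ids = [f"tf{j}" for j in range(X.shape[1])]
    if gene_ids is None:
        gene_ids = [f"gene{k}" for k in range(Y.shape[1])]
    tf_ids = list(tf_ids)
    gene_ids = list(gene_ids)
    if len(tf_ids) != X.shape[1] or len(gene_ids) != Y.shape[1]:
        raise ValueError("identifier lists must match matrix dimensions")

    Xs, Ys, scaler = standardize(X, Y)
    kept_tf = [t for t, keep in zip(tf_ids, scaler.x_kept) if keep]
    kept_gene = [g for g, keep in zip(gene_ids, scaler.y_kept) if keep]

    p, q = Xs.shape[1], Ys.shape[1]
    A = np.zeros((p, q))
    cF = np.eye(p)
    Xd, Yd = Xs, Ys
    components: list[PLSComponent] = []
    A_path: list[np.ndarray] = []
    for _ in range(K):
        comp = extract_component(
            Xd, Yd, lam, M=M, inner_tol=inner_tol, inner_max_iter=inner_max_iter
        )
        if comp is None:
            warnings.warn(
                f"component {len(components) + 1} rejected (fully shrunk or zero "
                "score); truncating the model",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        A, cF = accumulate(A, cF, comp.u, comp.c, comp.d)
        components.append(comp)
        A_path.append(A.copy())
        Xd, Yd = deflate(Xd, Yd, comp)
    if not components:
        raise ValueError("no usable components could be extracted at this penalty")

    return HBPLSModel(
        components=components,
        A=A,
        lam=float(lam),
        K=len(components),
        tf_ids=kept_tf,
        gene_ids=kept_gene,
        scaler=scaler,
        A_path=A_path,
    )


def save_model(model: HBPLSModel, path) -> None:
    """Serialize a fitted model to a single JSON file (round-trip exact)."""
    payload = {
        "lam": model.lam,
        "K": model.K,
        "tf_ids": model.tf_ids,
        "gene_ids": model.gene_ids,
        "A": model.A.tolist(),
        "A_path": [a.tolist() for a in model.A_path],
        "scaler": {
            "x_mean": model.scaler.x_mean.tolist(),
            "x_sd": model.scaler.x_sd.tolist(),
            "y_mean": model.scaler.y_mean.tolist(),
            "y_sd": model.scaler.y_sd.tolist(),
            "x_kept": model.scaler.x_kept.tolist(),
            "y_kept": model.scaler.y_kept.tolist(),
        },
        "components": [
            {
                "u": comp.u.tolist(),
                "v": comp.v.tolist(),
                "xi": comp.xi.tolist(),
                "c": comp.c.tolist(),
                "d": comp.d.tolist(),
                "n_alternations": comp.n_alternations,
                "converged": comp.converged,
            }
            for comp in model.components
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> HBPLSModel:
    """Load a model written by :func:`save_model`."""
    with open(path) as fh:
        payload = json.load(fh)
    sc = payload["scaler"]
    scaler = Standardizer(
        x_mean=np.asarray(sc["x_mean"], dtype=float),
        x_sd=np.asarray(sc["x_sd"], dtype=float),
        y_mean=np.asarray(sc["y_mean"], dtype=float),
        y_sd=np.asarray(sc["y_sd"], dtype=float),
        x_kept=np.asarray(sc["x_kept"], dtype=bool),
        y_kept=np.asarray(sc["y_kept"], dtype=bool),
    )
    components = [
        PLSComponent(
            u=np.asarray(c["u"], dtype=float),
            v=np.asarray(c["v"], dtype=float),
            xi=np.asarray(c["xi"], dtype=float),
            c=np.asarray(c["c"], dtype=float),
            d=np.asarray(c["d"], dtype=float),
            n_alternations=c["n_alternations"],
            converged=c["converged"],
        )
        for c in payload["components"]
    ]
    return HBPLSModel(
        components=components,
        A=np.asarray(payload["A"], dtype=float),
        lam=payload["lam"],
        K=payload["K"],
        tf_ids=payload["tf_ids"],
        gene_ids=payload["gene_ids"],
        scaler=scaler,
        A_path=[np.asarray(a, dtype=float) for a in payload["A_path"]],
    )
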