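"""Huber and Berhu scalar functions and their proximal operators.

The Huber function is quadratic for small arguments and linear beyond the
shape parameter ``M``; the Berhu ("reversed Huber") penalty is the opposite:
linear (LASSO-like) for small arguments and quadratic (ridge-like) beyond
``M``.  Both are convex, and the Berhu proximal map has a closed form as the
composition of soft-thresholding with a quadratic-tail shrinkage, which is
what makes proximal-gradient minimization of the Huber-Berhu objective cheap.

All functions are vectorized elementwise over numpy arrays and accept scalars.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "huber_value",
    "huber_gradient",
    "berhu_value",
    "prox_soft_threshold",
    "prox_quadratic_tail",
    "prox_berhu",
    "default_shape_parameter",
]


def _check_shape_param(M: float) -> float:
    M = float(M)
    if not np.isfinite(M) or M <= 0:
        raise ValueError(f"shape parameter M must be positive and finite, got {M}")
    return M


def huber_value(z, M):
    """Huber function: ``z**2`` for ``|z| <= M``, ``2*M*|z| - M**2`` beyond.

    Continuous and once-differentiable everywhere; even in ``z``.
    """
    M = _check_shape_param(M)
    z = np.asarray(z, dtype=float)
    a = np.abs(z)
    out = np.where(a <= M, z * z, 2.0 * M * a - M * M)
    return out if out.ndim else float(out)


def huber_gradient(z, M):
    """Derivative of :func:`huber_value`: ``2z`` inside, ``2M*sign(z)`` outside.

    Bounded by ``2M`` in absolute value, which is the source of the Huber
    loss's robustness to gross outliers.
    """
    M = _check_shape_param(M)
    z = np.asarray(z, dtype=float)
    out = np.where(np.abs(z) <= M, 2.0 * z, 2.0 * M * np.sign(z))
    return out if out.ndim else float(out)


def berhu_value(z, M):
    """Berhu penalty: ``|z|`` for ``|z| <= M``, ``(z**2 + M**2)/(2M)`` beyond.

    Convex and continuous (both branches equal ``M`` at ``|z| = M``), but not
    differentiable at zero — the kink is what induces sparsity.
    """
    M = _check_shape_param(M)
    z = np.asarray(z, dtype=float)
    a = np.abs(z)
    out = np.where(a <= M, a, (z * z + M * M) / (2.0 * M))
    return out if out.ndim else float(out)


def prox_soft_threshold(x, tlam):
    """Soft-thresholding ``sign(x) * max(|x| - tlam, 0)``.

    The proximal operator of ``tlam * |.|``: shrinks toward zero by ``tlam``
    and truncates, preserving sign.
    """
    tlam = float(tlam)
    if tlam < 0:
        raise ValueError(f"threshold must be nonnegative, got {tlam}")
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.maximum(np.abs(x) - tlam, 0.0)
    return out if out.ndim else float(out)


def prox_quadratic_tail(x, t, lam, M):
    """Proximal operator of the quadratic tail of the Berhu penalty.

    ``sign(x) * min(|x|, M/(M + t*lam) * (|x| + t*lam))`` — the identity for
    ``|x| <= M`` and a ridge-like multiplicative shrink beyond.
    """
    M = _check_shape_param(M)
    t = float(t)
    lam = float(lam)
    if t <= 0:
        raise ValueError(f"step size t must be positive, got {t}")
    if lam < 0:
        raise ValueError(f"penalty weight lam must be nonnegative, got {lam}")
    x = np.asarray(x, dtype=float)
    a = np.abs(x)
    shrunk = (M / (M + t * lam)) * (a + t * lam)
    out = np.sign(x) * np.minimum(a, shrunk)
    return out if out.ndim else float(out)


def prox_berhu(x, t, lam, M):
    """Proximal operator of ``lam * B_M`` with step ``t``.

    Exact minimizer of ``(1/2t)(z - x)**2 + lam * B_M(z)``, computed as the
    composition: soft-threshold first, then the quadratic-tail shrink.
    """
    p1 = prox_soft_threshold(x, t * lam)
    return prox_quadratic_tail(p1, t, lam, M)


def default_shape_parameter(values) -> float:
    """Default shape parameter: one tenth of the interquartile range.

    Quartiles use linear interpolation (numpy's default) so the value is
    reproducible.  A constant input has zero IQR; a small positive floor is
    returned instead, with a warning.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError("need at least 4 finite values to estimate IQR")
    q1, q3 = np.percentile(v, [25.0, 75.0])
    iqr = q3 - q1
    if iqr <= 0:
        floor = 1e-6 * max(float(np.max(np.abs(v))), 1.0)
        warnings.warn(
            "IQR is zero (near-constant input); using floor shape parameter "
            f"{floor:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
        return floor
    return float(iqr / 10.0)
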