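"""Proximal operators: soft thresholding, generalized q-shrinkage, singular
value p-shrinkage, and the Procrustes projection.

The generalized q-shrinkage operator solves, entrywise,

    min_b  h(b) = alpha * |b|^q + (1/2) * (b - z)^2,        0 < q <= 1,

by the three-case rule: the solution is 0 whenever |z| <= c2 with
c1 = (alpha*q*(1-q))^(1/(2-q)) and c2 = c1 + alpha*q*c1^(q-1); otherwise it is
the better of 0 and the stationary point of h on the same side as z, found by
Newton-Raphson initialized at z.  For q = 1 the operator reduces exactly to
the classical soft-thresholding (shrinkage) operator.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg

__all__ = [
    "soft_threshold",
    "q_shrink",
    "weighted_q_shrink",
    "sv_p_shrink",
    "procrustes",
]

_NEWTON_MAX_ITER = 100
_NEWTON_TOL = 1e-12


def soft_threshold(x, alpha: float):
    """Elementwise shrinkage sgn(x) * max(|x| - alpha, 0)."""
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - alpha, 0.0)


def _positive_branch_root(z: np.ndarray, alpha, q: float) -> np.ndarray:
    """Root of g(b) = alpha*q*b^(q-1) + b - z on (c1, z] for z > c2, via
    vectorized Newton iteration started at z.

    g is convex and increasing on [c1, z] (g'(c1) = 0), so Newton from z
    decreases monotonically to the root.  ``alpha`` may be an array
    broadcasting against ``z``.
    """
    b = z.copy()
    aq = alpha * q
    converged = np.zeros(b.shape, dtype=bool)
    for _ in range(_NEWTON_MAX_ITER):
        g = aq * b ** (q - 1.0) + b - z
        converged = np.abs(g) < _NEWTON_TOL
        if converged.all():
            break
        gp = aq * (q - 1.0) * b ** (q - 2.0) + 1.0
        step = np.where(converged, 0.0, g / np.where(gp == 0, 1.0, gp))
        b = b - step
    if not converged.all():
        # Bisection fallback on the bracketing interval [c1, z].
        warnings.warn(
            "Newton-Raphson did not converge for some q-shrinkage entries; "
            "falling back to bisection",
            RuntimeWarning,
            stacklevel=2,
        )
        bad = ~converged
        alpha_arr = np.broadcast_to(np.asarray(alpha, dtype=float), z.shape)
        c1 = (alpha_arr * q * (1.0 - q)) ** (1.0 / (2.0 - q))
        lo, hi = c1[bad].copy(), z[bad].copy()
        aq_bad = np.broadcast_to(np.asarray(aq, dtype=float), z.shape)[bad]
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            gm = aq_bad * mid ** (q - 1.0) + mid - z[bad]
            lo = np.where(gm < 0, mid, lo)
            hi = np.where(gm < 0, hi, mid)
        b[bad] = 0.5 * (lo + hi)
    return b


def q_shrink(z, alpha: float, q: float):
    """Generalized q-shrinkage: entrywise global minimizer of
    alpha*|b|^q + (1/2)*(b - z)^2 for q in (0, 1]."""
    if not 0.0 < q <= 1.0:
        raise ValueError("q must lie in (0, 1]")
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    if q == 1.0:
        return soft_threshold(z, alpha)
    z = np.asarray(z, dtype=float)
    scalar = z.ndim == 0
    z = np.atleast_1d(z)
    out = np.zeros_like(z)
    if alpha > 0:
        c1 = (alpha * q * (1.0 - q)) ** (1.0 / (2.0 - q))
        c2 = c1 + alpha * q * c1 ** (q - 1.0)
    else:
        c2 = 0.0
    az = np.abs(z)
    active = az > c2
    if active.any():
        rho = _positive_branch_root(az[active], alpha, q)
        # pick the argmin of h over {0, rho}; ties resolve to 0 (sparsity)
        h_rho = alpha * rho**q + 0.5 * (rho - az[active]) ** 2
        h_zero = 0.5 * az[active] ** 2
        take = h_rho < h_zero
        vals = np.where(take, rho * np.sign(z[active]), 0.0)
        out[active] = vals
    return out[0] if scalar else out


def weighted_q_shrink(Z: np.ndarray, alpha: float, W: np.ndarray, q: float):
    """q-shrinkage with per-entry threshold alpha * w_ij; entries with
    w_ij = 0 carry no penalty and are returned unchanged."""
    Z = np.asarray(Z, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.shape != Z.shape:
        raise ValueError(f"weight shape {W.shape} does not match data {Z.shape}")
    if (W < 0).any():
        raise ValueError("weights must be nonnegative")
    if not 0.0 < q <= 1.0:
        raise ValueError("q must lie in (0, 1]")
    out = Z.copy()
    free = W == 0
    penal = ~free
    if q == 1.0:
        out[penal] = np.sign(Z[penal]) * np.maximum(
            np.abs(Z[penal]) - alpha * W[penal], 0.0
        )
        return out
    w = W[penal]
    z = Z[penal]
    a = alpha * w
    res = np.zeros_like(z)
    if alpha > 0:
        c1 = (a * q * (1.0 - q)) ** (1.0 / (2.0 - q))
        c2 = c1 + a * q * c1 ** (q - 1.0)
    else:
        c2 = np.zeros_like(z)
    az = np.abs(z)
    active = az > c2
    if active.any():
        rho = _positive_branch_root(az[active], a[active], q)
        h_rho = a[active] * rho**q + 0.5 * (rho - az[active]) ** 2
        h_zero = 0.5 * az[active] ** 2
        res[active] = np.where(h_rho < h_zero, rho * np.sign(z[active]), 0.0)
    out[penal] = res
    return out


def sv_p_shrink(Z: np.ndarray, alpha: float, p: float) -> np.ndarray:
    """Generalized singular value p-shrinkage: q-shrinkage (exponent p,
    threshold alpha) applied to the singular values of Z, singular vectors
    unchanged.  Solves min_B alpha*||B||_Sp^p + (1/2)||B - Z||_F^2."""
    Z = np.asarray(Z, dtype=float)
    if not np.isfinite(Z).all():
        raise ValueError("input matrix contains non-finite entries")
    if alpha == 0:
        return Z.copy()
    try:
        U, s, Vt = linalg.svd(Z, full_matrices=False)
    except linalg.LinAlgError as exc:  # pragma: no cover - backend dependent
        raise linalg.LinAlgError(
            f"SVD failed in singular value p-shrinkage on shape {Z.shape}"
        ) from exc
    s_shrunk = q_shrink(s, alpha, p)
    return (U * s_shrunk) @ Vt


def procrustes(A: np.ndarray) -> np.ndarray:
    """Closed-form projection onto column-orthonormal matrices: U @ Vt from
    the thin SVD A = U S Vt.  Minimizes ||A - B||_F over B with B^T B = I."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] < A.shape[1]:
        raise ValueError("A must have at least as many rows as columns")
    U, _, Vt = linalg.svd(A, full_matrices=False)
    return U @ Vt
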