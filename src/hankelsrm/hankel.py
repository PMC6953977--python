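"""Block-Hankel linear map, its adjoint, and the associated proximal operator.

A multichannel trajectory is stored channel-major as a ``D x T`` array whose
column ``t`` is the observation at time ``t``.  The block-Hankel map stacks
``j`` shifted windows of the trajectory into an ``(m*j) x (n*k)`` matrix with
constant skew-diagonal blocks, optionally right-multiplied by a matrix
``gamma`` (used to project onto the nullspace of the input Hankel matrix in
input-output problems).  The rank of this matrix equals the order of the
minimal LTI system generating the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HankelSpec",
    "hankel_map",
    "hankel_adjoint",
    "adjoint_norm_bound",
    "apply_Q0",
    "dehankelize",
    "default_depth",
]

_GAMMA_SLACK = 1e-8  # numerical slack on sigma_max(gamma) <= 1


@dataclass
class HankelSpec:
    """Geometry of a block-Hankel matrix.

    Parameters
    ----------
    m : int
        Rows per time block (number of channels entering each block row).
    n_blk : int
        Columns per time block.
    j : int
        Number of block rows.
    k : int
        Number of block columns.
    gamma : ndarray of shape (n_blk * k, q_dim), optional
        Right multiplier with largest singular value <= 1.  Defaults to the
        identity (autonomous, output-only problems).
    """

    m: int
    n_blk: int
    j: int
    k: int
    gamma: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        for name in ("m", "n_blk", "j", "k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.gamma is not None:
            self.gamma = np.asarray(self.gamma, dtype=float)
            if self.gamma.shape[0] != self.n_blk * self.k:
                raise ValueError(
                    f"gamma has {self.gamma.shape[0]} rows, expected "
                    f"n_blk*k = {self.n_blk * self.k}"
                )
            smax = np.linalg.norm(self.gamma, 2)
            if smax > 1.0 + _GAMMA_SLACK:
                raise ValueError(
                    f"sigma_max(gamma) = {smax:.6g} exceeds 1; rescale gamma"
                )

    @property
    def T(self) -> int:
        """Number of time samples consumed: j + k - 1."""
        return self.j + self.k - 1

    @property
    def n_rows(self) -> int:
        return self.m * self.j

    @property
    def n_cols(self) -> int:
        """Column count after gamma (q_dim if gamma is given, else n_blk*k)."""
        if self.gamma is None:
            return self.n_blk * self.k
        return self.gamma.shape[1]

    @property
    def multiplicities(self) -> np.ndarray:
        """Skew-diagonal multiplicities c_t = #{(a, b): a + b = t}."""
        t = np.arange(self.T)
        return np.minimum.reduce(
            [t + 1, np.full_like(t, min(self.j, self.k)), self.T - t]
        )

    def validate_trajectory(self, A: np.ndarray) -> np.ndarray:
        A = np.asarray(A, dtype=float)
        expected = (self.m, self.n_blk * self.T)
        if A.shape != expected:
            raise ValueError(f"trajectory has shape {A.shape}, expected {expected}")
        return A


def hankel_map(A: np.ndarray, spec: HankelSpec) -> np.ndarray:
    """Apply the block-Hankel map H(A) = H_{m,n,j,k}(A) @ gamma.

    ``A`` is an ``m x n_blk*(j+k-1)`` trajectory of time blocks
    ``A_0 ... A_{j+k-2}``; block ``(a, b)`` of the result (before gamma)
    equals ``A_{a+b}``.
    """
    A = spec.validate_trajectory(A)
    m, n, j, k = spec.m, spec.n_blk, spec.j, spec.k
    # columns are grouped per time block, so axis 1 of the reshape is t
    A3 = A.reshape(m, spec.T, n)
    idx = np.add.outer(np.arange(j), np.arange(k))  # (j, k) -> t = a + b
    H4 = A3[:, idx, :]  # (m, j, k, n)
    H = H4.transpose(1, 0, 2, 3).reshape(m * j, k * n)
    if spec.gamma is not None:
        H = H @ spec.gamma
    return H


def hankel_adjoint(B: np.ndarray, spec: HankelSpec) -> np.ndarray:
    """Adjoint of :func:`hankel_map`: gamma^T on the right, then sum the
    blocks of the ``j x k`` block grid along each anti-diagonal."""
    B = np.asarray(B, dtype=float)
    expected = (spec.n_rows, spec.n_cols)
    if B.shape != expected:
        raise ValueError(f"matrix has shape {B.shape}, expected {expected}")
    if spec.gamma is not None:
        B = B @ spec.gamma.T
    m, n, j, k = spec.m, spec.n_blk, spec.j, spec.k
    B4 = B.reshape(j, m, k, n).transpose(1, 0, 2, 3)  # (m, j, k, n)
    out = np.zeros((m, spec.T, n))
    for a in range(j):
        out[:, a : a + k, :] += B4[:, a, :, :]
    return out.reshape(m, spec.T * n)


def adjoint_norm_bound(spec: HankelSpec) -> int:
    """Upper bound L = min{j, k} with ||H*(B)||_F^2 <= L ||B||_F^2."""
    return min(spec.j, spec.k)


def apply_Q0(P: np.ndarray, spec: HankelSpec) -> np.ndarray:
    """Apply the positive semi-definite operator Q0 = L*I - H* H to a
    trajectory.  Q0 induces the proximal (semi-)norm used in the solver's
    closed-form trajectory update."""
    P = spec.validate_trajectory(P)
    return adjoint_norm_bound(spec) * P - hankel_adjoint(hankel_map(P, spec), spec)


def dehankelize(H: np.ndarray, spec: HankelSpec) -> np.ndarray:
    """Recover a trajectory from a (nearly) block-Hankel matrix by averaging
    the skew-diagonal copies of each time block.

    Only valid when ``gamma`` is the identity (the map is then injective).
    For an exactly Hankel-structured input this inverts :func:`hankel_map`.
    """
    if spec.gamma is not None:
        raise ValueError("dehankelize requires gamma = identity")
    traj = hankel_adjoint(H, spec)
    counts = np.repeat(spec.multiplicities, spec.n_blk)
    return traj / counts


def default_depth(T: int, n_hint: int | None = None) -> int:
    """Default Hankel depth r for a length-T trajectory: the square-ish
    split r = max(n_hint + 1, floor(T/3)) capped at floor((T-1)/2), so that
    the Hankel matrix has j = r + 1 block rows and k = T - r block columns."""
    cap = (T - 1) // 2
    r = T // 3
    if n_hint is not None:
        r = max(n_hint + 1, r)
    return max(1, min(r, cap))
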