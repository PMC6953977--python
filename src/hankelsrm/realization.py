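"""Deterministic subspace realization of LTI systems and the continuous
behavior-prediction pipeline.

Given (cleaned) outputs ``Y`` and inputs ``U``, the system order is the rank
of the output Hankel matrix projected onto the nullspace of the input Hankel
matrix.  A rank-n factorization of that projection yields the extended
observability matrix, from which ``C`` (first block row) and ``A`` (shift
invariance least squares) follow; ``B``, ``D`` and the initial state are the
solution of the linear system obtained by writing the output equation over
the training horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .hankel import HankelSpec, default_depth, hankel_map
from .metrics import pearson_cor
from .solver import SolverConfig, SRMProblem, solve_admm, tune_lambda

__all__ = [
    "StateSpaceModel",
    "nullspace_basis",
    "realize",
    "simulate",
    "predict_behavior",
    "PredictionResult",
]


@dataclass
class StateSpaceModel:
    """Discrete-time LTI system x[t+1] = A x[t] + B u[t], y[t] = C x[t] + D u[t]."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D_mat: np.ndarray
    x0: np.ndarray
    order: int

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float).reshape(self.order, self.order)
        self.D_mat = np.atleast_2d(np.asarray(self.D_mat, dtype=float))
        C = np.asarray(self.C, dtype=float)
        if self.order == 0:
            self.C = C.reshape(self.D_mat.shape[0], 0)
        else:
            self.C = C.reshape(-1, self.order)
        self.B = np.asarray(self.B, dtype=float).reshape(
            self.order, self.D_mat.shape[1]
        )
        self.x0 = np.asarray(self.x0, dtype=float).reshape(self.order)

    @property
    def n_outputs(self) -> int:
        return self.C.shape[0] if self.order else self.D_mat.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.D_mat.shape[1]

    @property
    def spectral_radius(self) -> float:
        if self.order == 0:
            return 0.0
        return float(np.max(np.abs(np.linalg.eigvals(self.A))))


def nullspace_basis(H_U: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the (right) nullspace of ``H_U`` via SVD, with
    numerical-rank tolerance max(dim) * eps * sigma_max."""
    H_U = np.asarray(H_U, dtype=float)
    if np.linalg.norm(H_U) == 0:
        raise ValueError("input Hankel matrix is zero; nullspace is everything")
    U, s, Vt = linalg.svd(H_U)
    tol = max(H_U.shape) * np.finfo(float).eps * s[0]
    rank = int(np.sum(s > tol))
    if rank >= H_U.shape[1]:
        raise ValueError(
            "input Hankel matrix has a trivial nullspace; increase the number "
            "of block columns k (smaller depth r) or reduce the input dimension"
        )
    return Vt[rank:].T


def simulate(model: StateSpaceModel, U: np.ndarray | None = None,
             T: int | None = None) -> np.ndarray:
    """Exact forward recursion from ``x0``; returns an m x T output matrix."""
    if U is None:
        if T is None:
            raise ValueError("autonomous simulation requires T")
        U = np.zeros((model.n_inputs, T))
    U = np.atleast_2d(np.asarray(U, dtype=float))
    T = U.shape[1]
    m, n = model.n_outputs, model.order
    Y = np.zeros((m, T))
    x = model.x0.copy()
    for t in range(T):
        y = model.D_mat @ U[:, t] if model.n_inputs else np.zeros(m)
        if n:
            y = y + model.C @ x
            x = model.A @ x + (model.B @ U[:, t] if model.n_inputs else 0.0)
        Y[:, t] = y
    return Y


def _io_hankel(Y: np.ndarray, r: int) -> np.ndarray:
    m, T = Y.shape
    spec = HankelSpec(m=m, n_blk=1, j=r + 1, k=T - r)
    return hankel_map(Y, spec)


def realize(
    Y: np.ndarray,
    U: np.ndarray | None,
    order: int,
    r: int,
    ridge: float = 0.0,
) -> StateSpaceModel:
    """Realize a state-space model of the given order from output (and
    optionally input) trajectories using depth-``r`` Hankel matrices."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    m, T = Y.shape
    if order < 0:
        raise ValueError("order must be >= 0")
    if order and r <= order:
        raise ValueError("depth r must exceed the system order")
    if r + 1 >= T:
        raise ValueError("depth r too large for the trajectory length")
    d = 0
    if U is not None:
        U = np.atleast_2d(np.asarray(U, dtype=float))
        if U.shape[1] != T:
            raise ValueError("inputs and outputs must cover the same horizon")
        d = U.shape[0]

    if order == 0:
        D = np.zeros((m, d))
        if d:
            D = linalg.lstsq(U.T, Y.T)[0].T
        return StateSpaceModel(
            A=np.zeros((0, 0)), B=np.zeros((0, d)), C=np.zeros((m, 0)),
            D_mat=D, x0=np.zeros(0), order=0,
        )

    H_Y = _io_hankel(Y, r)
    if d:
        H_U = _io_hankel(U, r)
        # all-zero inputs: the nullspace is everything, no projection needed
        proj = H_Y @ nullspace_basis(H_U) if np.linalg.norm(H_U) > 0 else H_Y
    else:
        proj = H_Y
    Usvd, s, _ = linalg.svd(proj, full_matrices=False)
    if s.size > order and s[order] > 1e-8 * s[0]:
        warnings.warn(
            "projected output Hankel matrix is not numerically rank-"
            f"{order}; the data may be noisy or the inputs not persistently "
            "exciting",
            RuntimeWarning,
            stacklevel=2,
        )
    G = Usvd[:, :order] * np.sqrt(s[:order])  # extended observability matrix
    C = G[:m]
    G_up, G_down = G[:-m], G[m:]
    gram = G_up.T @ G_up
    cond = np.linalg.cond(gram)
    if cond > 1e12 or ridge > 0:
        if ridge == 0:
            ridge = 1e-10 * np.trace(gram) / max(order, 1)
            warnings.warn(
                "shift-invariance system is ill-conditioned; applying a "
                f"ridge of {ridge:.3g}",
                RuntimeWarning,
                stacklevel=2,
            )
        A = np.linalg.solve(gram + ridge * np.eye(order), G_up.T @ G_down)
    else:
        A = linalg.lstsq(G_up, G_down)[0]

    # Linear least squares for x0, B, D from the output equation over the
    # training horizon: y_t = C A^t x0 + sum_{s<t} C A^{t-1-s} B u_s + D u_t.
    n = order
    n_unknowns = n + n * d + m * d
    rows = np.zeros((m * T, n_unknowns))
    rhs = Y.T.reshape(-1)
    A_pow = np.eye(n)
    X_B = np.zeros((n, n * d))  # coefficient of x_t w.r.t. vec(B), row-major
    for t in range(T):
        block = rows[t * m : (t + 1) * m]
        block[:, :n] = C @ A_pow
        if d:
            block[:, n : n + n * d] = C @ X_B
            block[:, n + n * d :] = np.kron(np.eye(m), U[:, t])
            X_B = A @ X_B + np.kron(np.eye(n), U[:, t])
        A_pow = A @ A_pow
    theta = linalg.lstsq(rows, rhs)[0]
    x0 = theta[:n]
    B = theta[n : n + n * d].reshape(n, d) if d else np.zeros((n, 0))
    D = theta[n + n * d :].reshape(m, d) if d else np.zeros((m, 0))
    return StateSpaceModel(A=A, B=B, C=C, D_mat=D, x0=x0, order=n)


@dataclass
class PredictionResult:
    """Output of the end-to-end behavior-prediction pipeline."""

    Y_pred: np.ndarray
    Y_full: np.ndarray
    model: StateSpaceModel
    rank_estimate: int
    lam: float
    lam_scores: np.ndarray | None = None
    solver_result: object = field(default=None, repr=False)


def _fit_once(
    Y: np.ndarray,
    U: np.ndarray | None,
    r: int,
    p: float,
    q: float,
    lam: float,
    config: SolverConfig,
    order: int | None,
):
    """Denoise the outputs, estimate the order, realize a model."""
    m, T = Y.shape
    gamma = None
    if U is not None and U.shape[0] > 0:
        H_U = _io_hankel(U, r)
        if np.linalg.norm(H_U) > 0:
            gamma = nullspace_basis(H_U)  # zero inputs: nullspace is everything
    spec = HankelSpec(m=m, n_blk=1, j=r + 1, k=T - r, gamma=gamma)
    problem = SRMProblem(M=Y, spec=spec, p=p, q=q, lam=lam)
    result = solve_admm(problem, config)
    n_est = result.rank_estimate if order is None else order
    n_est = min(n_est, r - 1) if n_est else n_est
    model = realize(result.L, U, order=n_est, r=r)
    return model, result, n_est


def predict_behavior(
    Y_train: np.ndarray,
    U_train: np.ndarray | None,
    U_test: np.ndarray | None,
    p: float = 0.5,
    q: float = 0.5,
    lam: float | None = None,
    lam_grid=None,
    r: int | None = None,
    order: int | None = None,
    config: SolverConfig | None = None,
) -> PredictionResult:
    """End-to-end continuous prediction: denoise the training outputs via
    structured rank minimization (with the Hankel map projected onto the
    nullspace of the input Hankel matrix), estimate the order, realize a
    state-space model, and simulate over the full train+test horizon.

    When ``lam_grid`` is given, lambda is tuned by refitting on the first
    ``T_train - 2r`` samples and scoring hold-out Pearson correlation on the
    trailing ``2r`` training samples; ties resolve to the smallest lambda.
    """
    Y_train = np.atleast_2d(np.asarray(Y_train, dtype=float))
    m, T_train = Y_train.shape
    if U_train is not None:
        U_train = np.atleast_2d(np.asarray(U_train, dtype=float))
        U_test = np.atleast_2d(np.asarray(U_test, dtype=float))
        if U_train.shape[1] != T_train:
            raise ValueError("U_train must align with Y_train")
        T_test = U_test.shape[1]
        U_full = np.hstack([U_train, U_test])
    else:
        # autonomous: U_test is an integer prediction horizon (or None)
        T_test = int(U_test) if U_test is not None else 0
        U_full = None
    if config is None:
        config = SolverConfig()
    if r is None:
        r = default_depth(T_train, order)

    lam_scores = None
    if lam is None:
        if lam_grid is None:
            raise ValueError("provide either lam or lam_grid")
        T_fit = T_train - 2 * r
        if T_fit <= r + 1:
            raise ValueError(
                "not enough training samples to hold out 2r for validation; "
                "reduce the depth r"
            )
        Y_fit = Y_train[:, :T_fit]
        U_fit = U_train[:, :T_fit] if U_train is not None else None
        U_val = U_train[:, :T_train] if U_train is not None else None
        Y_val = Y_train[:, T_fit:]
        if np.std(Y_val) == 0:
            raise ValueError("validation target is constant; cannot tune lambda")

        def scorer(lam_c: float) -> float:
            try:
                model, _, _ = _fit_once(Y_fit, U_fit, r, p, q, lam_c, config, order)
                Y_hat = simulate(model, U_val, T=T_train)
                return pearson_cor(Y_hat[:, T_fit:], Y_val)
            except (ValueError, FloatingPointError):
                return -np.inf

        lam, _, lam_scores = tune_lambda(lam_grid, scorer)

    model, result, n_est = _fit_once(Y_train, U_train, r, p, q, lam, config, order)
    T_full = T_train + T_test
    Y_full = simulate(model, U_full, T=T_full)
    return PredictionResult(
        Y_pred=Y_full[:, T_train:],
        Y_full=Y_full,
        model=model,
        rank_estimate=n_est,
        lam=float(lam),
        lam_scores=lam_scores,
        solver_result=result,
    )
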