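"""ADMM solvers for l_q-regularized Schatten-p Hankel structured rank
minimization.

The optimization problem decomposes an observed trajectory ``M`` (channels x
time) into a component ``L`` whose block-Hankel matrix is low rank and a
sparse corruption ``E``:

    min_{N,L,E}  ||N||_Sp^p + lam * ||W o E||_q^q
    s.t.         M = L + E,   N = H(L),

with Schatten exponent ``p`` in (0, 1], sparsity exponent ``q`` in (0, 1]
(or q = 2 for a plain Frobenius data fit), and an entrywise weight/mask
``W`` encoding missing observations.  The augmented Lagrangian is minimized
block-wise: ``E`` by (weighted) generalized q-shrinkage, ``N`` by singular
value p-shrinkage, and ``L`` in closed form after adding a proximal term in
the semi-norm induced by Q0 = L_bound*I - H*H, which cancels the quadratic
coupling through the Hankel map.  A scalable variant replaces ``N`` by an
orthonormal-times-low-rank factorization ``Q R`` with ``K`` columns,
updating ``Q`` by the Procrustes projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .hankel import HankelSpec, adjoint_norm_bound, hankel_adjoint, hankel_map
from .operators import procrustes, q_shrink, weighted_q_shrink

__all__ = [
    "SRMProblem",
    "SolverConfig",
    "SRMResult",
    "solve_admm",
    "solve_admm_scalable",
    "check_convergence",
    "estimate_rank",
    "tune_lambda",
]


@dataclass
class SRMProblem:
    """Problem data: observations, mask, Hankel geometry and exponents."""

    M: np.ndarray
    spec: HankelSpec
    p: float = 1.0
    q: float = 1.0
    lam: float = 1.0
    W: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.spec.validate_trajectory(self.M)
        if self.W is None:
            self.W = np.ones_like(self.M)
        else:
            self.W = np.asarray(self.W, dtype=float)
            if self.W.shape != self.M.shape:
                raise ValueError("mask W must have the same shape as M")
            if (self.W < 0).any():
                raise ValueError("mask W must be nonnegative")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must lie in (0, 1]")
        if not (0.0 < self.q <= 1.0 or self.q == 2.0):
            raise ValueError("q must lie in (0, 1] or equal 2")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if not np.isfinite(self.M[self.W > 0]).all():
            raise ValueError("observed entries of M must be finite")


@dataclass
class SolverConfig:
    """ADMM hyper-parameters.

    The penalty schedule mu[0] = 1/||M||_2, mu[i+1] = min(mu_max,
    mu_growth * mu[i]) follows standard inexact augmented Lagrangian
    practice.  ``init`` selects the trajectory initialization: "scaled"
    (1.1 * M), "zeros", "gaussian", or an explicit array.
    """

    mu0: float | None = None
    mu_growth: float = 1.1
    mu_max: float = 1e10
    eps1: float = 1e-4
    eps2: float = 1e-7
    max_iter: int = 1000
    K: int | None = None
    init: str | np.ndarray = "scaled"
    rank_rel_tol: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu0 is not None and self.mu0 <= 0:
            raise ValueError("mu0 must be positive")
        if self.mu_growth < 1:
            raise ValueError("mu_growth must be >= 1")
        if self.eps1 <= 0 or self.eps2 <= 0:
            raise ValueError("eps1 and eps2 must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.K is not None and self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass
class SRMResult:
    """Solver output: the decomposition, rank estimate and diagnostics."""

    L: np.ndarray
    E: np.ndarray
    N: np.ndarray
    rank_estimate: int
    objective_trace: np.ndarray
    residual_trace: np.ndarray
    converged: bool
    iterations: int
    singular_values: np.ndarray = field(default=None)  # type: ignore[assignment]
    Q: np.ndarray | None = None
    R: np.ndarray | None = None


def _initial_L(problem: SRMProblem, config: SolverConfig) -> np.ndarray:
    if isinstance(config.init, np.ndarray):
        L0 = np.asarray(config.init, dtype=float)
        if L0.shape != problem.M.shape:
            raise ValueError("init array must have the same shape as M")
        return L0.copy()
    M0 = np.where(problem.W > 0, problem.M, 0.0)
    if config.init == "scaled":
        return 1.1 * M0
    if config.init == "zeros":
        return np.zeros_like(M0)
    if config.init == "gaussian":
        rng = np.random.default_rng(config.seed)
        return rng.standard_normal(M0.shape)
    raise ValueError(f"unknown init {config.init!r}")


def _update_E(V: np.ndarray, lam: float, mu: float, W: np.ndarray, q: float):
    """E block update: prox of (lam/mu) * ||W o E||_q^q at V."""
    if q == 2.0:
        # closed-form quadratic: lam*(w*e)^2/mu + (e - v)^2/2 minimized
        return V / (1.0 + 2.0 * lam * W**2 / mu)
    return weighted_q_shrink(V, lam / mu, W, q)


def _shrink_N(Z: np.ndarray, alpha: float, p: float):
    """Singular value p-shrinkage returning the shrunk spectrum as well."""
    U, s, Vt = linalg.svd(Z, full_matrices=False)
    s_shrunk = q_shrink(s, alpha, p)
    return (U * s_shrunk) @ Vt, s_shrunk


def check_convergence(
    state: dict,
    prev_state: dict,
    M: np.ndarray,
    eps1: float,
    eps2: float,
) -> bool:
    """Stopping rule: both feasibility residuals and all three iterate
    changes, each relative to ||M||_F, strictly below their tolerances."""
    normM = float(np.linalg.norm(M))
    if normM == 0.0:
        normM = 1.0  # absolute residuals for the degenerate all-zero input
    r_feas = max(
        np.linalg.norm(M - state["L"] - state["E"]),
        np.linalg.norm(state["N"] - state["HL"]),
    )
    r_change = max(
        np.linalg.norm(state["N"] - prev_state["N"]),
        np.linalg.norm(state["L"] - prev_state["L"]),
        np.linalg.norm(state["E"] - prev_state["E"]),
    )
    return bool(r_feas / normM < eps1 and r_change / normM < eps2)


def estimate_rank(N: np.ndarray, rel_tol: float = 1e-3) -> int:
    """Numerical rank: singular values above rel_tol times the largest."""
    N = np.asarray(N, dtype=float)
    if not np.isfinite(N).all():
        raise ValueError("matrix contains non-finite entries")
    s = linalg.svdvals(N)
    if s.size == 0 or s[0] == 0.0:
        return 0
    return int(np.sum(s > rel_tol * s[0]))


def _objective(s_shrunk: np.ndarray, p: float, E: np.ndarray, W: np.ndarray,
               lam: float, q: float) -> float:
    schatten = float(np.sum(s_shrunk**p))
    WE = W * E
    if q == 2.0:
        sparse = float(np.sum(WE**2))
    else:
        sparse = float(np.sum(np.abs(WE) ** q))
    return schatten + lam * sparse


def solve_admm(problem: SRMProblem, config: SolverConfig | None = None) -> SRMResult:
    """Full ADMM solver (Algorithm 1 shape): alternates the E, N and L block
    updates, then the multiplier and penalty updates, until the relative
    feasibility and iterate-change criteria are met or ``max_iter`` is hit.
    """
    if config is None:
        config = SolverConfig()
    M, W, spec = problem.M, problem.W, problem.spec
    M_filled = np.where(W > 0, M, 0.0)
    Lb = adjoint_norm_bound(spec)
    L = _initial_L(problem, config)
    E = np.zeros_like(M_filled)
    Lam1 = np.zeros_like(M_filled)
    Lam2 = np.zeros((spec.n_rows, spec.n_cols))
    N = np.zeros_like(Lam2)
    norm_spec = np.linalg.norm(M_filled, 2)
    mu = config.mu0 if config.mu0 is not None else (
        1.0 / norm_spec if norm_spec > 0 else 1.0
    )
    HL = hankel_map(L, spec)
    objective_trace, residual_trace = [], []
    converged = False
    s_shrunk = np.zeros(min(Lam2.shape))
    it = 0
    for it in range(1, config.max_iter + 1):
        prev = {"L": L, "E": E, "N": N}
        E = _update_E(M_filled - L + Lam1 / mu, problem.lam, mu, W, problem.q)
        N, s_shrunk = _shrink_N(HL - Lam2 / mu, 1.0 / mu, problem.p)
        L = (
            (M_filled - E + Lam1 / mu)
            + hankel_adjoint(N + Lam2 / mu, spec)
            + Lb * L
            - hankel_adjoint(HL, spec)
        ) / (1.0 + Lb)
        HL = hankel_map(L, spec)
        Lam1 = Lam1 + mu * (M_filled - L - E)
        Lam2 = Lam2 + mu * (N - HL)
        if not (np.isfinite(L).all() and np.isfinite(E).all()):
            raise FloatingPointError(
                f"non-finite iterate at iteration {it} (mu={mu:.3g}); "
                "consider a smaller mu_growth or rescaled data"
            )
        objective_trace.append(
            _objective(s_shrunk, problem.p, E, W, problem.lam, problem.q)
        )
        residual_trace.append(float(np.linalg.norm(M_filled - L - E)))
        state = {"L": L, "E": E, "N": N, "HL": HL}
        converged = check_convergence(state, prev, M_filled, config.eps1, config.eps2)
        mu = min(config.mu_max, config.mu_growth * mu)
        if converged:
            break
    return SRMResult(
        L=L,
        E=E,
        N=N,
        rank_estimate=int(np.sum(s_shrunk > config.rank_rel_tol * s_shrunk.max()))
        if s_shrunk.size and s_shrunk.max() > 0
        else 0,
        objective_trace=np.asarray(objective_trace),
        residual_trace=np.asarray(residual_trace),
        converged=converged,
        iterations=it,
        singular_values=s_shrunk,
    )


def solve_admm_scalable(
    problem: SRMProblem, config: SolverConfig | None = None
) -> SRMResult:
    """Scalable ADMM solver (Algorithm 2 shape): the low-rank surrogate is
    factorized as H(L) ~ Q R with column-orthonormal Q (n_rows x K).  The R
    block is updated by singular value p-shrinkage of Q^T(H(L) - Lam2/mu)
    (valid since ||Q R||_Sp = ||R||_Sp for orthonormal Q) and Q by the
    Procrustes projection of (H(L) - Lam2/mu) R^T."""
    if config is None:
        config = SolverConfig()
    if config.K is None:
        raise ValueError("the scalable solver requires config.K")
    M, W, spec = problem.M, problem.W, problem.spec
    K = config.K
    if K > min(spec.n_rows, spec.n_cols):
        raise ValueError(
            f"K={K} exceeds min Hankel dimension {min(spec.n_rows, spec.n_cols)}"
        )
    M_filled = np.where(W > 0, M, 0.0)
    Lb = adjoint_norm_bound(spec)
    L = _initial_L(problem, config)
    E = np.zeros_like(M_filled)
    Lam1 = np.zeros_like(M_filled)
    Lam2 = np.zeros((spec.n_rows, spec.n_cols))
    HL = hankel_map(L, spec)
    U0, _, _ = linalg.svd(HL, full_matrices=False)
    Q = U0[:, :K]
    if Q.shape[1] < K:  # degenerate, pad with an orthonormal completion
        Q = np.linalg.qr(np.hstack([Q, np.eye(spec.n_rows, K - Q.shape[1])]))[0][:, :K]
    R = Q.T @ HL
    N = Q @ R
    norm_spec = np.linalg.norm(M_filled, 2)
    mu = config.mu0 if config.mu0 is not None else (
        1.0 / norm_spec if norm_spec > 0 else 1.0
    )
    objective_trace, residual_trace = [], []
    converged = False
    s_shrunk = np.zeros(K)
    it = 0
    for it in range(1, config.max_iter + 1):
        prev = {"L": L, "E": E, "N": N}
        E = _update_E(M_filled - L + Lam1 / mu, problem.lam, mu, W, problem.q)
        Z = HL - Lam2 / mu
        R, s_shrunk = _shrink_N(Q.T @ Z, 1.0 / mu, problem.p)
        ZRt = Z @ R.T
        if np.linalg.norm(ZRt) > 0:
            Q = procrustes(ZRt)
        N = Q @ R
        L = (
            (M_filled - E + Lam1 / mu)
            + hankel_adjoint(N + Lam2 / mu, spec)
            + Lb * L
            - hankel_adjoint(HL, spec)
        ) / (1.0 + Lb)
        HL = hankel_map(L, spec)
        Lam1 = Lam1 + mu * (M_filled - L - E)
        Lam2 = Lam2 + mu * (N - HL)
        if not (np.isfinite(L).all() and np.isfinite(E).all()):
            raise FloatingPointError(
                f"non-finite iterate at iteration {it} (mu={mu:.3g})"
            )
        objective_trace.append(
            _objective(s_shrunk, problem.p, E, W, problem.lam, problem.q)
        )
        residual_trace.append(float(np.linalg.norm(M_filled - L - E)))
        state = {"L": L, "E": E, "N": N, "HL": HL}
        converged = check_convergence(state, prev, M_filled, config.eps1, config.eps2)
        mu = min(config.mu_max, config.mu_growth * mu)
        if converged:
            break
    return SRMResult(
        L=L,
        E=E,
        N=N,
        rank_estimate=int(np.sum(s_shrunk > config.rank_rel_tol * s_shrunk.max()))
        if s_shrunk.size and s_shrunk.max() > 0
        else 0,
        objective_trace=np.asarray(objective_trace),
        residual_trace=np.asarray(residual_trace),
        converged=converged,
        iterations=it,
        singular_values=s_shrunk,
        Q=Q,
        R=R,
    )


def tune_lambda(lambda_grid, scorer):
    """Grid search over the regularization weight.

    Parameters
    ----------
    lambda_grid : sequence of float
        Candidate values (e.g. ``np.logspace(-3, 0, 150)``).
    scorer : callable
        ``scorer(lam) -> float`` returning a validation score (higher is
        better, typically a hold-out Pearson correlation).

    Returns
    -------
    best_lam, best_score, scores : float, float, ndarray
        Ties resolve to the smallest lambda.
    """
    grid = np.asarray(list(lambda_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    order = np.argsort(grid)
    scores = np.full(grid.size, -np.inf)
    best_lam, best_score = None, -math.inf
    for idx in order:
        lam = float(grid[idx])
        score = float(scorer(lam))
        scores[idx] = score
        if np.isfinite(score) and score > best_score:
            best_lam, best_score = lam, score
    if best_lam is None:
        raise ValueError("no lambda in the grid produced a finite score")
    return best_lam, best_score, scores
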