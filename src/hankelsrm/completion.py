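"""Hankel structured completion of trajectories with missing entries.

Missing observations enter through the weight matrix ``W`` (zero weight =
unpenalized corruption = free entry), so the same solver both denoises the
observed entries and imputes the missing ones: the recovered ``L`` is forced
to follow the low-order linear dynamics of the observed part.
"""

from __future__ import annotations

import numpy as np

from .hankel import HankelSpec, default_depth
from .solver import SolverConfig, SRMProblem, solve_admm, tune_lambda

__all__ = [
    "build_mask",
    "complete_trajectory",
    "tune_lambda_completion",
    "CompletionResult",
]


def build_mask(D: int, T: int, observed) -> np.ndarray:
    """Binary observation mask: 1 at the (channel, time) pairs in
    ``observed``, 0 elsewhere."""
    W = np.zeros((D, T))
    for i, j in observed:
        if not (0 <= i < D and 0 <= j < T):
            raise IndexError(f"index ({i}, {j}) outside a {D} x {T} trajectory")
        W[i, j] = 1.0
    return W


class CompletionResult:
    """Completed trajectory plus the underlying solver diagnostics."""

    def __init__(self, completed, rank_estimate, solver_result):
        self.completed = completed
        self.rank_estimate = rank_estimate
        self.solver_result = solver_result


def complete_trajectory(
    M: np.ndarray,
    W: np.ndarray,
    spec: HankelSpec | None = None,
    p: float = 0.5,
    q: float = 2.0,
    lam: float = 1.0,
    config: SolverConfig | None = None,
    r: int | None = None,
) -> CompletionResult:
    """Recover missing entries of a trajectory by structured rank
    minimization.  ``M`` may stack outputs over inputs (D = m + d) when
    inputs exist; missing entries carry zero weight in ``W``.

    The completed trajectory is the low-rank component ``L`` (equivalently,
    the skew-diagonal average of the Hankel matrix H(L)); observed entries
    are preserved up to the solver's sparse correction.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    W = np.atleast_2d(np.asarray(W, dtype=float))
    D, T = M.shape
    if (W.sum(axis=1) == 0).any():
        raise ValueError("at least one channel has no observed entries")
    if spec is None:
        if r is None:
            r = default_depth(T)
        spec = HankelSpec(m=D, n_blk=1, j=r + 1, k=T - r)
    problem = SRMProblem(M=M, spec=spec, p=p, q=q, lam=lam, W=W)
    result = solve_admm(problem, config)
    return CompletionResult(
        completed=result.L,
        rank_estimate=result.rank_estimate,
        solver_result=result,
    )


def tune_lambda_completion(
    M: np.ndarray,
    W: np.ndarray,
    lambda_grid,
    spec: HankelSpec | None = None,
    p: float = 0.5,
    q: float = 0.5,
    config: SolverConfig | None = None,
    holdout_frac: float = 0.1,
    seed: int = 0,
    r: int | None = None,
):
    """Entry hold-out cross-validation for the regularization weight.

    A random ``holdout_frac`` of the observed entries is masked out; for each
    candidate lambda the solver completes the trajectory and is scored by the
    negative reconstruction error on the held-out entries (against their
    observed, possibly noisy, values).  Ties resolve to the smallest lambda.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    W = np.atleast_2d(np.asarray(W, dtype=float))
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(W > 0)
    n_hold = max(1, int(round(holdout_frac * len(obs_idx))))
    hold = obs_idx[rng.choice(len(obs_idx), size=n_hold, replace=False)]
    W_cv = W.copy()
    W_cv[hold[:, 0], hold[:, 1]] = 0.0
    if (W_cv.sum(axis=1) == 0).any():
        raise ValueError("hold-out left a channel with no observed entries")
    held_vals = M[hold[:, 0], hold[:, 1]]

    def scorer(lam: float) -> float:
        try:
            res = complete_trajectory(
                M, W_cv, spec=spec, p=p, q=q, lam=lam, config=config, r=r
            )
        except FloatingPointError:
            return -np.inf
        pred = res.completed[hold[:, 0], hold[:, 1]]
        return -float(np.linalg.norm(pred - held_vals))

    return tune_lambda(lambda_grid, scorer)
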