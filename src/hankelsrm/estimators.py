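"""scikit-learn style estimators over the structured rank minimization core.

`HankelRankMinimizer` is a transformer-shaped robust denoiser/decomposer
(low-rank-dynamics plus sparse corruption), `BehaviorPredictor` a
regressor-shaped wrapper around the LTI prediction pipeline.  Both follow
the usual conventions: constructor stores hyper-parameters verbatim, `fit`
validates input and sets trailing-underscore attributes, `get_params` /
`set_params` come from ``BaseEstimator`` so they compose with pipelines and
model selection.  Samples are rows (time along axis 0), matching the
``(n_samples, n_features)`` convention; trajectories are transposed to
channels x time internally.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .hankel import HankelSpec, default_depth
from .realization import predict_behavior, simulate
from .solver import SolverConfig, SRMProblem, solve_admm, solve_admm_scalable

__all__ = ["HankelRankMinimizer", "BehaviorPredictor"]


class HankelRankMinimizer(TransformerMixin, BaseEstimator):
    """Robust decomposition of a multichannel time series into a component
    with low-rank Hankel structure and a sparse corruption.

    Parameters
    ----------
    p : float, default=1.0
        Schatten exponent in (0, 1]; values below 1 give the non-convex
        rank surrogate.
    q : float, default=1.0
        Sparsity exponent in (0, 1], or 2 for a plain Frobenius data fit.
    lam : float, default=1.0
        Weight of the sparsity term.
    r : int or None
        Hankel depth (block rows minus one); defaults to the square-ish
        split of the trajectory length.
    scalable : bool, default=False
        Use the factorized solver with ``K`` orthonormal columns.
    K : int or None
        Factor rank for the scalable solver.

    Attributes
    ----------
    low_rank_ : ndarray of shape (n_samples, n_features)
        Denoised trajectory (the component with low-rank Hankel matrix).
    sparse_ : ndarray of shape (n_samples, n_features)
        Estimated sparse corruption.
    rank_ : int
        Estimated system order (numerical rank of the Hankel surrogate).
    n_iter_ : int
    converged_ : bool
    objective_trace_, residual_trace_ : ndarray
    """

    def __init__(
        self,
        p: float = 1.0,
        q: float = 1.0,
        lam: float = 1.0,
        r: int | None = None,
        scalable: bool = False,
        K: int | None = None,
        mask=None,
        mu0: float | None = None,
        mu_growth: float = 1.1,
        mu_max: float = 1e10,
        eps1: float = 1e-4,
        eps2: float = 1e-7,
        max_iter: int = 1000,
        init="scaled",
        rank_rel_tol: float = 1e-3,
        random_state: int = 0,
    ):
        self.p = p
        self.q = q
        self.lam = lam
        self.r = r
        self.scalable = scalable
        self.K = K
        self.mask = mask
        self.mu0 = mu0
        self.mu_growth = mu_growth
        self.mu_max = mu_max
        self.eps1 = eps1
        self.eps2 = eps2
        self.max_iter = max_iter
        self.init = init
        self.rank_rel_tol = rank_rel_tol
        self.random_state = random_state

    def _config(self) -> SolverConfig:
        return SolverConfig(
            mu0=self.mu0,
            mu_growth=self.mu_growth,
            mu_max=self.mu_max,
            eps1=self.eps1,
            eps2=self.eps2,
            max_iter=self.max_iter,
            K=self.K,
            init=self.init,
            rank_rel_tol=self.rank_rel_tol,
            seed=self.random_state,
        )

    def _solve(self, X: np.ndarray):
        M = X.T  # channels x time
        T = M.shape[1]
        r = self.r if self.r is not None else default_depth(T)
        spec = HankelSpec(m=M.shape[0], n_blk=1, j=r + 1, k=T - r)
        W = None if self.mask is None else np.asarray(self.mask, dtype=float).T
        problem = SRMProblem(M=M, spec=spec, p=self.p, q=self.q, lam=self.lam, W=W)
        solver = solve_admm_scalable if self.scalable else solve_admm
        return solver(problem, self._config())

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=3)
        result = self._solve(X)
        self.low_rank_ = result.L.T
        self.sparse_ = result.E.T
        self.rank_ = result.rank_estimate
        self.n_iter_ = result.iterations
        self.converged_ = result.converged
        self.objective_trace_ = result.objective_trace
        self.residual_trace_ = result.residual_trace
        self.singular_values_ = result.singular_values
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Denoise a trajectory: returns the low-rank-dynamics component."""
        check_is_fitted(self, "rank_")
        X = check_array(X, ensure_min_samples=3)
        if X.shape == self.low_rank_.shape and np.allclose(
            X, self.low_rank_ + self.sparse_
        ):
            return self.low_rank_
        return self._solve(X).L.T

    def fit_transform(self, X, y=None):
        return self.fit(X).low_rank_


class BehaviorPredictor(RegressorMixin, BaseEstimator):
    """Continuous behavior prediction from a learned low-order LTI system.

    ``fit(X, y)`` takes per-frame features ``X`` (n_frames, n_features) as
    system inputs and continuous annotations ``y`` (n_frames,) or
    (n_frames, n_outputs) as system outputs, denoises the outputs by
    structured rank minimization, realizes a state-space model of the
    estimated order, and ``predict(X_test)`` simulates the model over the
    concatenated train+test horizon, returning the test segment.
    """

    def __init__(
        self,
        p: float = 0.5,
        q: float = 0.5,
        lam: float | None = None,
        lam_grid=None,
        r: int | None = None,
        order: int | None = None,
        eps1: float = 1e-4,
        eps2: float = 1e-7,
        max_iter: int = 1000,
        random_state: int = 0,
    ):
        self.p = p
        self.q = q
        self.lam = lam
        self.lam_grid = lam_grid
        self.r = r
        self.order = order
        self.eps1 = eps1
        self.eps2 = eps2
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = check_array(X)
        y = np.asarray(y, dtype=float)
        self._single_output = y.ndim == 1
        Y = np.atleast_2d(y.T if y.ndim > 1 else y)
        if Y.shape[1] != X.shape[0]:
            raise ValueError("X and y must have the same number of frames")
        config = SolverConfig(
            eps1=self.eps1, eps2=self.eps2, max_iter=self.max_iter,
            seed=self.random_state,
        )
        lam = self.lam
        lam_grid = self.lam_grid
        if lam is None and lam_grid is None:
            lam_grid = np.logspace(-3, 0, 20)
        res = predict_behavior(
            Y_train=Y,
            U_train=X.T,
            U_test=np.zeros((X.shape[1], 0)),
            p=self.p,
            q=self.q,
            lam=lam,
            lam_grid=lam_grid,
            r=self.r,
            order=self.order,
            config=config,
        )
        self.model_ = res.model
        self.rank_ = res.rank_estimate
        self.lam_ = res.lam
        self.train_fit_ = res.Y_full
        self._X_train = X
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        """Simulate over the full train+test horizon; returns predictions
        for the ``X`` frames, assumed to follow the training frames."""
        check_is_fitted(self, "model_")
        X = check_array(X)
        T_train = self._X_train.shape[0]
        U_full = np.vstack([self._X_train, X]).T
        Y_full = simulate(self.model_, U_full)
        Y_pred = Y_full[:, T_train:]
        return Y_pred.ravel() if self._single_output else Y_pred.T
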