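"""ADMM solver: recovery oracles, convergence rule, rank estimation."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from hankelsrm.hankel import HankelSpec, hankel_map
from hankelsrm.solver import (
    SolverConfig,
    SRMProblem,
    check_convergence,
    estimate_rank,
    solve_admm,
    solve_admm_scalable,
    tune_lambda,
)
from hankelsrm.solver import _update_E
from hankelsrm.synthetic import benchmark_spec, generate_outputs, make_instance


def clean_problem(order, T=60, lam=100.0, p=0.5, q=0.5, seed=0):
    inst = make_instance(order, T=T, rho=0.0, seed=seed)
    spec = benchmark_spec(T)
    return inst, SRMProblem(M=inst.y, spec=spec, p=p, q=q, lam=lam)


def test_zero_input_gives_zero_solution():
    spec = benchmark_spec(20)
    result = solve_admm(
        SRMProblem(M=np.zeros((1, 20)), spec=spec, p=0.5, q=0.5, lam=1.0)
    )
    np.testing.assert_array_equal(result.L, np.zeros((1, 20)))
    np.testing.assert_array_equal(result.E, np.zeros((1, 20)))
    assert result.objective_trace[-1] == 0.0


@pytest.mark.parametrize("order", [2, 4])
def test_clean_signal_exact_recovery(order):
    """Noiseless low-order signals: E ~ 0 and the rank estimate is exact."""
    inst, problem = clean_problem(order)
    result = solve_admm(problem)
    assert result.rank_estimate == order
    assert np.linalg.norm(result.E) <= 1e-4 * np.linalg.norm(inst.y)
    assert np.linalg.norm(result.L - inst.y) <= 1e-4 * np.linalg.norm(inst.y)


def test_check_convergence_rule():
    M = np.ones((2, 6))
    spec = HankelSpec(m=2, n_blk=1, j=3, k=4)
    L = 0.5 * M
    state = {"L": L, "E": M - L, "N": hankel_map(L, spec),
             "HL": hankel_map(L, spec)}
    assert check_convergence(state, dict(state), M, 1e-4, 1e-7)
    # first step from a different previous state: change ratios too large
    prev = {"L": np.zeros_like(M), "E": np.zeros_like(M),
            "N": np.zeros_like(state["N"])}
    assert not check_convergence(state, prev, M, 1e-4, 1e-7)


def test_check_convergence_strict_at_boundary():
    """A residual ratio exactly at eps1 does not terminate (strict <)."""
    M = np.zeros((1, 3))
    M[0, 0] = 1.0  # ||M||_F = 1
    spec = HankelSpec(m=1, n_blk=1, j=2, k=2)
    eps1 = 0.25
    L = M.copy()
    E = np.zeros_like(M)
    E[0, 1] = eps1  # feasibility residual norm exactly eps1 * ||M||
    state = {"L": L, "E": E, "N": hankel_map(L, spec), "HL": hankel_map(L, spec)}
    assert not check_convergence(state, dict(state), M, eps1, 1e-7)
    assert check_convergence(state, dict(state), M, eps1 + 1e-12, 1e-7)


def test_estimate_rank():
    assert estimate_rank(np.zeros((4, 4))) == 0
    assert estimate_rank(np.diag([1.0, 1e-6]), rel_tol=1e-3) == 1
    y = generate_outputs(
        np.array([0.8 * np.exp(1j * 0.7), 0.8 * np.exp(-1j * 0.7),
                  0.6 * np.exp(1j * 1.9), 0.6 * np.exp(-1j * 1.9),
                  0.9 * np.exp(1j * 1.2), 0.9 * np.exp(-1j * 1.2)]), 60
    )
    H = hankel_map(y, benchmark_spec(60))
    assert estimate_rank(H) == 6


def test_q2_update_matches_scalar_quadratic_oracle(rng):
    """The closed-form q=2 data-fit update solves each entry's quadratic."""
    V = rng.standard_normal((3, 4))
    W = rng.random((3, 4))
    lam, mu = 0.7, 2.3
    out = _update_E(V, lam, mu, W, 2.0)
    for i in range(3):
        for j in range(4):
            res = minimize_scalar(
                lambda e: lam / mu * (W[i, j] * e) ** 2 + 0.5 * (e - V[i, j]) ** 2
            )
            assert abs(out[i, j] - res.x) < 1e-7


def test_masked_entries_are_free(rng):
    """Zero-weight (missing) entries are absorbed by E, leaving L smooth."""
    inst, problem = clean_problem(2, T=40)
    W = np.ones_like(inst.y)
    W[0, [5, 17, 30]] = 0.0
    M = inst.y.copy()
    M[0, [5, 17, 30]] = 0.0
    problem = SRMProblem(M=M, spec=problem.spec, p=0.5, q=0.5, lam=100.0, W=W)
    result = solve_admm(problem)
    np.testing.assert_allclose(result.L, inst.y, atol=1e-3)


def test_traces_monotone_after_transient():
    inst = make_instance(6, seed=3)
    spec = benchmark_spec(100)
    config = SolverConfig(max_iter=200, eps1=1e-12, eps2=1e-14)
    result = solve_admm(
        SRMProblem(M=inst.y_tilde, spec=spec, p=0.5, q=0.5, lam=0.3), config
    )
    assert result.residual_trace[-1] <= result.residual_trace[9]


def test_scalable_matches_full_solver_on_clean_data():
    inst, problem = clean_problem(4, T=60)
    full = solve_admm(problem)
    scal = solve_admm_scalable(problem, SolverConfig(K=8))
    rel = np.linalg.norm(full.L - scal.L) / np.linalg.norm(full.L)
    assert rel < 1e-3
    assert np.linalg.norm(scal.Q.T @ scal.Q - np.eye(8)) < 1e-8


def test_scalable_rank_one_capacity():
    """K = 1 suffices for a rank-1 (single real mode) Hankel trajectory."""
    T = 40
    y = 0.9 ** np.arange(1, T + 1)[None, :]
    spec = benchmark_spec(T)
    result = solve_admm_scalable(
        SRMProblem(M=y, spec=spec, p=0.5, q=0.5, lam=100.0), SolverConfig(K=1)
    )
    assert np.linalg.norm(result.L - y) <= 1e-4 * np.linalg.norm(y)


def test_scalable_requires_K():
    _, problem = clean_problem(2, T=30)
    with pytest.raises(ValueError, match="K"):
        solve_admm_scalable(problem, SolverConfig())


def test_nonconvergence_flag():
    inst = make_instance(6, seed=0)
    config = SolverConfig(max_iter=5)
    result = solve_admm(
        SRMProblem(M=inst.y_tilde, spec=benchmark_spec(100), p=0.5, q=0.5,
                   lam=0.5),
        config,
    )
    assert not result.converged
    assert result.iterations == 5


def test_tune_lambda_grid_rules():
    best, score, scores = tune_lambda([0.5], lambda lam: 1.0)
    assert best == 0.5 and score == 1.0
    # ties resolve to the smallest lambda
    best, _, _ = tune_lambda([1.0, 0.1, 0.5], lambda lam: 7.0)
    assert best == 0.1
    best, _, _ = tune_lambda([0.1, 0.2, 0.4], lambda lam: -abs(lam - 0.2))
    assert best == 0.2
    with pytest.raises(ValueError):
        tune_lambda([], lambda lam: 0.0)
    with pytest.raises(ValueError):
        tune_lambda([0.1, 1.0], lambda lam: float("nan"))


def test_problem_validation():
    spec = benchmark_spec(10)
    M = np.zeros((1, 10))
    with pytest.raises(ValueError):
        SRMProblem(M=M, spec=spec, p=1.5, q=0.5, lam=1.0)
    with pytest.raises(ValueError):
        SRMProblem(M=M, spec=spec, p=0.5, q=1.5, lam=1.0)
    with pytest.raises(ValueError):
        SRMProblem(M=M, spec=spec, p=0.5, q=0.5, lam=-1.0)
    with pytest.raises(ValueError):
        SRMProblem(M=M, spec=spec, p=0.5, q=0.5, lam=1.0, W=np.ones((2, 2)))
    # q = 2 is the allowed quadratic special case
    SRMProblem(M=M, spec=spec, p=0.5, q=2.0, lam=1.0)
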