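"""Proximal operators against brute-force and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hankelsrm.operators import (
    procrustes,
    q_shrink,
    soft_threshold,
    sv_p_shrink,
    weighted_q_shrink,
)


def h_value(b, z, alpha, q):
    return alpha * np.abs(b) ** q + 0.5 * (b - z) ** 2


def grid_minimize(z, alpha, q, lo=-6.0, hi=6.0):
    """Two-stage dense grid search for the scalar shrinkage subproblem."""
    b = np.arange(lo, hi, 1e-4)
    b0 = b[np.argmin(h_value(b, z, alpha, q))]
    b = np.arange(b0 - 2e-4, b0 + 2e-4, 1e-7)
    b = np.concatenate([b, [0.0]])  # the spike at zero matters for q < 1
    return b[np.argmin(h_value(b, z, alpha, q))]


@pytest.mark.parametrize("x,alpha,expected", [(3.0, 1.0, 2.0),
                                              (-0.5, 1.0, 0.0),
                                              (0.0, 5.0, 0.0),
                                              (-4.0, 1.5, -2.5)])
def test_soft_threshold_values(x, alpha, expected):
    assert soft_threshold(x, alpha) == expected


def test_soft_threshold_rejects_negative_alpha():
    with pytest.raises(ValueError):
        soft_threshold(1.0, -0.1)


@pytest.mark.parametrize("q", [0.1, 0.3, 0.5, 0.7, 0.9, 1.0])
@pytest.mark.parametrize("alpha", [0.2, 1.0, 3.0])
@pytest.mark.parametrize("z", [-4.0, -1.2, -0.3, 0.0, 0.5, 2.0, 5.0])
def test_q_shrink_matches_grid_search(q, alpha, z):
    expected = grid_minimize(z, alpha, q)
    got = q_shrink(z, alpha, q)
    # compare objective values: near the threshold the argmin jumps between
    # 0 and the root while h stays flat, so values are the robust comparison
    assert abs(h_value(got, z, alpha, q) - h_value(expected, z, alpha, q)) < 1e-8
    assert abs(got - expected) < 1e-5 or np.isclose(
        h_value(0.0, z, alpha, q), h_value(expected, z, alpha, q), atol=1e-8
    )


def test_q_shrink_reduces_to_soft_threshold_at_q1():
    z = np.linspace(-5, 5, 2001)
    np.testing.assert_array_equal(q_shrink(z, 0.7, 1.0), soft_threshold(z, 0.7))


def test_q_shrink_zero_below_threshold():
    alpha, q = 1.0, 0.5
    c1 = (alpha * q * (1 - q)) ** (1 / (2 - q))
    c2 = c1 + alpha * q * c1 ** (q - 1)
    z = np.linspace(-c2, c2, 101)
    np.testing.assert_array_equal(q_shrink(z, alpha, q), np.zeros_like(z))


def test_q_shrink_parameter_validation():
    with pytest.raises(ValueError):
        q_shrink(1.0, 1.0, 0.0)
    with pytest.raises(ValueError):
        q_shrink(1.0, 1.0, 1.5)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    z=st.floats(-20, 20),
    alpha=st.floats(0.01, 5.0),
    q=st.floats(0.05, 1.0),
)
def test_q_shrink_properties(z, alpha, q):
    """Oddness, monotone dominance by the input, and h-optimality vs 0/z."""
    out = q_shrink(z, alpha, q)
    assert q_shrink(-z, alpha, q) == -out
    assert abs(out) <= abs(z) + 1e-12
    assert h_value(out, z, alpha, q) <= h_value(0.0, z, alpha, q) + 1e-10
    assert h_value(out, z, alpha, q) <= h_value(z, z, alpha, q) + 1e-10


def test_q_shrink_monotone_in_z():
    z = np.linspace(-8, 8, 4001)
    for q in (0.3, 0.8):
        out = q_shrink(z, 1.0, q)
        assert (np.diff(out) >= -1e-12).all()


def test_weighted_q_shrink(rng):
    Z = rng.standard_normal((6, 7))
    ones = np.ones_like(Z)
    np.testing.assert_array_equal(
        weighted_q_shrink(Z, 0.8, ones, 0.5), q_shrink(Z, 0.8, 0.5)
    )
    W = (rng.random(Z.shape) > 0.5).astype(float)
    out = weighted_q_shrink(Z, 0.8, W, 1.0)
    np.testing.assert_array_equal(out[W == 0], Z[W == 0])
    np.testing.assert_array_equal(
        out[W == 1], soft_threshold(Z[W == 1], 0.8)
    )
    with pytest.raises(ValueError):
        weighted_q_shrink(Z, 0.8, np.ones((2, 2)), 0.5)


def test_sv_p_shrink_basics(rng):
    Z = rng.standard_normal((4, 5))
    np.testing.assert_array_equal(sv_p_shrink(Z, 0.0, 0.5), Z)
    out = sv_p_shrink(np.diag([3.0, 1.0]), 1.0, 1.0)
    np.testing.assert_allclose(out, np.diag([2.0, 0.0]), atol=1e-12)


def test_sv_p_shrink_never_increases_singular_values(rng):
    Z = rng.standard_normal((5, 5))
    s_in = np.linalg.svd(Z, compute_uv=False)
    s_out = np.linalg.svd(sv_p_shrink(Z, 0.5, 0.5), compute_uv=False)
    assert (s_out <= s_in + 1e-10).all()
    assert np.sum(s_out > 1e-12) <= np.sum(s_in > 1e-12)


def test_sv_p_shrink_optimality_random_perturbations(rng):
    """The shrunk spectrum minimizes the matrix objective among random
    perturbations of the singular values (with the same singular vectors)."""
    Z = rng.standard_normal((4, 4))
    alpha, p = 1.0, 0.5
    U, s, Vt = np.linalg.svd(Z)
    B = sv_p_shrink(Z, alpha, p)
    s_best = np.linalg.svd(B, compute_uv=False)

    def objective(sv):
        mat = (U * sv) @ Vt
        return alpha * np.sum(sv**p) + 0.5 * np.linalg.norm(mat - Z) ** 2

    base = objective(s_best)
    for _ in range(10_000):
        trial = np.abs(s_best + rng.normal(0, 0.3, size=4))
        assert base <= objective(trial) + 1e-9


def test_procrustes_properties(rng):
    A = rng.standard_normal((6, 3))
    P = procrustes(A)
    np.testing.assert_allclose(P.T @ P, np.eye(3), atol=1e-10)
    np.testing.assert_allclose(procrustes(np.diag([2.0, 3.0])), np.eye(2),
                               atol=1e-12)
    Q = np.linalg.qr(rng.standard_normal((5, 2)))[0]
    assert np.linalg.norm(procrustes(Q) - Q) < 1e-10
    with pytest.raises(ValueError):
        procrustes(rng.standard_normal((2, 4)))


def test_procrustes_maximality(rng):
    """<P, A> >= <B, A> over random column-orthonormal B."""
    A = rng.standard_normal((6, 3))
    P = procrustes(A)
    base = np.sum(P * A)
    for _ in range(10_000):
        B = np.linalg.qr(rng.standard_normal((6, 3)))[0]
        assert base >= np.sum(B * A) - 1e-9
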