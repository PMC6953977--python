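"""Tracklet similarity, exact GLA matching, stitching, and evaluation."""

from itertools import combinations, permutations

import numpy as np
import pytest

from hankelsrm.metrics import mmr, mota
from hankelsrm.tracklets import (
    Tracklet,
    evaluate_tracking,
    gla_match,
    inject_false_detections,
    remove_detections,
    stitch_tracklets,
    tracklet_similarity,
)


def line_track(tid, start, length, x0=0.0, vx=2.0, y0=5.0, vy=-1.0):
    t = np.arange(start, start + length, dtype=float)
    return Tracklet(id=tid, start=start, coords=np.vstack([x0 + vx * t,
                                                           y0 + vy * t]))


def test_similarity_same_dynamics_is_one():
    a = line_track(1, 0, 18)
    b = line_track(2, 23, 17)  # same line, 5-frame gap
    assert tracklet_similarity(a, b) == 1.0
    # zero gap, identical dynamics
    c = line_track(3, 18, 12)
    assert tracklet_similarity(a, c) == 1.0


def test_similarity_unrelated_dynamics_below_one():
    a = line_track(1, 0, 18)
    t = np.arange(17, dtype=float)
    osc = Tracklet(id=2, start=23, coords=np.vstack(
        [10 * np.cos(1.3 * t) + 3 * np.sin(0.4 * t), 10 * np.sin(2.1 * t)]
    ))
    assert tracklet_similarity(a, osc) < 1.0


def test_similarity_overlap_incompatible():
    a = line_track(1, 0, 20)
    b = line_track(2, 10, 20)
    assert tracklet_similarity(a, b) == 0.0


def test_similarity_scale_invariant():
    a = line_track(1, 0, 16)
    b = line_track(2, 20, 16)
    s1 = tracklet_similarity(a, b)
    a2 = Tracklet(id=1, start=0, coords=3.7 * a.coords)
    b2 = Tracklet(id=2, start=20, coords=3.7 * b.coords)
    assert tracklet_similarity(a2, b2) == s1


def brute_force_gla(P, threshold):
    """Enumerate all partial matchings of {0..n-1} x {0..n-1}."""
    n = P.shape[0]
    best = 0.0
    idx = range(n)
    for k in range(1, n + 1):
        for rows in combinations(idx, k):
            for cols in permutations(idx, k):
                val = 0.0
                ok = True
                for i, j in zip(rows, cols):
                    if i == j or P[i, j] < threshold:
                        ok = False
                        break
                    val += P[i, j]
                if ok:
                    best = max(best, val)
    return best


@pytest.mark.parametrize("seed", range(5))
def test_gla_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    P = rng.random((5, 5))
    np.fill_diagonal(P, 0.0)
    threshold = 0.35
    res = gla_match(P, threshold=threshold)
    got = sum(P[i, j] for i, j in res.pairs)
    assert np.isclose(got, brute_force_gla(P, threshold))
    assert (res.K.sum(axis=0) <= 1).all() and (res.K.sum(axis=1) <= 1).all()
    assert set(np.unique(res.K)) <= {0, 1}


def test_gla_threshold_and_degenerate_cases():
    P = np.full((3, 3), 0.2)
    np.fill_diagonal(P, 0.0)
    assert gla_match(P, threshold=0.5).pairs == []
    P = np.zeros((3, 3))
    P[0, 2] = 0.9
    assert gla_match(P, threshold=0.5).pairs == [(0, 2)]
    with pytest.raises(ValueError):
        gla_match(np.zeros((2, 3)))


def test_stitch_split_track_and_impute_gap():
    full = line_track(1, 0, 40)
    a = Tracklet(id=1, start=0, coords=full.coords[:, :18])
    b = Tracklet(id=2, start=23, coords=full.coords[:, 23:])
    merged, assignment, imputed = stitch_tracklets([a, b], max_gap=10)
    assert len(merged) == 1
    assert assignment.pairs == [(0, 1)]
    m = merged[0]
    assert m.start == 0 and m.length == 40
    np.testing.assert_allclose(m.coords[:, 18:23], full.coords[:, 18:23],
                               atol=1e-2)
    assert imputed[m.id] == [18, 19, 20, 21, 22]


def test_stitch_preserves_identity_through_crossing():
    t = np.arange(40, dtype=float)
    A = np.vstack([t, 0.5 * t])
    B = np.vstack([80.0 - t, 0.5 * t])  # crosses A near t = 40
    frags = [
        Tracklet(id=1, start=0, coords=A[:, :19]),
        Tracklet(id=11, start=22, coords=A[:, 22:]),
        Tracklet(id=2, start=0, coords=B[:, :19]),
        Tracklet(id=12, start=22, coords=B[:, 22:]),
    ]
    merged, assignment, _ = stitch_tracklets(frags, max_gap=10)
    assert sorted(assignment.pairs) == [(0, 1), (2, 3)]
    truth = [Tracklet(id=1, start=0, coords=A), Tracklet(id=2, start=0, coords=B)]
    counts = evaluate_tracking(truth, merged, match_radius=2.0)
    assert mota(counts) == 1.0
    assert mmr(counts) == 0.0


def test_stitch_single_tracklet_unchanged():
    a = line_track(5, 3, 12)
    merged, _, imputed = stitch_tracklets([a])
    assert len(merged) == 1
    assert merged[0].id == 5 and merged[0].start == 3
    np.testing.assert_array_equal(merged[0].coords, a.coords)
    assert imputed[5] == []


def test_evaluate_tracking_counts():
    a = line_track(1, 0, 20)
    b = line_track(2, 0, 20, x0=50.0, vx=-1.0, y0=0.0, vy=1.0)
    counts = evaluate_tracking([a, b], [a, b])
    assert counts.fn.sum() == counts.fp.sum() == counts.mm.sum() == 0
    assert mota(counts) == 1.0

    # one target's id flips mid-sequence -> exactly one mismatch
    flipped = [
        Tracklet(id=1, start=0, coords=a.coords[:, :10]),
        Tracklet(id=9, start=10, coords=a.coords[:, 10:]),
        b,
    ]
    counts = evaluate_tracking([a, b], flipped)
    assert counts.mm.sum() == 1

    # everything missed: MOTA = 0 via fn = g
    counts = evaluate_tracking([a], [])
    assert counts.fn.sum() == counts.g.sum()
    assert mota(counts) == 0.0


def test_remove_detections_fragments_contiguously():
    a = line_track(1, 0, 50)
    out = remove_detections([a], 0.2, seed=3)
    assert sum(t.length for t in out) < 50
    for t in out:
        assert t.length >= 1
        np.testing.assert_array_equal(np.diff(t.frames), 1)
    # zero removal leaves everything as-is
    assert remove_detections([a], 0.0, seed=3)[0] is a


def test_inject_false_detections_count():
    a = line_track(1, 0, 40)
    out = inject_false_detections([a], 0.25, seed=0)
    fakes = [t for t in out if t.id != 1]
    assert len(fakes) == 10
    assert all(t.length == 1 for t in fakes)


def test_tracklet_validation():
    with pytest.raises(ValueError, match="2 x length"):
        Tracklet(id=1, start=0, coords=np.zeros((3, 4)))
    with pytest.raises(ValueError, match="finite"):
        Tracklet(id=1, start=0, coords=np.full((2, 4), np.nan))
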