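"""Tracklet association by Hankel-rank similarity and generalized linear
assignment (GLA), plus tracking evaluation utilities.

A tracklet is a contiguous fragment of one target's 2-D detections.  Two
tracklets are candidates for stitching when the joint trajectory (with the
occluded gap treated as missing data and imputed by structured Hankel
completion) can be explained by an autonomous LTI system no more complex
than its parts; the similarity score is the ratio of the parts' Hankel
ranks to twice the joint completed rank, which equals 1 exactly when
joining adds no dynamical complexity.  Pairing is solved exactly as a
maximum-weight assignment with at-most-one predecessor/successor
constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .completion import complete_trajectory
from .hankel import HankelSpec, default_depth, hankel_map
from .metrics import TrackEvalCounts
from .solver import SolverConfig, estimate_rank

__all__ = [
    "Tracklet",
    "AssignmentResult",
    "tracklet_hankel_rank",
    "tracklet_similarity",
    "gla_match",
    "stitch_tracklets",
    "evaluate_tracking",
    "remove_detections",
    "inject_false_detections",
]


@dataclass
class Tracklet:
    """Contiguous per-frame 2-D detections of one target."""

    id: int
    start: int
    coords: np.ndarray  # 2 x length

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[0] != 2:
            raise ValueError("coords must be a 2 x length matrix")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords must be finite")

    @property
    def length(self) -> int:
        return self.coords.shape[1]

    @property
    def end(self) -> int:
        """Last frame index (inclusive)."""
        return self.start + self.length - 1

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.length)


@dataclass
class AssignmentResult:
    """GLA solution: binary adjacency K (k_ij = 1 iff tracklet i precedes j)
    under row/column sums <= 1, with the similarity matrix it maximized."""

    K: np.ndarray
    P: np.ndarray
    pairs: list = field(default_factory=list)


def tracklet_hankel_rank(coords: np.ndarray, rel_tol: float = 1e-3) -> int:
    """Numerical rank of the square-ish Hankel matrix of a 2 x len
    trajectory (autonomous, output-only spec)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    T = coords.shape[1]
    if T == 1:
        return 1 if np.linalg.norm(coords) > 0 else 0
    r = default_depth(T)
    spec = HankelSpec(m=coords.shape[0], n_blk=1, j=r + 1, k=T - r)
    return estimate_rank(hankel_map(coords, spec), rel_tol=rel_tol)


def _default_tracklet_config() -> SolverConfig:
    # tighter tolerances for the completion-driven similarity
    return SolverConfig(eps1=1e-7, eps2=1e-7)


def tracklet_similarity(
    Yi: Tracklet,
    Yj: Tracklet,
    p: float = 0.5,
    q: float = 2.0,
    lam: float = 10.0,
    config: SolverConfig | None = None,
) -> float:
    """Similarity p_ij in [0, 1] between a candidate predecessor Yi and
    successor Yj.

    The joint trajectory [Yi, gap, Yj] (gap entries masked) is imputed by
    structured Hankel completion; the score is
    (rank H(Yi) + rank H(Yj)) / (2 * rank H(joint completed)), clipped to
    [0, 1].  Overlapping tracklets are incompatible (similarity 0).
    """
    if Yj.start <= Yi.end:
        return 0.0
    if config is None:
        config = _default_tracklet_config()
    gap = Yj.start - Yi.end - 1
    T = Yi.length + gap + Yj.length
    M = np.zeros((2, T))
    W = np.zeros((2, T))
    M[:, : Yi.length] = Yi.coords
    M[:, Yi.length + gap :] = Yj.coords
    W[:, : Yi.length] = 1.0
    W[:, Yi.length + gap :] = 1.0
    res = complete_trajectory(M, W, p=p, q=q, lam=lam, config=config)
    rank_joint = tracklet_hankel_rank(res.completed)
    if rank_joint == 0:
        return 0.0
    rank_i = tracklet_hankel_rank(Yi.coords)
    rank_j = tracklet_hankel_rank(Yj.coords)
    return float(np.clip((rank_i + rank_j) / (2.0 * rank_joint), 0.0, 1.0))


def gla_match(P: np.ndarray, threshold: float = 0.0) -> AssignmentResult:
    """Exact generalized linear assignment: maximize sum p_ij * k_ij under
    row/column sums <= 1, k binary; entries below ``threshold`` are never
    matched.  Solved by the Hungarian algorithm on the nonnegative benefit
    matrix with sub-threshold entries zeroed (zero-benefit matches are
    pruned afterwards, which is optimal for the inequality constraints)."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    B = np.where(P >= threshold, P, 0.0)
    np.fill_diagonal(B, 0.0)
    rows, cols = linear_sum_assignment(B, maximize=True)
    K = np.zeros_like(B, dtype=int)
    pairs = []
    for i, j in zip(rows, cols):
        if B[i, j] > 0.0 and P[i, j] >= threshold and i != j:
            K[i, j] = 1
            pairs.append((int(i), int(j)))
    return AssignmentResult(K=K, P=P, pairs=pairs)


def _chains(pairs, n: int):
    succ = dict(pairs)
    has_pred = {j for _, j in pairs}
    chains = []
    for i in range(n):
        if i in has_pred:
            continue
        chain = [i]
        while chain[-1] in succ:
            chain.append(succ[chain[-1]])
        chains.append(chain)
    return chains


def stitch_tracklets(
    tracklets,
    p: float = 0.5,
    q: float = 2.0,
    lam: float = 10.0,
    max_gap: int = 30,
    threshold: float = 0.5,
    config: SolverConfig | None = None,
):
    """Merge tracklets that share linear dynamics.

    Similarities are computed for all temporally admissible pairs
    (predecessor ends before successor begins, gap at most ``max_gap``),
    the GLA is solved, matched chains are concatenated, and gap frames are
    imputed by Hankel completion of each chain's joint trajectory.

    Returns (merged tracklets, assignment, imputed), where ``imputed`` maps
    merged tracklet ids to the list of imputed frame indices.
    """
    tracklets = list(tracklets)
    n = len(tracklets)
    if config is None:
        config = _default_tracklet_config()
    P = np.zeros((n, n))
    for i, ti in enumerate(tracklets):
        for j, tj in enumerate(tracklets):
            if i == j:
                continue
            gap = tj.start - ti.end - 1
            if gap < 0 or gap > max_gap:
                continue
            P[i, j] = tracklet_similarity(ti, tj, p=p, q=q, lam=lam, config=config)
    assignment = gla_match(P, threshold=threshold)
    merged, imputed = [], {}
    for chain in _chains(assignment.pairs, n):
        parts = [tracklets[i] for i in chain]
        start = parts[0].start
        end = parts[-1].end
        T = end - start + 1
        M = np.zeros((2, T))
        W = np.zeros((2, T))
        for part in parts:
            sl = slice(part.start - start, part.start - start + part.length)
            M[:, sl] = part.coords
            W[:, sl] = 1.0
        new_id = parts[0].id
        if W.min() == 0:  # chain has occlusion gaps to impute
            res = complete_trajectory(M, W, p=p, q=q, lam=lam, config=config)
            gap_cols = W[0] == 0
            M[:, gap_cols] = res.completed[:, gap_cols]
            imputed[new_id] = (start + np.flatnonzero(gap_cols)).tolist()
        else:
            imputed[new_id] = []
        merged.append(Tracklet(id=new_id, start=start, coords=M))
    return merged, assignment, imputed


def _detections_by_frame(tracklets):
    frames: dict[int, list] = {}
    for t in tracklets:
        for offset, frame in enumerate(t.frames):
            frames.setdefault(int(frame), []).append((t.id, t.coords[:, offset]))
    return frames


def evaluate_tracking(truth, predicted, match_radius: float = 5.0) -> TrackEvalCounts:
    """Per-frame greedy nearest-detection matching within ``match_radius``;
    identity switches (a ground-truth target matched to a different
    predicted id than before) count as mismatches."""
    truth_frames = _detections_by_frame(truth)
    pred_frames = _detections_by_frame(predicted)
    all_frames = sorted(set(truth_frames) | set(pred_frames))
    fn, fp, mm, g = [], [], [], []
    last_match: dict[int, int] = {}
    for frame in all_frames:
        gts = truth_frames.get(frame, [])
        preds = pred_frames.get(frame, [])
        cand = []
        for a, (gid, gxy) in enumerate(gts):
            for b, (pid, pxy) in enumerate(preds):
                dist = float(np.linalg.norm(gxy - pxy))
                if dist <= match_radius:
                    cand.append((dist, a, b))
        cand.sort()
        used_g, used_p = set(), set()
        switches = 0
        for _, a, b in cand:
            if a in used_g or b in used_p:
                continue
            used_g.add(a)
            used_p.add(b)
            gid, pid = gts[a][0], preds[b][0]
            if gid in last_match and last_match[gid] != pid:
                switches += 1
            last_match[gid] = pid
        fn.append(len(gts) - len(used_g))
        fp.append(len(preds) - len(used_p))
        mm.append(switches)
        g.append(len(gts))
    return TrackEvalCounts(fn=np.array(fn), fp=np.array(fp), mm=np.array(mm),
                           g=np.array(g))


def remove_detections(tracklets, frac: float, seed: int = 0):
    """Remove a uniform fraction of true detections; tracklets fragment into
    contiguous pieces around the removed frames (fresh ids are assigned to
    the fragments after the first)."""
    rng = np.random.default_rng(seed)
    out = []
    next_id = max((t.id for t in tracklets), default=0) + 1
    for t in tracklets:
        keep = rng.random(t.length) >= frac
        if keep.all():
            out.append(t)
            continue
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            continue
        # split surviving indices into contiguous runs
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for s_i, run in enumerate(splits):
            tid = t.id if s_i == 0 else next_id
            if s_i > 0:
                next_id += 1
            out.append(
                Tracklet(id=tid, start=t.start + int(run[0]),
                         coords=t.coords[:, run[0] : run[-1] + 1])
            )
    return out


def inject_false_detections(tracklets, frac: float, bounds=(0.0, 100.0),
                            seed: int = 0):
    """Inject uniformly distributed false detections (as singleton
    tracklets) amounting to ``frac`` of the true detection count."""
    rng = np.random.default_rng(seed)
    total = sum(t.length for t in tracklets)
    n_fake = int(round(frac * total))
    frames = np.concatenate([t.frames for t in tracklets]) if tracklets else np.array([0])
    next_id = max((t.id for t in tracklets), default=0) + 1
    out = list(tracklets)
    lo, hi = bounds
    for i in range(n_fake):
        frame = int(rng.choice(frames))
        xy = rng.uniform(lo, hi, size=(2, 1))
        out.append(Tracklet(id=next_id + i, start=frame, coords=xy))
    return out
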