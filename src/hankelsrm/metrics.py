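"""Evaluation metrics: relative reconstruction error, Pearson correlation,
ICC(3,1), and the CLEAR-MOT style tracking scores MOTA and MMR."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "rel_error",
    "pearson_cor",
    "icc31",
    "TrackEvalCounts",
    "mota",
    "mmr",
]


def rel_error(s, s_hat) -> float:
    """Relative reconstruction error ||s - s_hat|| / ||s|| (Frobenius)."""
    s = np.asarray(s, dtype=float)
    s_hat = np.asarray(s_hat, dtype=float)
    denom = np.linalg.norm(s)
    if denom == 0:
        raise ValueError("reference signal has zero norm")
    return float(np.linalg.norm(s - s_hat) / denom)


def pearson_cor(a, b) -> float:
    """Sample Pearson correlation coefficient between two flattened signals."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("inputs must have the same length")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("Pearson correlation is undefined for a constant input")
    return float(np.corrcoef(a, b)[0, 1])


def icc31(ratings: np.ndarray) -> float:
    """Intraclass correlation ICC(3,1): two-way mixed model, single-rater
    consistency, (BMS - EMS) / (BMS + (k - 1) * EMS) from the two-way ANOVA
    decomposition of a targets x judges table.

    Consistency (not absolute agreement): judges differing by a constant
    offset still score 1.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("ratings must be a targets x judges matrix, >= 2 each")
    n, k = X.shape
    grand = X.mean()
    target_means = X.mean(axis=1)
    judge_means = X.mean(axis=0)
    ss_targets = k * np.sum((target_means - grand) ** 2)
    ss_judges = n * np.sum((judge_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_error = ss_total - ss_targets - ss_judges
    bms = ss_targets / (n - 1)
    ems = ss_error / ((n - 1) * (k - 1))
    if bms == 0:
        raise ValueError("zero between-target variance; ICC undefined")
    return float((bms - ems) / (bms + (k - 1) * ems))


@dataclass
class TrackEvalCounts:
    """Per-frame error counts for tracking evaluation.

    All fields are arrays over evaluated frames: false negatives ``fn``,
    false positives ``fp``, identity mismatches ``mm`` and ground-truth
    detections ``g``.
    """

    fn: np.ndarray
    fp: np.ndarray
    mm: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        for name in ("fn", "fp", "mm", "g"):
            arr = np.asarray(getattr(self, name), dtype=int)
            if (arr < 0).any():
                raise ValueError(f"{name} counts must be nonnegative")
            setattr(self, name, arr)


def mota(counts: TrackEvalCounts) -> float:
    """Multiple-object tracking accuracy
    1 - sum(fn + fp + mm) / sum(g); may be negative when errors exceed the
    ground truth (no clipping)."""
    g = counts.g.sum()
    if g <= 0:
        raise ValueError("no ground-truth detections in evaluated frames")
    return float(1.0 - (counts.fn.sum() + counts.fp.sum() + counts.mm.sum()) / g)


def mmr(counts: TrackEvalCounts) -> float:
    """MissMatch Ratio sum(mm) / sum(g)."""
    g = counts.g.sum()
    if g <= 0:
        raise ValueError("no ground-truth detections in evaluated frames")
    return float(counts.mm.sum() / g)
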