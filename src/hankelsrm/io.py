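"""Delimited-text I/O for trajectories and MOT-style tracklet files."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .tracklets import Tracklet

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_tracklets",
    "write_tracklets",
]


def read_trajectory(path):
    """Read a comma-separated trajectory: header row of channel names, one
    row per time sample.  Missing entries (empty fields or NaN) are
    returned as NaN.  Returns (D x T array, channel names)."""
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float).T, list(df.columns)


def write_trajectory(path, M: np.ndarray, channels=None) -> None:
    """Write a D x T trajectory as comma-separated text (one row per time
    sample, header of channel names)."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if channels is None:
        channels = [f"ch{i}" for i in range(M.shape[0])]
    pd.DataFrame(M.T, columns=list(channels)).to_csv(path, index=False)


def read_tracklets(path) -> list[Tracklet]:
    """Read MOT-challenge style detections (frame, id, x, y[, w, h, conf]):
    comma-separated, no header.  Rows sharing an id must form a contiguous
    frame range."""
    raw = pd.read_csv(path, header=None)
    raw = raw.rename(columns={0: "frame", 1: "id", 2: "x", 3: "y"})
    tracklets = []
    for tid, grp in raw.groupby("id"):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(dtype=int)
        if frames.size > 1 and not (np.diff(frames) == 1).all():
            raise ValueError(f"tracklet {tid} has a non-contiguous frame range")
        coords = grp[["x", "y"]].to_numpy(dtype=float).T
        tracklets.append(Tracklet(id=int(tid), start=int(frames[0]), coords=coords))
    return tracklets


def write_tracklets(path, tracklets, imputed: dict | None = None) -> None:
    """Write tracklets in the same MOT-style schema with a trailing flag
    column marking imputed rows (1 = filled in by completion)."""
    imputed = imputed or {}
    rows = []
    for t in tracklets:
        flagged = set(imputed.get(t.id, []))
        for offset, frame in enumerate(t.frames):
            rows.append(
                (int(frame), int(t.id), float(t.coords[0, offset]),
                 float(t.coords[1, offset]), int(frame in flagged))
            )
    rows.sort()
    df = pd.DataFrame(rows, columns=["frame", "id", "x", "y", "imputed"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, header=False)
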