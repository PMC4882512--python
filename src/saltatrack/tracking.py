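"""Frame-to-frame linking of detections into tracks.

Linking solves, for each consecutive frame pair, the optimal bipartite
assignment minimising total squared displacement, with a per-link gate at
``max_link_distance`` and explicit birth/death alternatives (cost slightly
above the gate), so behaviour is order-independent and deterministic.
Tracks not covering the entire observation period are removed by the
completeness filter before any motion analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .tracks import Track, TrackSet

__all__ = ["LinkingParams", "link_tracks", "filter_complete", "detections_by_frame"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LinkingParams:
    """Linker configuration.

    ``max_link_distance`` (μm per frame interval) gates candidate links;
    ``max_gap`` allows a track to survive that many missed frames (0 by
    default: the completeness filter discards gapped tracks anyway).
    """

    max_link_distance: float = 2.5
    max_gap: int = 0

    def __post_init__(self) -> None:
        if self.max_link_distance <= 0:
            raise ValueError("max_link_distance must be positive")
        if self.max_gap < 0:
            raise ValueError("max_gap must be non-negative")


def detections_by_frame(detections: pd.DataFrame, n_frames: int) -> list[np.ndarray]:
    """Group a detections table into per-frame (n_i, 2) position arrays."""
    out = [np.empty((0, 2)) for _ in range(n_frames)]
    for frame, g in detections.groupby("frame"):
        out[int(frame)] = g[["x_um", "y_um"]].to_numpy(dtype=float)
    return out


def _assign_pair(
    prev: np.ndarray, new: np.ndarray, max_dist: float
) -> list[tuple[int, int]]:
    """Optimal gated assignment between two position sets.

    Minimises total squared displacement plus a birth/death penalty of
    gate² × 1.0001 per unmatched endpoint, via the augmented square cost
    matrix (links gated at ``max_dist``; dummy-dummy completions free).
    """
    n, m = len(prev), len(new)
    if n == 0 or m == 0:
        return []
    d2 = ((prev[:, None, :] - new[None, :, :]) ** 2).sum(axis=2)
    gate2 = max_dist**2
    alt = gate2 * 1.0001
    big = 1e9
    cost = np.full((n + m, n + m), 0.0)
    top_left = np.where(d2 <= gate2, d2, big)
    cost[:n, :m] = top_left
    cost[:n, m:] = big
    cost[n:, :m] = big
    np.fill_diagonal(cost[:n, m:], alt)
    np.fill_diagonal(cost[n:, :m], alt)
    cost[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if r < n and c < m and d2[r, c] <= gate2]


def link_tracks(
    detections: list[np.ndarray] | pd.DataFrame,
    params: LinkingParams | None = None,
    frame_interval: float = 2.0,
    n_frames: int | None = None,
) -> TrackSet:
    """Link per-frame detections into tracks.

    ``detections`` is either a list of per-frame (n_i, 2) arrays of (x, y)
    positions in μm, or a detections table with frame/x_um/y_um columns.
    Unmatched detections start new tracks; tracks unmatched for more than
    ``max_gap`` frames terminate. Gap-closing interpolates linearly across
    skipped frames.
    """
    params = params or LinkingParams()
    if isinstance(detections, pd.DataFrame):
        if n_frames is None:
            n_frames = int(detections["frame"].max()) + 1 if len(detections) else 0
        per_frame = detections_by_frame(detections, n_frames)
    else:
        per_frame = [np.asarray(p, dtype=float).reshape(-1, 2) for p in detections]
        if n_frames is None:
            n_frames = len(per_frame)

    # Active track state: list of dicts with positions/frames.
    active: list[dict] = []
    finished: list[dict] = []
    next_id = 0
    for frame, pts in enumerate(per_frame):
        candidates = [a for a in active if frame - a["frames"][-1] <= params.max_gap + 1]
        prev = np.array([a["xy"][-1] for a in candidates]).reshape(-1, 2)
        gap_scale = np.array([frame - a["frames"][-1] for a in candidates], dtype=float)
        matched_prev: set[int] = set()
        matched_new: set[int] = set()
        if len(prev) and len(pts):
            pairs = _assign_pair(prev, pts, params.max_link_distance)
            for r, c in pairs:
                a = candidates[r]
                gap = int(gap_scale[r])
                if gap > 1:
                    # interpolate across the gap
                    x0, y0 = a["xy"][-1]
                    x1, y1 = pts[c]
                    for g in range(1, gap):
                        f = g / gap
                        a["frames"].append(a["frames"][-1] + 1)
                        a["xy"].append((x0 + f * (x1 - x0), y0 + f * (y1 - y0)))
                a["frames"].append(frame)
                a["xy"].append(tuple(pts[c]))
                matched_prev.add(id(a))
                matched_new.add(c)
        # Terminate tracks that exceeded the gap allowance.
        still_active = []
        for a in active:
            if id(a) in matched_prev or frame - a["frames"][-1] <= params.max_gap:
                still_active.append(a)
            else:
                finished.append(a)
        active = still_active
        # Births.
        for c in range(len(pts)):
            if c not in matched_new:
                active.append({"frames": [frame], "xy": [tuple(pts[c])]})
    finished.extend(active)

    finished.sort(key=lambda a: (a["frames"][0], a["xy"][0]))
    tracks = []
    for a in finished:
        xy = np.array(a["xy"])
        tracks.append(
            Track(
                track_id=next_id,
                frames=np.array(a["frames"]),
                x=xy[:, 0],
                y=xy[:, 1],
            )
        )
        next_id += 1
    ts = TrackSet(
        tracks=tracks,
        frame_interval=frame_interval,
        n_frames=n_frames,
        provenance="recovered",
    )
    ts.mark_complete()
    return ts


def filter_complete(track_set: TrackSet, n_frames: int | None = None) -> TrackSet:
    """Keep only tracks spanning the entire observation period.

    Organelles not tracked from the first to the last frame are deleted from
    the analysis; the number removed is logged.
    """
    n_frames = n_frames or track_set.n_frames
    kept = [
        t for t in track_set
        if len(t) == n_frames and t.frames[0] == 0 and t.frames[-1] == n_frames - 1
    ]
    removed = len(track_set) - len(kept)
    if removed:
        logger.info("completeness filter removed %d of %d tracks", removed, len(track_set))
    for t in kept:
        t.complete = True
    return TrackSet(
        tracks=kept,
        frame_interval=track_set.frame_interval,
        n_frames=n_frames,
        provenance=track_set.provenance,
    )
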