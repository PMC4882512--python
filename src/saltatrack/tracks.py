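"""Track containers shared by the simulator, the linker and the metrics layer.

Coordinates are physical (μm). The process axis ``s`` runs from the soma
(``s = 0``) distally, and for the straight 1-D geometry used throughout the
package it coincides with the image ``x`` coordinate. ``y`` is the transverse
position within the process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = ["Track", "TrackSet"]


@dataclass
class Track:
    """A time-ordered sequence of positions for one organelle.

    Parameters
    ----------
    track_id : int
        Stable identifier within a :class:`TrackSet`.
    frames : ndarray of int
        Strictly increasing frame indices.
    x, y : ndarray of float
        Positions in μm; ``x`` doubles as the process-axis coordinate ``s``.
    complete : bool
        True iff the track spans the full observation period
        (first frame 0, last frame ``n_frames - 1``).
    motion_class : str or None
        Ground-truth class label (``fast``/``slow``/``immobile``) when the
        track comes from the simulator; None for recovered tracks.
    direction_truth : str or None
        Ground-truth transport direction for fast simulated tracks.
    run_state : ndarray of bool or None
        Per-frame flag: organelle in a processive run during the interval
        ending at that frame (simulated tracks only).
    """

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    complete: bool = False
    motion_class: str | None = None
    direction_truth: str | None = None
    run_state: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.frames.ndim != 1 or len(self.frames) != len(self.x) or len(self.x) != len(self.y):
            raise ValueError("frames, x and y must be 1-D and equally long")
        if len(self.frames) > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def s(self) -> np.ndarray:
        """Axial position (alias of ``x`` in the straight-process geometry)."""
        return self.x

    @property
    def net_displacement_s(self) -> float:
        """Signed axial displacement, positive = anterograde (away from soma)."""
        return float(self.x[-1] - self.x[0])


@dataclass
class TrackSet:
    """A collection of tracks sharing one imaging run.

    ``provenance`` records whether the tracks are simulator ground truth or
    were recovered by detection + linking.
    """

    tracks: list[Track] = field(default_factory=list)
    frame_interval: float = 2.0
    n_frames: int = 0
    provenance: str = "ground_truth"

    def __post_init__(self) -> None:
        if self.provenance not in ("ground_truth", "recovered"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        for t in self.tracks:
            if len(t) and (t.frames[0] < 0 or t.frames[-1] > self.n_frames - 1):
                raise ValueError(f"track {t.track_id} has frames outside [0, {self.n_frames - 1}]")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def mark_complete(self) -> None:
        for t in self.tracks:
            t.complete = bool(len(t) and t.frames[0] == 0 and t.frames[-1] == self.n_frames - 1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (track, frame)."""
        rows = []
        for t in self.tracks:
            df = pd.DataFrame(
                {
                    "track_id": t.track_id,
                    "frame": t.frames,
                    "s_um": t.x,
                    "x_um": t.x,
                    "y_um": t.y,
                }
            )
            if t.motion_class is not None:
                df["class"] = t.motion_class
            if t.run_state is not None:
                df["run_state"] = t.run_state.astype(int)
            rows.append(df)
        if not rows:
            return pd.DataFrame(columns=["track_id", "frame", "s_um", "x_um", "y_um"])
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        frame_interval: float,
        n_frames: int,
        provenance: str = "recovered",
    ) -> "TrackSet":
        tracks = []
        for tid, g in df.groupby("track_id", sort=True):
            g = g.sort_values("frame")
            cls_label = str(g["class"].iloc[0]) if "class" in g.columns else None
            run = g["run_state"].to_numpy().astype(bool) if "run_state" in g.columns else None
            tracks.append(
                Track(
                    track_id=int(tid),
                    frames=g["frame"].to_numpy(),
                    x=g["x_um"].to_numpy(),
                    y=g["y_um"].to_numpy(),
                    motion_class=cls_label,
                    run_state=run,
                )
            )
        ts = cls(tracks=tracks, frame_interval=frame_interval, n_frames=n_frames, provenance=provenance)
        ts.mark_complete()
        return ts
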