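"""Readers and writers: calibrated TIFF movies, track/detection tables, configs.

Movies are multi-page TIFFs (frame-major, z within frame) with a JSON
sidecar carrying the physical calibration (``pixel_size_um``,
``frame_interval_s``, ``n_z``). Tables are plain CSV with units in the
column names. All writes round-trip losslessly through the matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .tracks import TrackSet

__all__ = [
    "MovieIOError",
    "write_movie",
    "read_movie",
    "write_tracks",
    "read_tracks",
    "write_detections",
    "read_detections",
    "load_config",
]

SIDECAR_KEYS = ("pixel_size_um", "frame_interval_s", "n_z")


class MovieIOError(IOError):
    """Raised for unreadable movies or missing calibration."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(
    path: str | Path,
    stack: np.ndarray,
    pixel_size: float,
    frame_interval: float,
) -> None:
    """Write a (n_frames, n_z, H, W) stack plus its calibration sidecar."""
    path = Path(path)
    stack = np.asarray(stack)
    if stack.ndim == 3:
        stack = stack[:, None]
    if stack.ndim != 4:
        raise ValueError("expected a (n_frames[, n_z], H, W) stack")
    n_frames, n_z, h, w = stack.shape
    tifffile.imwrite(path, stack.reshape(n_frames * n_z, h, w).astype(np.float32))
    sidecar = {
        "pixel_size_um": float(pixel_size),
        "frame_interval_s": float(frame_interval),
        "n_z": int(n_z),
        "n_frames": int(n_frames),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_movie(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a movie and its calibration; returns ((frame, z, row, col), meta).

    Raises :class:`MovieIOError` if the file is unreadable or the sidecar is
    missing or incomplete.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MovieIOError(
            f"missing calibration sidecar {sidecar.name}; expected JSON with keys {SIDECAR_KEYS}"
        )
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as e:
        raise MovieIOError(f"corrupt sidecar {sidecar}: {e}") from e
    missing = [k for k in SIDECAR_KEYS if k not in meta]
    if missing:
        raise MovieIOError(f"sidecar {sidecar} lacks keys {missing}; expected {SIDECAR_KEYS}")
    try:
        pages = tifffile.imread(path)
    except Exception as e:  # tifffile raises a mix of types for bad files
        raise MovieIOError(f"unreadable TIFF {path}: {e}") from e
    if pages.ndim == 2:
        pages = pages[None]
    n_z = int(meta["n_z"])
    if pages.shape[0] % n_z:
        raise MovieIOError(f"{path}: page count {pages.shape[0]} not divisible by n_z={n_z}")
    stack = pages.reshape(pages.shape[0] // n_z, n_z, *pages.shape[1:])
    return stack, meta


def write_tracks(path: str | Path, track_set: TrackSet) -> None:
    track_set.to_frame().to_csv(path, index=False)


def read_tracks(
    path: str | Path, frame_interval: float, n_frames: int, provenance: str = "recovered"
) -> TrackSet:
    df = pd.read_csv(path)
    return TrackSet.from_frame(df, frame_interval, n_frames, provenance)


def write_detections(path: str | Path, detections: pd.DataFrame) -> None:
    detections.to_csv(path, index=False)


def read_detections(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
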