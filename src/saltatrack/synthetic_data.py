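"""Synthetic ground truth for saltatory organelle transport.

The generator emulates the imaging regime of time-lapse peroxisome movies in
actin-free, axon-like processes: a straight, quasi-1-D process 150-300 μm
long and ~1 μm wide, imaged every 2 s for 4 min. Organelles fall into three
motion classes:

``fast``
    Saltatory run-and-pause transport: processive runs at a per-run speed
    drawn from a truncated normal, alternating with pauses; run and pause
    durations are exponential. Each fast organelle commits to one transport
    direction (anterograde with probability ``p_anterograde``), so the
    track-level anterograde fraction equals ``p_anterograde``.
``slow``
    Brownian-like axial jitter with per-frame step SD ``slow_step_sd``.
``immobile``
    Localisation noise only.

All tracks additionally carry isotropic localisation noise of SD
``loc_noise_sd`` and a small transverse (``y``) jitter confined to the
process width.

Randomness uses one master seed with a deterministic per-track substream, so
generating more tracks never perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tracks import Track, TrackSet

__all__ = [
    "MotionModelParams",
    "ImagingParams",
    "CellFieldParams",
    "make_condition_preset",
    "simulate_tracks",
    "render_movie",
    "render_cell_field",
    "CONDITION_PRESETS",
]


@dataclass(frozen=True)
class MotionModelParams:
    """Generative parameters for three-class transport along a 1-D process.

    Speeds are μm/s, durations s, lengths μm. ``slow_step_sd`` is μm per
    frame interval. The class fractions must sum to 1.
    """

    frac_fast: float = 0.10
    frac_slow: float = 0.63
    frac_immobile: float = 0.27
    fast_run_speed_mean: float = 0.55
    fast_run_speed_sd: float = 0.22
    fast_run_duration_mean: float = 6.0
    fast_pause_duration_mean: float = 9.0
    slow_step_sd: float = 0.09
    slow_step_dispersion: float = 0.48
    loc_noise_sd: float = 0.02
    p_anterograde: float = 0.609
    process_length: float = 240.0
    soma_margin: float = 20.0
    process_width: float = 1.0
    fast_run_speed_min: float = 0.10

    def __post_init__(self) -> None:
        fracs = (self.frac_fast, self.frac_slow, self.frac_immobile)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("class fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {sum(fracs)}")
        if not 0.0 <= self.p_anterograde <= 1.0:
            raise ValueError("p_anterograde must lie in [0, 1]")
        for name in (
            "fast_run_speed_mean",
            "fast_run_speed_sd",
            "fast_run_duration_mean",
            "fast_pause_duration_mean",
            "process_length",
            "process_width",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("slow_step_sd", "slow_step_dispersion", "loc_noise_sd", "soma_margin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ImagingParams:
    """Acquisition and rendering parameters.

    Defaults mirror the live-imaging regime: one (z-stacked) frame every 2 s
    for 240 s, high-magnification oil objective sampling, diffraction-limited
    GFP spots.
    """

    frame_interval: float = 2.0
    duration: float = 240.0
    pixel_size: float = 0.2
    n_z: int = 3
    psf_sigma: float = 0.25
    photon_scale: float = 300.0
    background: float = 10.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.frame_interval <= 0 or self.duration <= 0:
            raise ValueError("frame_interval and duration must be positive")
        if self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("pixel_size and psf_sigma must be positive")
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration / self.frame_interval)) + 1


@dataclass(frozen=True)
class CellFieldParams:
    """Layout of a synthetic multi-channel cell field for the
    cytoplasmic-marker quantification fixtures."""

    n_cells: int = 25
    nucleus_radius: float = 5.0
    cell_radius: float = 12.0
    marker_mean_per_condition: dict = field(
        default_factory=lambda: {"baseline": 50.0, "H2O2": 70.0, "EpoD+H2O2": 55.0}
    )
    marker_cell_sd: float = 4.0
    background: float = 2.0
    pixel_size: float = 1.0
    field_size: float = 300.0
    nucleus_intensity: float = 200.0
    cell_intensity: float = 100.0

    def __post_init__(self) -> None:
        if self.nucleus_radius >= self.cell_radius:
            raise ValueError("nucleus_radius must be smaller than cell_radius")
        if self.marker_cell_sd < 0 or self.background < 0:
            raise ValueError("intensities must be non-negative")
        if any(v < 0 for v in self.marker_mean_per_condition.values()):
            raise ValueError("marker means must be non-negative")


# Generative fast-mover fractions and anterograde probabilities per
# experimental condition. The patient fraction (2.3%) and the directional
# probabilities come from the measured group percentages; the epothilone-D
# preset restores the fast fraction and direction balance to control values.
# The non-fast mass is split 70/30 between slow and immobile.
CONDITION_PRESETS: dict[str, dict[str, float]] = {
    "control": {"frac_fast": 0.10, "p_anterograde": 0.609},
    "patient": {"frac_fast": 0.023, "p_anterograde": 0.861},
    "patient_epoD": {"frac_fast": 0.10, "p_anterograde": 0.609},
}


def make_condition_preset(name: str) -> MotionModelParams:
    """Return the motion-model parameters for a named experimental condition.

    ``control`` and ``patient_epoD`` share a 10% generative fast fraction and
    60.9% anterograde bias; ``patient`` has 2.3% fast movers with an 86.1%
    anterograde bias.
    """
    try:
        preset = CONDITION_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; expected one of {sorted(CONDITION_PRESETS)}"
        ) from None
    frac_fast = preset["frac_fast"]
    remainder = 1.0 - frac_fast
    return MotionModelParams(
        frac_fast=frac_fast,
        frac_slow=0.7 * remainder,
        frac_immobile=0.3 * remainder,
        p_anterograde=preset["p_anterograde"],
    )


def _track_rng(seed: int, track_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), int(track_index))))


def _fast_segments(
    rng: np.random.Generator, params: MotionModelParams, duration: float
) -> list[tuple[float, float, float]]:
    """Alternating (t_start, t_end, signed_speed) segments; pauses have speed 0."""
    segments = []
    t = 0.0
    in_run = rng.random() < (
        params.fast_run_duration_mean
        / (params.fast_run_duration_mean + params.fast_pause_duration_mean)
    )
    while t < duration:
        if in_run:
            dur = rng.exponential(params.fast_run_duration_mean)
            v = rng.normal(params.fast_run_speed_mean, params.fast_run_speed_sd)
            v = max(v, params.fast_run_speed_min)
        else:
            dur = rng.exponential(params.fast_pause_duration_mean)
            v = 0.0
        segments.append((t, min(t + dur, duration), v))
        t += dur
        in_run = not in_run
    return segments


def _simulate_fast(
    rng: np.random.Generator, params: MotionModelParams, imaging: ImagingParams
) -> tuple[np.ndarray, np.ndarray, str]:
    """Axial positions, per-frame run flags, direction for one fast track."""
    n = imaging.n_frames
    dt = imaging.frame_interval
    direction = "anterograde" if rng.random() < params.p_anterograde else "retrograde"
    sign = 1.0 if direction == "anterograde" else -1.0
    segments = _fast_segments(rng, params, imaging.duration)

    # Per-frame displacement: integrate run speed over each frame interval.
    disp = np.zeros(n - 1)
    run_time = np.zeros(n - 1)
    edges = np.arange(n) * dt
    for (t0, t1, v) in segments:
        if v == 0.0:
            continue
        lo = np.clip(t0, edges[:-1], edges[1:])
        hi = np.clip(t1, edges[:-1], edges[1:])
        overlap = np.maximum(hi - lo, 0.0)
        disp += sign * v * overlap
        run_time += overlap
    run_flags = np.concatenate([[False], run_time > 0.5 * dt])

    # Start the track where the expected excursion fits inside the process;
    # positions are clipped as a safety net in the caller.
    sweep = abs(disp.sum()) + 10.0
    lo, hi = params.soma_margin, params.process_length
    if direction == "anterograde":
        hi = max(lo + 1.0, params.process_length - min(sweep, 0.6 * params.process_length))
    else:
        lo = min(params.process_length - 1.0, lo + min(sweep, 0.6 * params.process_length))
    s0 = rng.uniform(lo, hi)
    s = np.concatenate([[s0], s0 + np.cumsum(disp)])
    return s, run_flags, direction


def simulate_tracks(
    params: MotionModelParams,
    imaging: ImagingParams,
    n_tracks: int,
    seed: int,
    id_offset: int = 0,
) -> TrackSet:
    """Simulate ground-truth tracks spanning the full observation period.

    Each track draws its motion class from the fraction parameters, then its
    trajectory from the class model, using a substream derived from
    ``(seed, track index)``. Positions are clipped to ``[0, process_length]``.

    ``id_offset`` shifts both the track ids and the substream indices, so
    that disjoint batches from the same seed are independent.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    n = imaging.n_frames
    frames = np.arange(n)
    thresholds = np.array([params.frac_fast, params.frac_fast + params.frac_slow])
    tracks = []
    for i in range(n_tracks):
        rng = _track_rng(seed, i + id_offset)
        u = rng.random()
        cls = "fast" if u < thresholds[0] else ("slow" if u < thresholds[1] else "immobile")
        direction = None
        run_flags = None
        if cls == "fast":
            s, run_flags, direction = _simulate_fast(rng, params, imaging)
        elif cls == "slow":
            s0 = rng.uniform(params.soma_margin, params.process_length)
            # Per-organelle mobility heterogeneity: lognormal dispersion of
            # the step SD keeps the population speed distribution continuous
            # between the immobile floor and the fast class; truncated at 3
            # sigma to bound outlier mobilities.
            mult = rng.lognormal(0.0, params.slow_step_dispersion)
            mult = min(mult, float(np.exp(3.0 * params.slow_step_dispersion)))
            step_sd = params.slow_step_sd * mult
            steps = rng.normal(0.0, step_sd, n - 1)
            s = np.concatenate([[s0], s0 + np.cumsum(steps)])
        else:
            s = np.full(n, rng.uniform(params.soma_margin, params.process_length))
        s = s + rng.normal(0.0, params.loc_noise_sd, n)
        s = np.clip(s, 0.0, params.process_length)
        # Transverse position: fixed lane within the process plus jitter,
        # reflected into [0, width].
        y0 = rng.uniform(0.0, params.process_width)
        y = y0 + rng.normal(0.0, params.loc_noise_sd, n)
        y = np.abs(y)
        y = params.process_width - np.abs(params.process_width - y)
        tracks.append(
            Track(
                track_id=i + id_offset,
                frames=frames.copy(),
                x=s,
                y=y,
                complete=True,
                motion_class=cls,
                direction_truth=direction,
                run_state=run_flags,
            )
        )
    return TrackSet(
        tracks=tracks,
        frame_interval=imaging.frame_interval,
        n_frames=n,
        provenance="ground_truth",
    )


def _z_weights(n_z: int, z_pos: float, sigma_z: float = 0.8) -> np.ndarray:
    k = np.arange(n_z)
    w = np.exp(-0.5 * ((k - z_pos) / sigma_z) ** 2)
    return w / w.sum()


def render_movie(
    track_set: TrackSet,
    imaging: ImagingParams,
    seed: int,
    origin: tuple[float, float] | None = None,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Render a track set as a (n_frames, n_z, H, W) photon-count stack.

    Each organelle is a 2-D Gaussian of width ``psf_sigma`` with peak
    ``photon_scale`` photons, distributed across z-slices with Gaussian
    weights around a per-track focal depth (total photons conserved).
    Poisson shot noise on signal + background, then Gaussian read noise.

    ``origin`` is the physical (x, y) of the top-left pixel centre in μm; by
    default the field is fitted to the tracks with a 2 μm margin. With an
    explicit ``origin``/``shape``, tracks outside the field raise an error.
    """
    n_frames = track_set.n_frames
    px = imaging.pixel_size
    margin = max(2.0, 5 * imaging.psf_sigma)
    if origin is None or shape is None:
        if len(track_set.tracks):
            xs = np.concatenate([t.x for t in track_set.tracks])
            ys = np.concatenate([t.y for t in track_set.tracks])
            x0, y0 = xs.min() - margin, ys.min() - margin
            W = int(np.ceil((xs.max() + margin - x0) / px)) + 1
            H = int(np.ceil((ys.max() + margin - y0) / px)) + 1
        else:
            x0, y0, H, W = 0.0, 0.0, 32, 32
        origin = (x0, y0)
        shape = (H, W)
    H, W = shape
    x0, y0 = origin

    sigma_px = imaging.psf_sigma / px
    rad = int(np.ceil(5 * sigma_px))
    signal = np.zeros((n_frames, imaging.n_z, H, W))
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 1_000_003)))

    for t in track_set.tracks:
        cx = (t.x - x0) / px
        cy = (t.y - y0) / px
        if cx.min() < rad or cy.min() < rad or cx.max() > W - 1 - rad or cy.max() > H - 1 - rad:
            if not (0 <= cx.min() and cx.max() <= W - 1 and 0 <= cy.min() and cy.max() <= H - 1):
                raise ValueError(
                    f"track {t.track_id} leaves the field of view "
                    f"(origin={origin}, shape={shape})"
                )
        zw = _z_weights(imaging.n_z, rng.uniform(0, imaging.n_z - 1) if imaging.n_z > 1 else 0.0)
        for fi, frame in enumerate(t.frames):
            ix, iy = int(round(cx[fi])), int(round(cy[fi]))
            xlo, xhi = max(ix - rad, 0), min(ix + rad + 1, W)
            ylo, yhi = max(iy - rad, 0), min(iy + rad + 1, H)
            if xlo >= xhi or ylo >= yhi:
                continue
            gx = np.arange(xlo, xhi) - cx[fi]
            gy = np.arange(ylo, yhi) - cy[fi]
            patch = imaging.photon_scale * np.exp(
                -(gy[:, None] ** 2 + gx[None, :] ** 2) / (2 * sigma_px**2)
            )
            signal[frame, :, ylo:yhi, xlo:xhi] += zw[:, None, None] * patch

    expected = signal + imaging.background
    if imaging.shot_noise:
        movie = rng.poisson(expected).astype(np.float32)
    else:
        movie = expected.astype(np.float32)
    if imaging.read_noise_sd > 0:
        movie = movie + rng.normal(0.0, imaging.read_noise_sd, movie.shape).astype(np.float32)
    return movie


def render_cell_field(
    params: CellFieldParams,
    condition: str,
    seed: int,
    max_retries: int = 2000,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a 3-channel (nucleus, cell mask, marker) field of round cells.

    Cells are discs of ``cell_radius`` with concentric nuclei; the marker
    channel carries a per-cell constant drawn from
    ``normal(marker_mean_per_condition[condition], marker_cell_sd)`` over the
    cytoplasm (cell minus nucleus) plus a uniform background. Returns the
    image stack ``(3, H, W)`` and a ground-truth table with one row per cell
    (centre, true marker mean).
    """
    if condition not in params.marker_mean_per_condition:
        raise ValueError(f"no marker mean configured for condition {condition!r}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 2_000_003)))
    n_px = int(round(params.field_size / params.pixel_size))
    img = np.zeros((3, n_px, n_px), dtype=float)
    img[2] += params.background

    r_cell_px = params.cell_radius / params.pixel_size
    r_nuc_px = params.nucleus_radius / params.pixel_size
    centres: list[tuple[float, float]] = []
    tries = 0
    while len(centres) < params.n_cells:
        if tries > max_retries:
            raise RuntimeError(
                f"could not place {params.n_cells} non-overlapping cells in a "
                f"{params.field_size} μm field after {max_retries} attempts"
            )
        tries += 1
        c = rng.uniform(r_cell_px + 2, n_px - r_cell_px - 3, size=2)
        if all((c[0] - a) ** 2 + (c[1] - b) ** 2 > (2.2 * r_cell_px) ** 2 for a, b in centres):
            centres.append((c[0], c[1]))

    yy, xx = np.mgrid[0:n_px, 0:n_px]
    records = []
    true_mean = float(params.marker_mean_per_condition[condition])
    for cid, (cy, cx) in enumerate(centres):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        cell = d2 <= r_cell_px**2
        nuc = d2 <= r_nuc_px**2
        img[0][nuc] = params.nucleus_intensity
        img[1][cell] = params.cell_intensity
        marker = rng.normal(true_mean, params.marker_cell_sd) if params.marker_cell_sd > 0 else true_mean
        marker = max(marker, 0.0)
        img[2][cell & ~nuc] += marker
        records.append(
            {
                "cell_id": cid,
                "cy_px": cy,
                "cx_px": cx,
                "true_marker_mean": marker,
                "condition": condition,
            }
        )
    truth = pd.DataFrame(records, columns=["cell_id", "cy_px", "cx_px", "true_marker_mean", "condition"])
    return img, truth


def with_overrides(params: MotionModelParams, **kwargs) -> MotionModelParams:
    """Return a copy of ``params`` with fields replaced (validated)."""
    return replace(params, **kwargs)
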