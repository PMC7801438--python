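"""Channel geometry, hydropathy and water-occupancy statistics.

A protein channel is represented by its centerline: an ordered polyline
of 3-D points with optional local radii and a list of channel-lining
residues.  Waters are "in" a channel when their minimum distance to the
centerline polyline (point-to-segment, not point-to-vertex) is within a
cutoff, 3 A by default.  Hydropathy uses the Kyte-Doolittle scale
normalized by 4.5 so values span [-1, 1] (positive = hydrophobic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KD_NORM, KYTE_DOOLITTLE
from .errors import ConfigurationError, DomainError
from .msd import Trajectory

__all__ = [
    "ChannelPath",
    "WaterCountSeries",
    "HydropathyProfile",
    "channel_length",
    "bottleneck",
    "hydropathy_profile",
    "count_channel_waters",
    "water_count_stats",
    "distances_to_centerline",
]

CHANNEL_LABELS = ("interface", "porous", "transient", "other")


@dataclass(frozen=True)
class ChannelPath:
    """Ordered channel centerline with optional radii and lining residues."""

    points: np.ndarray  # (n, 3) A
    radii: np.ndarray | None = None  # (n,) A
    lining_residues: tuple[tuple[str, int], ...] | None = None
    label: str = "other"

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[1] != 3 or pts.shape[0] < 1:
            raise DomainError("points must be an (n>=1, 3) array")
        if pts.shape[0] > 1 and np.any(
            np.linalg.norm(np.diff(pts, axis=0), axis=1) == 0
        ):
            raise DomainError("consecutive centerline points must be distinct")
        radii = self.radii
        if radii is not None:
            radii = np.asarray(radii, dtype=float)
            if radii.shape != (pts.shape[0],):
                raise DomainError("radii must match the number of points")
            if np.any(radii <= 0):
                raise DomainError("radii must be positive")
        lining = self.lining_residues
        if lining is not None:
            lining = tuple((str(n).upper(), int(i)) for n, i in lining)
        if self.label not in CHANNEL_LABELS:
            raise DomainError(f"label must be one of {CHANNEL_LABELS}")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "lining_residues", lining)


@dataclass(frozen=True)
class WaterCountSeries:
    """Per-frame counts of channel-resident waters at a given cutoff."""

    frame_times: np.ndarray  # ps
    counts: np.ndarray  # non-negative integers
    cutoff: float  # A

    def __post_init__(self) -> None:
        t = np.asarray(self.frame_times, dtype=float)
        c = np.asarray(self.counts, dtype=np.int64)
        if t.shape != c.shape or t.ndim != 1:
            raise DomainError("frame_times and counts must be equal-length 1-D")
        if np.any(c < 0):
            raise DomainError("counts must be non-negative")
        object.__setattr__(self, "frame_times", t)
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class HydropathyProfile:
    """Per-segment mean normalized hydropathy plus the overall extremes."""

    segment_means: np.ndarray
    overall_min: float
    overall_max: float


def channel_length(path: ChannelPath) -> float:
    """Polyline arc length in A (0 for a single point)."""
    if path.points.shape[0] < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(path.points, axis=0), axis=1).sum())


def bottleneck(path: ChannelPath) -> tuple[float, int]:
    """Minimum local radius and its first index.

    The corresponding channel "width" reported alongside profiles is the
    diameter, 2 * radius.
    """
    if path.radii is None:
        raise ConfigurationError("channel path carries no radii")
    i = int(np.argmin(path.radii))
    return float(path.radii[i]), i


def hydropathy_profile(path: ChannelPath, n_segments: int) -> HydropathyProfile:
    """Mean normalized Kyte-Doolittle hydropathy per centerline segment.

    Lining residues carry no coordinates, so they are assigned to
    segments in order, split as evenly as possible along the channel.
    Values are raw KD / 4.5, hence in [-1, 1].  Segments left empty when
    n_segments exceeds the residue count are NaN.
    """
    if not path.lining_residues:
        raise ConfigurationError("channel path carries no lining residues")
    if n_segments < 1:
        raise DomainError("n_segments must be >= 1")
    vals = []
    for name, _num in path.lining_residues:
        if name not in KYTE_DOOLITTLE:
            raise DomainError(f"unknown residue name {name!r}")
        vals.append(KYTE_DOOLITTLE[name] / KD_NORM)
    vals = np.asarray(vals)
    seg_of = np.floor(np.arange(vals.size) * n_segments / vals.size).astype(int)
    means = np.full(n_segments, np.nan)
    for s in range(n_segments):
        sel = seg_of == s
        if sel.any():
            means[s] = vals[sel].mean()
    return HydropathyProfile(
        segment_means=means,
        overall_min=float(vals.min()),
        overall_max=float(vals.max()),
    )


def distances_to_centerline(coords: np.ndarray, path: ChannelPath) -> np.ndarray:
    """Minimum distance of each point to the centerline polyline.

    Point-to-segment distances (projection clamped to the segment) are
    minimized over all segments; a single-point centerline degrades to
    point-to-point distance.  coords: (n, 3); returns (n,).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    pts = path.points
    if pts.shape[0] == 1:
        return np.linalg.norm(coords - pts[0], axis=1)
    p0 = pts[:-1]  # (S, 3)
    d = pts[1:] - p0  # (S, 3)
    L2 = np.einsum("sd,sd->s", d, d)  # nonzero by invariant
    # (n, S) projection parameter, clamped to the segment
    t = np.einsum("nsd,sd->ns", coords[:, None, :] - p0[None], d) / L2
    t = np.clip(t, 0.0, 1.0)
    closest = p0[None] + t[:, :, None] * d[None]
    diff = coords[:, None, :] - closest
    dist2 = np.einsum("nsd,nsd->ns", diff, diff)
    return np.sqrt(dist2.min(axis=1))


def count_channel_waters(
    traj: Trajectory,
    path: ChannelPath,
    cutoff: float = 3.0,
    water_selection=None,
) -> WaterCountSeries:
    """Per-frame count of selected waters within ``cutoff`` of the centerline.

    The boundary case (distance exactly equal to the cutoff) counts as
    inside.  Callers pass the particle ids of the water oxygens; the
    module performs no chemistry.
    """
    if cutoff <= 0:
        raise DomainError("cutoff must be positive")
    idx = traj.indices_of(water_selection)
    counts = np.empty(traj.n_frames, dtype=np.int64)
    for f in range(traj.n_frames):
        dist = distances_to_centerline(traj.positions[f, idx, :], path)
        counts[f] = int(np.count_nonzero(dist <= cutoff))
    return WaterCountSeries(traj.times, counts, float(cutoff))


def water_count_stats(
    series: WaterCountSeries, frame_stride: int | None = None
) -> tuple[float, float | None]:
    """Mean and sample SD (n-1) of water counts over strided frames.

    The default stride aims at frames ~100 ps apart, keeping the last ~10
    such frames when the series is longer (the tail of an equilibrated
    run); with fewer than 2 strided frames the SD is None.
    """
    n = series.counts.size
    if n == 0:
        raise DomainError("empty water-count series")
    if frame_stride is None:
        if n >= 2:
            dt = float(series.frame_times[1] - series.frame_times[0])
            frame_stride = max(1, int(round(100.0 / dt))) if dt > 0 else 1
        else:
            frame_stride = 1
    if frame_stride < 1:
        raise DomainError("frame_stride must be >= 1")
    strided = series.counts[::-1][::frame_stride][::-1]  # keep the last frames
    if strided.size > 10:
        strided = strided[-10:]
    mean = float(strided.mean())
    sd = float(strided.std(ddof=1)) if strided.size >= 2 else None
    return mean, sd
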