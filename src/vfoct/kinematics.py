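"""Surface point tracking and mucosal-wave velocity fields.

Per frame and per fold, 30 points are distributed equidistantly along the
lateral (x) extent of the superior EP surface, from the medial free edge
(index 0) to the lateral end of the detected superior contour.
Correspondence between frames is index-wise — point *i* at frame *t+1* is
paired with point *i* at frame *t* at the same relative x position; this is
a fixed-abscissa scheme, not feature tracking, so material points are only
approximated.

Velocity components per point, using the frame interval:

* ``vy`` (mm/s): vertical, positive toward superior (decreasing row);
* ``vx`` (mm/s): lateral, positive toward the anatomic midline.

Frames flagged unsegmentable create gaps in the field; velocities are never
interpolated across them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import ScanGeometry
from .segmentation import LayerSegmentation

__all__ = ["SurfaceTrack", "VelocityField", "sample_surface_points",
           "track_sequence", "point_displacements", "velocities",
           "net_vectors", "build_velocity_field"]

N_POINTS = 30


@dataclass
class SurfaceTrack:
    """Sampled superior-surface points: (n_frames, n_points, 2) of (row, col).

    NaN rows mark frames where the side was not segmented.  Index 0 is the
    medial edge; columns are strictly monotonic toward lateral.
    """

    side: str
    points: np.ndarray
    n_points: int = N_POINTS


def sample_surface_points(seg: LayerSegmentation, side: str,
                          n_points: int = N_POINTS) -> np.ndarray:
    """One frame's n equidistant surface points, medial to lateral.

    Columns are equally spaced between the medial edge and the lateral
    extent of the EP-outer profile; rows are linearly interpolated from the
    per-A-line profile.  Raises ``ValueError`` when the fold is narrower
    than ``n_points`` columns.
    """
    if not seg.has_side(side):
        raise ValueError(f"side {side!r} not segmented")
    cols = seg.side_columns(side)
    rows = seg.profiles[side]["ep_outer"]
    lo, hi = int(cols.min()), int(cols.max())
    if hi - lo + 1 < n_points:
        raise ValueError(
            f"fold width {hi - lo + 1} px < {n_points} sample points")
    if side == "left":
        medial, lateral = hi, lo   # medial edge borders the midline
    else:
        medial, lateral = lo, hi
    xs = np.linspace(medial, lateral, n_points)
    valid = ~np.isnan(rows)
    ys = np.interp(xs, np.flatnonzero(valid), rows[valid])
    return np.column_stack([ys, xs])


def track_sequence(segmentations: list[LayerSegmentation], side: str,
                   n_points: int = N_POINTS) -> SurfaceTrack:
    """Sample surface points on every segmentable frame of a sequence."""
    n = len(segmentations)
    pts = np.full((n, n_points, 2), np.nan)
    for i, seg in enumerate(segmentations):
        if seg.unsegmentable or not seg.has_side(side):
            continue
        try:
            pts[i] = sample_surface_points(seg, side, n_points)
        except ValueError:
            continue
    return SurfaceTrack(side=side, points=pts, n_points=n_points)


def point_displacements(track_t: np.ndarray,
                        track_t1: np.ndarray) -> np.ndarray:
    """Index-wise (drow, dcol) in px from frame t to t+1; (n_points, 2)."""
    track_t = np.asarray(track_t, dtype=float)
    track_t1 = np.asarray(track_t1, dtype=float)
    if track_t.shape != track_t1.shape:
        raise ValueError("tracks must have equal shape")
    return track_t1 - track_t


@dataclass
class VelocityField:
    """Per frame-pair, per point velocities of one fold.

    ``vx``/``vy``/``speed`` have shape (n_frames − 1, n_points), mm/s; NaN
    where either frame of the pair was unsegmented (gap).  ``direction`` is
    atan2(vy, vx) in radians.
    """

    side: str
    vx: np.ndarray
    vy: np.ndarray

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)

    @property
    def direction(self) -> np.ndarray:
        return np.arctan2(self.vy, self.vx)


def velocities(displacements_px: np.ndarray, geometry: ScanGeometry,
               side: str) -> tuple[np.ndarray, np.ndarray]:
    """Convert per-point (drow, dcol) px displacements to (vx, vy) mm/s.

    vy = −drow × tissue axial pitch × frame rate (positive = superior);
    vx = ±dcol × lateral pitch × frame rate, sign chosen so positive points
    toward the anatomic midline (image-left fold: +col is medial;
    image-right fold: −col is medial).
    """
    d = np.asarray(displacements_px, dtype=float)
    fr = geometry.frame_rate
    vy = -d[..., 0] * geometry.axial_pitch_tissue * fr / 1000.0
    medial_sign = 1.0 if side == "left" else -1.0
    vx = medial_sign * d[..., 1] * geometry.lateral_pitch * fr / 1000.0
    return vx, vy


def build_velocity_field(track: SurfaceTrack,
                         geometry: ScanGeometry) -> VelocityField:
    """Velocity field of a whole track (length n_frames − 1)."""
    disp = track.points[1:] - track.points[:-1]
    vx, vy = velocities(disp, geometry, track.side)
    return VelocityField(side=track.side, vx=vx, vy=vy)


def net_vectors(field: VelocityField) -> tuple[np.ndarray, np.ndarray]:
    """Polar form of the 2D velocity: (speed mm/s, direction rad)."""
    return field.speed, field.direction
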