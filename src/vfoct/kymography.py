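"""Depth-resolved videokymography and space-time velocity renderings.

A depth-resolved kymograph stacks per-A-line layer thickness over time: one
matrix row per frame, one column per A-line, cell value = thickness (μm) of
the chosen layer, with a reserved AIR sentinel where the A-line holds no
tissue (the glottal opening).  AIR is rendered light gray and is never
conflated with 0 μm.

Velocity maps place the two folds on one shared lateral axis of 2 × n
points, indices running lateral → medial on the image-left fold and
medial → lateral on the image-right fold, so the two medial free edges meet
at the center of the axis.  Vector maps draw the net 2D velocity as arrows:
up = superior, toward the axis center = anatomic medial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .calibration import ScanGeometry
from .kinematics import VelocityField
from .morphometry import ThicknessProfile

__all__ = ["AIR", "Kymograph", "build_vkg", "vkg_periodicity",
           "shared_axis_matrix", "render_vkg", "render_velocity_map",
           "render_vector_map"]

#: Sentinel for "no tissue on this A-line" — outside the valid thickness
#: range (thickness is never negative).
AIR = -1.0


@dataclass
class Kymograph:
    """Space-time thickness matrix [n_frames × n_alines] for one layer."""

    matrix: np.ndarray
    layer: str                      # ep | lp | combined
    frame_rate: float
    lateral_pitch: float            # μm/px

    @property
    def times(self) -> np.ndarray:
        """Time of each matrix row, s (row r ↔ r / frame_rate exactly)."""
        return np.arange(self.matrix.shape[0]) / self.frame_rate

    def air_fraction(self, columns: slice | np.ndarray | None = None) -> float:
        sub = self.matrix if columns is None else self.matrix[:, columns]
        return float(np.mean(sub == AIR))


def build_vkg(profiles_over_time: list[dict[str, ThicknessProfile]],
              layer: str, frame_rate: float,
              lateral_pitch: float) -> Kymograph:
    """Stack per-frame thickness profiles into a kymograph.

    ``profiles_over_time`` holds, per frame, the per-side profiles from
    :func:`vfoct.morphometry.thickness_profile`.  Cells carry the profile
    values exactly; A-lines with no tissue on either side carry AIR.
    """
    if not profiles_over_time:
        raise ValueError("empty profile sequence")
    n_cols = len(next(iter(profiles_over_time[0].values())).ep)
    n = len(profiles_over_time)
    mat = np.full((n, n_cols), AIR)
    for i, sides in enumerate(profiles_over_time):
        for prof in sides.values():
            vals = getattr(prof, layer)
            ok = ~np.isnan(vals)
            mat[i, ok] = vals[ok]
    return Kymograph(matrix=mat, layer=layer, frame_rate=frame_rate,
                     lateral_pitch=lateral_pitch)


def vkg_periodicity(kymo: Kymograph, band_width: int = 16,
                    min_rel_power: float = 0.05, min_sd_um: float = 5.0):
    """Dominant oscillation period (s) per lateral band of a kymograph.

    Each band of ``band_width`` A-lines is reduced to one signal per frame
    (mean thickness with AIR counted as 0, capturing both tissue/air
    alternation and thickness oscillation), detrended, and the period of
    the largest spectral peak is reported.  Bands whose signal is constant
    — standard deviation below ``min_sd_um`` (about the scale of sub-pixel
    boundary quantization ripple, ~1 px × the axial pitch) — or whose peak
    carries less than ``min_rel_power`` of the variance get None.

    Returns (band_start_columns, periods) with ``periods`` a list of
    float-or-None.
    """
    mat = np.where(kymo.matrix == AIR, 0.0, kymo.matrix)
    n, n_cols = mat.shape
    if n < 4:
        raise ValueError("need at least 4 frames for periodicity")
    starts = np.arange(0, n_cols, band_width)
    periods: list[float | None] = []
    for s in starts:
        sig = mat[:, s:s + band_width].mean(axis=1)
        sig = sig - sig.mean()
        var = float(np.var(sig))
        if var <= min_sd_um ** 2:
            periods.append(None)
            continue
        spec = np.abs(np.fft.rfft(sig)) ** 2
        spec[0] = 0.0
        k = int(np.argmax(spec))
        if k == 0 or spec[k] < min_rel_power * var * n:
            periods.append(None)
            continue
        freq = k * kymo.frame_rate / n
        periods.append(1.0 / freq)
    return starts, periods


def symmetry_report(kymo: Kymograph, midline_col: int,
                    band_width: int = 16) -> dict:
    """Left/right mucosal-wave comparison of a kymograph.

    Mirrors lateral bands about the glottal midline and reports the ratio
    of dominant periods (left / right) per mirrored band pair, plus the
    ratio of mean tissue thickness; 1.0 = symmetric.
    """
    starts, periods = vkg_periodicity(kymo, band_width=band_width)
    pairs = []
    for s, p in zip(starts, periods):
        if s + band_width <= midline_col:
            mirror = 2 * midline_col - s - band_width
            j = int(np.argmin(np.abs(starts - mirror)))
            q = periods[j]
            if p is not None and q is not None:
                pairs.append((int(s), p / q))
    left = kymo.matrix[:, :midline_col]
    right = kymo.matrix[:, midline_col:]
    lt = left[left != AIR]
    rt = right[right != AIR]
    thick_ratio = float(lt.mean() / rt.mean()) if lt.size and rt.size else None
    return {"period_ratios": pairs, "thickness_ratio": thick_ratio}


def render_vkg(kymo: Kymograph, ax=None, vmin=None, vmax=None):
    """Render a kymograph; AIR cells appear light gray."""
    if ax is None:
        _, ax = plt.subplots()
    data = np.ma.masked_equal(kymo.matrix, AIR)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad(color="0.85")
    extent = (0, kymo.matrix.shape[1], kymo.times[-1], 0)
    im = ax.imshow(data, cmap=cmap, aspect="auto", extent=extent,
                   vmin=vmin, vmax=vmax)
    ax.set_xlabel("A-line")
    ax.set_ylabel("time (s)")
    ax.set_title(f"{kymo.layer} thickness (μm)")
    plt.colorbar(im, ax=ax)
    return ax


def shared_axis_matrix(field_left: VelocityField, field_right: VelocityField,
                       component: str) -> np.ndarray:
    """Velocity component on the shared 2n-point lateral axis.

    Columns 0..n−1: image-left fold, lateral → medial; columns n..2n−1:
    image-right fold, medial → lateral (the medial edges meet mid-axis).
    Values equal the field values exactly.
    """
    if component not in ("vertical", "horizontal"):
        raise ValueError("component must be 'vertical' or 'horizontal'")
    lv = field_left.vy if component == "vertical" else field_left.vx
    rv = field_right.vy if component == "vertical" else field_right.vx
    return np.concatenate([lv[:, ::-1], rv], axis=1)


def render_velocity_map(field_left: VelocityField, field_right: VelocityField,
                        component: str, frame_rate: float, ax=None):
    """Signed space-time velocity map on the shared axis.

    Returns (ax, matrix); the color scale is symmetric about zero and the
    underlying matrix is returned unmodified alongside the image.
    """
    mat = shared_axis_matrix(field_left, field_right, component)
    if ax is None:
        _, ax = plt.subplots()
    lim = float(np.nanmax(np.abs(mat))) if np.isfinite(mat).any() else 1.0
    lim = lim or 1.0
    n_pairs = mat.shape[0]
    extent = (0, mat.shape[1], n_pairs / frame_rate, 0)
    im = ax.imshow(mat, cmap="RdBu_r", vmin=-lim, vmax=lim, aspect="auto",
                   extent=extent)
    ax.set_xlabel("surface point (shared axis, medial edges at center)")
    ax.set_ylabel("time (s)")
    ax.set_title(f"{component} velocity (mm/s)")
    plt.colorbar(im, ax=ax)
    return ax, mat


def render_vector_map(field_left: VelocityField, field_right: VelocityField,
                      frame_rate: float,
                      time_window: tuple[float, float] | None = None,
                      stride: int = 1, ax=None):
    """Quiver map of net 2D velocity vectors over (point, time).

    Arrow length ∝ speed; up = superior, toward the center of the shared
    axis = anatomic medial.  A reference arrow provides the speed scale.
    Raises ``ValueError`` on an empty time window.
    """
    vx_l = shared_axis_matrix(field_left, field_right, "horizontal")
    vy = shared_axis_matrix(field_left, field_right, "vertical")
    n_pairs, n_pts = vy.shape
    times = np.arange(n_pairs) / frame_rate
    if time_window is not None:
        t0, t1 = time_window
        sel = (times >= t0) & (times < t1)
        if not sel.any():
            raise ValueError("empty time window")
    else:
        sel = np.ones(n_pairs, dtype=bool)
    idx = np.flatnonzero(sel)[::stride]

    # medial on the shared axis = toward its center
    plot_dx = np.where(np.arange(n_pts) < n_pts // 2, vx_l, -vx_l)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    tt, pp = np.meshgrid(times[idx], np.arange(n_pts), indexing="ij")
    q = ax.quiver(pp, tt, plot_dx[idx], vy[idx], angles="xy")
    ax.quiverkey(q, 0.9, 1.05, 10, "10 mm/s", labelpos="E")
    ax.invert_yaxis()
    ax.set_xlabel("surface point (shared axis)")
    ax.set_ylabel("time (s)")
    return ax
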