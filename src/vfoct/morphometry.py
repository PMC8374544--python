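"""Per-A-line layer thickness, vertical displacement, and summary statistics.

Thickness is measured along A-lines (vertically, in whole image columns),
as the row distance between bounding layer contours times the tissue axial
pitch.  This mirrors how the measurements are defined on the pixel grid;
note that near the medial edge, mechanical stretching of the layers inflates
vertical thickness relative to the surface-normal thickness — that bias is
inherent to the A-line definition and is reproduced, not corrected.

Vertical displacement tracks the superior-medial point of each fold (the
topmost surface point within a medial band next to the glottal midline);
its baseline is the mean position over the labeled rest frames, and the
vibration amplitude is the largest absolute displacement during phonation.

Summaries report, per layer and phase, the full-distribution mean ± SD and
a single-pass "select" distribution restricted to points within ±3 SD of
the full mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import ScanGeometry
from .segmentation import LayerSegmentation, SIDES
from .sequence import PHONATION, REST

__all__ = [
    "ThicknessProfile", "DisplacementSeries", "ThicknessSummary",
    "thickness_profile", "superior_medial_point", "vertical_displacement",
    "summarize_thickness",
]


@dataclass
class ThicknessProfile:
    """Per-A-line EP / LP / combined thickness (μm) for one frame and side.

    Arrays span the full frame width; NaN marks A-lines where the layer is
    absent (NaN is "absent", never 0 μm).  ``combined`` is the exact sum of
    ``ep`` and ``lp`` wherever both are present.
    """

    frame_index: int
    side: str
    ep: np.ndarray
    lp: np.ndarray
    combined: np.ndarray


def thickness_profile(seg: LayerSegmentation, geometry: ScanGeometry,
                      frame_index: int = 0) -> dict[str, ThicknessProfile]:
    """Thickness per A-line from a segmentation, for both sides.

    EP thickness = (interface row − EP outer row) × tissue pitch; LP
    thickness = (deep LP row − interface row) × tissue pitch.  A-lines where
    a bounding contour is missing yield NaN for that layer.
    """
    pitch = geometry.axial_pitch_tissue
    out = {}
    for side in SIDES:
        prof = seg.profiles[side]
        ep = (prof["ep_lp_interface"] - prof["ep_outer"]) * pitch
        lp = (prof["lp_deep"] - prof["ep_lp_interface"]) * pitch
        combined = ep + lp
        out[side] = ThicknessProfile(frame_index=frame_index, side=side,
                                     ep=ep, lp=lp, combined=combined)
    return out


def superior_medial_point(seg: LayerSegmentation, side: str,
                          medial_band: float = 0.10) -> tuple[float, float] | None:
    """Topmost EP-outer point within the medial band of a fold.

    The band spans ``medial_band`` (default 10%) of the fold width nearest
    the glottal midline; the minimum-row point in the band is returned as
    (row, col), ties broken toward the midline.  None when the side is not
    segmented.
    """
    if not seg.has_side(side):
        return None
    cols = seg.side_columns(side)
    rows = seg.profiles[side]["ep_outer"]
    width = cols.max() - cols.min() + 1
    n_band = max(1, int(np.ceil(medial_band * width)))
    if side == "left":  # medial edge = rightmost columns
        band = cols[cols >= cols.max() - n_band + 1][::-1]
    else:               # medial edge = leftmost columns
        band = cols[cols <= cols.min() + n_band - 1]
    band_rows = rows[band]
    best = int(np.argmin(band_rows))  # first occurrence = most medial on tie
    return float(band_rows[best]), float(band[best])


@dataclass
class DisplacementSeries:
    """Superior-medial point track of one fold, in metric units.

    ``position_mm`` is the superior distance of the tracked point from image
    row 0 (larger = more superior); ``displacement_mm`` subtracts the
    baseline (mean over rest frames; positive = superior of rest).
    ``amplitude_mm`` is max |displacement| over phonation frames.
    """

    side: str
    frame_indices: np.ndarray
    point_row: np.ndarray      # px, NaN where unsegmented
    point_col: np.ndarray
    position_mm: np.ndarray
    baseline_mm: float
    displacement_mm: np.ndarray
    amplitude_mm: float
    baseline_from_rest: bool


def vertical_displacement(segmentations: list[LayerSegmentation],
                          geometry: ScanGeometry,
                          phase_labels: np.ndarray, side: str,
                          medial_band: float = 0.10) -> DisplacementSeries:
    """Track the superior-medial point across frames and convert to mm.

    Baseline = mean position over frames labeled ``rest``; if there are
    none, the first segmented phonation frame is used and flagged.  Raises
    ``ValueError`` if no frame on this side is segmented.
    """
    n = len(segmentations)
    rows = np.full(n, np.nan)
    cols = np.full(n, np.nan)
    for i, seg in enumerate(segmentations):
        if seg.unsegmentable:
            continue
        pt = superior_medial_point(seg, side, medial_band=medial_band)
        if pt is not None:
            rows[i], cols[i] = pt
    if np.all(np.isnan(rows)):
        raise ValueError(f"no segmented frames on side {side!r}")

    # larger position = more superior (toward row 0)
    position_mm = -rows * geometry.axial_pitch_tissue / 1000.0
    labels = np.asarray(phase_labels, dtype=object)
    rest = (labels == REST) & ~np.isnan(rows)
    if rest.any():
        baseline = float(np.mean(position_mm[rest]))
        from_rest = True
    else:
        first = int(np.flatnonzero(~np.isnan(rows))[0])
        baseline = float(position_mm[first])
        from_rest = False
    displacement = position_mm - baseline
    phon = (labels == PHONATION) & ~np.isnan(rows)
    if phon.any():
        amplitude = float(np.nanmax(np.abs(displacement[phon])))
    else:
        amplitude = float(np.nanmax(np.abs(displacement)))
    return DisplacementSeries(
        side=side, frame_indices=np.arange(n), point_row=rows, point_col=cols,
        position_mm=position_mm, baseline_mm=baseline,
        displacement_mm=displacement, amplitude_mm=amplitude,
        baseline_from_rest=from_rest)


@dataclass
class ThicknessSummary:
    """Full and ±3 SD "select" statistics of one layer in one phase (μm)."""

    layer: str
    phase: str
    n_points: int
    mean_full: float
    sd_full: float
    mean_select: float
    sd_select: float
    n_excluded: int


def summarize_thickness(values: np.ndarray, layer: str,
                        phase: str) -> ThicknessSummary:
    """Mean ± SD of thickness points, full and ±3 SD-trimmed ("select").

    The select distribution keeps points within mean ± 3 SD of the *full*
    distribution, in a single pass (the exclusion is not iterated).  NaNs
    (absent A-lines) are ignored.  SD is the sample standard deviation
    (ddof = 1).  Raises ``ValueError`` on fewer than two finite points.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise ValueError("need at least 2 thickness points")
    mean_full = float(v.mean())
    sd_full = float(v.std(ddof=1))
    keep = np.abs(v - mean_full) <= 3.0 * sd_full
    sel = v[keep]
    mean_sel = float(sel.mean())
    sd_sel = float(sel.std(ddof=1)) if sel.size > 1 else 0.0
    return ThicknessSummary(
        layer=layer, phase=phase, n_points=int(v.size),
        mean_full=mean_full, sd_full=sd_full,
        mean_select=mean_sel, sd_select=sd_sel,
        n_excluded=int(v.size - sel.size))


def summarize_profiles(profiles: list[ThicknessProfile], phase: str,
                       ) -> list[ThicknessSummary]:
    """Table-style summaries (EP, LP, combined) over a set of profiles."""
    if not profiles:
        raise ValueError("empty profile list")
    out = []
    for layer in ("ep", "lp", "combined"):
        vals = np.concatenate([getattr(p, layer) for p in profiles])
        out.append(summarize_thickness(vals, layer=layer, phase=phase))
    return out
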