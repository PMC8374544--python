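"""Dynamic intensity-based thresholding and fold layer segmentation.

OCT frames of the vocal folds have a characteristically tri-modal intensity
histogram: a noise-floor mode, an epithelium (EP) mode, and a brighter
lamina-propria (LP) mode (denser, more scattering tissue backscatters more).
Per frame, the histogram is smoothed with a quadratic univariate spline and
the local minima (troughs) separating the three most massive peaks are taken
as thresholds:

* ``t_noise_ep`` — separates noise/air from tissue; iso-contours at this
  level trace the EP outer (superior/air) boundary and, on the deep side,
  the transition where the LP signal falls into the noise floor (the deep LP
  boundary).
* ``t_ep_lp`` — separates EP from LP; iso-contours at this level trace the
  EP/LP interface (the basement-membrane zone lies between the two).

Frames whose histogram does not show three peaks fall back to the previous
accepted frame's thresholds when available (consecutive 4 ms frames are
temporally coherent), else to fixed fractions of the occupied intensity
range.

Contours are extracted sub-pixel with marching squares and then filtered:
small speckle islands are rejected by enclosed area, surviving contours are
split at the glottal midline (the column of least tissue occupancy between
the two folds) and reduced, per side, to three per-A-line boundary profiles
(EP outer, EP/LP interface, deep LP) whose vertical ordering is enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy import ndimage
from skimage import measure

__all__ = [
    "IntensityHistogram", "ThresholdSet", "Contour", "LayerSegmentation",
    "build_histogram", "find_thresholds", "extract_contours",
    "filter_and_assign", "detect_midline", "segment_frame",
    "segment_sequence",
]

SIDES = ("left", "right")
LAYERS = ("ep_outer", "ep_lp_interface", "lp_deep")

#: Default fractions of the occupied intensity range used when the
#: histogram does not expose three peaks and no earlier frame can be
#: carried forward.
DEFAULT_RATIOS = (0.25, 0.55)

#: Spline smoothing factor, as a fraction of total pixel count: the spline's
#: allowed sum of squared residuals is ``SPLINE_SMOOTHING * n_pixels`` on
#: the count histogram.  Chosen to suppress per-bin speckle counting noise
#: (variance ~ count) while keeping the three characteristic peaks.
SPLINE_SMOOTHING = 2.0

#: Two adjacent peaks whose separating trough is shallower than this
#: fraction of the lower flanking peak are treated as one mode.  Depth
#: attenuation smears the LP mode over a wide intensity band with internal
#: wiggles; only troughs that drop well below both flanks mark true mode
#: boundaries.
TROUGH_DEPTH_RATIO = 0.5


@dataclass
class IntensityHistogram:
    """Per-frame intensity histogram with its spline smoothing."""

    bin_edges: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray | None = None
    troughs: np.ndarray | None = None  # intensity values, ascending

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ThresholdSet:
    """The two intensity cuts separating noise | EP | LP, and their origin."""

    t_noise_ep: float
    t_ep_lp: float
    source: str = "histogram"  # histogram | default_ratio | carried_forward

    def __post_init__(self) -> None:
        if not self.t_noise_ep < self.t_ep_lp:
            raise ValueError("t_noise_ep must be < t_ep_lp")


@dataclass
class Contour:
    """Ordered sub-pixel polyline in (row, col) image coordinates."""

    points: np.ndarray
    closed: bool
    level: float
    side: str | None = None      # left | right
    layer: str | None = None     # ep_outer | ep_lp_interface | lp_deep

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if self.closed and len(self.points) < 3:
            raise ValueError("closed contour needs >= 3 points")

    def enclosed_area(self) -> float:
        """Shoelace area (px²); 0 for open contours."""
        if not self.closed:
            return 0.0
        r = self.points[:, 0]
        c = self.points[:, 1]
        return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))


@dataclass
class LayerSegmentation:
    """Per-frame, per-side layer boundaries as per-A-line row profiles.

    ``profiles[side][layer]`` is a length-``n_cols`` float array of boundary
    rows, NaN where the layer is absent on that A-line.  Columns at or left
    of ``midline_col`` belong to the image-left fold.
    """

    frame_shape: tuple[int, int]
    midline_col: float
    thresholds: ThresholdSet
    profiles: dict = field(default_factory=dict)
    contours: list = field(default_factory=list)
    unsegmentable: bool = False
    alignment_ok: bool = True

    def side_columns(self, side: str) -> np.ndarray:
        """Columns on ``side`` where the EP outer boundary exists."""
        rows = self.profiles[side]["ep_outer"]
        return np.flatnonzero(~np.isnan(rows))

    def has_side(self, side: str) -> bool:
        return len(self.side_columns(side)) > 0


def build_histogram(frame: np.ndarray, n_bins: int = 256) -> IntensityHistogram:
    """Histogram of a frame's intensities over its occupied value range."""
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")
    frame = np.asarray(frame)
    lo, hi = float(frame.min()), float(frame.max())
    if hi == lo:
        hi = lo + 1.0  # single occupied bin, no error
    counts, edges = np.histogram(frame, bins=n_bins, range=(lo, hi))
    return IntensityHistogram(bin_edges=edges, counts=counts)


def _smooth_counts(hist: IntensityHistogram,
                   smoothing: float = SPLINE_SMOOTHING) -> np.ndarray:
    centers = hist.bin_centers
    counts = hist.counts.astype(float)
    s = smoothing * max(hist.total, 1)
    spl = UnivariateSpline(centers, counts, k=2, s=s)
    return np.clip(spl(centers), 0.0, None)


def _local_extrema(y: np.ndarray):
    """Indices of local maxima and minima with plateau handling.

    A plateau counts once, at its center.  Endpoints are not extrema.
    """
    n = len(y)
    maxima, minima = [], []
    i = 1
    while i < n - 1:
        j = i
        while j < n - 1 and y[j + 1] == y[j]:
            j += 1
        left, right = y[i - 1], y[min(j + 1, n - 1)]
        center = (i + j) // 2
        if y[i] > left and y[i] > right:
            maxima.append(center)
        elif y[i] < left and y[i] < right:
            minima.append(center)
        i = j + 1
    return np.array(maxima, dtype=int), np.array(minima, dtype=int)


def _trough_between(hist: IntensityHistogram, smoothed: np.ndarray,
                    i_peak_lo: int, i_peak_hi: int) -> float:
    """Intensity of the trough between two peak bin indices.

    When the raw counts between the peaks are dominated by one zero run
    (covering at least half the interval — truly separated modes), its
    center is the trough; otherwise the (flat-run centered) minimum of the
    smoothed curve is used.
    """
    centers = hist.bin_centers
    lo, hi = i_peak_lo + 1, i_peak_hi  # exclusive of the peaks
    if hi <= lo:
        return float(centers[(i_peak_lo + i_peak_hi) // 2])
    raw = hist.counts[lo:hi]
    runs = _runs_of(raw == 0)
    if runs and max(r[1] for r in runs) >= 0.5 * (hi - lo):
        start, length = max(runs, key=lambda r: r[1])
        center_idx = lo + start + (length - 1) // 2
        if length % 2 == 0:
            # even run: midpoint between the two central bins
            a = centers[lo + start + length // 2 - 1]
            b = centers[lo + start + length // 2]
            return float(0.5 * (a + b))
        return float(centers[center_idx])
    seg = smoothed[lo:hi]
    m = seg.min()
    # near-minimum plateau: everything within 2% of the segment's dynamic
    # range above the minimum counts as the trough region; take the center
    # of its longest contiguous run (the smoothed curve can wiggle at the
    # bottom of a wide, nearly empty gap)
    tol = m + 0.02 * (seg.max() - m)
    runs = _runs_of(seg <= tol)
    start, length = max(runs, key=lambda r: r[1])
    return float(centers[lo + start + (length - 1) // 2])


def _runs_of(mask: np.ndarray):
    """(start, length) of each run of True in ``mask``."""
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def find_thresholds(hist: IntensityHistogram,
                    fallback: ThresholdSet | None = None,
                    smoothing: float = SPLINE_SMOOTHING,
                    default_ratios: tuple[float, float] = DEFAULT_RATIOS,
                    ) -> ThresholdSet:
    """Locate the two histogram troughs separating noise, EP, and LP.

    The count histogram is smoothed with a quadratic univariate spline;
    local minima of the smoothed curve are candidate troughs.  When three or
    more peaks are present, the three of greatest mass (sum of raw counts in
    the peak's basin) are kept, in ascending intensity, and the two troughs
    between them become ``t_noise_ep`` and ``t_ep_lp``.  Within a flat or
    zero trough region the center is taken.

    With fewer than three peaks the previous accepted frame's thresholds
    are carried forward when provided; otherwise thresholds are placed at
    ``default_ratios`` of the occupied intensity range.  A degenerate
    single-bin histogram with no fallback raises ``ValueError``.
    """
    occupied = np.flatnonzero(hist.counts)
    if len(occupied) < 2:
        if fallback is not None:
            return ThresholdSet(fallback.t_noise_ep, fallback.t_ep_lp,
                                source="carried_forward")
        raise ValueError("degenerate histogram and no fallback thresholds")

    smoothed = _smooth_counts(hist, smoothing)
    hist.smoothed = smoothed
    maxima, _ = _local_extrema(smoothed)
    # first/last occupied bins can be modes clipped at the range edge
    edge_candidates = []
    if len(maxima) == 0 or maxima.min() > occupied[0]:
        if smoothed[occupied[0]] > 0:
            edge_candidates.append(occupied[0])
    if len(maxima) == 0 or maxima.max() < occupied[-1]:
        if smoothed[occupied[-1]] > 0:
            edge_candidates.append(occupied[-1])
    peaks = np.unique(np.concatenate([maxima, np.array(edge_candidates,
                                                       dtype=int)]))

    peaks = _merge_shallow_peaks(smoothed, peaks)
    # discard insignificant peaks (spline wiggles over empty bins)
    if len(peaks):
        masses = _peak_masses(hist.counts, peaks)
        peaks = peaks[masses >= 0.01 * hist.total]
    if len(peaks) >= 3:
        masses = _peak_masses(hist.counts, peaks)
        top3 = np.sort(peaks[np.argsort(masses)[-3:]])
        t1 = _trough_between(hist, smoothed, top3[0], top3[1])
        t2 = _trough_between(hist, smoothed, top3[1], top3[2])
        hist.troughs = np.array([t1, t2])
        if t1 < t2:
            return ThresholdSet(t1, t2, source="histogram")

    if fallback is not None:
        return ThresholdSet(fallback.t_noise_ep, fallback.t_ep_lp,
                            source="carried_forward")
    centers = hist.bin_centers
    lo, hi = centers[occupied[0]], centers[occupied[-1]]
    r1, r2 = default_ratios
    return ThresholdSet(lo + r1 * (hi - lo), lo + r2 * (hi - lo),
                        source="default_ratio")


def _merge_shallow_peaks(smoothed: np.ndarray, peaks: np.ndarray,
                         depth_ratio: float = TROUGH_DEPTH_RATIO) -> np.ndarray:
    """Merge adjacent peaks whose separating trough is not deep enough.

    Repeatedly, the adjacent pair with the shallowest relative trough is
    collapsed onto its higher member until every remaining trough drops
    below ``depth_ratio`` times the lower flanking peak.
    """
    peaks = list(np.sort(peaks))
    while len(peaks) > 1:
        worst_idx, worst_rel = None, depth_ratio
        for i in range(len(peaks) - 1):
            lo, hi = peaks[i], peaks[i + 1]
            trough = smoothed[lo + 1:hi].min() if hi > lo + 1 \
                else min(smoothed[lo], smoothed[hi])
            flank = min(smoothed[lo], smoothed[hi])
            rel = trough / flank if flank > 0 else 0.0
            if rel >= worst_rel:
                worst_idx, worst_rel = i, rel
        if worst_idx is None:
            break
        i = worst_idx
        keep = peaks[i] if smoothed[peaks[i]] >= smoothed[peaks[i + 1]] \
            else peaks[i + 1]
        peaks[i:i + 2] = [keep]
    return np.array(peaks, dtype=int)


def _peak_masses(counts: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Mass of each peak = raw counts summed over its basin (between the
    midpoints toward neighboring peaks)."""
    bounds = [0] + [int((peaks[i] + peaks[i + 1]) // 2) + 1
                    for i in range(len(peaks) - 1)] + [len(counts)]
    return np.array([counts[bounds[i]:bounds[i + 1]].sum()
                     for i in range(len(peaks))], dtype=float)


def extract_contours(frame: np.ndarray,
                     thresholds: ThresholdSet) -> list[Contour]:
    """Sub-pixel marching-squares iso-contours at both threshold levels.

    The frame is padded with its minimum so that structures touching the
    border still produce closed contours; coordinates are shifted back.
    Contours at ``t_noise_ep`` bound whole-fold tissue (EP outer boundary
    above, deep LP boundary below); contours at ``t_ep_lp`` bound the LP.
    """
    frame = np.asarray(frame, dtype=float)
    lo = float(frame.min())
    padded = np.pad(frame, 1, constant_values=lo)
    out: list[Contour] = []
    for level in (thresholds.t_noise_ep, thresholds.t_ep_lp):
        if not (padded.min() < level < padded.max()):
            continue
        for pts in measure.find_contours(padded, level=level):
            pts = pts - 1.0
            closed = bool(np.allclose(pts[0], pts[-1]))
            out.append(Contour(points=pts, closed=closed, level=level))
    return out


def detect_midline(frame: np.ndarray, t_noise_ep: float) -> float | None:
    """Glottal midline: least-tissue-occupancy column between the two folds.

    The tissue mask is labeled; the column of minimum occupancy strictly
    between the centroids of the two largest components is returned (center
    of a flat minimum run).  None when two components cannot be found.
    """
    mask = np.asarray(frame) > t_noise_ep
    labels, n = ndimage.label(mask)
    if n < 2:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    if sizes[order[1]] < 0.05 * sizes[order[0]]:
        return None
    cents = ndimage.center_of_mass(mask, labels,
                                   index=[order[0] + 1, order[1] + 1])
    c1, c2 = sorted(c[1] for c in cents)
    lo, hi = int(np.ceil(c1)), int(np.floor(c2))
    if hi <= lo:
        return None
    occ = mask[:, lo:hi + 1].sum(axis=0)
    m = occ.min()
    flat = np.flatnonzero(occ == m)
    runs = _runs_of(np.isin(np.arange(len(occ)), flat))
    start, length = max(runs, key=lambda r: r[1])
    return float(lo + start + (length - 1) / 2.0)


def _crossings_at_columns(points: np.ndarray, n_cols: int):
    """Rows at which a polyline crosses each integer column.

    Returns (cols, rows) arrays of all crossings, by linear interpolation
    along each segment.
    """
    p = points
    a, b = p[:-1], p[1:]
    cols_out, rows_out = [], []
    dc = b[:, 1] - a[:, 1]
    for k in range(len(a)):
        c0, c1 = a[k, 1], b[k, 1]
        lo, hi = (c0, c1) if c0 <= c1 else (c1, c0)
        first, last = int(np.ceil(lo)), int(np.floor(hi))
        if last < first:
            continue
        cols = np.arange(first, last + 1)
        if dc[k] == 0:
            rows = np.full(len(cols), 0.5 * (a[k, 0] + b[k, 0]))
        else:
            t = (cols - c0) / dc[k]
            rows = a[k, 0] + t * (b[k, 0] - a[k, 0])
        keep = (cols >= 0) & (cols < n_cols)
        cols_out.append(cols[keep])
        rows_out.append(rows[keep])
    if not cols_out:
        return np.array([], dtype=int), np.array([])
    return np.concatenate(cols_out), np.concatenate(rows_out)


def _envelopes(contours: list[Contour], n_cols: int):
    """Upper (min-row) and lower (max-row) envelopes across contours.

    A-lines crossing a contour more than twice use the outermost pair.
    """
    upper = np.full(n_cols, np.nan)
    lower = np.full(n_cols, np.nan)
    for ct in contours:
        cols, rows = _crossings_at_columns(ct.points, n_cols)
        for c, r in zip(cols, rows):
            if np.isnan(upper[c]) or r < upper[c]:
                upper[c] = r
            if np.isnan(lower[c]) or r > lower[c]:
                lower[c] = r
    return upper, lower


def _refine_edge_rows(frame: np.ndarray, rows: np.ndarray, level: float,
                      probe: int = 2) -> np.ndarray:
    """Sub-pixel edge relocalization of per-column boundary rows.

    An iso-contour at intensity ``level`` crosses a one-pixel partial-volume
    edge between local plateaus ``a`` (above) and ``b`` (below) at an offset
    of (level − (a+b)/2)/(b − a) px from the true 50%-coverage boundary.
    Sampling the plateaus ``probe`` px away from each crossing gives a
    first-order correction, clamped to ±0.5 px (an edge is one pixel wide).
    """
    out = rows.copy()
    n_rows = frame.shape[0]
    cols = np.flatnonzero(~np.isnan(rows))
    for c in cols:
        r = rows[c]
        ra, rb = int(round(r)) - probe, int(round(r)) + probe
        if ra < 0 or rb >= n_rows:
            continue
        a, b = float(frame[ra, c]), float(frame[rb, c])
        if abs(b - a) < 1e-9:
            continue
        delta = ((a + b) / 2.0 - level) / (b - a)
        out[c] = r + float(np.clip(delta, -0.5, 0.5))
    return out


def filter_and_assign(contours: list[Contour], frame_shape: tuple[int, int],
                      thresholds: ThresholdSet,
                      midline_hint: float | None = None,
                      min_area: float = 50.0,
                      previous: "LayerSegmentation | None" = None,
                      alignment_tolerance: float = 25.0,
                      frame: np.ndarray | None = None) -> LayerSegmentation:
    """Filter candidate contours and assemble a per-side layer segmentation.

    Closed contours with enclosed area below ``min_area`` px² (speckle
    islands) are rejected.  Surviving tissue-level contours are split at the
    glottal midline (``midline_hint`` when given); per side, the upper/lower
    envelopes of the tissue contours give the EP outer and deep LP
    boundaries, and the upper envelope of the LP-level contours gives the
    EP/LP interface.  A-lines violating the vertical ordering EP outer <
    interface < deep LP are discarded.  If a previous frame's segmentation
    is supplied, a jump of the per-side median EP-outer row beyond
    ``alignment_tolerance`` px is flagged (``alignment_ok=False``) but the
    raw segmentation is kept.  When ``frame`` is given, boundary rows are
    refined with sub-pixel edge relocalization (see
    :func:`_refine_edge_rows`).
    """
    n_rows, n_cols = frame_shape
    kept = [c for c in contours
            if not c.closed or c.enclosed_area() >= min_area]
    tissue = [c for c in kept if c.level == thresholds.t_noise_ep]
    lp = [c for c in kept if c.level == thresholds.t_ep_lp]

    seg = LayerSegmentation(frame_shape=frame_shape,
                            midline_col=np.nan, thresholds=thresholds)
    empty = lambda: {layer: np.full(n_cols, np.nan) for layer in LAYERS}
    seg.profiles = {side: empty() for side in SIDES}

    if not tissue:
        seg.unsegmentable = True
        return seg

    t_upper, t_lower = _envelopes(tissue, n_cols)
    lp_upper, _ = _envelopes(lp, n_cols)
    if frame is not None:
        t_upper = _refine_edge_rows(frame, t_upper, thresholds.t_noise_ep)
        t_lower = _refine_edge_rows(frame, t_lower, thresholds.t_noise_ep)
        lp_upper = _refine_edge_rows(frame, lp_upper, thresholds.t_ep_lp)

    if midline_hint is not None:
        midline = float(midline_hint)
    else:
        occupied = np.flatnonzero(~np.isnan(t_upper))
        midline = float(occupied.mean()) if len(occupied) else n_cols / 2.0
    seg.midline_col = midline

    cols = np.arange(n_cols)
    for side in SIDES:
        sel = cols <= midline if side == "left" else cols > midline
        prof = seg.profiles[side]
        prof["ep_outer"][sel] = t_upper[sel]
        prof["lp_deep"][sel] = t_lower[sel]
        prof["ep_lp_interface"][sel] = lp_upper[sel]
        # enforce vertical ordering; discard violators per A-line
        eo, ifc, ld = (prof["ep_outer"], prof["ep_lp_interface"],
                       prof["lp_deep"])
        bad_if = ~np.isnan(ifc) & (np.isnan(eo) | (ifc <= eo) | (ifc >= ld))
        ifc[bad_if] = np.nan
        bad_t = ~np.isnan(eo) & ~np.isnan(ld) & (ld <= eo)
        eo[bad_t] = np.nan
        ld[bad_t] = np.nan

    for ct in tissue + lp:
        mean_col = ct.points[:, 1].mean()
        ct.side = "left" if mean_col <= midline else "right"
        ct.layer = "ep_outer" if ct.level == thresholds.t_noise_ep \
            else "ep_lp_interface"
    seg.contours = tissue + lp

    if not (seg.has_side("left") or seg.has_side("right")):
        seg.unsegmentable = True
        return seg

    if previous is not None and not previous.unsegmentable:
        for side in SIDES:
            if seg.has_side(side) and previous.has_side(side):
                cur = np.nanmedian(seg.profiles[side]["ep_outer"])
                prev = np.nanmedian(previous.profiles[side]["ep_outer"])
                if abs(cur - prev) > alignment_tolerance:
                    seg.alignment_ok = False
    return seg


def segment_frame(frame: np.ndarray, n_bins: int = 256,
                  fallback: ThresholdSet | None = None,
                  midline_hint: float | None = None,
                  min_area: float = 50.0,
                  previous: LayerSegmentation | None = None,
                  smoothing: float = SPLINE_SMOOTHING) -> LayerSegmentation:
    """Histogram → thresholds → contours → filtered layer segmentation."""
    hist = build_histogram(frame, n_bins=n_bins)
    try:
        thresholds = find_thresholds(hist, fallback=fallback,
                                     smoothing=smoothing)
    except ValueError:
        seg = LayerSegmentation(frame_shape=frame.shape, midline_col=np.nan,
                                thresholds=ThresholdSet(0.0, 1.0,
                                                        source="default_ratio"))
        seg.profiles = {side: {layer: np.full(frame.shape[1], np.nan)
                               for layer in LAYERS} for side in SIDES}
        seg.unsegmentable = True
        return seg
    contours = extract_contours(frame, thresholds)
    if midline_hint is None:
        midline_hint = detect_midline(frame, thresholds.t_noise_ep)
    return filter_and_assign(contours, frame.shape, thresholds,
                             midline_hint=midline_hint, min_area=min_area,
                             previous=previous, frame=frame)


def segment_sequence(frames, n_bins: int = 256, min_area: float = 50.0,
                     smoothing: float = SPLINE_SMOOTHING,
                     midline_hint: float | None = None,
                     alignment_tolerance: float = 25.0,
                     ) -> list[LayerSegmentation]:
    """Segment every frame of a sequence with sequence-level context.

    Two passes.  Pass one finds per-frame thresholds (carrying the previous
    accepted frame's thresholds into frames whose histogram lacks three
    peaks) and per-frame glottal-midline candidates; the sequence midline is
    their median, which survives frames of full glottal closure.  Pass two
    extracts and filters contours against that midline, tracking frame-to-
    frame alignment.
    """
    frames = np.asarray(frames)
    thresholds: list[ThresholdSet | None] = []
    midlines = []
    last: ThresholdSet | None = None
    for frame in frames:
        hist = build_histogram(frame, n_bins=n_bins)
        try:
            ts = find_thresholds(hist, fallback=last, smoothing=smoothing)
        except ValueError:
            thresholds.append(None)
            continue
        thresholds.append(ts)
        if ts.source == "histogram":
            last = ts
        ml = detect_midline(frame, ts.t_noise_ep)
        if ml is not None:
            midlines.append(ml)
    if midline_hint is None and midlines:
        midline_hint = float(np.median(midlines))

    segs: list[LayerSegmentation] = []
    previous: LayerSegmentation | None = None
    for frame, ts in zip(frames, thresholds):
        if ts is None:
            seg = LayerSegmentation(
                frame_shape=frame.shape, midline_col=np.nan,
                thresholds=ThresholdSet(0.0, 1.0, source="default_ratio"))
            seg.profiles = {side: {layer: np.full(frame.shape[1], np.nan)
                                   for layer in LAYERS} for side in SIDES}
            seg.unsegmentable = True
            segs.append(seg)
            continue
        contours = extract_contours(frame, ts)
        seg = filter_and_assign(contours, frame.shape, ts,
                                midline_hint=midline_hint, min_area=min_area,
                                previous=previous,
                                alignment_tolerance=alignment_tolerance,
                                frame=frame)
        segs.append(seg)
        if not seg.unsegmentable:
            previous = seg
    return segs
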