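"""Histogram thresholding, contour extraction, and layer assignment."""

import numpy as np
import pytest
from scipy.stats import norm

from vfoct.segmentation import (
    IntensityHistogram, LAYERS, SIDES, ThresholdSet, build_histogram,
    detect_midline, extract_contours, filter_and_assign, find_thresholds,
    segment_frame, segment_sequence,
)


class TestBuildHistogram:
    def test_two_valued_image_proportions(self):
        img = np.zeros((10, 10))
        img.flat[:40] = 10.0
        img.flat[40:] = 50.0
        hist = build_histogram(img, n_bins=8)
        occupied = np.flatnonzero(hist.counts)
        assert len(occupied) == 2
        assert hist.counts[occupied[0]] == 40
        assert hist.counts[occupied[1]] == 60

    def test_counts_conserve_pixels(self, small_speckled):
        _, seq, _ = small_speckled
        hist = build_histogram(seq.frames[0])
        assert hist.total == seq.frames[0].size

    def test_constant_image_single_bin(self):
        hist = build_histogram(np.full((5, 5), 3.0))
        assert (hist.counts > 0).sum() == 1

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            build_histogram(np.zeros((4, 4)), n_bins=4)

    def test_trimodal_phantom_three_smoothed_maxima(self, small_noiseless):
        _, seq, _ = small_noiseless
        hist = build_histogram(seq.frames[0])
        ts = find_thresholds(hist)  # fills hist.smoothed / troughs
        assert ts.source == "histogram"
        assert hist.troughs is not None and len(hist.troughs) == 2


def _delta_histogram(peak_bins, counts_value=1000, n_bins=128):
    """Histogram with integer bin centers 0..n_bins-1 and delta peaks."""
    counts = np.zeros(n_bins, dtype=int)
    for b in peak_bins:
        counts[b] = counts_value
    edges = np.arange(n_bins + 1) - 0.5
    return IntensityHistogram(bin_edges=edges, counts=counts)


class TestFindThresholds:
    def test_delta_peaks_threshold_at_gap_centers(self):
        hist = _delta_histogram([10, 50, 90])
        ts = find_thresholds(hist)
        assert ts.source == "histogram"
        assert ts.t_noise_ep == pytest.approx(30.0)
        assert ts.t_ep_lp == pytest.approx(70.0)

    def test_gaussian_mixture_near_optimal_cuts(self):
        # weights 0.5/0.25/0.25, means 20/90/180, sd 8
        rng = np.random.default_rng(42)
        n = 200_000
        comp = rng.choice(3, size=n, p=[0.5, 0.25, 0.25])
        means = np.array([20.0, 90.0, 180.0])
        samples = rng.normal(means[comp], 8.0)
        hist = build_histogram(samples.reshape(400, -1), n_bins=256)
        ts = find_thresholds(hist)
        assert ts.source == "histogram"

        # oracle: exhaustive scan of integer cut pairs minimizing the
        # analytic misclassification probability of the mixture
        w = np.array([0.5, 0.25, 0.25])
        cuts = np.arange(1, 255)

        def misclass(c1, c2):
            # mass of comp 0 above c1, comp 1 outside (c1, c2], comp 2 below c2
            e0 = w[0] * norm.sf(c1, 20.0, 8.0)
            e1 = w[1] * (norm.cdf(c1, 90.0, 8.0) + norm.sf(c2, 90.0, 8.0))
            e2 = w[2] * norm.cdf(c2, 180.0, 8.0)
            return e0 + e1 + e2

        best = min(((c1, c2) for c1 in cuts for c2 in cuts if c1 < c2),
                   key=lambda p: misclass(*p))
        assert abs(ts.t_noise_ep - best[0]) <= 10.0
        assert abs(ts.t_ep_lp - best[1]) <= 10.0

    def test_bimodal_uses_fallback(self):
        hist = _delta_histogram([20, 80])
        fb = ThresholdSet(15.0, 55.0, source="histogram")
        ts = find_thresholds(hist, fallback=fb)
        assert ts.source == "carried_forward"
        assert (ts.t_noise_ep, ts.t_ep_lp) == (15.0, 55.0)

    def test_bimodal_without_fallback_default_ratio(self):
        hist = _delta_histogram([20, 80])
        ts = find_thresholds(hist)
        assert ts.source == "default_ratio"
        # 0.25 / 0.55 of the occupied range [20, 80]
        assert ts.t_noise_ep == pytest.approx(20 + 0.25 * 60)
        assert ts.t_ep_lp == pytest.approx(20 + 0.55 * 60)

    def test_degenerate_single_bin_no_fallback(self):
        hist = build_histogram(np.full((5, 5), 3.0))
        with pytest.raises(ValueError):
            find_thresholds(hist)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            ThresholdSet(10.0, 5.0)


class TestExtractContours:
    def test_step_image_boundary_within_half_pixel(self):
        img = np.full((40, 100), 10.0)
        img[:, 50:] = 200.0  # boundary midway between pixel centers 49, 50
        ts = ThresholdSet(105.0, 150.0)
        contours = extract_contours(img, ts)
        level_contours = [c for c in contours if c.level == 105.0]
        assert level_contours
        pts = np.concatenate([c.points for c in level_contours])
        # away from the frame border (the bright half's closed boundary also
        # runs along the image edge), the iso-points trace the step edge
        interior = pts[(pts[:, 0] > 2) & (pts[:, 0] < 37) & (pts[:, 1] < 95)]
        assert len(interior) > 30
        assert np.all(np.abs(interior[:, 1] - 49.5) <= 0.5)

    def test_disk_perimeter_within_2_percent(self):
        r = 50.0
        yy, xx = np.mgrid[0:140, 0:140]
        dist = np.hypot(yy - 70.0, xx - 70.0)
        img = 10.0 + 190.0 * np.clip(r - dist + 0.5, 0.0, 1.0)
        ts = ThresholdSet(105.0, 201.0)
        contours = extract_contours(img, ts)
        disk = max(contours, key=lambda c: c.enclosed_area())
        assert disk.closed
        d = np.diff(disk.points, axis=0)
        perimeter = np.hypot(d[:, 0], d[:, 1]).sum()
        assert perimeter == pytest.approx(2 * np.pi * r, rel=0.02)

    def test_phantom_contours_within_1px_rms_of_truth(self, small_noiseless,
                                                      segmented_noiseless):
        _, _, truth = small_noiseless
        for fi in (0, 10, 20):
            seg = segmented_noiseless[fi]
            for si, side in enumerate(SIDES):
                for layer, t_arr in (
                        ("ep_outer", truth.ep_outer_rows),
                        ("ep_lp_interface", truth.interface_rows),
                        ("lp_deep", truth.lp_deep_rows)):
                    got = seg.profiles[side][layer]
                    want = t_arr[fi, si]
                    ok = ~np.isnan(got) & ~np.isnan(want)
                    assert ok.sum() > 50
                    rms = np.sqrt(np.mean((got[ok] - want[ok]) ** 2))
                    assert rms <= 1.0, (fi, side, layer)


class TestFilterAndAssign:
    def test_noiseless_phantom_three_layers_per_side(self, segmented_noiseless):
        seg = segmented_noiseless[0]
        assert not seg.unsegmentable
        for side in SIDES:
            for layer in LAYERS:
                assert np.isfinite(seg.profiles[side][layer]).sum() > 50

    def test_small_blob_rejected_frame_flagged(self):
        img = np.full((60, 60), 10.0)
        img[30:33, 30:33] = 200.0  # 9 px² speckle island < 50 px² minimum
        ts = ThresholdSet(50.0, 150.0)
        contours = extract_contours(img, ts)
        seg = filter_and_assign(contours, img.shape, ts)
        assert seg.unsegmentable

    def test_midline_detected_near_truth(self, small_noiseless,
                                         segmented_noiseless):
        _, _, truth = small_noiseless
        for seg in segmented_noiseless[:10]:
            assert abs(seg.midline_col - truth.midline_col) <= 10.0

    def test_ordering_invariant_on_accepted_frames(self, segmented_noiseless):
        for seg in segmented_noiseless:
            if seg.unsegmentable:
                continue
            for side in SIDES:
                p = seg.profiles[side]
                ok = ~np.isnan(p["ep_outer"]) & \
                    ~np.isnan(p["ep_lp_interface"]) & ~np.isnan(p["lp_deep"])
                assert np.all(p["ep_outer"][ok] < p["ep_lp_interface"][ok])
                assert np.all(p["ep_lp_interface"][ok] < p["lp_deep"][ok])

    def test_sides_respect_midline(self, segmented_noiseless):
        seg = segmented_noiseless[0]
        assert seg.side_columns("left").max() <= seg.midline_col
        assert seg.side_columns("right").min() > seg.midline_col


class TestSegmentSequence:
    def test_noiseless_cycle_all_frames_within_1px(self, small_noiseless,
                                                   segmented_noiseless):
        _, _, truth = small_noiseless
        assert not any(s.unsegmentable for s in segmented_noiseless)
        for fi, seg in enumerate(segmented_noiseless):
            for si, side in enumerate(SIDES):
                got = seg.profiles[side]["ep_outer"]
                want = truth.ep_outer_rows[fi, si]
                ok = ~np.isnan(got) & ~np.isnan(want)
                assert np.all(np.abs(got[ok] - want[ok]) <= 1.0)

    def test_speckled_cycle_segments_with_small_median_error(
            self, small_speckled, geometry):
        from vfoct.preprocess import denoise_tv
        _, seq, truth = small_speckled
        frames = np.stack([denoise_tv(f, 0.1) for f in seq.frames])
        segs = segment_sequence(frames)
        ok_frames = [s for s in segs if not s.unsegmentable]
        assert len(ok_frames) >= 0.9 * len(segs)
        errors = []
        for fi, seg in enumerate(segs):
            if seg.unsegmentable:
                continue
            for si, side in enumerate(SIDES):
                got = seg.profiles[side]["ep_outer"]
                want = truth.ep_outer_rows[fi, si]
                ok = ~np.isnan(got) & ~np.isnan(want)
                if ok.any():
                    errors.append(np.abs(got[ok] - want[ok]))
        assert np.median(np.concatenate(errors)) <= 2.0

    def test_featureless_frames_flagged_not_fatal(self):
        frames = np.full((4, 64, 64), 25.0)  # constant: no histogram modes
        segs = segment_sequence(frames)
        assert len(segs) == 4  # no exception; flags only
        assert all(s.unsegmentable for s in segs)


def test_detect_midline_two_blobs():
    img = np.full((60, 100), 10.0)
    img[20:50, 5:40] = 200.0
    img[20:50, 60:95] = 200.0
    ml = detect_midline(img, 50.0)
    assert ml == pytest.approx(49.5, abs=1.0)


def test_segment_frame_smoke(small_noiseless):
    _, seq, _ = small_noiseless
    seg = segment_frame(seq.frames[0])
    assert not seg.unsegmentable
    assert seg.thresholds.source == "histogram"
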