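"""Depth-resolved kymographs, periodicity, and velocity/vector rendering."""

import numpy as np
import pytest

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from vfoct.kinematics import VelocityField, build_velocity_field, track_sequence
from vfoct.kymography import (
    AIR, build_vkg, render_vector_map, render_velocity_map, render_vkg,
    shared_axis_matrix, symmetry_report, vkg_periodicity,
)
from vfoct.morphometry import thickness_profile
from vfoct.phantom import PhantomConfig, generate_sequence
from vfoct.segmentation import segment_sequence


@pytest.fixture(scope="module")
def noiseless_profiles(small_noiseless, segmented_noiseless, geometry):
    _, seq, _ = small_noiseless
    return [thickness_profile(seg, geometry, i)
            for i, seg in enumerate(segmented_noiseless)]


@pytest.fixture(scope="module")
def noiseless_kymo(noiseless_profiles, geometry):
    return {layer: build_vkg(noiseless_profiles, layer,
                             geometry.frame_rate, geometry.lateral_pitch)
            for layer in ("ep", "lp", "combined")}


class TestBuildVkg:
    def test_static_phantom_rows_identical(self, static_phantom, geometry):
        _, seq, _ = static_phantom
        segs = segment_sequence(seq.frames)
        profiles = [thickness_profile(s, geometry, i)
                    for i, s in enumerate(segs)]
        kymo = build_vkg(profiles, "ep", geometry.frame_rate,
                         geometry.lateral_pitch)
        assert np.array_equal(kymo.matrix, np.tile(kymo.matrix[0],
                                                   (len(segs), 1)))

    def test_air_sentinel_never_zero_um(self, noiseless_kymo):
        kymo = noiseless_kymo["ep"]
        assert (kymo.matrix == AIR).any()       # the glottal gap
        tissue = kymo.matrix[kymo.matrix != AIR]
        assert np.all(tissue >= 0.0)
        assert AIR < 0.0                         # sentinel outside range

    def test_cells_equal_profile_values_exactly(self, noiseless_profiles,
                                                noiseless_kymo):
        kymo = noiseless_kymo["lp"]
        prof = noiseless_profiles[4]["left"]
        ok = np.flatnonzero(~np.isnan(prof.lp))
        assert np.array_equal(kymo.matrix[4, ok], prof.lp[ok])

    def test_combined_is_cellwise_sum(self, noiseless_kymo):
        ep, lp, comb = (noiseless_kymo[k].matrix
                        for k in ("ep", "lp", "combined"))
        both = (ep != AIR) & (lp != AIR) & (comb != AIR)
        assert np.allclose(comb[both], ep[both] + lp[both])

    def test_empty_sequence_rejected(self, geometry):
        with pytest.raises(ValueError):
            build_vkg([], "ep", geometry.frame_rate, geometry.lateral_pitch)

    def test_time_axis_exact(self, noiseless_kymo, geometry):
        kymo = noiseless_kymo["ep"]
        r = np.arange(kymo.matrix.shape[0])
        assert np.array_equal(kymo.times, r / geometry.frame_rate)


class TestAirDutyCycle:
    def test_gap_duty_cycle_matches_schedule(self, geometry):
        # gap closes part of each cycle: rest half-gap 80 μm, lateral 0.15 mm;
        # symmetric motion so both medial edges meet at the midline together
        cfg = PhantomConfig(frame_shape=(200, 240), n_frames=100,
                            n_rest_frames=0, fundamental_freq=10.0,
                            vertical_amplitude=0.05, lateral_amplitude=0.15,
                            glottal_half_gap=80.0, speckle_sigma=0.0,
                            lateral_taper=0.05, phase_offset=0.0)
        seq, truth = generate_sequence(cfg, geometry)
        segs = segment_sequence(seq.frames)
        profiles = [thickness_profile(s, geometry, i)
                    for i, s in enumerate(segs)]
        kymo = build_vkg(profiles, "combined", geometry.frame_rate,
                         geometry.lateral_pitch)
        mid = int(truth.midline_col)
        # truth schedule: the exact midline is air when both half-gaps > 0
        open_truth = truth.gap_half_px.min(axis=1) > 0
        duty = open_truth.mean()
        measured = float((kymo.matrix[:, mid] == AIR).mean())
        n_cycles = 100 * 10.0 / 250.0
        tol = n_cycles * 1.0 / 100  # one frame per cycle
        assert measured == pytest.approx(duty, abs=tol + 1e-9)


class TestPeriodicity:
    def test_dominant_period_is_1_over_f(self, noiseless_kymo):
        kymo_all = noiseless_kymo["combined"]
        # drop the 5 leading rest frames: pure 10 Hz oscillation remains
        kymo = type(kymo_all)(matrix=kymo_all.matrix[5:], layer="combined",
                              frame_rate=kymo_all.frame_rate,
                              lateral_pitch=kymo_all.lateral_pitch)
        starts, periods = vkg_periodicity(kymo, band_width=16)
        found = [p for p in periods if p is not None]
        assert found
        assert np.median(found) == pytest.approx(1.0 / 10.0, rel=0.05)

    def test_static_phantom_absent(self, static_phantom, geometry):
        _, seq, _ = static_phantom
        segs = segment_sequence(seq.frames)
        profiles = [thickness_profile(s, geometry, i)
                    for i, s in enumerate(segs)]
        kymo = build_vkg(profiles, "ep", geometry.frame_rate,
                         geometry.lateral_pitch)
        _, periods = vkg_periodicity(kymo)
        assert all(p is None for p in periods)

    def test_symmetric_phantom_ratio_one(self, geometry):
        # mirror-symmetric motion: zero phase offset between folds
        cfg = PhantomConfig(frame_shape=(200, 240), n_frames=50,
                            n_rest_frames=0, fundamental_freq=10.0,
                            vertical_amplitude=0.08, lateral_amplitude=0.05,
                            glottal_half_gap=150.0, speckle_sigma=0.0,
                            lateral_taper=0.05, phase_offset=0.0)
        seq, truth = generate_sequence(cfg, geometry)
        segs = segment_sequence(seq.frames)
        profiles = [thickness_profile(s, geometry, i)
                    for i, s in enumerate(segs)]
        kymo = build_vkg(profiles, "combined", geometry.frame_rate,
                         geometry.lateral_pitch)
        report = symmetry_report(kymo, int(truth.midline_col), band_width=16)
        assert report["thickness_ratio"] == pytest.approx(1.0, abs=0.02)
        for _, ratio in report["period_ratios"]:
            assert ratio == pytest.approx(1.0, rel=0.02)


class TestVelocityMaps:
    def _fields(self, segs, geometry):
        return (build_velocity_field(track_sequence(segs, "left"), geometry),
                build_velocity_field(track_sequence(segs, "right"), geometry))

    def test_zero_field_zero_matrix(self, geometry):
        z = np.zeros((5, 30))
        fl = VelocityField(side="left", vx=z, vy=z)
        fr = VelocityField(side="right", vx=z, vy=z)
        ax, mat = render_velocity_map(fl, fr, "vertical",
                                      geometry.frame_rate)
        plt.close(ax.figure)
        assert not mat.any()
        assert mat.shape == (5, 60)

    def test_matrix_equals_field_values_exactly(self, segmented_noiseless,
                                                geometry):
        fl, fr = self._fields(segmented_noiseless, geometry)
        mat = shared_axis_matrix(fl, fr, "vertical")
        assert np.array_equal(mat[:, :30], fl.vy[:, ::-1])
        assert np.array_equal(mat[:, 30:], fr.vy)

    def test_vertical_map_alternates_horizontal_near_zero(
            self, segmented_noiseless, geometry, small_noiseless):
        fl, fr = self._fields(segmented_noiseless, geometry)
        vmat = shared_axis_matrix(fl, fr, "vertical")
        hmat = shared_axis_matrix(fl, fr, "horizontal")
        col = vmat[5:, 29]  # medial point of the left fold, phonation
        col = col[np.isfinite(col)]
        assert (col > 0).any() and (col < 0).any()
        # lateral amplitude 0.05 mm ≪ vertical 0.1 mm: |vx| stays small
        assert np.nanmax(np.abs(hmat)) < 0.5 * np.nanmax(np.abs(vmat))

    def test_out_of_phase_folds_opposite_sign(self, geometry):
        cfg = PhantomConfig(frame_shape=(200, 240), n_frames=30,
                            n_rest_frames=0, fundamental_freq=10.0,
                            vertical_amplitude=0.08, lateral_amplitude=0.0,
                            glottal_half_gap=150.0, speckle_sigma=0.0,
                            lateral_taper=0.05, phase_offset=np.pi)
        seq, _ = generate_sequence(cfg, geometry)
        segs = segment_sequence(seq.frames)
        fl, fr = self._fields(segs, geometry)
        left_my = fl.vy[:, 0]
        right_my = fr.vy[:, 0]
        big = np.abs(left_my) > 1.0
        assert np.all(np.sign(left_my[big]) == -np.sign(right_my[big]))

    def test_vector_map_renders_and_validates_window(self, geometry):
        z = np.zeros((10, 30))
        fl = VelocityField(side="left", vx=z, vy=z)
        fr = VelocityField(side="right", vx=z, vy=z)
        ax = render_vector_map(fl, fr, geometry.frame_rate,
                               time_window=(0.0, 0.02))
        plt.close(ax.figure)
        with pytest.raises(ValueError):
            render_vector_map(fl, fr, geometry.frame_rate,
                              time_window=(5.0, 6.0))


class TestRoundTrip:
    def test_kymograph_csv_round_trip_bit_exact(self, noiseless_kymo,
                                                tmp_path):
        from vfoct.io import load_kymograph_matrix, save_kymograph
        kymo = noiseless_kymo["ep"]
        path = tmp_path / "vkg.csv"
        save_kymograph(kymo, path)
        loaded = load_kymograph_matrix(path)
        assert np.array_equal(loaded, kymo.matrix)

    def test_render_smoke(self, noiseless_kymo):
        ax = render_vkg(noiseless_kymo["combined"])
        plt.close(ax.figure)
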