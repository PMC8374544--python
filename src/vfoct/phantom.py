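"""Synthetic vibrating vocal-fold phantom with exact ground truth.

The phantom renders a coronal OCT view of two opposed folds (image-left and
image-right) separated by a glottal gap.  Each fold is a two-layer slab: a
darker epithelium (EP) over a brighter, more scattering lamina propria (LP),
on a uniform noise floor.  The superior surface of each fold follows a rigid
vertical sinusoid (with a configurable left/right phase offset, so the folds
can be rendered out of phase, as sub-Nyquist sampling of real folds does),
and the medial edges move laterally with the same phase, opening and closing
the gap.  Signal decays exponentially with depth below the tissue surface to
mimic the ~1 mm optical penetration limit, and multiplicative log-normal
speckle can be overlaid.

Every rendered boundary is also reported analytically (sub-pixel, pre-noise)
in a :class:`PhantomTruth`, which downstream tests use as an oracle.

Conventions: image row 0 is superior (toward the scanner); rows increase
inferiorly.  Layer boundaries are rendered with partial-volume mixing so
that iso-contours recover the sub-pixel boundary position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .calibration import CalibrationRecord, ScanGeometry
from .sequence import FrameSequence, PHONATION, REST

__all__ = ["PhantomConfig", "PhantomTruth", "generate_sequence",
           "simulate_calibration"]


class PhantomConfigError(ValueError):
    """A phantom parameter is inconsistent with the frame/scan geometry."""


@dataclass
class PhantomConfig:
    """Parameters of the synthetic vibrating-fold sequence.

    Geometric parameters are metric (μm / mm) and are converted to pixels
    through the :class:`~vfoct.calibration.ScanGeometry` passed to
    :func:`generate_sequence`.  Defaults describe a sustained-phonation
    acquisition: 3 s of vibration at 110 Hz sampled at 250 Hz, 1.33 mm
    vertical amplitude at the medial edge, a 100 μm EP over a 420 μm
    detectable LP, and tri-modal intensities (noise < EP < LP).
    """

    frame_shape: tuple[int, int] = (800, 800)   # rows, cols (px)
    n_frames: int = 775                          # incl. leading rest frames
    n_rest_frames: int = 25
    frame_rate: float = 250.0                    # Hz
    ep_thickness: float = 100.0                  # μm
    lp_thickness: float = 420.0                  # μm
    glottal_half_gap: float = 200.0              # μm per side at rest
    fundamental_freq: float = 110.0              # Hz
    vertical_amplitude: float = 1.33             # mm, peak superior-medial shift
    lateral_amplitude: float = 0.10              # mm, medial-edge excursion
    phase_offset: float = math.pi / 2            # right-fold phase lag (rad)
    lateral_taper: float = 0.05                  # surface row increase per px lateral
    amplitude_decay: float = 0.0                 # fractional amplitude loss at lateral end
    intensity_means: tuple[float, float, float] = (25.0, 95.0, 200.0)
    speckle_sigma: float = 0.12                  # log-normal sigma; 0 = noiseless
    attenuation_depth: float = 1000.0            # μm, 1/e decay below surface
    rest_surface_row: float | None = None        # px; None = auto placement
    frame_jitter_px: int = 0                     # bulk-motion jitter, ± px
    edge_margin_px: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.ep_thickness <= 0 or self.lp_thickness <= 0:
            raise PhantomConfigError("ep_thickness and lp_thickness must be > 0")
        noise, ep, lp = self.intensity_means
        if not (noise < ep < lp):
            raise PhantomConfigError(
                "intensity_means must be strictly increasing (noise < EP < LP)")
        if self.speckle_sigma < 0:
            raise PhantomConfigError("speckle_sigma must be >= 0")
        if self.n_frames < 1 or self.n_rest_frames < 0 or \
                self.n_rest_frames > self.n_frames:
            raise PhantomConfigError("need 0 <= n_rest_frames <= n_frames, n_frames >= 1")
        if self.glottal_half_gap < 0 or self.lateral_amplitude < 0:
            raise PhantomConfigError("glottal_half_gap and lateral_amplitude must be >= 0")
        if self.frame_jitter_px < 0:
            raise PhantomConfigError("frame_jitter_px must be >= 0")
        if not 0.0 <= self.amplitude_decay <= 1.0:
            raise PhantomConfigError("amplitude_decay must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["frame_shape"] = list(self.frame_shape)
        d["intensity_means"] = list(self.intensity_means)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        d["frame_shape"] = tuple(d["frame_shape"])
        d["intensity_means"] = tuple(d["intensity_means"])
        return cls(**d)


@dataclass
class PhantomTruth:
    """Analytic ground truth of a rendered phantom sequence.

    Boundary arrays have shape (n_frames, 2, n_cols) — side index 0 is the
    image-left fold, 1 the image-right fold — and hold sub-pixel boundary
    rows at each integer column, NaN where the fold does not cover the
    column.  Thickness arrays are in μm.  ``trajectory_row`` /
    ``trajectory_mm`` track the superior-medial surface point of each fold;
    ``gap_half_px`` gives the per-side glottal half-gap (px, 0 = closed) and
    ``midline_col`` the glottal midline.  ``jitter_offsets`` records the
    bulk-motion (row, col) shift applied to each rendered frame; boundary
    truth is reported in unjittered coordinates.
    """

    ep_outer_rows: np.ndarray
    interface_rows: np.ndarray
    lp_deep_rows: np.ndarray
    ep_thickness_um: np.ndarray
    lp_thickness_um: np.ndarray
    trajectory_row: np.ndarray       # (n_frames, 2) px
    trajectory_mm: np.ndarray        # (n_frames, 2) superior displacement, mm
    gap_half_px: np.ndarray          # (n_frames, 2)
    midline_col: float
    jitter_offsets: np.ndarray       # (n_frames, 2) int
    times: np.ndarray                # s
    phase_labels: np.ndarray

    def air_mask(self) -> np.ndarray:
        """(n_frames, n_cols) boolean mask of columns with no tissue."""
        left = self.ep_outer_rows[:, 0, :]
        right = self.ep_outer_rows[:, 1, :]
        return np.isnan(left) & np.isnan(right)


def _pixel_sizes(config: PhantomConfig, geometry: ScanGeometry):
    ep_px = config.ep_thickness / geometry.axial_pitch_tissue
    lp_px = config.lp_thickness / geometry.axial_pitch_tissue
    vamp_px = config.vertical_amplitude * 1000.0 / geometry.axial_pitch_tissue
    lamp_px = config.lateral_amplitude * 1000.0 / geometry.lateral_pitch
    gap_px = config.glottal_half_gap / geometry.lateral_pitch
    return ep_px, lp_px, vamp_px, lamp_px, gap_px


def _validate_layout(config: PhantomConfig, geometry: ScanGeometry):
    rows, cols = config.frame_shape
    ep_px, lp_px, vamp_px, lamp_px, gap_px = _pixel_sizes(config, geometry)
    center = cols / 2.0
    top_margin = 4 + config.frame_jitter_px
    rest_row = config.rest_surface_row
    if rest_row is None:
        rest_row = vamp_px + top_margin
    if rest_row - vamp_px < top_margin - 2:
        raise PhantomConfigError(
            "vertical_amplitude: fold surface exits the top of the frame "
            f"(peak row {rest_row - vamp_px:.1f})")
    taper_rise = config.lateral_taper * (center - config.edge_margin_px)
    bottom = rest_row + vamp_px + taper_rise + ep_px + lp_px
    if bottom > rows - 2 - config.frame_jitter_px:
        raise PhantomConfigError(
            "lp_thickness/vertical_amplitude: fold bottom exits the frame "
            f"(max row {bottom:.1f} of {rows})")
    if center - (gap_px + lamp_px) < config.edge_margin_px + 10:
        raise PhantomConfigError(
            "glottal_half_gap/lateral_amplitude: folds too narrow for frame width")
    return rest_row


def generate_sequence(config: PhantomConfig,
                      geometry: ScanGeometry) -> tuple[FrameSequence, PhantomTruth]:
    """Render the phantom and return the frames plus analytic truth.

    Identical ``config`` (including ``rng_seed``) and ``geometry`` give a
    bit-identical sequence.  Raises :class:`PhantomConfigError` when a
    geometric parameter does not fit inside ``frame_shape``.
    """
    if not np.isclose(config.frame_rate, geometry.frame_rate, rtol=1e-9):
        raise PhantomConfigError(
            f"config frame_rate {config.frame_rate} != geometry frame_rate "
            f"{geometry.frame_rate}")
    rows, cols = config.frame_shape
    ep_px, lp_px, vamp_px, lamp_px, gap_px = _pixel_sizes(config, geometry)
    rest_row = _validate_layout(config, geometry)
    noise_mean, ep_mean, lp_mean = config.intensity_means
    center = cols / 2.0
    pitch = geometry.axial_pitch_tissue
    rng = np.random.default_rng(config.rng_seed)

    n = config.n_frames
    n_cols = cols
    times = np.arange(n) / config.frame_rate
    phase_labels = np.array(
        [REST] * config.n_rest_frames + [PHONATION] * (n - config.n_rest_frames),
        dtype=object)

    # per-frame oscillator phase; zero (at-rest position) during rest frames
    osc = np.zeros((n, 2))
    t_phon = (np.arange(n) - config.n_rest_frames) / config.frame_rate
    phases = (0.0, config.phase_offset)
    for s, ph in enumerate(phases):
        active = np.arange(n) >= config.n_rest_frames
        osc[active, s] = np.sin(
            2 * np.pi * config.fundamental_freq * t_phon[active] + ph)

    gap_half_t = np.clip(gap_px - lamp_px * osc, 0.0, None)  # (n, 2)

    ep_outer = np.full((n, 2, n_cols), np.nan)
    interface = np.full((n, 2, n_cols), np.nan)
    lp_deep = np.full((n, 2, n_cols), np.nan)
    frames = np.empty((n, rows, cols), dtype=np.float32)
    jitter = np.zeros((n, 2), dtype=int)

    col_idx = np.arange(n_cols, dtype=float)
    r_idx = np.arange(rows, dtype=float)[:, None]
    taper_term = config.lateral_taper * np.abs(col_idx - center)
    # vibration amplitude may decay from the medial free edge laterally
    half_width = center - config.edge_margin_px
    decay_factor = 1.0 - config.amplitude_decay * np.clip(
        np.abs(col_idx - center) / half_width, 0.0, 1.0)

    for i in range(n):
        img = np.full((rows, cols), noise_mean, dtype=np.float64)
        for s in range(2):
            g = gap_half_t[i, s]
            if s == 0:
                medial_edge = center - g
                lat_frac = np.clip(medial_edge - col_idx + 0.5, 0.0, 1.0)
                lat_frac[col_idx < config.edge_margin_px] = 0.0
            else:
                medial_edge = center + g
                lat_frac = np.clip(col_idx - medial_edge + 0.5, 0.0, 1.0)
                lat_frac[col_idx > n_cols - 1 - config.edge_margin_px] = 0.0
            covered = lat_frac > 0
            if not covered.any():
                continue
            s_top = rest_row + taper_term \
                - vamp_px * decay_factor * osc[i, s]
            s_if = s_top + ep_px
            s_bot = s_if + lp_px
            cov_top = np.clip(r_idx + 0.5 - s_top[None, :], 0.0, 1.0)
            cov_if = np.clip(r_idx + 0.5 - s_if[None, :], 0.0, 1.0)
            cov_bot = np.clip(r_idx + 0.5 - s_bot[None, :], 0.0, 1.0)
            ep_frac = cov_top - cov_if
            lp_frac = cov_if - cov_bot
            depth_um = np.clip(r_idx - s_top[None, :], 0.0, None) * pitch
            att = np.exp(-depth_um / config.attenuation_depth)
            img += lat_frac[None, :] * (
                ep_frac * (ep_mean * att - noise_mean)
                + lp_frac * (lp_mean * att - noise_mean))

            # truth: fully covered columns only (boundary column excluded)
            full_cols = lat_frac >= 1.0
            ep_outer[i, s, full_cols] = s_top[full_cols]
            interface[i, s, full_cols] = s_if[full_cols]
            lp_deep[i, s, full_cols] = s_bot[full_cols]

        if config.speckle_sigma > 0:
            sig = config.speckle_sigma
            img *= rng.lognormal(mean=-sig * sig / 2.0, sigma=sig,
                                 size=img.shape)
        if config.frame_jitter_px > 0:
            j = rng.integers(-config.frame_jitter_px,
                             config.frame_jitter_px + 1, size=2)
            jitter[i] = j
            img = _integer_shift(img, int(j[0]), int(j[1]), noise_mean)
        np.clip(img, 0.0, 255.0, out=img)
        frames[i] = img.astype(np.float32)

    ep_um = (interface - ep_outer) * pitch
    lp_um = (lp_deep - interface) * pitch

    # superior-medial point: surface row at the (moving) medial edge
    decay_med = 1.0 - config.amplitude_decay * np.clip(
        gap_half_t / half_width, 0.0, 1.0)
    traj_row = rest_row + config.lateral_taper * gap_half_t \
        - vamp_px * decay_med * osc
    traj_mm = (rest_row + config.lateral_taper * gap_px - traj_row) \
        * pitch / 1000.0  # + = superior displacement from rest

    seq = FrameSequence(frames=frames, geometry=geometry,
                        phase_labels=phase_labels)
    truth = PhantomTruth(
        ep_outer_rows=ep_outer, interface_rows=interface, lp_deep_rows=lp_deep,
        ep_thickness_um=ep_um, lp_thickness_um=lp_um,
        trajectory_row=traj_row, trajectory_mm=traj_mm,
        gap_half_px=gap_half_t, midline_col=center,
        jitter_offsets=jitter, times=times, phase_labels=phase_labels)
    return seq, truth


def _integer_shift(img: np.ndarray, dr: int, dc: int, fill: float) -> np.ndarray:
    out = np.full_like(img, fill)
    rows, cols = img.shape
    r0, r1 = max(0, dr), min(rows, rows + dr)
    c0, c1 = max(0, dc), min(cols, cols + dc)
    out[r0:r1, c0:c1] = img[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
    return out


def simulate_calibration(geometry: ScanGeometry, step_mm: float,
                         total_mm: float, jitter_px: float = 0,
                         rng_seed: int = 0) -> CalibrationRecord:
    """Simulate a mirror-on-translation-stage axial calibration sweep.

    The stage is stepped from 0 to ``total_mm`` inclusive in ``step_mm``
    increments; at each position the mirror line appears at pixel row
    ``round(position / axial_pitch_air)``, optionally perturbed by an
    integer jitter of up to ``jitter_px``.  The default instrument sweep
    (0.5 mm steps over 12 mm) yields 25 observations.
    """
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    if total_mm < 0:
        raise ValueError("total_mm must be non-negative")
    if jitter_px < 0:
        raise ValueError("jitter_px must be non-negative")
    n_steps = total_mm / step_mm
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("step_mm must divide total_mm")
    n_obs = int(round(n_steps)) + 1
    positions = np.arange(n_obs) * step_mm
    rows = np.round(positions * 1000.0 / geometry.axial_pitch_air).astype(int)
    if jitter_px > 0:
        rng = np.random.default_rng(rng_seed)
        rows = rows + rng.integers(-int(jitter_px), int(jitter_px) + 1,
                                   size=n_obs)
        rows = np.clip(rows, 0, None)
    return CalibrationRecord(stage_positions=positions, mirror_rows=rows)
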