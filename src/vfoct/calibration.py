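"""Pixel-to-metric calibration for long-range laryngeal OCT.

All measurements downstream (layer thickness, displacement, velocity) are
made on a rectilinear pixel grid and converted to metric units with the
constants collected here:

* **axial pitch in air** — μm of optical path per image row, measured with a
  mirror on a linear translation stage (see :func:`fit_stage_regression`);
* **axial pitch in tissue** — the air pitch divided by a bulk soft-tissue
  refractive index (default 1.4);
* **lateral pitch** — μm per A-line. The scanner fan widens with depth, so
  the single stored value is the mean of the fan width at the top and bottom
  of the frame divided by the A-line count. The fan propagates in air and is
  *not* divided by the refractive index.

Pitches are stored at full float precision; rounding to the conventionally
reported two decimals happens only in displays/reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ScanGeometry",
    "CalibrationRecord",
    "tissue_axial_pitch",
    "lateral_pitch_from_fan",
    "frame_rate_from_source",
    "aspect_ratio",
    "fit_stage_regression",
    "px_to_um",
    "um_to_px",
    "default_geometry",
]

#: Instrument constants of the 1310-nm, 200-kHz swept-source laryngeal
#: scanner the package is calibrated for by default.
VCSEL_AXIAL_PITCH_AIR_UM = 5.94
VCSEL_REFRACTIVE_INDEX = 1.4
VCSEL_FAN_WIDTH_TOP_MM = 7.8
VCSEL_FAN_WIDTH_BOTTOM_MM = 9.2
VCSEL_N_ALINES = 800
VCSEL_ALINE_RATE_HZ = 200_000

_AXES = ("axial_air", "axial_tissue", "lateral")


def tissue_axial_pitch(axial_pitch_air: float, refractive_index: float) -> float:
    """Axial μm/px inside tissue: air pitch divided by refractive index.

    >>> round(tissue_axial_pitch(5.94, 1.4), 2)
    4.24
    """
    if axial_pitch_air <= 0 or refractive_index <= 0:
        raise ValueError("axial_pitch_air and refractive_index must be positive")
    return axial_pitch_air / refractive_index


def lateral_pitch_from_fan(fan_width_top: float, fan_width_bottom: float,
                           n_alines: int) -> float:
    """Lateral μm/px from the fan-shaped scan extent.

    Parameters are the lateral scan widths (mm) at the top and bottom of the
    frame and the number of A-lines per frame.  The mean width divided by the
    A-line count gives a single depth-averaged pitch; the beam fans out in
    air, so no refractive-index correction applies.

    >>> lateral_pitch_from_fan(7.8, 9.2, 800)
    10.625
    """
    if fan_width_top <= 0 or fan_width_bottom <= 0 or n_alines <= 0:
        raise ValueError("fan widths and n_alines must be positive")
    return (fan_width_top + fan_width_bottom) / 2.0 / n_alines * 1000.0


def frame_rate_from_source(aline_rate: float, n_alines: int) -> float:
    """Frame rate (Hz) given the swept-source A-line rate and frame width."""
    if aline_rate <= 0 or n_alines <= 0:
        raise ValueError("aline_rate and n_alines must be positive")
    return aline_rate / n_alines


@dataclass
class ScanGeometry:
    """Scan-geometry sidecar: everything needed to convert px to μm and s.

    ``axial_pitch_tissue`` is derived from ``axial_pitch_air`` and
    ``refractive_index`` and kept at full float precision.
    """

    axial_pitch_air: float
    refractive_index: float
    lateral_pitch: float
    n_alines: int
    frame_rate: float
    fan_width_top: float | None = None
    fan_width_bottom: float | None = None
    working_distance: float | None = None
    axial_pitch_tissue: float = field(init=False)

    def __post_init__(self) -> None:
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")
        if self.lateral_pitch <= 0 or self.frame_rate <= 0:
            raise ValueError("lateral_pitch and frame_rate must be positive")
        self.axial_pitch_tissue = tissue_axial_pitch(
            self.axial_pitch_air, self.refractive_index)
        if self.fan_width_top is not None and self.fan_width_bottom is not None:
            expected = lateral_pitch_from_fan(
                self.fan_width_top, self.fan_width_bottom, self.n_alines)
            if not np.isclose(expected, self.lateral_pitch, rtol=1e-6):
                raise ValueError(
                    f"lateral_pitch {self.lateral_pitch} inconsistent with fan "
                    f"widths (expected {expected})")

    @classmethod
    def from_fan(cls, axial_pitch_air: float, refractive_index: float,
                 fan_width_top: float, fan_width_bottom: float,
                 n_alines: int, frame_rate: float,
                 working_distance: float | None = None) -> "ScanGeometry":
        return cls(
            axial_pitch_air=axial_pitch_air,
            refractive_index=refractive_index,
            lateral_pitch=lateral_pitch_from_fan(
                fan_width_top, fan_width_bottom, n_alines),
            n_alines=n_alines,
            frame_rate=frame_rate,
            fan_width_top=fan_width_top,
            fan_width_bottom=fan_width_bottom,
            working_distance=working_distance,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        d = dict(d)
        d.pop("axial_pitch_tissue", None)
        return cls(**d)


def default_geometry() -> ScanGeometry:
    """Geometry of the default instrument: 5.94 μm/px axial in air, n = 1.4,
    7.8/9.2 mm fan over 800 A-lines, 250 Hz frames."""
    return ScanGeometry.from_fan(
        axial_pitch_air=VCSEL_AXIAL_PITCH_AIR_UM,
        refractive_index=VCSEL_REFRACTIVE_INDEX,
        fan_width_top=VCSEL_FAN_WIDTH_TOP_MM,
        fan_width_bottom=VCSEL_FAN_WIDTH_BOTTOM_MM,
        n_alines=VCSEL_N_ALINES,
        frame_rate=frame_rate_from_source(VCSEL_ALINE_RATE_HZ, VCSEL_N_ALINES),
        working_distance=60.0,
    )


def aspect_ratio(geometry: ScanGeometry) -> float:
    """Display width-to-height ratio that renders tissue isotropically.

    Uses the unrounded tissue pitch, so the default geometry gives 2.5042…,
    reported as 2.50 at two decimals.
    """
    return geometry.lateral_pitch / geometry.axial_pitch_tissue


@dataclass
class CalibrationRecord:
    """Mirror-row observations of a linear-stage sweep plus the OLS fit.

    ``slope`` is px/mm, ``intercept`` px, ``r_squared`` the coefficient of
    determination of rows regressed on metric stage positions.
    """

    stage_positions: np.ndarray  # mm, strictly increasing
    mirror_rows: np.ndarray      # px, non-negative integers
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None

    def __post_init__(self) -> None:
        self.stage_positions = np.asarray(self.stage_positions, dtype=float)
        self.mirror_rows = np.asarray(self.mirror_rows)
        if self.stage_positions.ndim != 1 or \
                self.stage_positions.shape != self.mirror_rows.shape:
            raise ValueError("positions and rows must be 1-D and equal length")
        if len(self.stage_positions) > 1 and \
                not np.all(np.diff(self.stage_positions) > 0):
            raise ValueError("stage positions must be strictly increasing")
        if np.any(self.mirror_rows < 0):
            raise ValueError("mirror rows must be non-negative")


def fit_stage_regression(positions: Sequence[float],
                         rows: Sequence[float]) -> CalibrationRecord:
    """Ordinary least squares of mirror pixel row on metric stage position.

    Requires at least three observations with non-degenerate positions.
    Returns a :class:`CalibrationRecord` with slope (px/mm), intercept (px)
    and R².
    """
    positions = np.asarray(positions, dtype=float)
    rows_arr = np.asarray(rows, dtype=float)
    if positions.size < 3:
        raise ValueError("need at least 3 calibration points")
    if positions.shape != rows_arr.shape:
        raise ValueError("positions and rows must have equal length")
    if np.ptp(positions) == 0:
        raise ValueError("stage positions have zero variance")
    res = stats.linregress(positions, rows_arr)
    return CalibrationRecord(
        stage_positions=positions,
        mirror_rows=np.asarray(rows),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
    )


def _pitch_for_axis(axis: str, geometry: ScanGeometry) -> float:
    if axis == "axial_air":
        return geometry.axial_pitch_air
    if axis == "axial_tissue":
        return geometry.axial_pitch_tissue
    if axis == "lateral":
        return geometry.lateral_pitch
    raise ValueError(f"unknown axis {axis!r}; expected one of {_AXES}")


def px_to_um(value_px, axis: str, geometry: ScanGeometry):
    """Convert pixels to μm along ``axis`` (axial_air, axial_tissue, lateral)."""
    return np.asarray(value_px, dtype=float) * _pitch_for_axis(axis, geometry)


def um_to_px(value_um, axis: str, geometry: ScanGeometry):
    """Inverse of :func:`px_to_um`; does not round."""
    return np.asarray(value_um, dtype=float) / _pitch_for_axis(axis, geometry)
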