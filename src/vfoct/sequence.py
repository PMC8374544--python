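"""Ordered grayscale OCT frame sequences with scan geometry and phase labels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import ScanGeometry

__all__ = ["FrameSequence", "REST", "PHONATION", "UNKNOWN"]

REST = "rest"
PHONATION = "phonation"
UNKNOWN = "unknown"


@dataclass
class FrameSequence:
    """A stack of equally shaped grayscale frames plus acquisition metadata.

    ``frames`` is a float array of shape (n_frames, rows, cols).  Phase
    labels mark each frame as acquired during quiet respiration (``rest``),
    sustained phonation (``phonation``) or ``unknown``.  ``offsets`` records
    the per-frame (row, col) shift applied by stabilization — applying then
    subtracting the offsets restores the original indexing.  ``roi_origin``
    records the top-left corner of the current crop in the coordinates of
    the original acquisition.
    """

    frames: np.ndarray
    geometry: ScanGeometry
    phase_labels: np.ndarray | None = None
    offsets: np.ndarray = field(default=None)  # (n, 2) int, row/col shifts
    roi_origin: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (n, rows, cols) stack")
        n = self.frames.shape[0]
        if self.phase_labels is None:
            self.phase_labels = np.full(n, UNKNOWN, dtype=object)
        else:
            self.phase_labels = np.asarray(self.phase_labels, dtype=object)
            if self.phase_labels.shape != (n,):
                raise ValueError("phase_labels must have one entry per frame")
        if self.offsets is None:
            self.offsets = np.zeros((n, 2), dtype=int)
        else:
            self.offsets = np.asarray(self.offsets, dtype=int)
            if self.offsets.shape != (n, 2):
                raise ValueError("offsets must be (n_frames, 2)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.geometry.frame_rate

    def copy_with(self, **kw) -> "FrameSequence":
        out = dict(
            frames=self.frames,
            geometry=self.geometry,
            phase_labels=self.phase_labels,
            offsets=self.offsets,
            roi_origin=self.roi_origin,
        )
        out.update(kw)
        return FrameSequence(**out)
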