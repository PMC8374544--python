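"""Shared fixtures: instrument geometry and phantom sequences.

Phantoms are module-scoped because rendering plus segmentation dominates
suite runtime; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from vfoct.calibration import ScanGeometry, default_geometry
from vfoct.phantom import PhantomConfig, generate_sequence


@pytest.fixture(scope="session")
def geometry() -> ScanGeometry:
    """Default instrument geometry (5.94 μm/px air, n=1.4, 250 Hz)."""
    return default_geometry()


@pytest.fixture(scope="session")
def small_noiseless(geometry):
    """Small noiseless phantom: one slow vibration cycle (10 Hz, 25 frames)."""
    cfg = PhantomConfig(
        frame_shape=(200, 240), n_frames=30, n_rest_frames=5,
        fundamental_freq=10.0, vertical_amplitude=0.1,
        lateral_amplitude=0.05, glottal_half_gap=150.0,
        speckle_sigma=0.0, lateral_taper=0.05, rng_seed=0)
    seq, truth = generate_sequence(cfg, geometry)
    return cfg, seq, truth


@pytest.fixture(scope="session")
def small_speckled(geometry):
    """Same scene with default multiplicative speckle."""
    cfg = PhantomConfig(
        frame_shape=(200, 240), n_frames=30, n_rest_frames=5,
        fundamental_freq=10.0, vertical_amplitude=0.1,
        lateral_amplitude=0.05, glottal_half_gap=150.0,
        speckle_sigma=0.12, lateral_taper=0.05, rng_seed=7)
    seq, truth = generate_sequence(cfg, geometry)
    return cfg, seq, truth


@pytest.fixture(scope="session")
def static_phantom(geometry):
    """Noiseless phantom with no motion at all."""
    cfg = PhantomConfig(
        frame_shape=(200, 240), n_frames=8, n_rest_frames=0,
        fundamental_freq=10.0, vertical_amplitude=0.0,
        lateral_amplitude=0.0, glottal_half_gap=150.0,
        speckle_sigma=0.0, lateral_taper=0.05, rng_seed=0)
    seq, truth = generate_sequence(cfg, geometry)
    return cfg, seq, truth


@pytest.fixture(scope="session")
def segmented_noiseless(small_noiseless):
    """Segmentations of the noiseless cycle (computed once)."""
    from vfoct.segmentation import segment_sequence
    _, seq, _ = small_noiseless
    return segment_sequence(seq.frames)
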