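"""End-to-end run orchestration: phantom/frames → preprocess → segment →
morphometry → kinematics → kymography, with a reproducibility manifest.

Stage order is fixed (stabilize → crop → denoise → segment → measure);
toggles only switch stages off.  A frame that fails to segment is flagged
and skipped by downstream stages, never fatal to the run.  Frame-phase
labels (rest vs phonation) come from the input sidecar or phantom config,
not from any automatic voicing detection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .calibration import ScanGeometry, default_geometry
from . import io as vio
from .kinematics import build_velocity_field, track_sequence
from .kymography import build_vkg, render_velocity_map, render_vkg
from .morphometry import (summarize_profiles, thickness_profile,
                          vertical_displacement)
from .phantom import PhantomConfig, generate_sequence
from .preprocess import crop_roi, denoise_sequence, stabilize
from .segmentation import SIDES, segment_sequence
from .sequence import FrameSequence, PHONATION, REST

__all__ = ["RunConfig", "RunManifest", "run"]

logger = logging.getLogger("vfoct")

_KNOWN_KEYS = {
    "frames_path", "phantom", "geometry", "output_dir", "seed",
    "stabilize_template", "search_margin", "roi", "denoise", "tv_weight",
    "n_bins", "min_area", "n_points", "medial_band", "kymo_band_width",
    "write_plots", "log_level",
}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    Exactly one of ``frames_path`` (TIFF + sidecar) or ``phantom`` (a
    :class:`~vfoct.phantom.PhantomConfig`) supplies the input.  Unknown keys
    in a config mapping are rejected.
    """

    output_dir: str
    frames_path: str | None = None
    phantom: PhantomConfig | None = None
    geometry: ScanGeometry | None = None
    seed: int = 0
    stabilize_template: tuple[int, int, int, int] | None = None
    search_margin: int = 10
    roi: tuple[int, int, int, int] | None = None
    denoise: bool = True
    tv_weight: float = 0.1
    n_bins: int = 256
    min_area: float = 50.0
    n_points: int = 30
    medial_band: float = 0.10
    kymo_band_width: int = 16
    write_plots: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.frames_path is None) == (self.phantom is None):
            raise ValueError(
                "exactly one of frames_path or phantom must be given")
        if self.phantom is not None and self.geometry is None:
            self.geometry = default_geometry()

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        data = dict(data)
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "phantom" in data and data["phantom"] is not None:
            ph = dict(data["phantom"])
            if "rng_seed" not in ph:
                ph["rng_seed"] = data.get("seed", 0)
            data["phantom"] = PhantomConfig.from_dict(ph)
        if "geometry" in data and data["geometry"] is not None:
            data["geometry"] = ScanGeometry.from_dict(data["geometry"])
        for key in ("stabilize_template", "roi"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class RunManifest:
    """Everything needed to reproduce and audit a run."""

    version: str
    config: dict
    n_frames: int = 0
    n_accepted: int = 0
    n_unsegmentable: int = 0
    n_alignment_flagged: int = 0
    threshold_sources: dict = field(default_factory=dict)
    midline_col: float | None = None
    amplitudes_mm: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def _load_input(config: RunConfig):
    if config.phantom is not None:
        seq, truth = generate_sequence(config.phantom, config.geometry)
        return seq, truth
    seq = vio.load_sequence(config.frames_path)
    if config.geometry is not None:
        seq = seq.copy_with(geometry=config.geometry)
    return seq, None


def run(config: RunConfig) -> RunManifest:
    """Execute all stages; returns the manifest (also written to disk)."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cfg_dict = {k: v for k, v in asdict(config).items()}
    manifest = RunManifest(version=__version__, config=cfg_dict)

    seq, truth = _load_input(config)
    geometry = seq.geometry
    if truth is not None:
        vio.save_truth(truth, out_dir / "truth")
        vio.save_sequence(seq, out_dir, stem="frames", config=config.phantom)

    if config.stabilize_template is not None:
        seq = stabilize(seq, config.stabilize_template,
                        search_margin=config.search_margin)
        logger.info("stabilized: max |offset| = %d px",
                    int(np.abs(seq.offsets).max()))
    if config.roi is not None:
        seq = crop_roi(seq, config.roi)
    if config.denoise:
        seq = denoise_sequence(seq, weight=config.tv_weight)

    segs = segment_sequence(seq.frames, n_bins=config.n_bins,
                            min_area=config.min_area)
    manifest.n_frames = seq.n_frames
    manifest.n_unsegmentable = sum(s.unsegmentable for s in segs)
    manifest.n_accepted = manifest.n_frames - manifest.n_unsegmentable
    manifest.n_alignment_flagged = sum(not s.alignment_ok for s in segs)
    sources = {}
    for s in segs:
        sources[s.thresholds.source] = sources.get(s.thresholds.source, 0) + 1
    manifest.threshold_sources = sources
    good = [s for s in segs if not s.unsegmentable]
    if good:
        manifest.midline_col = float(np.nanmedian(
            [s.midline_col for s in good]))
    vio.save_segmentations(segs, out_dir / "segmentations.json")
    manifest.outputs.append("segmentations.json")

    if manifest.n_accepted == 0:
        (out_dir / "manifest.json").write_text(manifest.to_json())
        logger.warning("no frame segmented; stopping after segmentation")
        return manifest

    profiles = [thickness_profile(seg, geometry, frame_index=i)
                for i, seg in enumerate(segs)]
    vio.profiles_to_frame(profiles).to_csv(out_dir / "thickness.csv",
                                           index=False)
    manifest.outputs.append("thickness.csv")

    labels = seq.phase_labels
    summaries = []
    for phase in (REST, PHONATION):
        phase_profiles = [
            p for sides, lab, s in zip(profiles, labels, segs)
            if lab == phase and not s.unsegmentable
            for p in sides.values()]
        if phase_profiles:
            try:
                summaries.extend(summarize_profiles(phase_profiles, phase))
            except ValueError:
                pass
    if summaries:
        vio.summaries_to_frame(summaries).to_csv(
            out_dir / "thickness_summary.csv", index=False)
        manifest.outputs.append("thickness_summary.csv")

    disp_rows = []
    for side in SIDES:
        try:
            series = vertical_displacement(segs, geometry, labels, side,
                                           medial_band=config.medial_band)
        except ValueError:
            continue
        manifest.amplitudes_mm[side] = series.amplitude_mm
        for i in range(len(series.frame_indices)):
            disp_rows.append((side, i, series.point_row[i],
                              series.point_col[i], series.position_mm[i],
                              series.displacement_mm[i]))
    if disp_rows:
        import pandas as pd
        pd.DataFrame(disp_rows, columns=[
            "side", "frame", "row_px", "col_px", "position_mm",
            "displacement_mm"]).to_csv(out_dir / "displacement.csv",
                                       index=False)
        manifest.outputs.append("displacement.csv")

    fields = {}
    for side in SIDES:
        track = track_sequence(segs, side, n_points=config.n_points)
        if np.isnan(track.points).all():
            continue
        fields[side] = build_velocity_field(track, geometry)
    if fields:
        import pandas as pd
        rows = []
        for side, fld in fields.items():
            n_pairs, n_pts = fld.vx.shape
            for t in range(n_pairs):
                for p in range(n_pts):
                    rows.append((t, side, p, fld.vx[t, p], fld.vy[t, p],
                                 fld.speed[t, p], fld.direction[t, p]))
        pd.DataFrame(rows, columns=[
            "frame_pair", "side", "point", "vx_mm_s", "vy_mm_s",
            "speed_mm_s", "direction_rad"]).to_csv(
                out_dir / "velocity.csv", index=False)
        manifest.outputs.append("velocity.csv")

    for layer in ("ep", "lp", "combined"):
        kymo = build_vkg(profiles, layer, geometry.frame_rate,
                         geometry.lateral_pitch)
        vio.save_kymograph(kymo, out_dir / f"vkg_{layer}.csv")
        manifest.outputs.append(f"vkg_{layer}.csv")
        if config.write_plots:
            import matplotlib.pyplot as plt
            ax = render_vkg(kymo)
            ax.figure.savefig(out_dir / f"vkg_{layer}.png", dpi=110)
            plt.close(ax.figure)
            manifest.outputs.append(f"vkg_{layer}.png")

    if config.write_plots and len(fields) == 2:
        import matplotlib.pyplot as plt
        for component in ("vertical", "horizontal"):
            ax, mat = render_velocity_map(fields["left"], fields["right"],
                                          component, geometry.frame_rate)
            np.savetxt(out_dir / f"velocity_map_{component}.csv", mat,
                       delimiter=",", fmt="%.17g")
            ax.figure.savefig(out_dir / f"velocity_map_{component}.png",
                              dpi=110)
            plt.close(ax.figure)
            manifest.outputs.extend([f"velocity_map_{component}.csv",
                                     f"velocity_map_{component}.png"])

    (out_dir / "manifest.json").write_text(manifest.to_json())
    manifest.outputs.append("manifest.json")
    return manifest
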