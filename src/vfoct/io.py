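"""Reading and writing sequences, sidecars, and analysis tables.

Frames travel as multi-page TIFF with a YAML sidecar carrying the scan
geometry, phase labels, stabilization offsets, and ROI origin.  Analysis
products are plain CSV/JSON so they can be diffed and versioned.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibration import CalibrationRecord, ScanGeometry
from .kymography import Kymograph
from .morphometry import ThicknessProfile, ThicknessSummary
from .phantom import PhantomConfig, PhantomTruth
from .segmentation import LayerSegmentation, SIDES, LAYERS
from .sequence import FrameSequence

__all__ = [
    "save_sequence", "load_sequence", "save_geometry", "load_geometry",
    "save_calibration", "save_truth", "save_segmentations",
    "profiles_to_frame", "summaries_to_frame", "save_kymograph",
    "load_kymograph_matrix",
]


def save_geometry(geometry: ScanGeometry, path: str | Path) -> None:
    path = Path(path)
    data = geometry.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data))


def load_geometry(path: str | Path) -> ScanGeometry:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return ScanGeometry.from_dict(data)


def save_sequence(seq: FrameSequence, directory: str | Path,
                  stem: str = "frames",
                  config: PhantomConfig | None = None) -> Path:
    """Write frames as multi-page TIFF + YAML sidecar; returns TIFF path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tiff_path = directory / f"{stem}.tiff"
    tifffile.imwrite(tiff_path, np.asarray(seq.frames, dtype=np.float32),
                     photometric="minisblack")
    sidecar = {
        "geometry": seq.geometry.to_dict(),
        "phase_labels": [str(p) for p in seq.phase_labels],
        "offsets": seq.offsets.tolist(),
        "roi_origin": list(seq.roi_origin),
    }
    if config is not None:
        sidecar["phantom_config"] = config.to_dict()
    (directory / f"{stem}.yaml").write_text(yaml.safe_dump(sidecar))
    return tiff_path


def load_sequence(tiff_path: str | Path) -> FrameSequence:
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path)
    sidecar_path = tiff_path.with_suffix(".yaml")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    sidecar = yaml.safe_load(sidecar_path.read_text())
    return FrameSequence(
        frames=frames,
        geometry=ScanGeometry.from_dict(sidecar["geometry"]),
        phase_labels=np.array(sidecar["phase_labels"], dtype=object),
        offsets=np.array(sidecar["offsets"], dtype=int),
        roi_origin=tuple(sidecar["roi_origin"]),
    )


def save_calibration(record: CalibrationRecord, directory: str | Path,
                     stem: str = "calibration") -> None:
    """CSV of (position_mm, row_px) plus a JSON fit summary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "position_mm": record.stage_positions,
        "row_px": record.mirror_rows,
    }).to_csv(directory / f"{stem}.csv", index=False)
    fit = {"slope_px_per_mm": record.slope, "intercept_px": record.intercept,
           "r_squared": record.r_squared}
    (directory / f"{stem}_fit.json").write_text(json.dumps(fit, indent=2))


def save_truth(truth: PhantomTruth, directory: str | Path) -> None:
    """Phantom ground truth: per-A-line CSV + contour/trajectory JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n, _, n_cols = truth.ep_outer_rows.shape
    rows = []
    for i in range(n):
        for s, side in enumerate(SIDES):
            ok = ~np.isnan(truth.ep_outer_rows[i, s])
            for c in np.flatnonzero(ok):
                rows.append((i, side, int(c),
                             truth.ep_outer_rows[i, s, c],
                             truth.interface_rows[i, s, c],
                             truth.lp_deep_rows[i, s, c],
                             truth.ep_thickness_um[i, s, c],
                             truth.lp_thickness_um[i, s, c]))
    pd.DataFrame(rows, columns=[
        "frame", "side", "col", "ep_outer_row", "interface_row",
        "lp_deep_row", "ep_um", "lp_um",
    ]).to_csv(directory / "truth_alines.csv", index=False)
    traj = {
        "times_s": truth.times.tolist(),
        "trajectory_row_px": truth.trajectory_row.tolist(),
        "trajectory_mm": truth.trajectory_mm.tolist(),
        "gap_half_px": truth.gap_half_px.tolist(),
        "midline_col": truth.midline_col,
        "jitter_offsets": truth.jitter_offsets.tolist(),
    }
    (directory / "truth_trajectory.json").write_text(json.dumps(traj))


def save_segmentations(segs: list[LayerSegmentation],
                       path: str | Path) -> None:
    """Per-frame, per-side boundary polylines as JSON."""
    out = []
    for i, seg in enumerate(segs):
        rec = {"frame": i, "unsegmentable": bool(seg.unsegmentable),
               "midline_col": None if np.isnan(seg.midline_col)
               else float(seg.midline_col),
               "thresholds": {"t_noise_ep": seg.thresholds.t_noise_ep,
                              "t_ep_lp": seg.thresholds.t_ep_lp,
                              "source": seg.thresholds.source},
               "sides": {}}
        for side in SIDES:
            layers = {}
            for layer in LAYERS:
                prof = seg.profiles[side][layer]
                ok = np.flatnonzero(~np.isnan(prof))
                layers[layer] = {"cols": ok.tolist(),
                                 "rows": prof[ok].round(4).tolist()}
            rec["sides"][side] = layers
        out.append(rec)
    Path(path).write_text(json.dumps(out))


def profiles_to_frame(profiles_over_time: list[dict[str, ThicknessProfile]],
                      ) -> pd.DataFrame:
    """Long-format table: frame, side, col, ep_um, lp_um, combined_um."""
    rows = []
    for sides in profiles_over_time:
        for side, prof in sides.items():
            ok = ~(np.isnan(prof.ep) & np.isnan(prof.lp))
            for c in np.flatnonzero(ok):
                rows.append((prof.frame_index, side, int(c),
                             prof.ep[c], prof.lp[c], prof.combined[c]))
    return pd.DataFrame(rows, columns=["frame", "side", "col", "ep_um",
                                       "lp_um", "combined_um"])


def summaries_to_frame(summaries: list[ThicknessSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "layer": s.layer, "phase": s.phase, "n_points": s.n_points,
        "mean_full_um": s.mean_full, "sd_full_um": s.sd_full,
        "mean_select_um": s.mean_select, "sd_select_um": s.sd_select,
        "n_excluded": s.n_excluded,
    } for s in summaries])


def save_kymograph(kymo: Kymograph, path: str | Path) -> None:
    """Numeric matrix dump (CSV); cells are μm, AIR sentinel preserved."""
    np.savetxt(path, kymo.matrix, delimiter=",", fmt="%.17g")


def load_kymograph_matrix(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))
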