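"""Plain-text/PNG serialisation for every pipeline artifact.

Frames travel as numbered 8-bit grey PNGs with a JSON sidecar (fps, ground
sample distance); everything tabular is CSV with stable column names; fits
and summaries are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .adcp import ADCPEnsemble, VelocitySection
from .synthetic_data.video import FrameSequence, SceneGroundTruth
from .tracker import Track
from .video_detection import Detection

__all__ = [
    "write_frames",
    "read_frames",
    "write_ground_truth",
    "write_detections",
    "read_detections",
    "write_tracks",
    "write_ensembles",
    "read_ensembles",
    "write_section",
]


def write_frames(seq: FrameSequence, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for k in range(len(seq)):
        iio.imwrite(out_dir / f"frame_{k:06d}.png", seq.frames[k])
    (out_dir / "metadata.json").write_text(json.dumps({
        "fps": seq.fps,
        "ground_sample_distance": seq.ground_sample_distance,
        "n_frames": len(seq),
    }, indent=1))


def read_frames(in_dir: Path) -> FrameSequence:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "metadata.json").read_text())
    files = sorted(in_dir.glob("frame_*.png"))
    frames = np.stack([iio.imread(f) for f in files])
    return FrameSequence(frames=frames, fps=meta["fps"],
                         ground_sample_distance=meta["ground_sample_distance"])


def write_ground_truth(gt: SceneGroundTruth, out_dir: Path,
                       gsd: float) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ([(i, "bird", f, x / gsd, y / gsd) for (i, f, x, y) in gt.bird_tracks]
            + [(i, "foam", f, x / gsd, y / gsd) for (i, f, x, y) in gt.foam_tracks])
    pd.DataFrame(rows, columns=["object_id", "class", "frame", "x_px", "y_px"]) \
        .to_csv(out_dir / "ground_truth.csv", index=False)
    (out_dir / "ground_truth_summary.json").write_text(json.dumps({
        "n_bird_ids": len({i for (i, _, _, _) in gt.bird_tracks}),
        "n_foam_ids": len({i for (i, _, _, _) in gt.foam_tracks}),
        "n_glint": len(gt.glint_events),
        "true_shedding_frequency_per_min": gt.true_shedding_frequency,
    }, indent=1))


def write_detections(dets_per_frame: Sequence[Sequence[Detection]],
                     path: Path) -> None:
    rows = [(d.frame, d.centroid[0], d.centroid[1], d.area)
            for frame_dets in dets_per_frame for d in frame_dets]
    pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "area_px2"]) \
        .to_csv(path, index=False)


def read_detections(path: Path) -> List[List[Detection]]:
    df = pd.read_csv(path)
    n_frames = int(df.frame.max()) + 1 if len(df) else 0
    out: List[List[Detection]] = [[] for _ in range(n_frames)]
    for row in df.itertuples():
        out[int(row.frame)].append(Detection(
            frame=int(row.frame), centroid=(row.x_px, row.y_px),
            area=int(row.area_px2),
            bbox=(int(row.x_px), int(row.y_px), int(row.x_px) + 1, int(row.y_px) + 1),
            mean_intensity=float("nan")))
    return out


def write_chips(chips: np.ndarray, out_dir: Path,
                labels: Optional[np.ndarray] = None) -> None:
    """Chips as 8-bit PNG tiles plus a CSV manifest (and optional labels)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, chip in enumerate(chips):
        name = f"chip_{i:06d}.png"
        iio.imwrite(out_dir / name, (np.clip(chip, 0, 1) * 255).astype(np.uint8))
        rows.append((name, int(labels[i]) if labels is not None else -1))
    pd.DataFrame(rows, columns=["file", "label"]) \
        .to_csv(out_dir / "manifest.csv", index=False)


def read_chips(in_dir: Path) -> Tuple[np.ndarray, np.ndarray]:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    chips = np.stack([iio.imread(in_dir / f).astype(float) / 255.0
                      for f in manifest["file"]])
    return chips, manifest["label"].to_numpy()


def write_tracks(tracks: Sequence[Track], path: Path) -> None:
    rows = [(tr.id, t, x, y) for tr in tracks for (t, x, y) in tr.points]
    pd.DataFrame(rows, columns=["track_id", "t_s", "x_m", "y_m"]) \
        .to_csv(path, index=False)


def write_ensembles(ensembles: Sequence[ADCPEnsemble], path: Path) -> None:
    """Long-format CSV: one row per (ping, beam, bin) with velocities."""
    rows = []
    for ping, e in enumerate(ensembles):
        nb, nbins = e.echo_counts.shape
        for beam in range(nb):
            for b in range(nbins):
                rows.append((ping, e.ping_time, e.position_along_transect,
                             beam, b + 1, e.echo_counts[beam, b],
                             e.measured_velocity[b, 0], e.measured_velocity[b, 1],
                             e.measured_velocity[b, 2],
                             e.bottom_track_velocity[0], e.bottom_track_velocity[1],
                             e.temperature, e.salinity))
    pd.DataFrame(rows, columns=[
        "ping", "ping_time_s", "y_m", "beam", "bin", "echo_counts",
        "u", "v", "w", "bt_u", "bt_v", "temperature", "salinity",
    ]).to_csv(path, index=False)


def read_ensembles(path: Path) -> List[ADCPEnsemble]:
    df = pd.read_csv(path)
    out = []
    for ping, g in df.groupby("ping"):
        beams = sorted(g.beam.unique())
        bins = sorted(g.bin.unique())
        counts = np.zeros((len(beams), len(bins)))
        vel = np.zeros((len(bins), 3))
        for row in g.itertuples():
            counts[int(row.beam), int(row.bin) - 1] = row.echo_counts
            vel[int(row.bin) - 1] = (row.u, row.v, row.w)
        first = g.iloc[0]
        out.append(ADCPEnsemble(
            ping_time=first.ping_time_s,
            position_along_transect=first.y_m,
            echo_counts=counts, measured_velocity=vel,
            bottom_track_velocity=np.array([first.bt_u, first.bt_v]),
            temperature=first.temperature, salinity=first.salinity,
        ))
    return out


def write_section(section: VelocitySection, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ny, nz = section.y.size, section.z.size
    yy, zz = np.meshgrid(section.y, section.z)
    pd.DataFrame({
        "y_m": yy.ravel(), "z_m": zz.ravel(),
        "speed": section.speed.ravel(), "sv_max": section.sv_max.ravel(),
        "w": section.w.ravel(), "n_samples": section.n_samples.ravel(),
    }).to_csv(out_dir / "section.csv", index=False)
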