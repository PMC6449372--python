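"""End-to-end stage orchestration with seeds, manifests and versioning.

Stages: simulate (video / counts / adcp / flow), detect, classify, track,
adcp processing, hurdle fitting, and particle transit.  Each stage derives
its own RNG stream from the global seed and the stage name via a stable
hash, so adding or reordering stages never silently changes another stage's
stream.  Every run writes a manifest (inputs hashed, seeds, package version,
outputs) and never mutates another stage's outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .adcp import InstrumentConfig, grid_section, wake_deficit_extent
from .bof_classifier import (build_vocabulary, classify_chips,
                             compute_descriptors, encode, train_classifier)
from .hurdle_model import expected_count, fit_hurdle, term_f_test
from .particle_transit import ReleaseSchedule, run_release, transit_summary
from .synthetic_data import (ADCPSimConfig, FlowFieldConfig, SceneConfig,
                             SurveyConfig, generate_adcp_transect,
                             generate_chip_dataset, generate_flow_field,
                             generate_survey_counts, generate_wake_video)
from .tracker import (TrackerConfig, compile_tracks,
                      filter_tracks_by_duration, trajectory_metrics)
from .video_detection import detect_sequence, extract_chip

log = logging.getLogger("wakewatch")

__all__ = ["stage_seed", "run", "load_config"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed by a stable hash."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def load_config(path: Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _cfg(cls, block: Optional[dict], **overrides):
    block = dict(block or {})
    block.update(overrides)
    return cls(**block)


def run(config: dict, out_dir: Path, seed: int = 0) -> dict:
    """Execute the requested stages in dependency order; return the manifest.

    ``config`` maps stage names to their config blocks, e.g.::

        stages: [simulate_video, detect, track]
        simulate_video: {duration: 4.0, n_birds: 3}
        detect: {diff_threshold: 25.0}

    Stage outputs land in per-stage subdirectories of ``out_dir``; a stage
    requested without its upstream artifact raises before anything is
    written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: List[str] = config.get("stages", [])
    manifest: Dict = {"version": __version__, "seed": seed,
                      "stages": stages, "outputs": {}, "stage_seeds": {}}

    order = ["simulate_video", "simulate_counts", "simulate_adcp",
             "simulate_flow", "detect", "classify", "track", "adcp",
             "hurdle", "transit"]
    unknown = [s for s in stages if s not in order]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    stages = [s for s in order if s in stages]

    deps = {"detect": "simulate_video", "classify": "detect",
            "track": "detect", "adcp": "simulate_adcp",
            "hurdle": "simulate_counts", "transit": "simulate_flow"}
    for s in stages:
        d = deps.get(s)
        if d and d not in stages and not (out_dir / d).exists():
            raise ValueError(f"stage {s!r} needs {d!r}: run it first")

    for s in stages:
        sseed = stage_seed(seed, s)
        manifest["stage_seeds"][s] = sseed
        sdir = out_dir / s
        log.info("running stage %s (seed %d)", s, sseed)
        outputs = _run_stage(s, config.get(s), sseed, sdir, out_dir)
        manifest["outputs"][s] = {
            str(p.relative_to(out_dir)): _hash_file(p) for p in outputs}

    manifest_path = out_dir / "manifest.json"
    history = []
    if manifest_path.exists():  # manifests are append-only
        prev = json.loads(manifest_path.read_text())
        history = prev.get("history", []) + [
            {k: v for k, v in prev.items() if k != "history"}]
    manifest["history"] = history
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _run_stage(stage: str, block: Optional[dict], sseed: int,
               sdir: Path, out_dir: Path) -> List[Path]:
    sdir.mkdir(parents=True, exist_ok=True)
    if stage == "simulate_video":
        cfg = _cfg(SceneConfig, block, seed=sseed)
        if isinstance(cfg.frame_size, list):
            cfg.frame_size = tuple(cfg.frame_size)
        seq, gt = generate_wake_video(cfg)
        io.write_frames(seq, sdir / "frames")
        io.write_ground_truth(gt, sdir, cfg.ground_sample_distance)
        return sorted(sdir.rglob("*.*"))

    if stage == "simulate_counts":
        cfg = _cfg(SurveyConfig, block, seed=sseed)
        df, truth = generate_survey_counts(cfg)
        df.to_csv(sdir / "counts.csv", index=False)
        (sdir / "true_params.json").write_text(json.dumps({
            "presence": {k: list(v) for k, v in truth.presence_coefs.items()},
            "abundance": {k: list(v) for k, v in truth.abundance_coefs.items()},
            "theta": truth.nb_dispersion, "ar1_rho": truth.ar1_rho,
        }, indent=1))
        return [sdir / "counts.csv", sdir / "true_params.json"]

    if stage == "simulate_adcp":
        block = dict(block or {})
        inst = block.pop("instrument", None)
        cfg = _cfg(ADCPSimConfig, block, seed=sseed)
        if inst:
            cfg.instrument = InstrumentConfig(**inst)
        ens, truth = generate_adcp_transect(cfg)
        io.write_ensembles(ens, sdir / "ensembles.csv")
        (sdir / "true_wake.json").write_text(json.dumps(asdict(truth), indent=1))
        return [sdir / "ensembles.csv", sdir / "true_wake.json"]

    if stage == "simulate_flow":
        cfg = _cfg(FlowFieldConfig, block)
        generate_flow_field(cfg)  # validates
        (sdir / "flow.json").write_text(json.dumps(asdict(cfg), indent=1))
        return [sdir / "flow.json"]

    if stage == "detect":
        block = dict(block or {})
        seq = io.read_frames(out_dir / "simulate_video" / "frames")
        dets = detect_sequence(seq.frames, **block)
        io.write_detections(dets, sdir / "detections.csv")
        return [sdir / "detections.csv"]

    if stage == "classify":
        # train a BoF model on generator chips matching the scene appearance,
        # then label every detection's chip as tern or foam
        block = dict(block or {})
        seq = io.read_frames(out_dir / "simulate_video" / "frames")
        dets = io.read_detections(out_dir / "detect" / "detections.csv")
        chip_side = block.pop("chip_side", 32)
        n_train = block.pop("n_train_per_class", 150)
        k = block.pop("k", 100)
        chips, labels = generate_chip_dataset(n_train, chip_side=chip_side,
                                              seed=sseed)
        descs = [compute_descriptors(c) for c in chips]
        vocab = build_vocabulary(descs, k=k, seed=sseed)
        model = train_classifier([encode(d, vocab) for d in descs],
                                 labels, vocab, seed=sseed)
        from .bof_classifier import save_model
        save_model(model, sdir / "bof_model.npz")
        rows = []
        for frame_dets in dets:
            for j, d in enumerate(frame_dets):
                chip = extract_chip(seq.frames[d.frame], d, chip_side)
                label = int(classify_chips(model, [chip.pixels])[0])
                rows.append((d.frame, j, label))
        pd.DataFrame(rows, columns=["frame", "det_index", "label"]) \
            .to_csv(sdir / "classes.csv", index=False)
        return [sdir / "classes.csv", sdir / "bof_model.npz"]

    if stage == "track":
        block = dict(block or {})
        seq_meta = json.loads(
            (out_dir / "simulate_video" / "frames" / "metadata.json").read_text())
        dets = io.read_detections(out_dir / "detect" / "detections.csv")
        classes_path = out_dir / "classify" / "classes.csv"
        if classes_path.exists():
            # tern-labelled detections only enter the tracker
            cls = pd.read_csv(classes_path)
            tern = {(int(r.frame), int(r.det_index))
                    for r in cls.itertuples() if r.label == 1}
            dets = [[d for j, d in enumerate(fd) if (k, j) in tern]
                    for k, fd in enumerate(dets)]
        tcfg = TrackerConfig(**block.pop("tracker", {}))
        tracks = compile_tracks(dets, fps=seq_meta["fps"],
                                scale=seq_meta["ground_sample_distance"],
                                config=tcfg)
        tracks = filter_tracks_by_duration(
            tracks, block.pop("min_duration", 2.0))
        io.write_tracks(tracks, sdir / "tracks.csv")
        metrics = []
        for tr in tracks:
            m = trajectory_metrics(tr)
            metrics.append({"track_id": tr.id, "duration_s": m.duration,
                            "path_length_m": m.path_length,
                            "sinuosity": (None if np.isinf(m.sinuosity)
                                          else m.sinuosity),
                            "mean_speed_m_s": m.mean_speed})
        (sdir / "metrics.json").write_text(json.dumps(metrics, indent=1))
        return [sdir / "tracks.csv", sdir / "metrics.json"]

    if stage == "adcp":
        block = dict(block or {})
        inst = InstrumentConfig(**block.pop("instrument", {}))
        ens = io.read_ensembles(out_dir / "simulate_adcp" / "ensembles.csv")
        section = grid_section(ens, inst, y_bin=block.pop("y_bin", 5.0))
        io.write_section(section, sdir)
        extent = wake_deficit_extent(section)
        (sdir / "wake_metrics.json").write_text(json.dumps({
            "deficit_extent_m": extent,
            "absorption_model": "Francois-Garrison (1982), pH 8",
            "noise_floor": ("configured" if inst.noise_floor is not None
                            else "per-beam profile minimum"),
        }, indent=1))
        return [sdir / "section.csv", sdir / "wake_metrics.json"]

    if stage == "hurdle":
        block = dict(block or {})
        df = pd.read_csv(out_dir / "simulate_counts" / "counts.csv")
        fit = fit_hurdle(df, **block)
        tide_grid = np.linspace(0, 12.4, 50, endpoint=False)
        preds = []
        for site in fit.presence.info.sites:
            p = expected_count(fit, site, tide_grid)
            p.insert(0, "site", site)
            preds.append(p)
        pd.concat(preds).to_csv(sdir / "predictions.csv", index=False)
        tests = [term_f_test(fit.presence, "site")] + [
            term_f_test(fit.presence, f"s(tide):{s}")
            for s in fit.presence.info.sites]
        pd.DataFrame([{"part": "presence", "term": t.term, "F": t.F,
                       "df_num": t.df_num, "df_den": t.df_den, "p": round(t.p, 3)}
                      for t in tests]).to_csv(sdir / "term_tests.csv", index=False)
        (sdir / "fit_summary.json").write_text(json.dumps({
            "presence": {"lambda": fit.presence.lam, "edf": fit.presence.edf,
                         "ar1_rho": fit.presence.ar1_rho},
            "abundance": {"lambda": fit.abundance.lam, "theta": fit.abundance.theta,
                          "edf": fit.abundance.edf,
                          "ar1_rho": fit.abundance.ar1_rho},
        }, indent=1))
        return [sdir / "predictions.csv", sdir / "term_tests.csv",
                sdir / "fit_summary.json"]

    if stage == "transit":
        block = dict(block or {})
        flow_cfg = FlowFieldConfig(
            **json.loads((out_dir / "simulate_flow" / "flow.json").read_text()))
        flow = generate_flow_field(flow_cfg)
        sched = ReleaseSchedule(**block.pop("schedule", {}))
        target_x = block.pop("target_x", 2100.0)
        total_time = block.pop("total_time_s", 3600.0 * 3)
        ens = run_release(sched, flow, target_x, total_time, seed=sseed,
                          dt=block.pop("dt", 5.0))
        summary = transit_summary(ens)
        (sdir / "transit_summary.json").write_text(json.dumps(summary, indent=1))
        pd.DataFrame({
            "release_s": ens.release_time, "arrival_s": ens.arrival_time,
            "status": ens.status,
        }).to_csv(sdir / "particles.csv", index=False)
        return [sdir / "transit_summary.json", sdir / "particles.csv"]

    raise ValueError(f"unknown stage {stage!r}")
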