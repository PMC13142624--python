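"""End-to-end pipeline: tracking, reconstruction, profiles, and the file queue.

One worker per tubule with no shared mutable state, so a parallel run yields
per-track results identical to a serial run.  Flagged tracks are written to an
append-only JSON-lines queue; a re-run picks up corrections from a JSON-lines
corrections file, resumes those tracks, and leaves finished tracks untouched.
"""

from __future__ import annotations

import json
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .morphometry import morphometric_profiles
from .reconstruct import interpolate_cross_sections, save_straightened_hdf5, straighten
from .segmentation import SegmentationModelSpec
from .tracking import (
    CenterlineNode,
    FlagQueueEntry,
    Track,
    TrackingConfig,
    apply_correction,
    resume_track,
    track_tubule,
)
from .volume_io import load_volume

__all__ = ["PipelineConfig", "run_pipeline", "track_to_json", "track_from_json"]


@dataclass
class PipelineConfig:
    volume_path: str
    channel: str = "raw"
    level: int = 0
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    models: list[SegmentationModelSpec] = field(
        default_factory=lambda: [SegmentationModelSpec("default")]
    )
    out_dir: str = "tubetrace_out"
    workers: int = 1
    straighten_interval_um: float = 10.0
    cytometry_window_um: float = 20.0
    reconstruct: bool = True
    do_straighten: bool = False

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError("worker count must be >= 1")
        if not Path(self.volume_path).exists():
            raise FileNotFoundError(f"volume path does not exist: {self.volume_path}")


def track_to_json(track: Track) -> dict:
    return {
        "track_id": track.track_id,
        "seed1": track.seed1.tolist(),
        "seed2": track.seed2.tolist(),
        "status": track.status,
        "model_index": track.model_index,
        "interventions": track.interventions,
        "flag": None
        if track.flag is None
        else {"node_index": track.flag.node_index, "reason": track.flag.reason},
        "nodes": [
            {
                "position_um": n.position_um.tolist(),
                "s_um": n.s_um,
                "diameter_um": n.diameter_um,
                "model_id": n.model_id,
                "flags": sorted(n.flags),
            }
            for n in track.nodes
        ],
    }


def track_from_json(data: dict) -> Track:
    track = Track(
        data["track_id"],
        np.asarray(data["seed1"], float),
        np.asarray(data["seed2"], float),
        status=data["status"],
        model_index=data.get("model_index", 0),
        interventions=data.get("interventions", []),
    )
    for n in data["nodes"]:
        track.nodes.append(
            CenterlineNode(
                np.asarray(n["position_um"], float),
                float(n["s_um"]),
                float(n["diameter_um"]),
                None,
                n["model_id"],
                set(n["flags"]),
            )
        )
    if data.get("flag"):
        track.flag = FlagQueueEntry(
            data["track_id"], data["flag"]["node_index"], data["flag"]["reason"]
        )
    return track


def _process_one(args) -> dict:
    """Worker: track one tubule and write its outputs (no shared state)."""
    config_dict, seed_rec, resume_json = args
    cfg: PipelineConfig = config_dict
    volume = load_volume(cfg.volume_path, cfg.level, cfg.channel)
    out = Path(cfg.out_dir)
    tid = str(seed_rec["id"])
    stop_points = [np.asarray(p, float) for p in seed_rec.get("stop_points", [])]
    if resume_json is not None:
        track = track_from_json(resume_json)
        track = resume_track(volume, track, cfg.tracking, cfg.models, stop_points=stop_points)
    else:
        track = track_tubule(
            volume,
            (np.asarray(seed_rec["seed1_zyx_um"], float), np.asarray(seed_rec["seed2_zyx_um"], float)),
            cfg.tracking,
            cfg.models,
            stop_points=stop_points,
            track_id=tid,
        )
    payload = track_to_json(track)
    (out / f"track_{tid}.json").write_text(json.dumps(payload, indent=1))
    masked = [n for n in track.nodes if n.mask is not None]
    if cfg.reconstruct and len(masked) >= 2:
        rec = interpolate_cross_sections(track, volume)
        np.savez_compressed(
            out / f"reconstruction_{tid}.npz",
            crop=rec.crop,
            offset_vox=rec.offset_vox,
            spacing=rec.spacing,
        )
    if cfg.do_straighten and track.length_um > cfg.straighten_interval_um:
        stack = straighten(volume, track, cfg.straighten_interval_um)
        save_straightened_hdf5(stack, out / f"straightened_{tid}.h5")
    if len(track.nodes) >= 4:
        morphometric_profiles(track).to_frame().to_csv(
            out / f"profile_{tid}.csv", index=False
        )
    return payload


def run_pipeline(config: PipelineConfig, seeds: list[dict] | str | Path) -> list[Track]:
    """Run tracking (and downstream outputs) for every seed record.

    ``seeds`` is a list of records ``{id, seed1_zyx_um, seed2_zyx_um,
    stop_points}`` or a path to a JSON-lines file of them.  Returns the
    tracks; unresolved flags are appended to ``flags.jsonl`` in the output
    directory.  Re-running resumes flagged tracks for which
    ``corrections.jsonl`` supplies points, and leaves finished tracks alone.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(seeds, (str, Path)):
        seeds = [json.loads(line) for line in Path(seeds).read_text().splitlines() if line.strip()]

    corrections: dict[str, dict] = {}
    corr_path = out / "corrections.jsonl"
    if corr_path.exists():
        for line in corr_path.read_text().splitlines():
            if line.strip():
                rec = json.loads(line)
                corrections[str(rec["track_id"])] = rec

    jobs = []
    finished: list[dict] = []
    volume_for_corrections = None
    for rec in seeds:
        tid = str(rec["id"])
        existing = out / f"track_{tid}.json"
        resume_json = None
        if existing.exists():
            prev = json.loads(existing.read_text())
            if prev["status"] != "flagged":
                finished.append(prev)
                continue
            corr = corrections.get(tid)
            if corr is None:
                finished.append(prev)  # still waiting for a correction
                continue
            track = track_from_json(prev)
            if volume_for_corrections is None:
                volume_for_corrections = load_volume(config.volume_path, config.level, config.channel)
            apply_correction(
                track, corr["points_zyx_um"], volume_for_corrections, resume=corr.get("resume", True)
            )
            resume_json = track_to_json(track)
        jobs.append((config, rec, resume_json))

    if config.workers > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            results = list(pool.map(_process_one, jobs))
    else:
        results = [_process_one(j) for j in jobs]

    all_payloads = finished + results
    flags = [p for p in all_payloads if p["status"] == "flagged"]
    with (out / "flags.jsonl").open("w") as f:
        for p in flags:
            f.write(json.dumps({"track_id": p["track_id"], **p["flag"]}) + "\n")
    return [track_from_json(p) for p in all_payloads]
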