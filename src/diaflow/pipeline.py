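"""End-to-end orchestration: cine loop in, kinematic curves out.

Stage order: read -> 3x3 mean filter -> threshold segmentation of frame 0
-> largest connected region -> random seeding (300 points) -> DBSCAN
filtering -> pyramidal LK tracking -> 15-group assignment -> displacement
and strain curves -> size-5 smoothing -> respiratory-cycle detection ->
drift correction -> per-cycle peak-to-peak summaries.

A run is a pure function of (input bytes, configuration, seed): one global
seed deterministically derives every stage-local seed, and the run report
records all parameters plus per-stage point counts, so the report alone
suffices to re-execute an identical run.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import kinematics, optical_flow, segmentation, video_io
from .config import PipelineConfig, validate_config
from .errors import ConfigError, InputError
from .kinematics import CycleAnnotation, KinematicCurves, PeakToPeak
from .segmentation import SeedPoints
from .video_io import FrameSequence

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """All artefacts of one pipeline run."""

    curves: KinematicCurves  # raw (unsmoothed) curves
    output_curves: KinematicCurves  # smoothed / drift-corrected, as written to CSV
    cycles: CycleAnnotation
    seeds: SeedPoints
    tracked: optical_flow.TrackedPoints
    peak_to_peak: dict[str, PeakToPeak]
    report: dict


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic stage-local seed below 2**31."""
    tag = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence([int(global_seed), tag])
    return int(ss.generate_state(1)[0] % (2**31))


def load_input(config: PipelineConfig) -> FrameSequence:
    """Read the configured input (DICOM file or image directory)."""
    path = config["input"]
    if path is None:
        raise ConfigError("no input path configured")
    p = Path(path)
    interval = config["frame_interval"]
    if p.is_dir():
        if interval is None:
            raise ConfigError("frame_interval is required for image-directory input")
        return video_io.read_image_directory(p, frame_interval=interval)
    seq = video_io.read_dicom_sequence(p, default_interval=interval)
    if interval is not None:
        seq.frame_interval = float(interval)
    return seq


def run_pipeline(
    config: PipelineConfig | dict | None = None,
    seq: FrameSequence | None = None,
) -> PipelineResult:
    """Execute the full tracking pipeline.

    ``seq`` may be passed directly (library use, phantoms); otherwise the
    configured input path is read.  Outputs are written to the configured
    output directory when one is set.
    """
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    if seq is None:
        seq = load_input(config)

    report: dict = {"config": config.to_dict(), "source_id": seq.source_id,
                    "n_frames": seq.n_frames, "frame_interval_s": seq.frame_interval}

    # --- segmentation of frame 0
    manual_T = config["threshold.value"] if config["threshold.mode"] == "manual" else None
    mask = segmentation.segment_first_frame(seq.frames[0], manual_threshold=manual_T)
    report["threshold_used"] = mask.threshold_used
    report["mask_white_pixels"] = mask.n_white
    report["mask_bbox"] = list(mask.bbox)

    # --- seeding + density filtering
    seed_seed = config["seed_points.seed"]
    if seed_seed is None:
        seed_seed = derive_seed(config["seed"], "seed_points")
    seeds = segmentation.seed_random_points(mask, n=config["seed_points.n"], seed=seed_seed)
    seeds = segmentation.dbscan_filter(
        seeds,
        eps=config["dbscan.eps"],
        min_pts=config["dbscan.min_pts"],
        keep_all_clusters=config["dbscan.keep_all_clusters"],
    )
    report["points_seeded"] = len(seeds.coords)
    report["points_kept_after_dbscan"] = seeds.n_kept

    # --- tracking + grouping
    tracked = optical_flow.track_sequence(
        seq,
        seeds,
        m=config["lk.window"],
        pyramid_levels=config["lk.pyramid_levels"],
        iterations=config["lk.iterations"],
        min_eig_floor=config["lk.min_eig_floor"],
        max_condition=config["lk.max_condition"],
    )
    tracked = optical_flow.assign_groups(tracked, k=config["groups.k"])
    report["points_valid_final_frame"] = int(tracked.valid_mask[-1].sum())

    # --- curves
    curves = kinematics.displacement_curves(tracked, seq.frame_interval)
    centroids = optical_flow.group_centroids(tracked)
    curves.length, curves.gs = kinematics.strain_curve(centroids)

    kernel = config["smooth.kernel"]

    def smooth(series: np.ndarray, cumulative: bool = False) -> np.ndarray:
        # odd reflection keeps cumulative-type curves exactly zero at t=0
        boundary = "reflect_odd" if cumulative else "replicate"
        return kinematics.smooth_curve(series, kernel_size=kernel, boundary=boundary)

    smoothed = {
        "interframe_h": smooth(curves.interframe_h),
        "interframe_v": smooth(curves.interframe_v),
        "cumulative_h": smooth(curves.cumulative_h, cumulative=True),
        "cumulative_v": smooth(curves.cumulative_v, cumulative=True),
        "gs": smooth(curves.gs, cumulative=True),
    }

    # --- cycles + drift correction
    cycles = kinematics.detect_cycles(
        smoothed[config["cycles.curve"]],
        seq.frame_interval,
        min_prominence=config["cycles.min_prominence"],
        source_curve=config["cycles.curve"],
    )
    report["period_T_s"] = cycles.period_T
    report["n_peaks"] = len(cycles.peaks)
    report["n_troughs"] = len(cycles.troughs)

    corrected = dict(smoothed)
    if config["drift.enabled"]:
        for name in ("cumulative_h", "cumulative_v", "gs"):
            corrected[name] = kinematics.drift_correct(
                smoothed[name], cycles.period_T, seq.frame_interval
            )

    output_curves = KinematicCurves(
        time=curves.time,
        interframe_h=corrected["interframe_h"],
        interframe_v=corrected["interframe_v"],
        cumulative_h=corrected["cumulative_h"],
        cumulative_v=corrected["cumulative_v"],
        length=curves.length,
        gs=corrected["gs"],
    )

    # --- per-cycle peak-to-peak summaries
    p2p = {}
    for name in ("interframe_h", "interframe_v", "cumulative_h", "cumulative_v", "gs"):
        try:
            p2p[name] = kinematics.peak_to_peak(corrected[name], cycles)
        except kinematics.CycleError:
            logger.warning("no complete cycle for %s peak-to-peak", name)
    report["peak_to_peak"] = {
        name: {"mean": v.mean, "sd": v.sd, "per_cycle": v.values.tolist()}
        for name, v in p2p.items()
    }

    # --- outputs
    out_dir = config["out"]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        video_io.write_curves(
            output_curves, cycles, out / "curves.csv",
            pixel_spacing=seq.pixel_spacing, config=config.to_dict(),
        )
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    return PipelineResult(
        curves=curves,
        output_curves=output_curves,
        cycles=cycles,
        seeds=seeds,
        tracked=tracked,
        peak_to_peak=p2p,
        report=report,
    )
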