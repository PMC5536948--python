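"""End-to-end analysis pipeline: movie -> tracks -> kymographs -> scores.

The pipeline either loads a movie (one multi-page TIFF per channel) or
simulates one, then segments and tracks cells on the reference channel,
builds a membrane kymograph per mother cell on the signal channel,
computes per-cell timelines and polarity scores, optionally quantifies
puncta colocalization, and writes CSV/JSON outputs plus a provenance
record.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .config import CellScript, RecruitmentKinetics, SimConfig
from .kymograph import Kymograph, build_kymograph, map_point_to_arc
from .metrics import (
    CellTimeline,
    bud_target_angle,
    detect_appearance,
    on_target,
    polarization_efficiency_deg,
    population_appearance,
    presence_mask,
    score_polarized,
    whi5_exit_time,
)
from .movie import Movie
from .simulate import GroundTruth, simulate_movie
from .targets import TargetSchedule, read_targets
from .tracking import filter_mother_cells, segment_frame, track_cells

logger = logging.getLogger(__name__)


class DetectorParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    k: float = Field(3.0, gt=0, description="background sigmas above mean")
    m: int = Field(3, ge=1, description="consecutive frames required")
    halfwidth: int = Field(5, ge=1, description="arc-window half width, samples")


class SimulateBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sim: SimConfig = Field(default_factory=SimConfig)
    scripts: list[CellScript] = Field(default_factory=list)
    kinetics: RecruitmentKinetics = Field(default_factory=RecruitmentKinetics)


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    simulate: Optional[SimulateBlock] = None
    movie_paths: Optional[dict[str, str]] = None
    pixel_size: float = 0.162
    frame_interval: float = 30.0
    targets_csv: Optional[str] = None
    out_dir: str = "polarity_scope_out"
    signal_channel: str = "biosensor"
    reference_channel: str = "reference"
    detector: DetectorParams = Field(default_factory=DetectorParams)
    run_colocalization: bool = False
    coloc_channels: tuple[str, str] = ("bem1", "cdc24")
    coloc_max_dist_px: float = 2.0
    early_bud_window_s: float = 1200.0
    seed: int = 0
    log_level: str = "INFO"


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:16]


def _match_schedule_cell(track, schedule: TargetSchedule) -> Optional[object]:
    """Schedule cell_id whose mean target position is nearest this track."""
    best, best_d = None, np.inf
    c = track.mother_centroid()
    for cid in schedule.cell_ids:
        df = schedule.for_cell(cid)
        d = np.hypot(df["x_px"].mean() - c[0], df["y_px"].mean() - c[1])
        if d < best_d:
            best, best_d = cid, d
    if best is not None and best_d < 40:
        return best
    return None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the report dict.

    Outputs written under ``out_dir``: ``cells.csv`` (one row per cell
    timeline), ``kinetics.csv`` (binned appearance curve),
    ``colocalization.csv`` (if enabled), ``kymographs/*.tif``,
    ``ground_truth.json`` (simulations only) and ``report.json``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "kymographs").mkdir(exist_ok=True)

    truth: Optional[GroundTruth] = None
    if config.simulate is not None:
        block = config.simulate
        sim_cfg = block.sim.model_copy(update={"rng_seed": config.seed})
        if config.targets_csv:
            schedule = read_targets(config.targets_csv)
        else:
            schedule = TargetSchedule.empty()
        movie, truth = simulate_movie(sim_cfg, block.scripts, schedule, block.kinetics)
        truth.save_json(out / "ground_truth.json")
        movie.save(out / "movie")
    elif config.movie_paths:
        for role, p in config.movie_paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"movie channel {role!r}: no such file {p}")
        movie = Movie.load(
            config.movie_paths,
            pixel_size=config.pixel_size,
            frame_interval=config.frame_interval,
        )
        schedule = read_targets(config.targets_csv) if config.targets_csv else TargetSchedule.empty()
    else:
        raise ValueError("config must provide either a simulate block or movie_paths")

    ref = movie.channel(config.reference_channel)
    frame_polys = [segment_frame(ref[i]) for i in range(movie.n_frames)]
    tracks = track_cells(frame_polys, image_shape=movie.shape)
    mothers = filter_mother_cells(
        tracks, movie.frame_interval, early_bud_window_s=config.early_bud_window_s
    )

    signal = movie.channel(config.signal_channel)
    det = config.detector
    timelines: list[CellTimeline] = []
    kymos: dict[int, Kymograph] = {}
    for tr in mothers:
        sched_id = _match_schedule_cell(tr, schedule)
        target_points = {}
        if sched_id is not None:
            for f in tr.frames:
                seg = schedule.active_segment(sched_id, f * movie.frame_interval)
                if seg is not None:
                    target_points[f] = (seg.x, seg.y)
        kym = build_kymograph(
            signal,
            tr,
            frame_interval=movie.frame_interval,
            target_points=target_points or None,
        )
        kymos[tr.cell_id] = kym
        tl = CellTimeline(cell_id=tr.cell_id)
        f_bud = tr.bud_emergence_frame()
        if f_bud is not None:
            tl.bud_emergence_time = f_bud * movie.frame_interval
        if "whi5" in movie.channels:
            tl.whi5_exit_time = whi5_exit_time(
                movie.channel("whi5"), tr, frame_interval=movie.frame_interval
            )
        # appearance at the target site (arc of the median target annotation);
        # background estimated from pre-illumination frames when possible
        tgt_arcs = [a for _, a, lab in kym.annotations if lab == "target"]
        if tgt_arcs:
            arc = float(np.median(tgt_arcs))
            baseline = None
            if sched_id is not None and len(schedule.pulse_times(sched_id)):
                first_pulse = schedule.pulse_times(sched_id)[0]
                quiet = [
                    i for i, f in enumerate(tr.frames)
                    if f * movie.frame_interval < first_pulse
                ]
                if len(quiet) >= 2:
                    baseline = quiet
            row = detect_appearance(
                kym, arc, halfwidth=det.halfwidth, k=det.k, m=det.m,
                baseline_rows=baseline,
            )
            tl.appearance_times[config.signal_channel] = (
                None if row is None else tr.frames[row] * movie.frame_interval
            )
            tl.polarized = score_polarized(
                presence_mask(
                    kym, arc, halfwidth=det.halfwidth, k=det.k, baseline_rows=baseline
                ),
                movie.frame_interval,
            )
        if f_bud is not None and sched_id is not None:
            try:
                theta = bud_target_angle(
                    tr, schedule, sched_id, frame_interval=movie.frame_interval
                )
                tl.theta_deg = theta
                tl.polarization_efficiency = polarization_efficiency_deg(theta)
                tl.on_target = on_target(theta)
            except ValueError as e:
                tl.excluded_reason = str(e)
                logger.info("cell %d excluded from PE: %s", tr.cell_id, e)
        timelines.append(tl)
        tifffile.imwrite(
            out / "kymographs" / f"cell_{tr.cell_id}.tif",
            kym.matrix.astype(np.float32),
        )

    cells_df = pd.DataFrame([tl.to_row() for tl in timelines])
    cells_df.to_csv(out / "cells.csv", index=False)

    rel = [
        (tl.appearance_times.get(config.signal_channel) - tl.bud_emergence_time) / 60.0
        if tl.bud_emergence_time is not None
        and tl.appearance_times.get(config.signal_channel) is not None
        else None
        for tl in timelines
    ]
    if any(r is not None for r in rel):
        kin = population_appearance(rel)
        pd.DataFrame(
            {
                "bin_mid_min": kin.bin_mid_min,
                "fraction": kin.fraction,
                "n_appeared": kin.n_appeared,
                "n_total": kin.n_total,
            }
        ).to_csv(out / "kinetics.csv", index=False)

    if config.run_colocalization:
        from .colocalization import colocalization_fraction, detect_puncta, stage_stratified_summary
        from .tracking import classify_stage

        ch_a, ch_b = config.coloc_channels
        records = []
        for tr in mothers:
            f = tr.frames[0]
            stage = classify_stage(
                tr, f, movie.pixel_size, fluor_image=movie.channel(ch_a)[f]
            )
            sa = detect_puncta(movie.channel(ch_a)[f], tr, f, channel=ch_a)
            sb = detect_puncta(movie.channel(ch_b)[f], tr, f, channel=ch_b)
            if len(sa) and len(sb):
                fa, fb, _ = colocalization_fraction(sa, sb, config.coloc_max_dist_px)
                records.append({"stage": stage, "pair": f"{ch_a}|{ch_b}", "fraction": fa})
                records.append({"stage": stage, "pair": f"{ch_b}|{ch_a}", "fraction": fb})
        stage_stratified_summary(records).to_csv(out / "colocalization.csv", index=False)

    pe_scores = [
        tl.polarization_efficiency for tl in timelines if tl.polarization_efficiency is not None
    ]
    report = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_tracks": len(tracks),
        "n_mothers": len(mothers),
        "n_scored": len(pe_scores),
        "population_pe": float(np.mean(pe_scores)) if pe_scores else None,
        "outputs": sorted(
            {p.name for p in out.iterdir() if p.is_file()} | {"report.json"}
        ),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
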