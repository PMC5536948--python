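"""Synthetic yeast time-lapse movies with ground truth.

The simulator renders mother cells as circles with a Gaussian-profile
membrane annulus, growing tangent-circle buds, light-triggered cortical
recruitment following the optogenetic LOVpep/ePDZ kinetics (fast linear
rise, exponential dark-state decay with an 80 s half-time), scripted
polarity-protein accumulation timed relative to bud emergence, Whi5
nuclear exit, cortical puncta with controllable pairwise colocalization,
and a Poisson + Gaussian camera-noise model.  Everything the renderer
does is recorded in a :class:`GroundTruth` sidecar so downstream stages
can be tested quantitatively without any real microscopy data.

Fluorescence follows the script, not biochemistry: there is no
reaction-diffusion model here, only a faithful raster of prescribed
events.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .config import CellScript, PunctumSpec, RecruitmentKinetics, SimConfig
from .targets import TargetSchedule

LN2 = math.log(2.0)

#: Which scripted event provides the accumulation onset for each channel.
CHANNEL_ONSET_EVENT = {
    "biosensor": "biosensor_onset",
    "bem1": "bem1_onset",
    "cdc24": "bem1_onset",
}


# ---------------------------------------------------------------------
# Recruitment kinetics
# ---------------------------------------------------------------------
def _pulse_kernel(dt_since_pulse: np.ndarray, kinetics: RecruitmentKinetics) -> np.ndarray:
    """Bound signal contributed by a single pulse, peak-normalized to 1.

    Linear rise over ``on_time`` followed by exponential dark-state decay
    ``exp(-ln2 * t / dark_half_time)`` from the peak.
    """
    t = np.asarray(dt_since_pulse, dtype=float)
    out = np.zeros_like(t)
    on = kinetics.on_time
    rising = (t >= 0) & (t < on)
    if on > 0:
        out[rising] = t[rising] / on
    decaying = t >= on
    out[decaying] = np.exp(-LN2 * (t[decaying] - on) / kinetics.dark_half_time)
    return out


def simulate_recruitment_trace(
    kinetics: RecruitmentKinetics,
    pulse_times: Sequence[float],
    horizon: float,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Bound-signal time series for a pulse train.

    Pulses superpose linearly; each contributes a unit-peak rise-and-decay
    kernel, so the trace is in units of the single-pulse plateau.  Between
    pulses the signal decays by ``exp(-ln2 * Δt / dark_half_time)``.

    Returns
    -------
    (times, trace) : two 1-D arrays covering ``0 .. horizon`` at step ``dt``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if horizon < 0:
        raise ValueError(f"horizon must be non-negative, got {horizon}")
    pulse_times = np.sort(np.asarray(list(pulse_times), dtype=float))
    times = np.arange(0.0, horizon + dt / 2, dt)
    trace = np.zeros_like(times)
    for tp in pulse_times:
        trace += _pulse_kernel(times - tp, kinetics)
    return times, trace


def fit_decay_half_time(times: np.ndarray, trace: np.ndarray) -> float:
    """Fit ``A * exp(-ln2 * t / t_half)`` to a decaying trace; return t_half (s).

    A log-linear least-squares fit; all trace values must be positive.
    """
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if np.any(trace <= 0):
        raise ValueError("decay fit requires strictly positive trace values")
    slope, _ = np.polyfit(times, np.log(trace), 1)
    if slope >= 0:
        raise ValueError("trace is not decaying; cannot fit a half-time")
    return LN2 / -slope


# ---------------------------------------------------------------------
# Puncta placement
# ---------------------------------------------------------------------
def plant_puncta(
    script: CellScript,
    colocal_fraction: float,
    rng: np.random.Generator,
    *,
    channel_a: str = "bem1",
    channel_b: str = "cdc24",
    n_a: int = 20,
    colocal_dist_px: float = 2.0,
    pixel_size: float = 0.162,
    intensity: float = 200.0,
) -> list[PunctumSpec]:
    """Script cortical puncta for a channel pair with a known overlap.

    Exactly ``round(colocal_fraction * n_a)`` A-channel puncta receive a
    B-channel partner within ``colocal_dist_px`` (chord distance on the
    membrane); every other A punctum has no B punctum within twice that
    distance.  Puncta are spread around the perimeter with a small angular
    jitter, keeping neighbours far enough apart that partnerships are
    unambiguous.
    """
    if not 0.0 <= colocal_fraction <= 1.0:
        raise ValueError(f"colocal_fraction must be in [0, 1], got {colocal_fraction}")
    if n_a < 1:
        raise ValueError("n_a must be >= 1")
    r_px = script.radius / pixel_size
    pair_sep_deg = math.degrees(2.0 * colocal_dist_px / r_px)  # exclusion diameter
    spacing = 360.0 / n_a
    if spacing < 1.8 * pair_sep_deg:
        raise ValueError(
            f"{n_a} puncta on a radius-{script.radius} µm cell are too dense for a "
            f"{colocal_dist_px} px colocalization criterion"
        )
    jitter = min(1.0, 0.1 * spacing)
    n_pairs = round(colocal_fraction * n_a)
    paired = rng.choice(n_a, size=n_pairs, replace=False)
    partner_offset_deg = math.degrees(0.5 * colocal_dist_px / r_px)

    puncta: list[PunctumSpec] = []
    for i in range(n_a):
        angle = (i * spacing + rng.uniform(-jitter, jitter)) % 360.0
        is_paired = i in paired
        puncta.append(
            PunctumSpec(
                channel=channel_a,
                angle_deg=angle,
                intensity=intensity,
                partner=channel_b if is_paired else None,
            )
        )
        if is_paired:
            puncta.append(
                PunctumSpec(
                    channel=channel_b,
                    angle_deg=(angle + partner_offset_deg) % 360.0,
                    intensity=intensity,
                    partner=channel_a,
                )
            )
    return puncta


# ---------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------
@dataclass
class CellTruth:
    """Everything the renderer did for one cell."""

    cell_id: int
    script: dict
    event_times: dict[str, Optional[float]]
    outlines: list[list[list[float]]]  # per frame: [[x, y], ...]
    bud_outlines: dict[int, list[list[float]]] = field(default_factory=dict)
    target_angles_deg: list[Optional[float]] = field(default_factory=list)
    colocal_fractions: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "script": self.script,
            "event_times": self.event_times,
            "outlines": self.outlines,
            "bud_outlines": {str(k): v for k, v in self.bud_outlines.items()},
            "target_angles_deg": self.target_angles_deg,
            "colocal_fractions": self.colocal_fractions,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellTruth":
        return cls(
            cell_id=d["cell_id"],
            script=d["script"],
            event_times=d["event_times"],
            outlines=d["outlines"],
            bud_outlines={int(k): v for k, v in d["bud_outlines"].items()},
            target_angles_deg=d["target_angles_deg"],
            colocal_fractions=d["colocal_fractions"],
        )

    def outline_array(self, frame: int) -> np.ndarray:
        return np.asarray(self.outlines[frame], dtype=float)


@dataclass
class GroundTruth:
    """Simulation sidecar: one record per cell plus global calibration."""

    cells: list[CellTruth] = field(default_factory=list)
    rng_seed: int = 0
    pixel_size: float = 0.162
    frame_interval: float = 30.0

    def to_dict(self) -> dict:
        return {
            "rng_seed": self.rng_seed,
            "pixel_size": self.pixel_size,
            "frame_interval": self.frame_interval,
            "cells": [c.to_dict() for c in self.cells],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            cells=[CellTruth.from_dict(c) for c in d["cells"]],
            rng_seed=d["rng_seed"],
            pixel_size=d["pixel_size"],
            frame_interval=d["frame_interval"],
        )

    def save_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load_json(cls, path: Union[str, Path]) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------
def circle_polygon(center_px: tuple[float, float], radius_px: float, n: int = 64) -> np.ndarray:
    """CCW circle outline as an (n, 2) array of (x, y) vertices (open)."""
    ang = np.arange(n) * (2 * np.pi / n)
    return np.column_stack(
        [center_px[0] + radius_px * np.cos(ang), center_px[1] + radius_px * np.sin(ang)]
    )


def _wrapped_gaussian(dphi: np.ndarray, sigma: float) -> np.ndarray:
    """Angular Gaussian, wrap-aware; dphi in radians."""
    d = np.angle(np.exp(1j * dphi))
    return np.exp(-0.5 * (d / sigma) ** 2)


def _soft_disc(dist: np.ndarray, radius: float) -> np.ndarray:
    return np.clip(radius + 0.5 - dist, 0.0, 1.0)


def _bud_radius_um(script: CellScript, t: float) -> float:
    if script.bud_emergence_time is None or t < script.bud_emergence_time:
        return 0.0
    return script.bud_growth_rate * (t - script.bud_emergence_time)


def _bud_center_px(script: CellScript, t: float, pixel_size: float) -> tuple[float, float]:
    r_b = _bud_radius_um(script, t) / pixel_size
    r_m = script.radius / pixel_size
    th = math.radians(script.bud_site_angle)
    return (
        script.center[0] + (r_m + r_b) * math.cos(th),
        script.center[1] + (r_m + r_b) * math.sin(th),
    )


def _accum_ramp(dt: float, ramp_s: float = 120.0) -> float:
    """Scripted accumulation rises linearly to plateau over ``ramp_s``."""
    if dt < 0:
        return 0.0
    return min(dt / ramp_s, 1.0) if ramp_s > 0 else 1.0


# ---------------------------------------------------------------------
# Movie synthesis
# ---------------------------------------------------------------------
def _validate_scene(config: SimConfig, scripts: Sequence[CellScript], targets: TargetSchedule):
    n = config.field_size_px
    for i, s in enumerate(scripts):
        r_px = s.radius / config.pixel_size
        cx, cy = s.center
        if not (0 <= cx < n and 0 <= cy < n):
            raise ValueError(f"cell {i} centre {s.center} outside the field of view")
        if cx - r_px < -1 or cy - r_px < -1 or cx + r_px > n or cy + r_px > n:
            raise ValueError(f"cell {i} does not fit inside the {n}-px field")
    for i, a in enumerate(scripts):
        for j, b in enumerate(scripts[:i]):
            d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if d < (a.radius + b.radius) / config.pixel_size + 2:
                raise ValueError(f"cells {j} and {i} overlap (centre distance {d:.1f} px)")
    if len(targets):
        xs = targets.records["x_px"].to_numpy()
        ys = targets.records["y_px"].to_numpy()
        ts = targets.records["t_s"].to_numpy()
        if (xs < 0).any() or (xs >= n).any() or (ys < 0).any() or (ys >= n).any():
            raise ValueError("target position outside the field of view")
        if (ts < 0).any() or (ts > config.duration).any():
            raise ValueError("target time outside the movie duration")


def _truth_colocal_fractions(puncta: list[PunctumSpec]) -> dict[str, float]:
    channels = sorted({p.channel for p in puncta})
    out: dict[str, float] = {}
    for a in channels:
        for b in channels:
            if a == b:
                continue
            in_a = [p for p in puncta if p.channel == a]
            if in_a:
                out[f"{a}|{b}"] = sum(p.partner == b for p in in_a) / len(in_a)
    return out


def simulate_movie(
    config: SimConfig,
    scripts: Sequence[CellScript],
    targets: Optional[TargetSchedule] = None,
    kinetics: Optional[RecruitmentKinetics] = None,
) -> tuple["Movie", GroundTruth]:
    """Render a multi-channel movie from cell scripts and a pulse schedule.

    Target records are matched to cells by ``cell_id`` equal to the index
    of the script in ``scripts``.  Recruitment signal at a target rises
    within ``kinetics.on_time`` of each pulse and decays exponentially
    with the configured dark-state half-time after the last pulse; buds
    appear as growing tangent discs from their scripted emergence time.
    """
    from .movie import Movie

    targets = targets if targets is not None else TargetSchedule.empty()
    kinetics = kinetics or RecruitmentKinetics()
    _validate_scene(config, scripts, targets)

    n = config.field_size_px
    times = np.arange(config.n_frames) * config.frame_interval
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    rng = np.random.default_rng(config.rng_seed)

    # per-cell precomputation
    cells = []
    for i, s in enumerate(scripts):
        cx, cy = s.center
        dist = np.hypot(xx - cx, yy - cy)
        phi = np.arctan2(yy - cy, xx - cx)
        pulse_times = targets.pulse_times(i)
        _, trace = (
            simulate_recruitment_trace(kinetics, pulse_times, config.duration, config.frame_interval)
            if len(pulse_times)
            else (times, np.zeros_like(times))
        )
        cells.append({"script": s, "dist": dist, "phi": phi, "trace": trace, "pulses": pulse_times})

    r_px = lambda um: um / config.pixel_size
    sigma_m = r_px(config.membrane_thickness)
    stacks = {c: np.zeros((len(times), n, n), dtype=np.float64) for c in config.channels}

    truth_cells: list[CellTruth] = []
    for i, cell in enumerate(cells):
        s: CellScript = cell["script"]
        truth_cells.append(
            CellTruth(
                cell_id=i,
                script=s.model_dump(mode="json"),
                event_times={
                    "bud_emergence": s.bud_emergence_time,
                    **{
                        name: s.event_time(name)
                        for name in s.event_offsets
                        if s.event_time(name) is not None
                    },
                },
                outlines=[],
                colocal_fractions=_truth_colocal_fractions(s.puncta_script),
            )
        )

    for k, t in enumerate(times):
        for i, cell in enumerate(cells):
            s: CellScript = cell["script"]
            dist, phi = cell["dist"], cell["phi"]
            rm = r_px(s.radius)
            ring = np.exp(-0.5 * ((dist - rm) / sigma_m) ** 2)
            body = _soft_disc(dist, rm)

            rb = r_px(_bud_radius_um(s, t))
            bud_center = _bud_center_px(s, t, config.pixel_size) if rb > 0 else None
            if bud_center is not None:
                bdist = np.hypot(xx - bud_center[0], yy - bud_center[1])
                bud_body = _soft_disc(bdist, rb)
                bud_ring = np.exp(-0.5 * ((bdist - rb) / sigma_m) ** 2)
            else:
                bud_body = bud_ring = None

            # ground truth geometry
            truth = truth_cells[i]
            truth.outlines.append(circle_polygon(s.center, rm, 64).tolist())
            if bud_center is not None and rb > 0.5:
                truth.bud_outlines[k] = circle_polygon(bud_center, rb, 32).tolist()

            seg = targets.active_segment(i, t)
            if seg is not None:
                tgt_angle = math.degrees(math.atan2(seg.y - s.center[1], seg.x - s.center[0])) % 360
            else:
                tgt_angle = None
            truth.target_angles_deg.append(tgt_angle)

            sigma_phi = kinetics.pulse_footprint_sigma / s.radius  # radians

            for role in config.channels:
                img = stacks[role][k]
                if role == "reference":
                    img += 150.0 * body
                    if bud_body is not None:
                        img += 150.0 * bud_body
                elif role == "whi5":
                    img += 30.0 * body
                    t_exit = s.event_time("whi5_exit")
                    if t_exit is not None:
                        excess = 60.0 * np.clip((t_exit - t) / 180.0, 0.0, 1.0)
                    else:
                        excess = 60.0  # constitutively nuclear when never budding
                    ndist = dist  # nucleus rendered at the cell centre
                    img += excess * _soft_disc(ndist, r_px(s.nuclear_radius))
                else:
                    img += config.membrane_base_level * ring
                    if bud_ring is not None:
                        img += config.membrane_base_level * bud_ring
                    # light-triggered recruitment at the active target
                    amp = cell["trace"][k]
                    if amp > 0 and tgt_angle is not None:
                        img += (
                            config.recruit_peak_level
                            * amp
                            * ring
                            * _wrapped_gaussian(phi - math.radians(tgt_angle), sigma_phi)
                        )
                    # scripted accumulation at the future bud site
                    event = CHANNEL_ONSET_EVENT.get(role)
                    if event == "biosensor_onset" and s.responder and len(cell["pulses"]):
                        event = "biosensor_onset_recruited"
                    t_on = s.event_time(event) if event else None
                    if t_on is not None and t >= t_on:
                        img += (
                            0.6
                            * config.recruit_peak_level
                            * _accum_ramp(t - t_on)
                            * ring
                            * _wrapped_gaussian(phi - math.radians(s.bud_site_angle), sigma_phi)
                        )
                    # cortical puncta
                    for p in s.puncta_script:
                        if p.channel != role or not (p.birth_s <= t < p.death_s):
                            continue
                        px = s.center[0] + rm * math.cos(math.radians(p.angle_deg))
                        py = s.center[1] + rm * math.sin(math.radians(p.angle_deg))
                        pd2 = (xx - px) ** 2 + (yy - py) ** 2
                        img += p.intensity * np.exp(-0.5 * pd2 / 1.2**2)

    for role in config.channels:
        stacks[role] += config.ambient_level
        if config.noise.enabled:
            photons = rng.poisson(stacks[role] / config.noise.gain)
            read = rng.normal(0.0, config.noise.read_sd, size=stacks[role].shape)
            stacks[role] = config.noise.background + config.noise.gain * photons + read
        else:
            stacks[role] = config.noise.background + stacks[role]

    movie = Movie(
        channels={c: stacks[c].astype(np.float32) for c in config.channels},
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
    )
    truth = GroundTruth(
        cells=truth_cells,
        rng_seed=config.rng_seed,
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
    )
    return movie, truth
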