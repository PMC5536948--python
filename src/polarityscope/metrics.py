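"""Polarity statistics and scoring rules.

The central statistic is the polarization efficiency: for each cell, θ is
the angle between the site of bud emergence and the illumination target,
measured at the mother centroid, and the per-cell score is ``1 - 2θ/π``
(1 for budding at the target centre, -1 for budding diametrically
opposite).  The population value is the arithmetic mean with its
standard error.

Around it sit the event-scoring rules used throughout the analysis:
a bud is "on target" when θ < 45°; a cell is "polarized" when a cortical
accumulation persists for more than 15 min; a targeting move is
"Outcompeted" when the biosensor signal disappears from the old site and
appears at the new one within the hold window of the new target.  Manual
by-eye appearance calls are replaced by an explicit detector: the first
time the windowed membrane signal exceeds the background mean by k
standard deviations for m consecutive frames.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .kymograph import N_ARC_SAMPLES, Kymograph
from .targets import TargetSchedule
from .tracking import CellTrack

logger = logging.getLogger(__name__)

ON_TARGET_MAX_DEG = 45.0
POLARIZED_PERSISTENCE_MIN = 15.0


# ---------------------------------------------------------------------
# Polarization efficiency
# ---------------------------------------------------------------------
def polarization_efficiency(theta_rad: float) -> float:
    """Per-cell score ``1 - 2θ/π`` for θ in radians on [0, π]."""
    if not 0.0 <= theta_rad <= math.pi + 1e-12:
        raise ValueError(f"theta must be in [0, pi], got {theta_rad}")
    return 1.0 - 2.0 * theta_rad / math.pi


def polarization_efficiency_deg(theta_deg: float) -> float:
    """Per-cell score ``1 - θ/90`` for θ in degrees on [0, 180]."""
    return polarization_efficiency(math.radians(theta_deg))


def population_pe(scores: Sequence[float]) -> tuple[float, float]:
    """Population polarization efficiency: (mean, SEM)."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("no scores")
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return float(arr.mean()), sem


def on_target(theta_deg: float) -> bool:
    """Bud formed within 45° of the target (strict inequality)."""
    return theta_deg < ON_TARGET_MAX_DEG


def minimal_angle_deg(a_deg: float, b_deg: float) -> float:
    """Minimal angular difference between two directions, in [0, 180]."""
    d = abs((a_deg - b_deg) % 360.0)
    return min(d, 360.0 - d)


def bud_target_angle(
    track: CellTrack,
    schedule: TargetSchedule,
    cell_id=None,
    *,
    frame_interval: float = 30.0,
) -> float:
    """θ: minimal angle at the mother centroid between bud and target.

    Uses the target segment active at bud emergence (or the last segment
    before it).  Raises if the track has no detected bud or the schedule
    has no applicable segment — such cells are excluded from scoring.
    """
    cell_id = track.cell_id if cell_id is None else cell_id
    bud_angle = track.bud_angle_deg()
    if bud_angle is None:
        raise ValueError(f"cell {cell_id}: no bud detected; cannot score theta")
    f_bud = track.bud_emergence_frame()
    seg = schedule.active_segment(cell_id, f_bud * frame_interval)
    if seg is None:
        raise ValueError(f"cell {cell_id}: no target segment before bud emergence")
    c = track.mother_centroid()
    tgt_angle = math.degrees(math.atan2(seg.y - c[1], seg.x - c[0])) % 360.0
    return minimal_angle_deg(bud_angle, tgt_angle)


# ---------------------------------------------------------------------
# Appearance detection
# ---------------------------------------------------------------------
def detect_appearance(
    kymo: Kymograph,
    arc_center: float,
    *,
    halfwidth: int = 5,
    k: float = 3.0,
    m: int = 3,
    baseline_rows: Optional[Sequence[int]] = None,
    search_from_row: int = 0,
) -> Optional[int]:
    """Earliest row from which the windowed signal is persistently high.

    The window mean must exceed ``μ_bg + k σ_bg`` for at least ``m``
    consecutive rows; background statistics come from ``baseline_rows``
    (default: the first 5 rows).  Returns the row index, or None.
    """
    trace = kymo.window_trace(arc_center, halfwidth)
    if baseline_rows is None:
        baseline_rows = range(min(5, len(trace)))
    base = trace[list(baseline_rows)]
    base = base[np.isfinite(base)]
    if base.size < 2:
        raise ValueError("background not estimable: too few finite baseline rows")
    mu, sd = float(base.mean()), float(base.std(ddof=1))
    thresh = mu + k * max(sd, 1e-12)
    above = np.nan_to_num(trace, nan=-np.inf) > thresh
    run = 0
    for i in range(search_from_row, len(above)):
        run = run + 1 if above[i] else 0
        if run >= m:
            return i - m + 1
    return None


def presence_mask(
    kymo: Kymograph,
    arc_center: float,
    *,
    halfwidth: int = 5,
    k: float = 3.0,
    baseline_rows: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Boolean per-row signal presence in an arc window (no persistence)."""
    trace = kymo.window_trace(arc_center, halfwidth)
    if baseline_rows is None:
        baseline_rows = range(min(5, len(trace)))
    base = trace[list(baseline_rows)]
    base = base[np.isfinite(base)]
    if base.size < 2:
        raise ValueError("background not estimable")
    thresh = float(base.mean()) + k * max(float(base.std(ddof=1)), 1e-12)
    return np.nan_to_num(trace, nan=-np.inf) > thresh


def score_polarized(
    presence: Sequence[bool],
    frame_interval_s: float,
    persistence_min: float = POLARIZED_PERSISTENCE_MIN,
) -> bool:
    """Polarized iff an accumulation persists strictly longer than 15 min.

    A run of L consecutive positive frames spans ``(L - 1) *
    frame_interval`` seconds (first to last frame); gaps reset the run.
    """
    presence = np.asarray(presence, dtype=bool)
    best = run = 0
    for p in presence:
        run = run + 1 if p else 0
        best = max(best, run)
    duration_min = (best - 1) * frame_interval_s / 60.0 if best else 0.0
    return duration_min > persistence_min


# ---------------------------------------------------------------------
# Relative intensity (target vs 180° control)
# ---------------------------------------------------------------------
def relative_intensity(
    kymo: Kymograph,
    target_arc: float,
    mode: str,
    *,
    first_pulse_time: Optional[float] = None,
    bud_emergence_time: Optional[float] = None,
    halfwidth: int = 3,
    avoid_arcs: Sequence[float] = (),
    return_details: bool = False,
):
    """Target-site intensity normalized to a control site.

    ``mode='polarized'`` measures 10 min after the first illumination;
    ``mode='non-polarized'`` measures 10 min before bud emergence.  The
    control window sits 50 arc samples (180°) from the target unless that
    would overlap the bud site or another target, in which case it is
    shifted to the nearest clear position and flagged.
    """
    if mode == "polarized":
        if first_pulse_time is None:
            raise ValueError("polarized mode needs first_pulse_time")
        t = first_pulse_time + 600.0
    elif mode == "non-polarized":
        if bud_emergence_time is None:
            raise ValueError("non-polarized mode needs bud_emergence_time")
        t = bud_emergence_time - 600.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    row = kymo.row_at_time(t)

    control_arc = (target_arc + N_ARC_SAMPLES / 2) % N_ARC_SAMPLES
    shifted = False
    blocked = list(avoid_arcs)
    if kymo.bud_registered:
        blocked.append(0.0)

    def clear(arc: float) -> bool:
        return all(
            _arc_distance(arc, b) > 2 * halfwidth + 1 for b in blocked
        ) and _arc_distance(arc, target_arc) > 2 * halfwidth + 1

    if not clear(control_arc):
        for step in range(1, N_ARC_SAMPLES):
            for cand in (control_arc + step, control_arc - step):
                cand %= N_ARC_SAMPLES
                if clear(cand):
                    control_arc, shifted = cand, True
                    break
            if shifted:
                break
        logger.info("control window shifted to arc %.1f", control_arc)

    tgt = float(np.nanmean(kymo.matrix[row, kymo.arc_window(target_arc, halfwidth)]))
    ctl = float(np.nanmean(kymo.matrix[row, kymo.arc_window(control_arc, halfwidth)]))
    ratio = tgt / ctl
    if return_details:
        return ratio, {"row": row, "control_arc": control_arc, "control_shifted": shifted}
    return ratio


def _arc_distance(a: float, b: float) -> float:
    d = abs((a - b) % N_ARC_SAMPLES)
    return min(d, N_ARC_SAMPLES - d)


# ---------------------------------------------------------------------
# Whi5 nuclear exit
# ---------------------------------------------------------------------
def whi5_exit_time(
    whi5_stack: np.ndarray,
    track: CellTrack,
    *,
    frame_interval: float,
    nucleus_radius_px: float = 5.0,
    ratio_tol: float = 0.05,
) -> Optional[float]:
    """Time (s) at which nuclear Whi5 first equals the cytoplasmic level.

    The nucleus is taken as the brightest interior disc; exit is the
    first frame where the nuclear/cytoplasmic mean ratio drops to
    1 (within ``ratio_tol``).  Returns None if the ratio never falls,
    i.e. Whi5 stays nuclear.
    """
    from scipy.ndimage import gaussian_filter

    from .tracking import rasterize_polygon

    shape = whi5_stack.shape[1:]
    for i, f in enumerate(track.frames):
        interior = rasterize_polygon(track.polygons[i], shape)
        # erode away the membrane-adjacent rim
        from scipy.ndimage import binary_erosion

        interior = binary_erosion(interior, iterations=2)
        if interior.sum() < 10:
            continue
        img = whi5_stack[f].astype(float)
        sm = gaussian_filter(img, 1.0)
        sm_in = np.where(interior, sm, -np.inf)
        cy, cx = np.unravel_index(np.argmax(sm_in), shape)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        nuc = ((xx - cx) ** 2 + (yy - cy) ** 2 <= nucleus_radius_px**2) & interior
        cyto = interior & ~nuc
        if nuc.sum() < 5 or cyto.sum() < 10:
            continue
        ratio = img[nuc].mean() / img[cyto].mean()
        if ratio <= 1.0 + ratio_tol:
            return f * frame_interval
    return None


# ---------------------------------------------------------------------
# Population kinetics
# ---------------------------------------------------------------------
@dataclass
class PopulationKinetics:
    """Binned fraction-of-cells-with-signal curve.

    ``bin_mid_min`` are bin midpoints in minutes relative to the chosen
    reference event (bud emergence or Whi5 exit); ``fraction`` is the
    cumulative fraction of cells whose signal has appeared by that
    midpoint; ``n_appeared`` counts them.
    """

    bin_mid_min: np.ndarray
    fraction: np.ndarray
    n_appeared: np.ndarray
    n_total: int


def population_appearance(
    relative_times_min: Sequence[Optional[float]],
    bin_minutes: float = 10.0,
) -> PopulationKinetics:
    """Cumulative appearance curve from per-cell relative event times.

    ``relative_times_min`` are appearance times in minutes relative to
    the reference event (negative = before); None means never appeared
    (the cell still counts in the denominator).  Bins are half-open
    ``[mid - w/2, mid + w/2)`` with midpoints at multiples of the bin
    width, following the convention of plotting binned data at the
    middle time point.
    """
    times = [t for t in relative_times_min if t is not None]
    n_total = len(list(relative_times_min))
    if n_total == 0:
        raise ValueError("no cells supplied")
    if not times:
        raise ValueError("no cell has the reference event / an appearance time")
    w = float(bin_minutes)
    lo = math.floor(min(times) / w) * w
    hi = math.ceil(max(times) / w) * w
    mids = np.arange(lo, hi + w / 2, w)
    t_arr = np.asarray(times, dtype=float)
    n_appeared = np.array([(t_arr <= m).sum() for m in mids])
    return PopulationKinetics(
        bin_mid_min=mids,
        fraction=n_appeared / n_total,
        n_appeared=n_appeared,
        n_total=n_total,
    )


def half_population_time(kinetics: PopulationKinetics) -> float:
    """First bin midpoint at which at least half the cells show signal."""
    idx = np.nonzero(kinetics.fraction >= 0.5)[0]
    if idx.size == 0:
        raise ValueError("population never reaches 50%")
    return float(kinetics.bin_mid_min[idx[0]])


# ---------------------------------------------------------------------
# Competition and two-site scoring
# ---------------------------------------------------------------------
@dataclass
class TargetMove:
    """A relocation of the illumination target on the kymograph."""

    move_row: int
    old_arc: float
    new_arc: float
    hold_end_row: int  # last row during which the new target is maintained


def score_competition(
    kymo: Kymograph,
    moves: Sequence[TargetMove],
    *,
    halfwidth: int = 5,
    k: float = 3.0,
    m: int = 3,
    baseline_rows: Optional[Sequence[int]] = None,
) -> list[str]:
    """Score each target move as Outcompeted / Not Outcompeted / Indeterminate.

    A move is **Outcompeted** when the signal disappears from the old
    site (below threshold for >= m consecutive rows) and accumulates at
    the new site within the hold window.  It is **Not Outcompeted** when
    the old-site signal persists and the new site never accumulates.
    Mixed outcomes are flagged indeterminate and excluded from the
    two-class tally.  Moves held for fewer than 2 rows are excluded.
    """
    outcomes = []
    for mv in moves:
        if mv.hold_end_row - mv.move_row < 2:
            logger.info("move at row %d held <2 frames; excluded", mv.move_row)
            outcomes.append("Excluded")
            continue
        old = presence_mask(kymo, mv.old_arc, halfwidth=halfwidth, k=k, baseline_rows=baseline_rows)
        window = slice(mv.move_row, mv.hold_end_row + 1)
        old_w = old[window]
        # disappearance: a run of >= m consecutive absent rows in the hold window
        run = best = 0
        for p in ~old_w:
            run = run + 1 if p else 0
            best = max(best, run)
        old_disappeared = best >= m
        old_persisted = old_w.all()
        new_appear = detect_appearance(
            kymo,
            mv.new_arc,
            halfwidth=halfwidth,
            k=k,
            m=m,
            baseline_rows=baseline_rows,
            search_from_row=mv.move_row,
        )
        new_appeared = new_appear is not None and new_appear <= mv.hold_end_row - m + 1
        if old_disappeared and new_appeared:
            outcomes.append("Outcompeted")
        elif old_persisted and not new_appeared:
            outcomes.append("Not Outcompeted")
        else:
            outcomes.append("Indeterminate")
    return outcomes


def score_two_sites(
    kymo: Kymograph,
    arc_a: float,
    arc_b: float,
    *,
    halfwidth: int = 5,
    k: float = 3.0,
    baseline_rows: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Per-row state at two simultaneous target sites: none | one | both."""
    if _arc_distance(arc_a, arc_b) <= 2 * halfwidth:
        raise ValueError("the two target windows overlap")
    pa = presence_mask(kymo, arc_a, halfwidth=halfwidth, k=k, baseline_rows=baseline_rows)
    pb = presence_mask(kymo, arc_b, halfwidth=halfwidth, k=k, baseline_rows=baseline_rows)
    states = np.where(pa & pb, "both", np.where(pa | pb, "one", "none"))
    return states


def two_site_state_fractions(
    states_by_cell: Sequence[np.ndarray],
    times_by_cell: Sequence[np.ndarray],
    bin_minutes: float = 5.0,
) -> "pd.DataFrame":
    """Fraction of cells in each state versus time to bud emergence.

    Times are seconds relative to bud emergence; data are binned in
    half-open ``bin_minutes`` intervals labelled at midpoints.
    """
    import pandas as pd

    rows = []
    for states, times in zip(states_by_cell, times_by_cell):
        for s, t in zip(states, times):
            rows.append((t / 60.0, s))
    df = pd.DataFrame(rows, columns=["t_min", "state"])
    w = bin_minutes
    df["bin_mid"] = (np.floor(df["t_min"] / w + 0.5)) * w
    out = (
        df.pivot_table(index="bin_mid", columns="state", aggfunc="size", fill_value=0)
        .pipe(lambda d: d.div(d.sum(axis=1), axis=0))
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------
# Per-cell timeline
# ---------------------------------------------------------------------
@dataclass
class CellTimeline:
    """All per-cell event times and scores, on the movie clock (seconds)."""

    cell_id: int
    bud_emergence_time: Optional[float] = None
    whi5_exit_time: Optional[float] = None
    appearance_times: dict[str, Optional[float]] = field(default_factory=dict)
    target_move_times: list[float] = field(default_factory=list)
    theta_deg: Optional[float] = None
    polarization_efficiency: Optional[float] = None
    on_target: Optional[bool] = None
    polarized: Optional[bool] = None
    competition_outcomes: list[str] = field(default_factory=list)
    excluded_reason: Optional[str] = None

    def __post_init__(self) -> None:
        pe = self.polarization_efficiency
        if pe is not None and not -1.0 <= pe <= 1.0:
            raise ValueError(f"polarization efficiency {pe} outside [-1, 1]")

    def to_row(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "bud_emergence_s": self.bud_emergence_time,
            "whi5_exit_s": self.whi5_exit_time,
            **{f"appearance_{ch}_s": t for ch, t in self.appearance_times.items()},
            "theta_deg": self.theta_deg,
            "polarization_efficiency": self.polarization_efficiency,
            "on_target": self.on_target,
            "polarized": self.polarized,
            "competition": ";".join(self.competition_outcomes),
            "excluded_reason": self.excluded_reason,
        }
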