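"""Cell outline segmentation, tracking, bud detection and staging.

Segmentation is a smoothed global threshold (Otsu by default) followed by
marching-squares contour extraction with sub-pixel vertices.  Tracking
links polygons across frames by nearest-centroid matching under a
displacement gate.  A bud is detected either as a new small polygon whose
boundary comes within a few pixels of a mother's boundary, or — once the
bud fuses with the mother into a single connected component — as the part
of the merged outline that lies outside the mother's reference footprint.

Stage classification follows the conventions of the cell-cycle-stratified
analyses: a budded cell is "large-bud" only when the bud area strictly
exceeds 4.5 µm²; unbudded cells are split into early G1 (distinct cortical
puncta) and late G1 (a wide cortical band) when a fluorescence image is
available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import draw, measure
from skimage.filters import gaussian, threshold_otsu

logger = logging.getLogger(__name__)

LARGE_BUD_AREA_UM2 = 4.5


# ---------------------------------------------------------------------
# Polygon utilities
# ---------------------------------------------------------------------
def polygon_area(poly: np.ndarray) -> float:
    """Unsigned shoelace area of an (N, 2) polygon in px²."""
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_centroid(poly: np.ndarray) -> np.ndarray:
    """Area-weighted centroid of a closed polygon, (x, y) in px."""
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-9:
        return poly.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def ensure_ccw(poly: np.ndarray) -> np.ndarray:
    """Orient so the signed area is positive (counter-clockwise in the
    stated image coordinate convention: x rightward, y downward)."""
    x, y = poly[:, 0], poly[:, 1]
    signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return poly if signed >= 0 else poly[::-1].copy()


def rasterize_polygon(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the polygon interior on an image grid."""
    rr, cc = draw.polygon(poly[:, 1], poly[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------
def segment_frame(
    image: np.ndarray,
    *,
    sigma: float = 1.0,
    threshold: Optional[float] = None,
    min_area_px: float = 20.0,
) -> list[np.ndarray]:
    """Extract closed cell-body outlines from one frame.

    Returns one CCW polygon (sub-pixel vertices, (x, y) order) per
    connected component whose enclosed area exceeds ``min_area_px``.
    A blank frame (nothing above threshold) yields an empty list.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    smoothed = gaussian(image, sigma=sigma, preserve_range=True)
    if threshold is None:
        if smoothed.max() - smoothed.min() < 1e-12:
            return []
        threshold = threshold_otsu(smoothed)
        # Otsu on a frame with no foreground splits noise; reject if the
        # "foreground" is not meaningfully brighter than the background.
        fg, bg = smoothed[smoothed > threshold], smoothed[smoothed <= threshold]
        if fg.size == 0 or fg.mean() - bg.mean() < 3 * max(bg.std(), 1e-12):
            return []
    contours = measure.find_contours(smoothed, level=threshold)
    polys = []
    for c in contours:
        closed = np.allclose(c[0], c[-1])
        poly = c[:-1] if closed else c
        poly = np.column_stack([poly[:, 1], poly[:, 0]])  # rc -> xy
        if len(poly) >= 3 and polygon_area(poly) >= min_area_px:
            polys.append(ensure_ccw(poly))
    return polys


# ---------------------------------------------------------------------
# Tracking
# ---------------------------------------------------------------------
@dataclass
class CellTrack:
    """Per-frame geometry of one tracked mother cell.

    ``polygons[i]`` is the full tracked outline at ``frames[i]`` (which
    includes the bud once mother and bud merge into one component);
    ``bud_areas_px`` / ``bud_centroids`` are populated from the frame at
    which a bud is first detected.
    """

    cell_id: int
    frames: list[int] = field(default_factory=list)
    polygons: list[np.ndarray] = field(default_factory=list)
    centroids: list[np.ndarray] = field(default_factory=list)
    areas_px: list[float] = field(default_factory=list)
    bud_areas_px: dict[int, float] = field(default_factory=dict)
    bud_centroids: dict[int, np.ndarray] = field(default_factory=dict)
    bud_polygons: dict[int, np.ndarray] = field(default_factory=dict)
    is_daughter: bool = False
    truncated: bool = False

    @property
    def first_frame(self) -> int:
        return self.frames[0]

    def index_of(self, frame: int) -> int:
        try:
            return self.frames.index(frame)
        except ValueError:
            raise KeyError(f"track {self.cell_id} has no frame {frame}") from None

    def mother_centroid(self) -> np.ndarray:
        """Reference centroid: from the first frame, before any bud biases it."""
        return self.centroids[0]

    def bud_emergence_frame(self, min_area_px: float = 4.0) -> Optional[int]:
        for f in sorted(self.bud_areas_px):
            if self.bud_areas_px[f] >= min_area_px:
                return f
        return None

    def bud_angle_deg(self) -> Optional[float]:
        """Direction of the bud from the mother centroid, degrees in [0, 360)."""
        f = self.bud_emergence_frame()
        if f is None:
            return None
        # use a later frame if available: a bigger bud gives a stabler centroid
        fs = [g for g in sorted(self.bud_centroids) if g >= f]
        g = fs[min(len(fs) - 1, 3)]
        c = self.mother_centroid()
        b = self.bud_centroids[g]
        return float(math.degrees(math.atan2(b[1] - c[1], b[0] - c[0])) % 360.0)


def _boundary_distance(poly_a: np.ndarray, poly_b: np.ndarray) -> float:
    d = np.linalg.norm(poly_a[:, None, :] - poly_b[None, :, :], axis=2)
    return float(d.min())


def track_cells(
    frame_polygons: Sequence[Sequence[np.ndarray]],
    *,
    image_shape: Optional[tuple[int, int]] = None,
    max_displacement_px: float = 5.0,
    bud_attach_dist_px: float = 2.0,
    bud_min_area_px: float = 4.0,
) -> list[CellTrack]:
    """Link per-frame polygons into cell tracks with bud annotations.

    Matching is nearest-centroid within ``max_displacement_px``; ties
    (two candidates inside the gate) are broken by the smaller area
    change and logged.  A polygon smaller than the typical cell that
    appears within ``bud_attach_dist_px`` of an existing track's boundary
    is attached to that track as its bud; otherwise it starts a new track
    flagged as a daughter.  Once mother and bud merge into a single
    component, the bud is recovered as the part of the merged outline
    outside the mother's first-frame footprint.
    """
    if image_shape is None:
        hi = 0
        for polys in frame_polygons:
            for p in polys:
                hi = max(hi, int(np.ceil(p.max())) + 2)
        image_shape = (hi, hi)

    tracks: list[CellTrack] = []
    active: list[CellTrack] = []
    ref_masks: dict[int, np.ndarray] = {}  # cell_id -> dilated first-frame mask

    for f_idx, polys in enumerate(frame_polygons):
        cents = [polygon_centroid(p) for p in polys]
        areas = [polygon_area(p) for p in polys]
        unmatched = set(range(len(polys)))
        assigned: dict[int, int] = {}

        # match existing tracks to candidates
        for tr in active:
            last_c = tr.centroids[-1]
            last_a = tr.areas_px[-1]
            cands = [
                (np.linalg.norm(cents[j] - last_c), j)
                for j in unmatched
                if np.linalg.norm(cents[j] - last_c) <= max_displacement_px
            ]
            if not cands:
                continue
            cands.sort()
            if len(cands) > 1 and cands[1][0] - cands[0][0] < 1.0:
                # ambiguous: prefer the candidate with the smaller area change
                best = min(cands[:2], key=lambda c: abs(areas[c[1]] - last_a))
                logger.info(
                    "frame %d: ambiguous match for track %d resolved by area", f_idx, tr.cell_id
                )
                j = best[1]
            else:
                j = cands[0][1]
            assigned[tr.cell_id] = j
            unmatched.discard(j)

        for tr in active:
            if tr.cell_id in assigned:
                j = assigned[tr.cell_id]
                tr.frames.append(f_idx)
                tr.polygons.append(polys[j])
                tr.centroids.append(cents[j])
                tr.areas_px.append(areas[j])
            else:
                tr.truncated = True
                logger.info("frame %d: track %d lost (left field?)", f_idx, tr.cell_id)
        active = [tr for tr in active if tr.cell_id in assigned]

        # leftover polygons: buds of existing tracks, or new cells
        for j in sorted(unmatched):
            attached = False
            for tr in active:
                if _boundary_distance(polys[j], tr.polygons[-1]) <= bud_attach_dist_px and areas[
                    j
                ] < 0.8 * tr.areas_px[-1]:
                    if areas[j] >= bud_min_area_px:
                        tr.bud_areas_px[f_idx] = areas[j]
                        tr.bud_centroids[f_idx] = cents[j]
                        tr.bud_polygons[f_idx] = polys[j]
                    attached = True
                    break
            if not attached:
                new = CellTrack(cell_id=len(tracks), is_daughter=(f_idx > 0))
                new.frames.append(f_idx)
                new.polygons.append(polys[j])
                new.centroids.append(cents[j])
                new.areas_px.append(areas[j])
                tracks.append(new)
                active.append(new)
                ref_masks[new.cell_id] = ndi.binary_dilation(
                    rasterize_polygon(polys[j], image_shape), iterations=1
                )

        # merged mother+bud: residual of the outline beyond the reference mask
        for tr in active:
            if tr.frames[-1] != f_idx or f_idx in tr.bud_areas_px:
                continue
            mask_now = rasterize_polygon(tr.polygons[-1], image_shape)
            residual = mask_now & ~ref_masks[tr.cell_id]
            lab, nlab = ndi.label(residual)
            if nlab == 0:
                continue
            sizes = ndi.sum_labels(residual, lab, index=range(1, nlab + 1))
            best = int(np.argmax(sizes)) + 1
            if sizes[best - 1] >= bud_min_area_px:
                ys, xs = np.nonzero(lab == best)
                tr.bud_areas_px[f_idx] = float(sizes[best - 1])
                tr.bud_centroids[f_idx] = np.array([xs.mean(), ys.mean()])

    return tracks


# ---------------------------------------------------------------------
# Staging and exclusion filters
# ---------------------------------------------------------------------
def classify_stage(
    track: CellTrack,
    frame: int,
    pixel_size: float,
    *,
    fluor_image: Optional[np.ndarray] = None,
    large_bud_area_um2: float = LARGE_BUD_AREA_UM2,
    band_fraction_threshold: float = 0.25,
) -> str:
    """Cell-cycle stage at ``frame``.

    Budded cells split at a bud area of 4.5 µm² — strictly greater is
    "large-bud", otherwise "small-bud".  Unbudded cells are split into
    "unbudded-early" (distinct cortical puncta) versus "unbudded-late"
    (a wide cortical band covering more than ``band_fraction_threshold``
    of the perimeter) when ``fluor_image`` is given; otherwise the label
    is simply "unbudded".
    """
    idx = track.index_of(frame)
    bud_area_px = track.bud_areas_px.get(frame)
    if bud_area_px is not None:
        bud_area_um2 = bud_area_px * pixel_size**2
        return "large-bud" if bud_area_um2 > large_bud_area_um2 else "small-bud"
    if fluor_image is None:
        return "unbudded"
    from .kymograph import linearize_membrane

    profile = linearize_membrane(fluor_image, track.polygons[idx])
    finite = profile[np.isfinite(profile)]
    if finite.size == 0 or np.ptp(finite) < 1e-12:
        return "unbudded"
    # half-maximum width of the cortical signal along the perimeter
    half = finite.min() + 0.5 * np.ptp(finite)
    frac_above = float(np.mean(finite > half))
    return "unbudded-late" if frac_above > band_fraction_threshold else "unbudded-early"


def filter_mother_cells(
    tracks: Sequence[CellTrack],
    frame_interval: float,
    *,
    early_bud_window_s: float = 20 * 60.0,
    bud_min_area_px: float = 4.0,
) -> list[CellTrack]:
    """Apply the standard scoring exclusions.

    Analysis is limited to mother cells (tracks that did not themselves
    appear as daughters), and cells that bud within the first
    ``early_bud_window_s`` of the movie (default 20 min) are excluded.
    """
    kept = []
    for tr in tracks:
        if tr.is_daughter:
            continue
        f = tr.bud_emergence_frame(bud_min_area_px)
        if f is not None and f * frame_interval < early_bud_window_s:
            continue
        kept.append(tr)
    return kept
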