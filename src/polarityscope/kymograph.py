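"""Membrane kymographs by iterative outline linearization.

Each frame's cell outline is resampled to 100 arc-length-uniform
positions; at every position the image is averaged over a 6-pixel band
along the inward normal (bilinear sub-pixel sampling).  Stacking the
rows over time yields a 100-column kymograph.  The arc origin is
propagated frame to frame (anchor at the boundary point nearest the
previous frame's origin) and, when a bud is present, the whole kymograph
is re-registered so bud emergence sits at arc position 0 and time 0.

Missing data — failed outlines, bands leaving the image — is encoded as
NaN, never zero-filled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi

from .tracking import CellTrack, ensure_ccw, polygon_centroid

logger = logging.getLogger(__name__)

N_ARC_SAMPLES = 100
DEFAULT_BAND_WIDTH = 6


def resample_closed_polygon(poly: np.ndarray, n: int = N_ARC_SAMPLES) -> np.ndarray:
    """Resample a closed polygon to ``n`` arc-length-uniform vertices.

    The first output vertex coincides with the first input vertex, so
    rolling the input sets the arc origin.
    """
    poly = np.asarray(poly, dtype=float)
    if len(poly) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    closed = np.vstack([poly, poly[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate polygon (zero perimeter)")
    t = np.arange(n) * (total / n)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    return np.column_stack([x, y])


def _inward_normals(pts: np.ndarray) -> np.ndarray:
    """Unit normals pointing toward the polygon centroid at each vertex."""
    nxt = np.roll(pts, -1, axis=0)
    prv = np.roll(pts, 1, axis=0)
    tang = nxt - prv
    nrm = np.column_stack([-tang[:, 1], tang[:, 0]])
    lens = np.linalg.norm(nrm, axis=1)
    lens[lens == 0] = 1.0
    nrm /= lens[:, None]
    centroid = polygon_centroid(pts)
    flip = np.einsum("ij,ij->i", centroid[None, :] - pts, nrm) < 0
    nrm[flip] *= -1
    return nrm


def linearize_membrane(
    image: np.ndarray,
    polygon: np.ndarray,
    band_width: int = DEFAULT_BAND_WIDTH,
    n_samples: int = N_ARC_SAMPLES,
) -> np.ndarray:
    """One kymograph row: the membrane profile along a cell outline.

    Samples the image at ``n_samples`` equally spaced arc-length
    positions, averaging ``band_width`` bilinear samples taken at
    1-pixel steps along the inward normal starting on the contour.
    Positions whose band leaves the image are returned as NaN.
    """
    if band_width < 1:
        raise ValueError("band_width must be >= 1")
    image = np.asarray(image, dtype=float)
    pts = resample_closed_polygon(np.asarray(polygon, dtype=float), n_samples)
    normals = _inward_normals(pts)
    offsets = np.arange(band_width, dtype=float)
    # sample coordinates: (band, n_samples, 2)
    coords = pts[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    xs, ys = coords[..., 0], coords[..., 1]
    h, w = image.shape
    inside = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    vals = ndi.map_coordinates(image, [ys.ravel(), xs.ravel()], order=1, mode="nearest")
    vals = vals.reshape(xs.shape)
    profile = vals.mean(axis=0)
    profile[~inside.all(axis=0)] = np.nan
    return profile


def map_point_to_arc(polygon: np.ndarray, point: Sequence[float], n_fine: int = 1000) -> float:
    """Arc position in [0, 100) of the boundary point nearest ``point``.

    Raises if the query is ambiguous (near-equidistant from the whole
    boundary, e.g. the centre of a circle).
    """
    pts = resample_closed_polygon(np.asarray(polygon, dtype=float), n_fine)
    d = np.linalg.norm(pts - np.asarray(point, dtype=float)[None, :], axis=1)
    if np.ptp(d) < 0.5:
        raise ValueError(
            "point is nearly equidistant from the entire boundary; arc position is ambiguous"
        )
    return float(np.argmin(d) * (N_ARC_SAMPLES / n_fine)) % N_ARC_SAMPLES


@dataclass
class Kymograph:
    """Time × arc-length membrane intensity matrix for one cell.

    ``matrix[i]`` is the 100-sample membrane profile at ``frames[i]``;
    ``times_s`` is on the movie clock unless ``bud_registered``, in which
    case time 0 is bud emergence and arc 0 is the bud site.
    ``annotations`` holds (row, arc_position, label) markers.
    """

    matrix: np.ndarray
    frames: list[int]
    times_s: np.ndarray
    band_width: int = DEFAULT_BAND_WIDTH
    bud_registered: bool = False
    arc_shift: int = 0
    annotations: list[tuple[int, float, str]] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def row_at_time(self, t: float) -> int:
        return int(np.argmin(np.abs(self.times_s - t)))

    def arc_window(self, center: float, halfwidth: int) -> np.ndarray:
        """Wrap-aware column indices of an arc window."""
        c = int(round(center))
        return np.arange(c - halfwidth, c + halfwidth + 1) % N_ARC_SAMPLES

    def window_trace(self, center: float, halfwidth: int) -> np.ndarray:
        cols = self.arc_window(center, halfwidth)
        return np.nanmean(self.matrix[:, cols], axis=1)


def build_kymograph(
    channel_stack: np.ndarray,
    track: CellTrack,
    *,
    frame_interval: float,
    band_width: int = DEFAULT_BAND_WIDTH,
    target_points: Optional[dict[int, tuple[float, float]]] = None,
    register_to_bud: bool = True,
    previous_bud_point: Optional[tuple[float, float]] = None,
) -> Kymograph:
    """Iteratively linearize a track's outlines into a kymograph.

    The arc origin of each row is anchored at the boundary point nearest
    the previous row's origin, keeping the arc coordinate continuous over
    time.  If the track has a detected bud and ``register_to_bud`` is
    set, rows are circularly shifted so the bud site sits at arc 0 and
    the time axis is offset so bud emergence is t = 0.

    ``target_points`` maps frame index -> (x, y) of the active
    illumination target; each is annotated at its arc position.
    """
    rows = []
    origin: Optional[np.ndarray] = None
    resampled: list[Optional[np.ndarray]] = []
    for i, f in enumerate(track.frames):
        poly = ensure_ccw(track.polygons[i])
        try:
            pts = resample_closed_polygon(poly, N_ARC_SAMPLES)
        except ValueError:
            logger.warning("cell %d frame %d: outline failed, row set to NaN", track.cell_id, f)
            rows.append(np.full(N_ARC_SAMPLES, np.nan))
            resampled.append(None)
            continue
        if origin is not None:
            k = int(np.argmin(np.linalg.norm(pts - origin[None, :], axis=1)))
            pts = np.roll(pts, -k, axis=0)
        origin = pts[0]
        resampled.append(pts)
        rows.append(linearize_membrane(channel_stack[f], pts, band_width))
    matrix = np.vstack(rows) if rows else np.zeros((0, N_ARC_SAMPLES))

    annotations: list[tuple[int, float, str]] = []
    if target_points:
        for i, f in enumerate(track.frames):
            if f in target_points and resampled[i] is not None:
                try:
                    a = map_point_to_arc(resampled[i], target_points[f])
                except ValueError:
                    continue
                annotations.append((i, a, "target"))

    times = np.asarray([f * frame_interval for f in track.frames], dtype=float)
    shift = 0
    bud_registered = False
    bud_frame = track.bud_emergence_frame()
    if register_to_bud and bud_frame is not None and bud_frame in track.frames:
        i_bud = track.index_of(bud_frame)
        ref = resampled[i_bud]
        if ref is not None:
            bud_point = track.bud_centroids[bud_frame]
            try:
                arc_bud = map_point_to_arc(ref, bud_point)
            except ValueError:
                arc_bud = None
            if arc_bud is not None:
                shift = int(round(arc_bud)) % N_ARC_SAMPLES
                matrix = np.roll(matrix, -shift, axis=1)
                annotations = [
                    (i, (a - shift) % N_ARC_SAMPLES, lab) for i, a, lab in annotations
                ]
                times = times - bud_frame * frame_interval
                bud_registered = True
                annotations.append((i_bud, 0.0, "bud_emergence"))
    if previous_bud_point is not None and resampled and resampled[0] is not None:
        try:
            a_prev = (map_point_to_arc(resampled[0], previous_bud_point) - shift) % N_ARC_SAMPLES
            annotations.append((0, a_prev, "previous_bud"))
        except ValueError:
            pass

    return Kymograph(
        matrix=matrix,
        frames=list(track.frames),
        times_s=times,
        band_width=band_width,
        bud_registered=bud_registered,
        arc_shift=shift,
        annotations=annotations,
    )
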