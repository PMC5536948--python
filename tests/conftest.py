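"""Shared fixtures: small synthetic scenes generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import polarityscope as ps


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def render_ring(
    shape=(64, 64), center=(32.0, 32.0), radius_px=20.0, sigma_px=1.5,
    hotspot_deg=None, hotspot_amp=1.0, hotspot_sigma_rad=0.3, base=1.0,
):
    """Independent ring renderer used as an oracle for membrane profiles."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dist = np.hypot(xx - center[0], yy - center[1])
    img = base * np.exp(-0.5 * ((dist - radius_px) / sigma_px) ** 2)
    if hotspot_deg is not None:
        phi = np.arctan2(yy - center[1], xx - center[0])
        d = np.angle(np.exp(1j * (phi - np.deg2rad(hotspot_deg))))
        img += hotspot_amp * np.exp(-0.5 * ((dist - radius_px) / sigma_px) ** 2) * np.exp(
            -0.5 * (d / hotspot_sigma_rad) ** 2
        )
    return img


@pytest.fixture(scope="session")
def responder_scene():
    """One responder cell, pulsed east target, bud on target; noise on.

    Shared across modules to keep the suite fast; treat as read-only.
    """
    cfg = ps.SimConfig(duration=2400.0, frame_interval=30.0, rng_seed=7)
    script = ps.CellScript(center=(50.0, 50.0), bud_emergence_time=1800.0, bud_site_angle=0.0)
    schedule = ps.TargetSchedule.from_pulses(
        66.0, 50.0, [60.0 + 20.0 * i for i in range(30)], cell_id=0
    )
    movie, truth = ps.simulate_movie(cfg, [script], schedule)
    ref = movie.channel("reference")
    polys = [ps.segment_frame(ref[i]) for i in range(movie.n_frames)]
    tracks = ps.track_cells(polys, image_shape=movie.shape)
    return {
        "config": cfg,
        "script": script,
        "schedule": schedule,
        "movie": movie,
        "truth": truth,
        "tracks": tracks,
    }


@pytest.fixture(scope="session")
def responder_kymograph(responder_scene):
    sc = responder_scene
    tr = sc["tracks"][0]
    target_points = {f: (66.0, 50.0) for f in tr.frames}
    kym = ps.build_kymograph(
        sc["movie"].channel("biosensor"),
        tr,
        frame_interval=sc["movie"].frame_interval,
        target_points=target_points,
    )
    return kym
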