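"""Simulator: recruitment kinetics, rendering, noise statistics, puncta."""

import math

import numpy as np
import pytest

import polarityscope as ps
from polarityscope.simulate import fit_decay_half_time


class TestRecruitmentTrace:
    def test_single_pulse_decay_anchors(self):
        """After the peak the trace halves every 80 s: 50% at +80 s, 25% at +160 s."""
        kin = ps.RecruitmentKinetics()  # on 10 s, half-time 80 s
        t, tr = ps.simulate_recruitment_trace(kin, [0.0], 400.0, 1.0)
        peak_i = int(np.argmax(tr))
        assert t[peak_i] == pytest.approx(kin.on_time)
        assert tr[peak_i] == pytest.approx(1.0)
        v80 = tr[np.searchsorted(t, t[peak_i] + 80.0)]
        v160 = tr[np.searchsorted(t, t[peak_i] + 160.0)]
        assert v80 == pytest.approx(0.5, rel=0.01)
        assert v160 == pytest.approx(0.25, rel=0.01)

    def test_no_pulses_is_identically_zero(self):
        _, tr = ps.simulate_recruitment_trace(ps.RecruitmentKinetics(), [], 300.0, 5.0)
        assert np.all(tr == 0.0)

    def test_frequent_pulses_reach_higher_plateau(self):
        """3 pulses/min sustains more bound reporter than 1 pulse/min."""
        kin = ps.RecruitmentKinetics()
        fast = [20.0 * i for i in range(45)]  # every 20 s over 15 min
        slow = [60.0 * i for i in range(15)]  # every 60 s
        _, tr_fast = ps.simulate_recruitment_trace(kin, fast, 900.0, 5.0)
        _, tr_slow = ps.simulate_recruitment_trace(kin, slow, 900.0, 5.0)
        # compare late plateaus (last 3 min)
        assert tr_fast[-36:].mean() > 1.5 * tr_slow[-36:].mean()
        # closed-form geometric plateau for the fast train
        q = math.exp(-math.log(2) * 20.0 / kin.dark_half_time)
        expected_peak = 1.0 / (1.0 - q)
        assert tr_fast.max() == pytest.approx(expected_peak, rel=0.05)

    def test_decay_fit_recovers_half_time(self):
        kin = ps.RecruitmentKinetics(dark_half_time=80.0)
        t, tr = ps.simulate_recruitment_trace(kin, [0.0], 700.0, 10.0)
        post = t > kin.on_time
        fitted = fit_decay_half_time(t[post] - t[post][0], tr[post])
        assert fitted == pytest.approx(80.0, rel=0.02)

    def test_invalid_inputs(self):
        kin = ps.RecruitmentKinetics()
        with pytest.raises(ValueError):
            ps.simulate_recruitment_trace(kin, [0.0], -1.0, 1.0)
        with pytest.raises(ValueError):
            ps.simulate_recruitment_trace(kin, [0.0], 100.0, 0.0)


class TestSimulateMovie:
    def test_membrane_signal_tracks_pulse_and_decay(self):
        """Noise off, one pulse: target-site membrane signal peaks within
        on_time and falls to half its peak 80 s later (within 1%)."""
        cfg = ps.SimConfig(
            duration=600.0, frame_interval=10.0, rng_seed=0,
            noise=ps.NoiseModel(enabled=False),
        )
        kin = ps.RecruitmentKinetics()
        script = ps.CellScript(center=(50.0, 50.0))
        sched = ps.TargetSchedule.from_pulses(66.0, 50.0, [100.0], cell_id=0)
        movie, _ = ps.simulate_movie(cfg, [script], sched, kin)
        sig = movie.channel("biosensor")
        # pixel on the membrane at the target angle
        r_px = script.radius / cfg.pixel_size
        x, y = int(round(50 + r_px)), 50
        trace = sig[:, y, x] - sig[0, y, x]
        t = movie.times
        peak_i = int(np.argmax(trace))
        assert t[peak_i] <= 100.0 + kin.on_time + cfg.frame_interval
        i80 = int(np.searchsorted(t, t[peak_i] + 80.0))
        assert trace[i80] / trace[peak_i] == pytest.approx(0.5, abs=0.01)

    def test_empty_scripts_give_uniform_background(self):
        cfg = ps.SimConfig(duration=60.0, frame_interval=30.0, noise=ps.NoiseModel(enabled=False))
        movie, truth = ps.simulate_movie(cfg, [], ps.TargetSchedule.empty())
        assert truth.cells == []
        ref = movie.channel("reference")
        assert np.allclose(ref, ref.flat[0])

    def test_seed_determinism(self):
        cfg = ps.SimConfig(duration=120.0, frame_interval=30.0, rng_seed=3)
        script = ps.CellScript(center=(50.0, 50.0))
        m1, _ = ps.simulate_movie(cfg, [script])
        m2, _ = ps.simulate_movie(cfg, [script])
        for ch in m1.channels:
            assert np.array_equal(m1.channels[ch], m2.channels[ch])
        cfg2 = cfg.model_copy(update={"rng_seed": 4})
        m3, _ = ps.simulate_movie(cfg2, [script])
        assert not np.array_equal(m1.channels["reference"], m3.channels["reference"])

    def test_overlapping_cells_rejected(self):
        cfg = ps.SimConfig(duration=60.0, frame_interval=30.0)
        a = ps.CellScript(center=(40.0, 50.0))
        b = ps.CellScript(center=(55.0, 50.0))  # 15 px apart, radii ~15.4 px each
        with pytest.raises(ValueError, match="overlap"):
            ps.simulate_movie(cfg, [a, b])

    def test_target_outside_field_rejected(self):
        cfg = ps.SimConfig(duration=60.0, frame_interval=30.0)
        script = ps.CellScript(center=(50.0, 50.0))
        sched = ps.TargetSchedule.from_pulses(150.0, 50.0, [10.0], cell_id=0)
        with pytest.raises(ValueError, match="outside"):
            ps.simulate_movie(cfg, [script], sched)

    def test_camera_noise_variance(self):
        """Flat-region pixel variance ~ gain * mean_signal + read_sd**2."""
        noise = ps.NoiseModel(enabled=True, background=100.0, gain=2.0, read_sd=3.0)
        cfg = ps.SimConfig(
            duration=600.0, frame_interval=30.0, ambient_level=50.0, noise=noise, rng_seed=5
        )
        movie, _ = ps.simulate_movie(cfg, [])
        ref = movie.channel("reference").astype(float)
        mean_sig = ref.mean() - noise.background
        expected_var = noise.gain * mean_sig + noise.read_sd**2
        assert ref.var() == pytest.approx(expected_var, rel=0.05)

    def test_membrane_maxima_on_true_outline(self):
        """Radial intensity maxima sit within 1 px of the scripted circle."""
        cfg = ps.SimConfig(duration=30.0, frame_interval=30.0, noise=ps.NoiseModel(enabled=False))
        script = ps.CellScript(center=(50.0, 50.0))
        movie, truth = ps.simulate_movie(cfg, [script])
        sig = movie.channel("biosensor")[0]
        r_px = script.radius / cfg.pixel_size
        radii = np.linspace(r_px - 6, r_px + 6, 61)
        for ang in np.deg2rad([0, 45, 135, 200, 300]):
            xs = 50.0 + radii * np.cos(ang)
            ys = 50.0 + radii * np.sin(ang)
            vals = sig[np.round(ys).astype(int), np.round(xs).astype(int)]
            assert abs(radii[int(np.argmax(vals))] - r_px) <= 1.0


class TestGroundTruth:
    def test_json_round_trip_is_lossless(self, tmp_path):
        cfg = ps.SimConfig(duration=90.0, frame_interval=30.0, rng_seed=2)
        script = ps.CellScript(center=(50.0, 50.0), bud_emergence_time=60.0)
        _, truth = ps.simulate_movie(cfg, [script])
        p = tmp_path / "gt.json"
        truth.save_json(p)
        loaded = ps.GroundTruth.load_json(p)
        assert loaded.to_dict() == truth.to_dict()
        assert len(loaded.cells) == 1


class TestPlantPuncta:
    def _positions(self, puncta, radius_um, pixel_size=0.162):
        r = radius_um / pixel_size
        return {
            ch: np.array(
                [
                    [r * np.cos(np.deg2rad(p.angle_deg)), r * np.sin(np.deg2rad(p.angle_deg))]
                    for p in puncta
                    if p.channel == ch
                ]
            )
            for ch in {p.channel for p in puncta}
        }

    def test_full_colocalization(self, rng):
        script = ps.CellScript(center=(50.0, 50.0), radius=4.0)
        out = ps.plant_puncta(script, 1.0, rng, n_a=12)
        a = [p for p in out if p.channel == "bem1"]
        assert all(p.partner == "cdc24" for p in a)
        assert sum(p.channel == "cdc24" for p in out) == 12

    def test_zero_colocalization_respects_exclusion(self, rng):
        script = ps.CellScript(center=(50.0, 50.0), radius=4.0)
        out = ps.plant_puncta(script, 0.0, rng, n_a=12, colocal_dist_px=2.0)
        pos = self._positions(out, 4.0)
        assert "cdc24" not in pos or len(pos["cdc24"]) == 0

    def test_pair_count_arithmetic(self, rng):
        """35% of 20 A-puncta -> exactly 7 B partners."""
        script = ps.CellScript(center=(50.0, 50.0), radius=4.0)
        out = ps.plant_puncta(script, 0.35, rng, n_a=20, colocal_dist_px=2.0)
        a = [p for p in out if p.channel == "bem1"]
        b = [p for p in out if p.channel == "cdc24"]
        assert len(a) == 20 and len(b) == 7
        assert sum(p.partner is not None for p in a) == 7
        # geometric guarantees: partners close, non-partners far
        pos = self._positions(out, 4.0)
        d = np.linalg.norm(pos["bem1"][:, None] - pos["cdc24"][None, :], axis=2)
        paired = [i for i, p in enumerate(a) if p.partner]
        unpaired = [i for i, p in enumerate(a) if not p.partner]
        assert np.all(d[paired].min(axis=1) <= 2.0)
        assert np.all(d[unpaired].min(axis=1) > 4.0)

    def test_invalid_fraction_rejected(self, rng):
        with pytest.raises(ValueError):
            ps.plant_puncta(ps.CellScript(center=(50.0, 50.0), radius=4.0), 1.5, rng)
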