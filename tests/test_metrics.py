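"""Polarity statistics: PE, on-target, appearance, persistence,
competition, two-site scoring, Whi5 exit and population kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polarityscope as ps
from polarityscope.kymograph import Kymograph
from polarityscope.metrics import TargetMove


def make_kymograph(matrix, frame_interval=30.0):
    m = np.asarray(matrix, dtype=float)
    return Kymograph(
        matrix=m,
        frames=list(range(m.shape[0])),
        times_s=np.arange(m.shape[0]) * frame_interval,
    )


def noisy_matrix(rng, n_rows, level=100.0, sd=2.0):
    return rng.normal(level, sd, size=(n_rows, 100))


class TestPolarizationEfficiency:
    @pytest.mark.parametrize(
        "theta,expected",
        [(0.0, 1.0), (math.pi, -1.0), (math.pi / 2, 0.0)],
    )
    def test_linear_map_endpoints_and_midpoint(self, theta, expected):
        assert ps.polarization_efficiency(theta) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ps.polarization_efficiency(-0.1)
        with pytest.raises(ValueError):
            ps.polarization_efficiency(3.5)

    @given(st.floats(0.0, 180.0))
    @settings(max_examples=50, deadline=None)
    def test_scores_bounded(self, theta_deg):
        assert -1.0 <= ps.polarization_efficiency_deg(theta_deg) <= 1.0

    def test_uniform_angles_average_to_zero(self, rng):
        thetas = rng.uniform(0.0, 180.0, size=2000)
        mean, sem = ps.population_pe([ps.polarization_efficiency_deg(t) for t in thetas])
        assert abs(mean) < 3 * sem

    def test_population_pe_linearity_in_mean_angle(self, rng):
        """Population PE equals 1 - mean(θ)/90 exactly (degrees form)."""
        thetas = rng.uniform(0.0, 180.0, size=500)
        mean, _ = ps.population_pe([ps.polarization_efficiency_deg(t) for t in thetas])
        assert mean == pytest.approx(1.0 - thetas.mean() / 90.0, abs=1e-12)


class TestOnTarget:
    @pytest.mark.parametrize("theta,expected", [(30.0, True), (44.9, True), (45.0, False), (90.0, False)])
    def test_strict_45_degree_rule(self, theta, expected):
        assert ps.on_target(theta) is expected


class TestBudTargetAngle:
    def test_recovers_scripted_angle(self, responder_scene):
        sc = responder_scene
        theta = ps.bud_target_angle(sc["tracks"][0], sc["schedule"], 0, frame_interval=30.0)
        assert theta < 5.0  # bud scripted exactly at the target
        assert ps.polarization_efficiency_deg(theta) > 0.9

    def test_no_bud_is_excluded(self):
        tr = ps.CellTrack(cell_id=0)
        tr.frames, tr.centroids = [0], [np.array([10.0, 10.0])]
        tr.polygons, tr.areas_px = [ps.circle_polygon((10, 10), 5)], [78.0]
        with pytest.raises(ValueError, match="no bud"):
            ps.bud_target_angle(tr, ps.TargetSchedule.from_pulses(20, 10, [0.0]), 0)

    def test_minimal_angle_wraps(self):
        assert ps.minimal_angle_deg(10.0, 350.0) == pytest.approx(20.0)
        assert ps.minimal_angle_deg(0.0, 180.0) == pytest.approx(180.0)


class TestRelativeIntensity:
    def test_uniform_ring_ratio_is_one(self, rng):
        kym = make_kymograph(np.full((30, 100), 50.0))
        r = ps.relative_intensity(kym, 20.0, "polarized", first_pulse_time=0.0)
        assert r == pytest.approx(1.0)

    def test_twofold_hotspot_at_target(self):
        m = np.full((30, 100), 50.0)
        m[:, 17:24] = 100.0
        kym = make_kymograph(m)
        r = ps.relative_intensity(kym, 20.0, "polarized", first_pulse_time=0.0)
        assert r == pytest.approx(2.0, rel=0.02)

    def test_hotspot_at_control_gives_half(self):
        m = np.full((30, 100), 50.0)
        m[:, 67:74] = 100.0  # at the 180° control of target arc 20
        kym = make_kymograph(m)
        r = ps.relative_intensity(kym, 20.0, "non-polarized", bud_emergence_time=900.0)
        assert r == pytest.approx(0.5, rel=0.02)

    def test_blocked_control_is_shifted_and_flagged(self):
        m = np.full((30, 100), 50.0)
        kym = make_kymograph(m)
        r, info = ps.relative_intensity(
            kym, 20.0, "polarized", first_pulse_time=0.0,
            avoid_arcs=[70.0], return_details=True,
        )
        assert info["control_shifted"]
        assert r == pytest.approx(1.0)

    def test_unknown_mode_rejected(self):
        kym = make_kymograph(np.full((5, 100), 1.0))
        with pytest.raises(ValueError):
            ps.relative_intensity(kym, 0.0, "sideways")


class TestDetectAppearance:
    def test_flat_noise_yields_none(self, rng):
        kym = make_kymograph(noisy_matrix(rng, 40))
        assert ps.detect_appearance(kym, 50.0) is None

    def test_single_frame_spike_fails_persistence(self, rng):
        m = noisy_matrix(rng, 40)
        m[20, 45:56] += 500.0
        kym = make_kymograph(m)
        assert ps.detect_appearance(kym, 50.0, m=3) is None

    def test_step_onset_recovered_exactly(self, rng):
        m = noisy_matrix(rng, 40)
        m[25:, 45:56] += 50.0
        kym = make_kymograph(m)
        assert ps.detect_appearance(kym, 50.0) == 25

    def test_too_few_baseline_rows_is_an_error(self, rng):
        kym = make_kymograph(noisy_matrix(rng, 10))
        with pytest.raises(ValueError, match="background"):
            ps.detect_appearance(kym, 50.0, baseline_rows=[0])

    def test_scripted_recruited_onset_recovered(self, responder_scene, responder_kymograph):
        """The precocious (recruited) biosensor onset scripted 27 min before
        bud emergence is recovered within one frame of the first pulse-driven
        signal rise."""
        sc = responder_scene
        kym = responder_kymograph
        arcs = [a for _, a, lab in kym.annotations if lab == "target"]
        row = ps.detect_appearance(kym, float(np.median(arcs)), baseline_rows=[0, 1])
        assert row is not None
        detected_t = sc["movie"].frame_interval * sc["tracks"][0].frames[row]
        first_pulse = sc["schedule"].pulse_times(0)[0]
        assert 0.0 <= detected_t - first_pulse <= 2 * sc["movie"].frame_interval


class TestScorePolarized:
    def test_sixteen_minute_run_is_polarized(self):
        # 33 consecutive frames at 30 s span 16 min
        assert ps.score_polarized([True] * 33, 30.0) is True

    def test_fifteen_minute_run_is_not(self):
        # 31 frames span exactly 15 min; the rule is strictly greater
        assert ps.score_polarized([True] * 31, 30.0) is False

    def test_interrupted_accumulation_does_not_count(self):
        # two 8-min runs separated by a gap: persistence requires consecutiveness
        run = [True] * 17
        assert ps.score_polarized(run + [False] + run, 30.0) is False


class TestWhi5Exit:
    def _tracked_cell(self, movie):
        ref = movie.channel("reference")
        polys = [ps.segment_frame(ref[i]) for i in range(movie.n_frames)]
        return ps.track_cells(polys, image_shape=movie.shape)[0]

    def _make_movie(self, bud_time, offsets):
        cfg = ps.SimConfig(
            duration=1800.0, frame_interval=30.0, rng_seed=11,
            channels=["reference", "whi5"],
        )
        script = ps.CellScript(
            center=(50.0, 50.0), bud_emergence_time=bud_time, event_offsets=offsets
        )
        movie, truth = ps.simulate_movie(cfg, [script])
        return movie, truth

    def test_scripted_exit_recovered_within_one_frame(self):
        movie, truth = self._make_movie(1740.0, {"whi5_exit": -20.0})  # exit at 540 s
        tr = self._tracked_cell(movie)
        t = ps.whi5_exit_time(movie.channel("whi5"), tr, frame_interval=30.0)
        true_t = truth.cells[0].event_times["whi5_exit"]
        assert t is not None
        assert abs(t - true_t) <= 30.0

    def test_constitutively_cytoplasmic_first_frame(self):
        # exit scripted before the movie starts -> never any nuclear excess
        movie, _ = self._make_movie(60.0, {"whi5_exit": -10.0})
        tr = self._tracked_cell(movie)
        assert ps.whi5_exit_time(movie.channel("whi5"), tr, frame_interval=30.0) == 0.0

    def test_constitutively_nuclear_returns_none(self):
        movie, _ = self._make_movie(None, {})
        tr = self._tracked_cell(movie)
        assert ps.whi5_exit_time(movie.channel("whi5"), tr, frame_interval=30.0) is None


class TestPopulationKinetics:
    def test_synchronous_population(self):
        kin = ps.population_appearance([-20.0] * 8, bin_minutes=10.0)
        assert ps.half_population_time(kin) == -20.0
        assert kin.n_total == 8

    def test_cumulative_rule_on_mixture(self):
        """Half at -30 min, half at -10 min: the cumulative fraction first
        reaches one half at the -30 min bin midpoint."""
        kin = ps.population_appearance([-30.0] * 5 + [-10.0] * 5, bin_minutes=10.0)
        assert ps.half_population_time(kin) == -30.0
        # and the curve is complete by -10
        assert kin.fraction[kin.bin_mid_min == -10.0][0] == pytest.approx(1.0)

    def test_empty_bins_carry_fraction(self):
        kin = ps.population_appearance([-40.0, -40.0, -5.0], bin_minutes=10.0)
        mid = kin.bin_mid_min
        # bins between the two groups keep the running fraction, add no cells
        inner = (mid > -40) & (mid < -10)
        assert np.all(kin.fraction[inner] == pytest.approx(2 / 3))

    def test_never_appearing_cells_stay_in_denominator(self):
        kin = ps.population_appearance([-20.0, -20.0, None, None], bin_minutes=10.0)
        assert kin.fraction.max() == pytest.approx(0.5)

    def test_monotone_nondecreasing(self):
        kin = ps.population_appearance([-35.0, -22.0, -18.0, -4.0], bin_minutes=5.0)
        assert np.all(np.diff(kin.fraction) >= 0)


class TestCompetition:
    def _competition_kym(self, rng, handover: bool, fade_only: bool = False):
        m = noisy_matrix(rng, 40)
        old_cols, new_cols = slice(15, 26), slice(55, 66)
        m[5:20, old_cols] += 60.0  # signal at the old site until the move
        if handover:
            m[22:, new_cols] += 60.0  # appears at the new site
        elif not fade_only:
            m[5:, old_cols] += 0.0  # keep old signal going
            m[20:, old_cols] += 60.0
        return make_kymograph(m)

    def test_full_handover_is_outcompeted(self, rng):
        kym = self._competition_kym(rng, handover=True)
        mv = TargetMove(move_row=20, old_arc=20.0, new_arc=60.0, hold_end_row=39)
        assert ps.score_competition(kym, [mv]) == ["Outcompeted"]

    def test_persistent_old_site_is_not_outcompeted(self, rng):
        kym = self._competition_kym(rng, handover=False)
        mv = TargetMove(move_row=20, old_arc=20.0, new_arc=60.0, hold_end_row=39)
        assert ps.score_competition(kym, [mv]) == ["Not Outcompeted"]

    def test_fade_without_new_signal_is_indeterminate(self, rng):
        kym = self._competition_kym(rng, handover=False, fade_only=True)
        mv = TargetMove(move_row=20, old_arc=20.0, new_arc=60.0, hold_end_row=39)
        assert ps.score_competition(kym, [mv]) == ["Indeterminate"]

    def test_short_hold_window_excluded(self, rng):
        kym = self._competition_kym(rng, handover=True)
        mv = TargetMove(move_row=20, old_arc=20.0, new_arc=60.0, hold_end_row=21)
        assert ps.score_competition(kym, [mv]) == ["Excluded"]


class TestTwoSites:
    def test_both_to_one_transition(self, rng):
        m = noisy_matrix(rng, 40)
        m[5:, 15:26] += 60.0          # site A holds throughout
        m[5:25, 55:66] += 60.0        # site B drops out at row 25
        kym = make_kymograph(m)
        states = ps.score_two_sites(kym, 20.0, 60.0)
        assert set(states[:5]) == {"none"}
        assert set(states[6:24]) == {"both"}
        assert set(states[26:]) == {"one"}

    def test_silent_cell_is_all_none(self, rng):
        kym = make_kymograph(noisy_matrix(rng, 20))
        states = ps.score_two_sites(kym, 20.0, 60.0, baseline_rows=range(20))
        assert set(states) == {"none"}

    def test_overlapping_windows_rejected(self, rng):
        kym = make_kymograph(noisy_matrix(rng, 10))
        with pytest.raises(ValueError, match="overlap"):
            ps.score_two_sites(kym, 20.0, 25.0)
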