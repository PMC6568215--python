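import math

import numpy as np
import pytest

from clockmaze.errors import CapabilityError, MalformedTrialError, ValidationError
from clockmaze.metrics import (
    MetricsParams,
    compute_trial_metrics,
    count_rotations,
    detect_inspections,
    heading_to_exit,
    meander_count,
    occupancy_map,
    path_length,
    zone_dwell_times,
)
from clockmaze.arena import ZoneKind, probe_zones
from clockmaze.simulate import SimConfig, simulate_trial, trial_rng
from clockmaze.trackio import Track, TrialRecord

from .conftest import make_track
from .oracles import inspection_oracle

RATE = 30.0
DT = 1.0 / RATE


def _nose_track(nose_points, rate_hz=RATE):
    """Track whose nose follows the given points; centre trails 4 cm behind."""
    nose = np.asarray(nose_points, dtype=float)
    n = len(nose)
    center = nose * 0.9  # anywhere inside; detection only uses the nose
    tail = nose * 0.8
    t = np.arange(n) / rate_hz
    return Track(t=t, center=center, nose=nose, tail=tail, rate_hz=rate_hz)


def _hold(point, seconds, rate_hz=RATE):
    return [list(point)] * int(round(seconds * rate_hz))


class TestDetectInspections:
    def test_two_decoys_then_exit(self, arena):
        """Nose dwells 0.3 s in decoys 2 and 3, then exits at hole 9."""
        c2, c3, c9 = arena.hole_center(2), arena.hole_center(3), arena.hole_center(9)
        pts = (
            _hold((0, 0), 0.2)
            + _hold(c2, 0.3)
            + _hold((0, 0), 0.2)
            + _hold(c3, 0.3)
            + _hold((0, 0), 0.2)
            + _hold(c9, 0.3)
        )
        track = _nose_track(pts)
        events = detect_inspections(track, arena, true_exit=9)
        decoy = [e for e in events if not e.is_true_exit]
        assert len(decoy) == 2
        assert {e.zone_name for e in decoy} == {"decoy_2", "decoy_3"}
        assert sum(e.is_true_exit for e in events) == 1
        # cross-check against the literal per-frame oracle
        oracle = inspection_oracle(track, arena, 9)
        got = [(e.zone_name, e.t_on, e.t_off, e.is_true_exit) for e in events]
        assert got == oracle

    def test_single_frame_graze_ignored(self, arena):
        c5 = arena.hole_center(5)
        pts = _hold((0, 0), 0.2) + [list(c5)] + _hold((0, 0), 0.2)
        track = _nose_track(pts)
        assert detect_inspections(track, arena, true_exit=9) == []

    def test_rearm_requires_leaving_dilated_zone(self, arena):
        """Enter decoy 5, retreat beyond 1.5x the zone, re-enter -> 2 events;
        retreat only to the dilated ring -> 1 event."""
        c5 = np.array(arena.hole_center(5))
        inward = -c5 / np.linalg.norm(c5)
        just_outside = c5 + inward * 2.5      # outside core, inside 3 cm dilated
        far_outside = c5 + inward * 4.0       # beyond the dilated ring
        two = _nose_track(
            _hold(c5, 0.3) + _hold(far_outside, 0.3) + _hold(c5, 0.3)
        )
        one = _nose_track(
            _hold(c5, 0.3) + _hold(just_outside, 0.3) + _hold(c5, 0.3)
        )
        ev2 = detect_inspections(two, arena, true_exit=9)
        ev1 = detect_inspections(one, arena, true_exit=9)
        assert len(ev2) == 2 and all(e.zone_name == "decoy_5" for e in ev2)
        assert len(ev1) == 1
        for track, events in ((two, ev2), (one, ev1)):
            oracle = inspection_oracle(track, arena, 9)
            assert [(e.zone_name, e.t_on, e.t_off, e.is_true_exit) for e in events] == oracle

    def test_degraded_track_refused(self, arena):
        track = make_track([[0, 0], [1, 0], [2, 0]])
        with pytest.raises(CapabilityError):
            detect_inspections(track, arena, true_exit=9)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_oracle_on_simulated_tracks(self, arena, seed):
        rng = trial_rng(seed, "oracle", 1)
        policy = ["spatial", "chain", "futile"][seed % 3]
        trial = TrialRecord(subject_id="oracle", true_exit_hole=1 + seed % 12,
                            cutoff_s=20.0)
        track, _ = simulate_trial(policy, arena, trial, SimConfig(), rng)
        events = detect_inspections(track, arena, trial.true_exit_hole)
        oracle = inspection_oracle(track, arena, trial.true_exit_hole)
        assert [(e.zone_name, e.t_on, e.t_off, e.is_true_exit) for e in events] == oracle


class TestPathLength:
    def test_collinear(self):
        track = make_track([[0, 0], [3, 0], [6, 0]])
        assert path_length(track) == pytest.approx(6.0)

    def test_back_and_forth(self):
        track = make_track([[0, 0], [5, 0], [0, 0]])
        assert path_length(track) == pytest.approx(10.0)

    def test_noisy_straight_within_5_percent(self):
        rng = np.random.default_rng(0)
        n = 600
        x = 0.5 * np.arange(n)  # 0.5 cm steps
        clean = np.column_stack([x, np.zeros(n)])
        noisy = clean + rng.normal(0, 0.1, size=(n, 2))
        track = make_track(noisy)
        truth = 0.5 * (n - 1)
        assert abs(path_length(track) - truth) / truth < 0.05

    def test_stationary_jitter_filtered(self):
        rng = np.random.default_rng(1)
        pts = np.cumsum(rng.normal(0, 0.005, size=(100, 2)), axis=0) * 0
        pts += rng.normal(0, 0.01, size=(100, 2))
        track = make_track(pts)
        assert path_length(track) == 0.0


def _heading_track(headings_deg):
    """Stationary body rotating through the given heading sequence."""
    h = np.radians(headings_deg)
    nose = np.column_stack([4 * np.cos(h), 4 * np.sin(h)])
    tail = -nose
    center = np.zeros_like(nose)
    return make_track(center, nose=nose, tail=tail)


class TestCountRotations:
    def test_monotone_750_gives_2(self):
        track = _heading_track(np.linspace(0, 750, 200))
        assert count_rotations(track) == 2

    def test_oscillation_90_gives_0(self):
        sweep = np.concatenate([np.linspace(0, 90, 30), np.linspace(90, -90, 60),
                                np.linspace(-90, 0, 30)])
        assert count_rotations(_heading_track(sweep)) == 0

    def test_full_cw_then_full_ccw_gives_2(self):
        # step through the counting rule: the CW excursion completes at -360
        # (count 1, reference rebased), then the CCW excursion completes (2)
        sweep = np.concatenate([np.linspace(0, -360, 120), np.linspace(-360, 0, 120)])
        assert count_rotations(_heading_track(sweep)) == 2

    def test_cancelled_excursion_not_counted(self):
        # 350 forward, 60 back (beyond the 45-degree hysteresis), 10 forward
        sweep = np.concatenate([np.linspace(0, 350, 120), np.linspace(350, 290, 30),
                                np.linspace(290, 300, 10)])
        assert count_rotations(_heading_track(sweep)) == 0

    def test_degraded_refused(self):
        with pytest.raises(CapabilityError):
            count_rotations(make_track([[0, 0], [1, 0]]))


class TestMeanderCount:
    def test_straight_is_zero(self, straight_track):
        assert meander_count(straight_track) == 0

    def test_zigzag_alternations(self):
        # 5 cm legs alternating +x / +y; turning sequence at 1 Hz sampling is
        # +90, -90, +90, -90 -> 3 sign reversals, all flanks above threshold
        pts = [[0, 0]]
        for i in range(5):
            last = pts[-1]
            step = [5, 0] if i % 2 == 0 else [0, 5]
            pts.append([last[0] + step[0], last[1] + step[1]])
        track = make_track(pts, t=np.arange(6, dtype=float))
        assert meander_count(track, smooth_window=1) == 3

    def test_smooth_arc_below_threshold(self):
        ang = np.linspace(0, np.pi, 200)
        pts = np.column_stack([30 * np.cos(ang), 30 * np.sin(ang)])
        track = make_track(pts)
        assert meander_count(track, smooth_window=1, turn_threshold_deg=20) == 0


class TestHeadingToExit:
    def test_straight_at_exit(self):
        track = make_track([[0, 0], [1, 0], [2, 0], [3, 0]], t=[0, 0.1, 0.2, 0.3])
        assert heading_to_exit(track, (42.5, 0.0)) == pytest.approx(0.0, abs=1e-9)

    def test_straight_away(self):
        track = make_track([[0, 0], [-1, 0], [-2, 0]], t=[0, 0.1, 0.2])
        assert heading_to_exit(track, (42.5, 0.0)) == pytest.approx(180.0)

    def test_stationary_returns_none(self):
        track = make_track([[0, 0], [0, 0], [0, 0]], t=[0, 1, 2])
        assert heading_to_exit(track, (42.5, 0.0)) is None

    def test_circular_path_matches_per_step_oracle(self):
        ang = np.linspace(0, 2 * np.pi, 400)
        pts = np.column_stack([20 * np.cos(ang), 20 * np.sin(ang)])
        t = np.linspace(0, 20, 400)
        track = make_track(pts, t=t)
        exit_c = (42.5, 0.0)
        got = heading_to_exit(track, exit_c)
        # literal per-step recomputation
        vals = []
        for i in range(len(pts) - 1):
            dx, dy = pts[i + 1] - pts[i]
            dt = t[i + 1] - t[i]
            if math.hypot(dx, dy) / dt < 2.0:
                continue
            ex, ey = exit_c[0] - pts[i][0], exit_c[1] - pts[i][1]
            a = math.degrees(math.atan2(dy, dx)) - math.degrees(math.atan2(ey, ex))
            vals.append(abs((a + 180) % 360 - 180))
        assert got == pytest.approx(np.mean(vals))
        assert 0.0 <= got <= 180.0


class TestZoneDwell:
    def test_periphery_full_duration(self, arena):
        n = 301
        t = np.linspace(0, 60, n)
        pts = np.tile([40.0, 0.0], (n, 1))
        track = make_track(pts, t=t)
        dwell = zone_dwell_times(track, [arena.zone("periphery")])
        assert dwell["periphery"] == pytest.approx(60.0)

    def test_center_never_in_hole_zones(self, arena):
        n = 61
        track = make_track(np.zeros((n, 2)), t=np.linspace(0, 60, n))
        dwell = zone_dwell_times(track, arena.zones_of_kind(ZoneKind.HOLE))
        assert all(v == 0.0 for v in dwell.values())

    def test_half_and_half_quadrants(self, arena):
        n = 200
        t = np.linspace(0, 60, n)
        pts = np.array([[0.0, 20.0]] * (n // 2) + [[0.0, -20.0]] * (n // 2))
        track = make_track(pts, t=t)
        quads = arena.zones_of_kind(ZoneKind.QUADRANT)
        dwell = zone_dwell_times(track, quads)
        dt = t[1] - t[0]
        top = dwell["quadrant_NE"]  # sector [45, 135] holds (0, 20)
        bottom = dwell["quadrant_SW"]
        assert abs(top - 30.0) <= dt + 1e-9
        assert abs(bottom - 30.0) <= dt + 1e-9


class TestOccupancy:
    def test_stationary_single_bin(self):
        n = 100
        track = make_track(np.tile([3.2, -1.7], (n, 1)), t=np.linspace(0, 10, n))
        omap = occupancy_map(track, bin_cm=1.0, radius_cm=42.5)
        assert omap.total() == pytest.approx(10.0)
        assert (omap.grid > 0).sum() == 1

    def test_two_far_bins_split(self):
        n = 200
        pts = np.array([[-20.0, 0.0], [20.0, 0.0]] * (n // 2))
        track = make_track(pts, t=np.linspace(0, 60, n))
        omap = occupancy_map(track, bin_cm=1.0, radius_cm=42.5)
        top_two = np.sort(omap.grid.ravel())[-2:]
        assert omap.total() == pytest.approx(60.0)
        assert top_two == pytest.approx([30.0, 30.0], abs=60.0 / (n - 1))

    def test_additivity_of_chunked_maps(self):
        """Sum of per-chunk maps equals the map of the full track when chunks
        share their boundary sample."""
        rng = np.random.default_rng(5)
        n = 400
        pts = np.cumsum(rng.normal(0, 0.5, size=(n, 2)), axis=0)
        t = np.arange(n) / 5.0
        full = occupancy_map(make_track(pts, t=t), bin_cm=2.0, radius_cm=60.0)
        parts = None
        for lo in range(0, n - 1, 40):
            hi = min(lo + 41, n)
            m = occupancy_map(make_track(pts[lo:hi], t=t[lo:hi]), bin_cm=2.0,
                              radius_cm=60.0)
            parts = m if parts is None else parts + m
        assert np.allclose(parts.grid, full.grid)
        assert parts.total() == pytest.approx(full.total())

    def test_bad_bin_rejected(self, straight_track):
        with pytest.raises(ValidationError):
            occupancy_map(straight_track, bin_cm=0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_on_simulated_tracks(self, arena, seed):
        rng = trial_rng(seed, "occ", 2)
        trial = TrialRecord(subject_id="occ", true_exit_hole=4, cutoff_s=15.0)
        track, _ = simulate_trial(["spatial", "chain", "futile"][seed % 3],
                                  arena, trial, SimConfig(), rng)
        omap = occupancy_map(track, radius_cm=44.0)
        dt = 1.0 / track.rate_hz
        assert abs(omap.total() - track.duration_s) <= dt + 1e-9


class TestComputeTrialMetrics:
    def test_straight_run_to_hole_3(self, arena):
        """Constant 10 cm/s run from the centre to hole 3; the trial ends the
        moment the nose (4 cm ahead) crosses the 2 cm exit zone."""
        speed = 10.0
        reach = 42.5 - 2.0 - 4.0  # centre x where the nose hits the zone edge
        n_end = math.ceil(reach / speed * RATE)
        t = np.arange(n_end + 1) * DT
        x = speed * t
        center = np.column_stack([x, np.zeros_like(x)])
        nose = center + [4.0, 0.0]
        tail = center - [4.0, 0.0]
        track = Track(t=t, center=center, nose=nose, tail=tail)
        trial = TrialRecord(subject_id="s", true_exit_hole=3)
        m = compute_trial_metrics(track, trial, arena)
        assert m.escaped
        assert m.latency_s == pytest.approx(reach / speed, abs=DT)
        assert m.n_errors == 0
        assert m.distance_cm == pytest.approx(x[-1], rel=1e-6)
        assert m.mean_speed_cm_s == pytest.approx(speed, rel=1e-2)
        assert m.heading_to_exit_deg == pytest.approx(0.0, abs=1e-6)
        assert m.rotations == 0

    def test_cutoff_track_censored(self, arena):
        n = 1801
        t = np.arange(n) * DT
        center = np.tile([10.0, 0.0], (n, 1))
        track = Track(t=t, center=center, nose=center + [4, 0], tail=center - [4, 0])
        trial = TrialRecord(subject_id="s", true_exit_hole=3)
        m = compute_trial_metrics(track, trial, arena)
        assert not m.escaped
        assert m.latency_s == 60.0

    def test_escaped_iff_latency_below_cutoff(self, arena):
        for seed in range(6):
            rng = trial_rng(seed, "esc", 3)
            trial = TrialRecord(subject_id="esc", true_exit_hole=7)
            policy = ["spatial", "chain", "futile"][seed % 3]
            track, _ = simulate_trial(policy, arena, trial, SimConfig(), rng)
            m = compute_trial_metrics(track, trial, arena)
            assert m.escaped == (m.latency_s < trial.cutoff_s)
            assert (not m.escaped) == (m.latency_s == trial.cutoff_s)
            assert m.periphery_s <= m.latency_s + 1e-9
            disp = np.hypot(*(track.center[-1] - track.center[0]))
            assert m.distance_cm >= disp - 0.1

    def test_early_end_outside_exit_is_malformed(self, arena):
        n = 30
        t = np.arange(n) * DT
        center = np.tile([5.0, 5.0], (n, 1))
        track = Track(t=t, center=center, nose=center + [4, 0], tail=center - [4, 0])
        trial = TrialRecord(subject_id="s", true_exit_hole=3)
        with pytest.raises(MalformedTrialError):
            compute_trial_metrics(track, trial, arena)

    def test_stationary_60s_zero_distance(self, arena):
        rng = np.random.default_rng(2)
        n = 1801
        t = np.arange(n) * DT
        center = np.tile([0.0, 0.0], (n, 1)) + rng.normal(0, 0.005, (n, 2))
        track = Track(t=t, center=center, nose=center + [4, 0], tail=center - [4, 0])
        trial = TrialRecord(subject_id="s", true_exit_hole=3)
        m = compute_trial_metrics(track, trial, arena)
        assert m.distance_cm == 0.0
        assert m.mean_speed_cm_s == 0.0

    def test_probe_trial_has_no_errors(self, arena):
        rng = trial_rng(9, "probe", 13)
        trial = TrialRecord(subject_id="probe", true_exit_hole=11, probe=True)
        track, _ = simulate_trial("futile", arena, trial, SimConfig(), rng)
        m = compute_trial_metrics(track, trial, arena)
        assert not m.escaped
        assert m.latency_s == trial.cutoff_s
        assert m.n_errors is None

    def test_post_cutoff_samples_truncated(self, arena):
        """Guided portion after the cutoff must not leak into the metrics."""
        n = 2101  # 70 s at 30 Hz
        t = np.arange(n) * DT
        x = np.linspace(0, 30, n)
        center = np.column_stack([x, np.zeros(n)])
        track = Track(t=t, center=center, nose=center + [4, 0], tail=center - [4, 0])
        trial = TrialRecord(subject_id="s", true_exit_hole=3)
        m = compute_trial_metrics(track, trial, arena)
        assert not m.escaped and m.latency_s == 60.0
        assert m.distance_cm <= 30.0 * (60.0 / 70.0) + 0.1
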