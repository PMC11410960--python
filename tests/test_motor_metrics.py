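"""Locomotor metric computations on hand-built and simulated tracks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenoscreen.motor_metrics import (
    CentroidTrack, MotorConfig, PhaseSchedule, compute_motor_metrics,
    detect_bouts, displacement_series, qc_tracking, speed_histogram,
    vmr_phase_endpoint,
)
from phenoscreen.synthetic_data import (CTRL_BOUTS, TAU_BOUTS,
                                        simulate_bout_track)


def track_from_speeds(speeds, frame_rate=1.0, mm_per_unit=1.0):
    """Build a straight-line track whose instantaneous speeds equal the
    given series."""
    disp = np.asarray(speeds, dtype=float) / frame_rate
    x = np.concatenate(([0.0], np.cumsum(disp))) / mm_per_unit
    return CentroidTrack("toy", frame_rate, mm_per_unit,
                         np.column_stack([x, np.zeros_like(x)]))


class TestDisplacementSeries:
    def test_stationary_fish_all_zero(self):
        track = CentroidTrack("still", 25.0, 1.0, np.zeros((100, 2)))
        disp, speed, valid = displacement_series(track)
        assert np.all(disp == 0) and np.all(speed == 0) and valid.all()

    def test_constant_velocity_identity(self):
        # 4 mm/s at 25 Hz: every displacement 0.16 mm
        t = np.arange(50) / 25.0
        pos = np.column_stack([4.0 * t, np.zeros_like(t)])
        disp, speed, _ = displacement_series(CentroidTrack("c", 25.0, 1.0, pos))
        assert np.allclose(disp, 0.16) and np.allclose(speed, 4.0)

    def test_hand_computed_euclidean(self):
        pos = np.array([[0, 0], [3, 4], [3, 4]], dtype=float)
        disp, _, _ = displacement_series(CentroidTrack("t", 1.0, 1.0, pos))
        assert np.allclose(disp, [5.0, 0.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            CentroidTrack("x", 1.0, 1.0, np.zeros((1, 2)))

    def test_invalid_frames_flagged(self):
        pos = np.array([[0, 0], [1, 0], [2, 0], [3, 0]], dtype=float)
        mask = np.array([True, False, True, True])
        disp, _, valid = displacement_series(
            CentroidTrack("t", 1.0, 1.0, pos, mask))
        assert not valid[0] and not valid[1] and valid[2]
        assert np.isnan(disp[0]) and np.isnan(disp[1]) and disp[2] == 1.0


class TestDetectBouts:
    def test_all_zero_speed_empty(self):
        assert detect_bouts(np.zeros(100), 25.0) == []

    def test_single_pulse_identity(self):
        # 0.4 s rectangular pulse at 10 mm/s, 25 Hz
        speed = np.zeros(100)
        speed[20:30] = 10.0
        bouts = detect_bouts(speed, 25.0, activity_threshold=1.0)
        assert bouts == [(20, 30)]
        assert (bouts[0][1] - bouts[0][0]) / 25.0 == pytest.approx(0.4)

    def test_short_gap_merged(self):
        # two pulses [2, 4) and [6, 8) at 10 Hz with min_gap 0.5 s
        # (5 frames): the 2-frame gap merges into one 6-frame bout
        speed = np.zeros(20)
        speed[2:4] = 5.0
        speed[6:8] = 5.0
        bouts = detect_bouts(speed, 10.0, 1.0, min_gap=0.5, min_duration=0.1)
        assert bouts == [(2, 8)]

    def test_long_gap_not_merged(self):
        speed = np.zeros(40)
        speed[2:6] = 5.0
        speed[20:24] = 5.0
        bouts = detect_bouts(speed, 10.0, 1.0, min_gap=0.5, min_duration=0.1)
        assert len(bouts) == 2

    def test_min_duration_gate(self):
        speed = np.zeros(50)
        speed[10] = 5.0  # 1 frame = 0.04 s at 25 Hz
        assert detect_bouts(speed, 25.0, 1.0, min_duration=0.08) == []


class TestComputeMotorMetrics:
    def test_hand_enumerated_toy(self):
        # speeds [0,0,5,5,0,0,0,6,6,0] at 1 Hz: 2 bouts, 40% active,
        # IMI 3 s, active speed 5.5
        track = track_from_speeds([0, 0, 5, 5, 0, 0, 0, 6, 6, 0])
        m = compute_motor_metrics(track, MotorConfig(min_gap=0.5,
                                                     min_duration=0.5))
        assert m.n_bouts == 2
        assert m.pct_time_active == pytest.approx(40.0)
        assert m.imi_mean == pytest.approx(3.0)
        assert m.active_speed == pytest.approx(5.5)
        assert m.bout_duration_mean == pytest.approx(2.0)

    def test_uninterrupted_bout(self):
        track = track_from_speeds([5.0] * 20)
        m = compute_motor_metrics(track)
        assert m.pct_time_active == 100.0
        assert np.isnan(m.imi_mean)
        assert m.active_speed == pytest.approx(m.mean_speed)

    def test_no_bouts_undefined_markers(self):
        m = compute_motor_metrics(track_from_speeds([0.0] * 20))
        assert m.n_bouts == 0
        assert np.isnan(m.imi_mean) and np.isnan(m.bout_duration_mean)
        assert m.pct_time_active == 0.0

    def test_mean_speed_decomposition(self, ctrl_track_1h):
        m = compute_motor_metrics(ctrl_track_1h)
        _, speed, valid = displacement_series(ctrl_track_1h)
        f_active = m.pct_time_active / 100.0
        inactive = np.nanmean(speed) - f_active * m.active_speed
        # mean = f*active + (1-f)*inactive by construction
        inactive_speed = inactive / (1.0 - f_active)
        recomposed = f_active * m.active_speed + (1 - f_active) * inactive_speed
        assert recomposed == pytest.approx(m.mean_speed, rel=1e-9)

    def test_total_distance_mean_speed_identity(self, ctrl_track_1h):
        m = compute_motor_metrics(ctrl_track_1h)
        assert m.mean_speed == pytest.approx(
            m.total_distance / ctrl_track_1h.duration_s, rel=1e-6)

    def test_recovers_planted_parameters(self, recovery_track_1h):
        """IMI, bout duration, and active speed recover the generator's
        planted values within 3 simulation SEs over a 1-h session."""
        m = compute_motor_metrics(recovery_track_1h)
        p = recovery_track_1h.meta["params"]
        n = m.n_bouts
        se_imi = (p.imi_mean / np.sqrt(p.imi_shape)) / np.sqrt(n - 1)
        assert abs(m.imi_mean - p.imi_mean) < 3 * se_imi
        sd_dur = p.dur_mean * np.sqrt(np.expm1(p.dur_sigma ** 2))
        assert abs(m.bout_duration_mean - p.dur_mean) < \
            3 * sd_dur / np.sqrt(n) + 1.0 / recovery_track_1h.frame_rate
        assert abs(m.active_speed - p.speed_mean) < \
            3 * p.speed_sigma / np.sqrt(n) + 0.15 * p.speed_sigma

    def test_rigid_motion_invariance(self, ctrl_track_1h):
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = CentroidTrack("rot", ctrl_track_1h.frame_rate,
                              ctrl_track_1h.mm_per_unit,
                              ctrl_track_1h.positions @ rot.T + [5.0, -2.0])
        m0 = compute_motor_metrics(ctrl_track_1h)
        m1 = compute_motor_metrics(moved)
        assert m1.mean_speed == pytest.approx(m0.mean_speed, rel=1e-9)
        assert m1.n_bouts == m0.n_bouts
        assert m1.pct_time_active == pytest.approx(m0.pct_time_active)


class TestQCTracking:
    def test_clean_track_passes(self):
        track = CentroidTrack("ok", 25.0, 1.0, np.zeros((200, 2)))
        assert qc_tracking(track)

    def test_six_percent_invalid_fails(self):
        mask = np.ones(200, dtype=bool)
        mask[:12] = False  # 6%
        track = CentroidTrack("bad", 25.0, 1.0, np.zeros((200, 2)), mask)
        assert not qc_tracking(track)

    def test_exactly_five_percent_passes(self):
        # the exclusion rule is strictly greater-than 5%
        mask = np.ones(200, dtype=bool)
        mask[:10] = False  # exactly 5%
        track = CentroidTrack("edge", 25.0, 1.0, np.zeros((200, 2)), mask)
        assert qc_tracking(track)


class TestSpeedHistogram:
    def test_stationary_all_zero(self):
        track = CentroidTrack("s", 25.0, 1.0, np.zeros((50, 2)))
        h = speed_histogram(track, np.linspace(0.001, 30, 31))
        assert np.all(h.distance_per_bin == 0)

    def test_constant_speed_single_bin(self):
        # exact 4 mm/frame at 1 Hz so every instantaneous speed is 4.0
        x = 4.0 * np.arange(100)
        track = CentroidTrack("c", 1.0, 1.0,
                              np.column_stack([x, np.zeros_like(x)]))
        edges = np.arange(0, 31, 1.0)
        h = speed_histogram(track, edges)
        assert h.distance_per_bin[4] == pytest.approx(h.distance_per_bin.sum())

    def test_hand_binning_and_conservation(self):
        track = track_from_speeds([1.0, 3.0, 3.0])
        edges = np.array([0.0, 2.0, 4.0])
        h = speed_histogram(track, edges)
        assert h.distance_per_bin[0] == pytest.approx(1.0)
        assert h.distance_per_bin[1] == pytest.approx(6.0)
        m = compute_motor_metrics(track)
        assert h.distance_per_bin.sum() == pytest.approx(m.total_distance)


class TestVMR:
    def schedule(self):
        return PhaseSchedule([(0.0, 10.0, "dark"), (10.0, 20.0, "light"),
                              (20.0, 30.0, "dark"), (30.0, 40.0, "light")])

    def test_constant_speed_any_phase(self):
        track = track_from_speeds([2.0] * 40)
        out = vmr_phase_endpoint([track], self.schedule(), "light")
        assert out[0] == pytest.approx(2.0)

    def test_fish_active_only_in_dark(self):
        speeds = np.zeros(40)
        speeds[:10] = 5.0
        speeds[20:30] = 5.0
        track = track_from_speeds(speeds)
        assert vmr_phase_endpoint([track], self.schedule(), "light")[0] == 0.0
        assert vmr_phase_endpoint([track], self.schedule(), "dark")[0] == \
            pytest.approx(5.0)

    def test_missing_phase_rejected(self):
        sched = PhaseSchedule([(0.0, 40.0, "light")])
        with pytest.raises(ValueError):
            vmr_phase_endpoint([track_from_speeds([1.0] * 40)], sched, "dark")

    def test_tau_slower_than_sibling_in_light(self):
        """Group light-phase means order sib > tau in nearly all paired
        seeds (direction of the hypokinetic phenotype)."""
        wins = 0
        schedule = [(300.0, "light")]
        sched = PhaseSchedule([(0.0, 300.0, "light")])
        for s in range(100):
            tau = simulate_bout_track(TAU_BOUTS, schedule, 25.0, seed=3000 + s)
            sib = simulate_bout_track(CTRL_BOUTS, schedule, 25.0,
                                      seed=6000 + s)
            vt = vmr_phase_endpoint([tau], sched, "light")[0]
            vs = vmr_phase_endpoint([sib], sched, "light")[0]
            wins += vs > vt
        assert wins >= 95

    def test_default_vmr_schedule_shape(self):
        sched = PhaseSchedule.vmr_default()
        assert sched.duration_s == pytest.approx(60 * 60 + 6 * 600)
        labels = [seg[2] for seg in sched.segments]
        assert labels == ["light"] + ["dark", "light"] * 3


@settings(derandomize=True, max_examples=25)
@given(scale=st.floats(0.1, 10.0))
def test_metrics_scale_with_calibration(scale):
    """Distances and speeds scale linearly with mm_per_unit."""
    rng = np.random.default_rng(7)
    pos = np.cumsum(rng.normal(0, 0.4, size=(200, 2)), axis=0)
    base = compute_motor_metrics(CentroidTrack("a", 25.0, 1.0, pos))
    scaled = compute_motor_metrics(
        CentroidTrack("b", 25.0, scale, pos / scale))
    assert scaled.mean_speed == pytest.approx(base.mean_speed, rel=1e-9)
    assert scaled.total_distance == pytest.approx(base.total_distance,
                                                  rel=1e-9)
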