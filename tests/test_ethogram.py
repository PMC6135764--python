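"""Binning, state labels, jump/pause detection and trial classification."""

import numpy as np
import pytest

import loomassay as la
from loomassay.ethogram import (
    bin_trajectory,
    build_ethogram,
    classify_bins,
    detect_jumps,
    detect_pause,
    opto_success,
    startle_profile,
    window_state,
)


def make_traj(speed, motion=None, fr=60.0):
    """Trajectory with a prescribed speed series (straight-line path)."""
    speed = np.asarray(speed, float)
    x = np.concatenate([[0.0], np.cumsum(speed[1:]) / fr])
    traj = la.Trajectory.from_positions(x, np.zeros_like(x), fr)
    traj.speed_mm_s = speed  # prescribe frame 0 as well
    if motion is not None:
        traj.motion_px = np.asarray(motion, float)
    return traj


def pause_oracle(speed, i0, i1, thresh, min_frames):
    """Exhaustive scan for the first run of sub-threshold frames."""
    for s in range(i0, max(i0, i1 - min_frames + 1)):
        if np.all(speed[s : s + min_frames] < thresh):
            return True, s
    return False, None


class TestBinning:
    def test_constant_speed(self, etho_cfg):
        traj = make_traj(np.full(300, 6.0))
        binned = bin_trajectory(traj, etho_cfg)
        assert len(binned.speed_mm_s) == 10
        np.testing.assert_allclose(binned.speed_mm_s, 6.0)

    def test_ten_minute_session_bin_count(self, looming_session, etho_cfg):
        traj, _ = looming_session
        assert len(bin_trajectory(traj, etho_cfg).speed_mm_s) == 1200

    def test_alternating_frames_average(self, etho_cfg):
        speed = np.tile([0.0, 8.0], 60)
        traj = make_traj(speed)
        binned = bin_trajectory(traj, etho_cfg)
        np.testing.assert_allclose(binned.speed_mm_s, 4.0)

    def test_partial_bin_dropped_and_short_error(self, etho_cfg):
        assert len(bin_trajectory(make_traj(np.zeros(75)), etho_cfg).speed_mm_s) == 2
        with pytest.raises(ValueError):
            bin_trajectory(make_traj(np.zeros(10)), etho_cfg)

    def test_motion_rate_units(self, etho_cfg):
        traj = make_traj(np.zeros(60), motion=np.full(60, 2.0))
        binned = bin_trajectory(traj, etho_cfg)
        np.testing.assert_allclose(binned.motion_px_s, 120.0)  # 2 px/frame * 60 Hz


class TestClassifyBins:
    @pytest.mark.parametrize(
        "speed,motion,label",
        [
            (5.0, 300.0, "walk"),
            (0.5, 20.0, "freeze"),
            (1.0, 400.0, "groom"),
            (4.0, 40.0, "freeze"),  # walking requires strictly > 4 mm/s
        ],
    )
    def test_threshold_rules(self, etho_cfg, speed, motion, label):
        traj = make_traj(np.full(30, speed), motion=np.full(30, motion / 60.0))
        binned = bin_trajectory(traj, etho_cfg)
        assert classify_bins(binned, etho_cfg)[0] == label

    def test_determinism(self, looming_session, etho_cfg):
        traj, _ = looming_session
        a = build_ethogram(traj, etho_cfg)
        b = build_ethogram(traj, etho_cfg)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.jump_times_s, b.jump_times_s)

    def test_jump_bin_never_freeze(self, etho_cfg):
        speed = np.zeros(60)
        speed[10] = 100.0  # jump spike in an otherwise still bin
        traj = make_traj(speed, motion=np.zeros(60))
        etho = build_ethogram(traj, etho_cfg)
        assert etho.labels[0] == "walk"
        assert etho.labels[1] == "freeze"


class TestJumps:
    def test_single_frame_spike(self, etho_cfg):
        speed = np.zeros(100)
        speed[40] = 80.0
        times = detect_jumps(make_traj(speed), etho_cfg)
        assert len(times) == 1
        assert times[0] == pytest.approx(40 / 60.0)

    def test_exact_threshold_not_a_jump(self, etho_cfg):
        speed = np.zeros(100)
        speed[40] = 75.0
        assert len(detect_jumps(make_traj(speed), etho_cfg)) == 0

    def test_consecutive_frames_merge(self, etho_cfg):
        speed = np.zeros(100)
        speed[40:43] = 90.0
        times = detect_jumps(make_traj(speed), etho_cfg)
        assert len(times) == 1

    def test_matches_run_length_oracle(self, etho_cfg):
        rng = np.random.default_rng(8)
        for _ in range(50):
            speed = rng.choice([0.0, 10.0, 80.0, 120.0], size=200,
                               p=[0.5, 0.3, 0.1, 0.1])
            above = speed > 75.0
            want = [
                k for k in range(200) if above[k] and (k == 0 or not above[k - 1])
            ]
            got = detect_jumps(make_traj(speed), etho_cfg)
            np.testing.assert_allclose(got, np.asarray(want) / 60.0)


class TestPause:
    def test_ten_frames_is_a_pause(self, etho_cfg):
        speed = np.full(200, 8.0)
        speed[63:73] = 2.0  # 10 frames starting 50 ms after onset
        paused, onset = detect_pause(make_traj(speed), 1.0, etho_cfg)
        assert paused
        assert onset == pytest.approx(63 / 60.0)

    def test_nine_frames_is_not(self, etho_cfg):
        speed = np.full(200, 8.0)
        speed[63:72] = 2.0
        paused, onset = detect_pause(make_traj(speed), 1.0, etho_cfg)
        assert not paused and onset is None

    def test_matches_exhaustive_oracle(self, etho_cfg):
        rng = np.random.default_rng(9)
        fr = 60.0
        for _ in range(300):
            speed = rng.uniform(0.0, 8.0, size=150)
            traj = make_traj(speed)
            onset = 0.5
            i0 = int(onset * fr)
            i1 = min(150, i0 + int(etho_cfg.pause_window_s * fr))
            want = pause_oracle(speed, i0, i1, 4.0, 10)
            got = detect_pause(traj, onset, etho_cfg)
            assert got[0] == want[0]
            if want[0]:
                assert got[1] == pytest.approx(want[1] / fr)

    def test_window_truncated_at_recording_end(self, etho_cfg):
        speed = np.full(70, 8.0)
        speed[60:70] = 1.0
        paused, _ = detect_pause(make_traj(speed), 1.0, etho_cfg)
        assert paused


class TestOrientation:
    def test_cardinal_directions(self):
        fr = 60.0
        n = 60
        toward = la.Trajectory.from_positions(np.zeros(n), np.arange(n) * 0.1, fr)
        away = la.Trajectory.from_positions(np.zeros(n), -np.arange(n) * 0.1, fr)
        assert la.path_orientation(toward, 0.0, 0.9) == pytest.approx(90.0)
        assert la.path_orientation(away, 0.0, 0.9) == pytest.approx(270.0)

    def test_zero_displacement_undefined(self):
        still = la.Trajectory.from_positions(np.zeros(60), np.zeros(60), 60.0)
        assert np.isnan(la.path_orientation(still, 0.0, 0.9))


class TestTrialClassification:
    def _session(self, seed=11):
        schedule = la.build_schedule("open_loop_looming")
        return la.simulate_fly(la.AgentParams(), schedule, 600.0, seed=seed)

    def test_frozen_before_and_after_is_freeze(self, etho_cfg):
        # frozen fly (speed 0, sub-threshold motion) through the whole trial
        n = 600
        traj = make_traj(np.zeros(n), motion=np.full(n, 0.2))
        etho = build_ethogram(traj, etho_cfg)
        trial = la.classify_looming_trial(traj, etho, 5.0, etho_cfg)
        assert trial.pre_state == "freeze"
        assert trial.response == "freeze"

    def test_jump_takes_precedence(self, etho_cfg):
        speed = np.full(600, 8.0)
        speed[312] = 100.0  # 200 ms after a 5.0 s onset
        traj = make_traj(speed, motion=np.full(600, 10.0))
        etho = build_ethogram(traj, etho_cfg)
        trial = la.classify_looming_trial(traj, etho, 5.0, etho_cfg)
        assert trial.response == "jump"

    def test_flee_pause_composition(self, etho_cfg):
        speed = np.full(600, 9.0)
        speed[305:317] = 1.0  # 12-frame stop shortly after onset
        traj = make_traj(speed, motion=np.full(600, 10.0))
        etho = build_ethogram(traj, etho_cfg)
        trial = la.classify_looming_trial(traj, etho, 5.0, etho_cfg)
        assert trial.response == "flee_pause"
        assert trial.paused and trial.pause_onset_s == pytest.approx(305 / 60.0)

    def test_walk_through_is_flee_no_pause(self, etho_cfg):
        traj = make_traj(np.full(600, 9.0), motion=np.full(600, 10.0))
        etho = build_ethogram(traj, etho_cfg)
        trial = la.classify_looming_trial(traj, etho, 5.0, etho_cfg)
        assert trial.response == "flee_no_pause"

    def test_insufficient_margin_skipped(self, etho_cfg):
        traj = make_traj(np.full(120, 9.0))
        with pytest.raises(ValueError):
            la.classify_looming_trial(traj, build_ethogram(traj, etho_cfg), 0.2,
                                      etho_cfg)
        assert la.classify_trials(traj, [0.2], etho_cfg) == []

    def test_one_label_per_trial_partition(self, etho_cfg):
        traj, gt = self._session()
        trials = la.classify_trials(traj, gt.looming_onsets(), etho_cfg)
        assert len(trials) == 20
        from loomassay.ethogram import RESPONSES

        counts = {r: sum(t.response == r for t in trials) for r in RESPONSES}
        assert sum(counts.values()) == len(trials)


class TestStartleProfile:
    def test_peak_at_end_of_expansion(self, etho_cfg):
        # a fly that certainly freezes at the first looming, then startles
        import dataclasses

        params = dataclasses.replace(
            la.AgentParams(), p_freeze_max=1.0, freeze_speed_mid=1e6, p_jump=0.0,
            freeze_long_weight=1.0, freeze_long_mean_s=1e4,
        )
        schedule = la.build_schedule("open_loop_looming")
        traj, gt = la.simulate_fly(params, schedule, 600.0, seed=4)
        prof = startle_profile([traj], [gt.looming_onsets()], etho_cfg)
        assert prof.n_trials >= 10
        peak = prof.rel_time_s[np.argmax(prof.mean_motion_px)]
        assert 0.3 <= peak <= 0.5

    def test_no_startle_flat_profile(self, etho_cfg):
        n = 1200
        traj = make_traj(np.zeros(n), motion=np.zeros(n))
        prof = startle_profile([traj], [[5.0]], etho_cfg)
        assert prof.n_trials == 1
        assert np.all(prof.mean_motion_px == 0)
        assert np.all(prof.sem_motion_px == 0)  # single trial: sem 0

    def test_no_qualifying_trials_empty(self, etho_cfg):
        traj = make_traj(np.full(1200, 9.0), motion=np.full(1200, 10.0))
        prof = startle_profile([traj], [[5.0]], etho_cfg)
        assert prof.n_trials == 0
        assert prof.mean_motion_px.size == 0


class TestOptoSuccess:
    def _etho(self, freeze_bins, n_bins=10):
        labels = np.array(
            ["freeze" if i in freeze_bins else "walk" for i in range(n_bins)],
            dtype="<U6",
        )
        return la.Ethogram(np.arange(n_bins) * 0.5, labels, np.array([]), 0.5)

    def test_above_quarter_succeeds(self, etho_cfg):
        # stim [0.2, 2.2]: frozen bins give 0.5 + 0.2 = 0.7 s > 0.5 s
        etho = self._etho({1, 4})
        assert opto_success(etho, 0.2, 2.0, etho_cfg)

    def test_exactly_quarter_fails(self, etho_cfg):
        # stim [0.0, 2.0]: one frozen bin = 0.5 s, not strictly more than 25%
        etho = self._etho({1})
        assert not opto_success(etho, 0.0, 2.0, etho_cfg)

    def test_fully_frozen_succeeds(self, etho_cfg):
        etho = self._etho(set(range(10)))
        assert opto_success(etho, 0.5, 2.0, etho_cfg)

    def test_stim_outside_recording(self, etho_cfg):
        with pytest.raises(ValueError):
            opto_success(self._etho({1}), 4.5, 2.0, etho_cfg)


def test_window_state_matches_bin_rules(looming_session, etho_cfg):
    """Window classification on the bin grid equals the gridded labels."""
    traj, _ = looming_session
    etho = build_ethogram(traj, etho_cfg)
    for i in range(0, etho.n_bins, 97):
        t0 = etho.bin_start_s[i]
        assert window_state(traj, t0, t0 + 0.5, etho_cfg) == etho.labels[i]
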