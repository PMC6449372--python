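"""Kalman tracking: filter algebra, association, metrics, shedding."""

import numpy as np
import pytest
from itertools import permutations

from wakewatch import tracker as TK
from wakewatch.synthetic_data import SceneConfig, generate_wake_video
from wakewatch.tracker import (Track, TrackState, TrackerConfig, associate,
                               compile_tracks, estimate_shedding_frequency,
                               filter_tracks_by_duration, kalman_predict_update,
                               trajectory_metrics)
from wakewatch.video_detection import default_area_bounds, detect_sequence


class TestKalmanStep:
    def test_prediction_without_observation_advances_position(self):
        ts = TrackState(np.array([0.0, 0.0, 1.0, 1.0]), np.eye(4))
        out = kalman_predict_update(ts, dt=1.0)
        assert np.allclose(out.state[:2], [1.0, 1.0])

    def test_zero_observation_noise_snaps_to_observation(self):
        cfg = TrackerConfig(observation_noise=1e-9)
        ts = TrackState(np.array([0.0, 0.0, 1.0, 1.0]), np.eye(4))
        out = kalman_predict_update(ts, dt=1.0, observation=(5.0, -3.0),
                                    config=cfg)
        assert np.allclose(out.state[:2], [5.0, -3.0], atol=1e-6)

    def test_posterior_matches_matrix_arithmetic_oracle(self):
        # independent hand-coded 4x4 KF algebra on one fixed step
        cfg = TrackerConfig(process_noise=0.7, observation_noise=0.3)
        x0 = np.array([1.0, -2.0, 0.5, 0.25])
        P0 = np.diag([0.2, 0.3, 0.4, 0.5])
        z = np.array([1.7, -1.6])
        dt = 0.2

        F = np.eye(4); F[0, 2] = F[1, 3] = dt
        q = 0.7
        Q = q * np.array([[dt**3/3, 0, dt**2/2, 0],
                          [0, dt**3/3, 0, dt**2/2],
                          [dt**2/2, 0, dt, 0],
                          [0, dt**2/2, 0, dt]])
        H = np.zeros((2, 4)); H[0, 0] = H[1, 1] = 1.0
        R = 0.3**2 * np.eye(2)
        xp = F @ x0
        Pp = F @ P0 @ F.T + Q
        K = Pp @ H.T @ np.linalg.inv(H @ Pp @ H.T + R)
        x_exp = xp + K @ (z - H @ xp)
        P_exp = (np.eye(4) - K @ H) @ Pp

        out = kalman_predict_update(TrackState(x0, P0), dt, tuple(z), cfg)
        assert np.allclose(out.state, x_exp, atol=1e-10)
        assert np.allclose(out.covariance, (P_exp + P_exp.T) / 2, atol=1e-10)

    def test_invalid_inputs_rejected(self):
        ts = TrackState(np.zeros(4), np.eye(4))
        with pytest.raises(ValueError):
            kalman_predict_update(ts, dt=0.0)
        with pytest.raises(ValueError, match="positive definite"):
            kalman_predict_update(
                TrackState(np.zeros(4), -np.eye(4)), dt=1.0)


class TestAssociate:
    def test_single_pair_inside_gate_matches(self):
        m, ut, ud = associate([np.array([0.0, 0.0])],
                              [np.array([0.5, 0.0])], gate_radius=1.0)
        assert m == [(0, 0)] and ut == [] and ud == []

    def test_detection_outside_gate_left_unmatched(self):
        m, ut, ud = associate([np.array([0.0, 0.0])],
                              [np.array([5.0, 0.0])], gate_radius=1.0)
        assert m == [] and ut == [0] and ud == [0]

    @pytest.mark.parametrize("n,seed", [(3, 0), (4, 1), (4, 2), (3, 3)])
    def test_assignment_equals_brute_force_minimum(self, n, seed):
        rng = np.random.default_rng(seed)
        tracks = [rng.uniform(0, 10, 2) for _ in range(n)]
        dets = [rng.uniform(0, 10, 2) for _ in range(n)]
        gate = 50.0
        m, _, _ = associate(tracks, dets, gate)
        cost = {(r, c): np.linalg.norm(tracks[r] - dets[c])
                for r in range(n) for c in range(n)}
        best = min(permutations(range(n)),
                   key=lambda p: sum(cost[(r, p[r])] for r in range(n)))
        got = sum(cost[rc] for rc in m)
        expect = sum(cost[(r, best[r])] for r in range(n))
        assert np.isclose(got, expect)


class TestCompileTracks:
    def test_single_bird_yields_one_accurate_track(self):
        cfg = SceneConfig(n_birds=1, n_foam_patches=0, glint_rate=0.0,
                          duration=3.0, fps=10.0, seed=5)
        seq, gt = generate_wake_video(cfg)
        lo, hi = default_area_bounds(cfg.bird_size_px)
        dets = detect_sequence(seq.frames, diff_threshold=25,
                               min_area=lo, max_area=hi)
        tracks = compile_tracks(dets, fps=cfg.fps,
                                scale=cfg.ground_sample_distance,
                                config=TrackerConfig(gate_radius=2.0))
        tracks = [t for t in tracks if len(t.points) > 5]
        assert len(tracks) == 1
        errs = []
        for (t, x, y) in tracks[0].points:
            k = int(round(t * cfg.fps))
            p = gt.bird_positions(k)[0]
            errs.append(np.hypot(x - p[0], y - p[1]))
        rmse = np.sqrt(np.mean(np.square(errs)))
        assert rmse < 1.0 * cfg.ground_sample_distance  # < 1 rendered pixel

    def test_crossing_birds_keep_identities_with_tight_gate(self):
        # two synthetic detection streams crossing at frame 10; the gate is
        # smaller than their separation at the crossing frame
        from wakewatch.video_detection import Detection
        frames = []
        for k in range(21):
            a = (0.3 * k, 10.0)                       # straight along y=10
            b = (0.3 * k + 1.0, 10.0 + 0.4 * (10 - k))  # crosses y=10 at k=10
            frames.append([
                Detection(k, a, 5, (0, 0, 1, 1), 0.0),
                Detection(k, b, 5, (0, 0, 1, 1), 0.0),
            ])
        tracks = compile_tracks(frames, fps=1.0, scale=1.0,
                                config=TrackerConfig(gate_radius=0.6,
                                                     observation_noise=0.01))
        long = [t for t in tracks if len(t.points) >= 15]
        assert len(long) == 2
        # identities preserved: the crossing track ends below y=10, the
        # straight one stays on it
        ys = sorted(t.points[-1][2] for t in long)
        assert ys[0] < 7.0 and np.isclose(ys[1], 10.0, atol=0.2)

    def test_empty_stream_gives_empty_trackset(self):
        assert compile_tracks([[], [], []], fps=10.0, scale=0.1) == []

    def test_missing_scale_or_fps_rejected(self):
        with pytest.raises(ValueError):
            compile_tracks([[]], fps=0.0, scale=0.1)
        with pytest.raises(ValueError):
            compile_tracks([[]], fps=10.0, scale=None)


class TestDurationFilter:
    def test_strictly_greater_than_threshold(self):
        def track_of(duration):
            n = max(int(duration * 100) + 1, 2)
            ts = np.linspace(0, duration, n)
            return Track(0, [(t, 0.0, 0.0) for t in ts])
        tracks = [track_of(1.9), track_of(2.0), track_of(2.04)]
        kept = filter_tracks_by_duration(tracks, 2.0)
        assert len(kept) == 1
        assert np.isclose(kept[0].duration, 2.04)

    def test_zero_threshold_keeps_all_multipoint_tracks(self):
        tracks = [Track(0, [(0, 0, 0), (1, 1, 1)]), Track(1, [(0, 0, 0)])]
        kept = filter_tracks_by_duration(tracks, 0.0)
        assert [t.id for t in kept] == [0]

    def test_filter_idempotent_and_count_matches_enumeration(self):
        rng = np.random.default_rng(4)
        tracks = []
        durations = rng.uniform(0.5, 4.0, 20)
        for i, d in enumerate(durations):
            tracks.append(Track(i, [(0.0, 0, 0), (float(d), 1, 1)]))
        kept = filter_tracks_by_duration(tracks, 2.0)
        assert len(kept) == int(np.sum(durations > 2.0))
        assert filter_tracks_by_duration(kept, 2.0) == kept


class TestTrajectoryMetrics:
    def test_straight_track(self):
        tr = Track(0, [(t, t * 2.0, 0.0) for t in np.linspace(0, 1, 11)])
        m = trajectory_metrics(tr)
        assert np.isclose(m.sinuosity, 1.0)
        assert np.allclose(m.turning_angles, 0.0)
        assert np.isclose(m.mean_speed, 2.0)

    def test_semicircle_sinuosity_is_half_pi(self):
        th = np.linspace(0, np.pi, 100)
        tr = Track(0, [(t, np.cos(a), np.sin(a))
                       for t, a in zip(np.linspace(0, 1, 100), th)])
        m = trajectory_metrics(tr)
        assert np.isclose(m.sinuosity, np.pi / 2, rtol=1e-3)

    def test_speed_from_displacement_over_time(self):
        tr = Track(0, [(0.0, 0, 0), (0.5, 2.0, 0.0)])
        assert np.isclose(trajectory_metrics(tr).mean_speed, 4.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            trajectory_metrics(Track(0, [(0.0, 0, 0)]))

    def test_metrics_invariant_to_rigid_motion(self):
        rng = np.random.default_rng(7)
        pts = np.cumsum(rng.normal(0, 1, (20, 2)), axis=0)
        t = np.arange(20, dtype=float)
        tr = Track(0, [(tt, x, y) for tt, (x, y) in zip(t, pts)])
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = pts @ R.T + np.array([100.0, -50.0])
        tr2 = Track(1, [(tt, x, y) for tt, (x, y) in zip(t, moved)])
        m1, m2 = trajectory_metrics(tr), trajectory_metrics(tr2)
        assert np.isclose(m1.path_length, m2.path_length)
        assert np.isclose(m1.sinuosity, m2.sinuosity)
        assert np.allclose(m1.turning_angles, m2.turning_angles, atol=1e-9)


class TestSheddingFrequency:
    def test_twelve_crossings_in_a_minute(self):
        tracks = [Track(i, [(0.0, 0.0, 0.0), (1.0, 10.0, 0.0)])
                  for i in range(12)]
        assert estimate_shedding_frequency(tracks, 60.0, line_x=5.0) == 12.0

    def test_reentry_of_same_track_counted_once(self):
        # crosses forward, drifts back, crosses forward again
        tr = Track(0, [(0, 0, 0), (1, 10, 0), (2, 0, 0), (3, 10, 0)])
        other = Track(1, [(0, 0, 0), (1, 10, 0)])
        est = estimate_shedding_frequency([tr, other], 60.0, line_x=5.0)
        assert est == 2.0  # 2 distinct tracks, not 3 crossings

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            estimate_shedding_frequency([], 0.0, line_x=0.0)
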