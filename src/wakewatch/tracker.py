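"""Multi-target Kalman tracking of tern detections and trajectory metrics.

A constant-velocity Kalman filter per target, globally cost-minimal
(Hungarian) gated association, track spawning/closing bookkeeping, the strict
"over 2 s" duration filter, per-track metrics (speed, turning angles,
sinuosity as path/chord ratio), and a surface-eddy shedding-frequency
estimator that counts tracked foam features crossing a cross-stream line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .video_detection import Detection

__all__ = [
    "TrackState",
    "Track",
    "TrackerConfig",
    "TrajectoryMetrics",
    "kalman_predict_update",
    "associate",
    "compile_tracks",
    "filter_tracks_by_duration",
    "trajectory_metrics",
    "estimate_shedding_frequency",
]


@dataclass
class TrackState:
    """Kalman state: (x, y, vx, vy) in metres / m s-1 with 4x4 covariance."""

    state: np.ndarray
    covariance: np.ndarray
    last_update: int = 0


@dataclass
class Track:
    id: int
    points: List[Tuple[float, float, float]] = field(default_factory=list)  # (t, x, y)
    n_misses: int = 0
    status: str = "active"

    @property
    def duration(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return self.points[-1][0] - self.points[0][0]


@dataclass
class TrackerConfig:
    process_noise: float = 1.0       # white-acceleration intensity q
    observation_noise: float = 0.05  # m, measurement SD per axis
    initial_velocity_sd: float = 10.0
    gate_radius: float = 2.0         # m
    max_misses: int = 5


def _cv_matrices(dt: float, q: float) -> Tuple[np.ndarray, np.ndarray]:
    F = np.array([[1, 0, dt, 0],
                  [0, 1, 0, dt],
                  [0, 0, 1, 0],
                  [0, 0, 0, 1]], dtype=float)
    # white-acceleration (continuous) process noise, standard CV discretisation
    dt2, dt3 = dt ** 2, dt ** 3
    Q = q * np.array([[dt3 / 3, 0, dt2 / 2, 0],
                      [0, dt3 / 3, 0, dt2 / 2],
                      [dt2 / 2, 0, dt, 0],
                      [0, dt2 / 2, 0, dt]], dtype=float)
    return F, Q


_H = np.array([[1, 0, 0, 0],
               [0, 1, 0, 0]], dtype=float)


def _check_pd(P: np.ndarray) -> None:
    if not np.allclose(P, P.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    if np.any(np.linalg.eigvalsh((P + P.T) / 2) <= 0):
        raise ValueError("covariance must be positive definite")


def kalman_predict_update(
    ts: TrackState,
    dt: float,
    observation: Optional[Tuple[float, float]] = None,
    config: TrackerConfig = TrackerConfig(),
) -> TrackState:
    """One constant-velocity predict step, plus update when observed."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    _check_pd(ts.covariance)
    F, Q = _cv_matrices(dt, config.process_noise)
    x = F @ ts.state
    P = F @ ts.covariance @ F.T + Q
    if observation is not None:
        R = config.observation_noise ** 2 * np.eye(2)
        z = np.asarray(observation, dtype=float)
        S = _H @ P @ _H.T + R
        K = P @ _H.T @ np.linalg.inv(S)
        x = x + K @ (z - _H @ x)
        P = (np.eye(4) - K @ _H) @ P
        P = (P + P.T) / 2
    return TrackState(state=x, covariance=P, last_update=ts.last_update + 1)


def associate(
    predicted: Sequence[np.ndarray],
    detections: Sequence[np.ndarray],
    gate_radius: float,
) -> Tuple[List[Tuple[int, int]], List[int], List[int]]:
    """Gated, globally cost-minimal one-to-one assignment (Hungarian).

    ``predicted`` and ``detections`` are (x, y) positions in metres.  Returns
    (matches, unmatched_track_idx, unmatched_detection_idx); pairs farther
    apart than the gate are never matched.
    """
    if gate_radius <= 0:
        raise ValueError("gate_radius must be > 0")
    nt, nd = len(predicted), len(detections)
    if nt == 0 or nd == 0:
        return [], list(range(nt)), list(range(nd))
    P = np.asarray(predicted, dtype=float).reshape(nt, 2)
    D = np.asarray(detections, dtype=float).reshape(nd, 2)
    cost = np.linalg.norm(P[:, None, :] - D[None, :, :], axis=2)
    BIG = 1e9
    gated = np.where(cost <= gate_radius, cost, BIG)
    rows, cols = linear_sum_assignment(gated)
    matches, ut, ud = [], set(range(nt)), set(range(nd))
    for r, c in zip(rows, cols):
        if gated[r, c] < BIG:
            matches.append((int(r), int(c)))
            ut.discard(r)
            ud.discard(c)
    return matches, sorted(ut), sorted(ud)


def compile_tracks(
    detections_per_frame: Sequence[Sequence[Detection]],
    fps: float,
    scale: float,
    config: TrackerConfig = TrackerConfig(),
) -> List[Track]:
    """Predict/associate/update over frames; positions reported in metres.

    New tracks spawn from unmatched detections; a track closes after
    ``max_misses`` consecutive misses.  ``scale`` is metres per pixel.
    """
    if fps is None or fps <= 0 or scale is None or scale <= 0:
        raise ValueError("fps and scale (m per pixel) are required and > 0")
    dt = 1.0 / fps
    tracks: List[Track] = []
    states: Dict[int, TrackState] = {}
    active: List[int] = []
    next_id = 0

    for k, dets in enumerate(detections_per_frame):
        t = k * dt
        obs = [np.array(d.centroid, dtype=float) * scale for d in dets]
        # predict
        predicted = {}
        for tid in active:
            ts = states[tid]
            F, Q = _cv_matrices(dt, config.process_noise)
            predicted[tid] = TrackState(F @ ts.state,
                                        F @ ts.covariance @ F.T + Q,
                                        ts.last_update)
        pred_pos = [predicted[tid].state[:2] for tid in active]
        matches, u_tr, u_det = associate(pred_pos, obs, config.gate_radius)

        matched_tids = set()
        for r, c in matches:
            tid = active[r]
            ts = predicted[tid]
            R = config.observation_noise ** 2 * np.eye(2)
            S = _H @ ts.covariance @ _H.T + R
            K = ts.covariance @ _H.T @ np.linalg.inv(S)
            x = ts.state + K @ (obs[c] - _H @ ts.state)
            P = (np.eye(4) - K @ _H) @ ts.covariance
            states[tid] = TrackState(x, (P + P.T) / 2, k)
            tr = tracks[tid]
            tr.points.append((t, float(x[0]), float(x[1])))
            tr.n_misses = 0
            matched_tids.add(tid)

        for r in u_tr:
            tid = active[r]
            states[tid] = predicted[tid]
            tracks[tid].n_misses += 1

        for c in u_det:
            x0 = np.array([obs[c][0], obs[c][1], 0.0, 0.0])
            P0 = np.diag([config.observation_noise ** 2,
                          config.observation_noise ** 2,
                          config.initial_velocity_sd ** 2,
                          config.initial_velocity_sd ** 2])
            states[next_id] = TrackState(x0, P0, k)
            tracks.append(Track(id=next_id,
                                points=[(t, float(obs[c][0]), float(obs[c][1]))]))
            next_id += 1

        active = []
        for tr in tracks:
            if tr.status == "active":
                if tr.n_misses > config.max_misses:
                    tr.status = "closed"
                else:
                    active.append(tr.id)
    return tracks


def filter_tracks_by_duration(tracks: Sequence[Track],
                              min_duration: float = 2.0) -> List[Track]:
    """Keep tracks whose duration strictly exceeds ``min_duration`` seconds."""
    if min_duration < 0:
        raise ValueError("min_duration must be >= 0")
    return [t for t in tracks if len(t.points) >= 2 and t.duration > min_duration]


@dataclass
class TrajectoryMetrics:
    duration: float
    path_length: float
    net_displacement: float
    sinuosity: float           # path / chord; inf flagged for tiny chords
    mean_speed: float
    turning_angles: np.ndarray


def trajectory_metrics(track: Track, fps: Optional[float] = None,
                       eps: float = 1e-9) -> TrajectoryMetrics:
    """Path length, sinuosity (path/chord), mean speed and turning angles."""
    pts = np.asarray([(x, y) for (_, x, y) in track.points], dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points for trajectory metrics")
    t = np.asarray([p[0] for p in track.points])
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    path = float(seg_len.sum())
    net = float(np.linalg.norm(pts[-1] - pts[0]))
    duration = float(t[-1] - t[0])
    sinuosity = path / net if net > eps else float("inf")
    mean_speed = path / duration if duration > 0 else float("nan")
    if pts.shape[0] >= 3:
        headings = np.arctan2(seg[:, 1], seg[:, 0])
        turning = np.mod(np.diff(headings) + np.pi, 2 * np.pi) - np.pi
    else:
        turning = np.zeros(0)
    return TrajectoryMetrics(duration=duration, path_length=path,
                             net_displacement=net, sinuosity=sinuosity,
                             mean_speed=mean_speed, turning_angles=turning)


def estimate_shedding_frequency(
    tracks: Sequence[Track],
    duration_s: float,
    line_x: float,
) -> float:
    """Eddy shedding frequency (events per minute) from surface-feature tracks.

    Counts distinct track ids whose path crosses the cross-stream line
    ``line_x`` in the downstream direction at least once (re-entries of the
    same feature are counted once), divided by the observation duration.
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    n_crossing = 0
    for tr in tracks:
        xs = np.asarray([x for (_, x, _) in tr.points])
        if xs.size >= 2 and np.any((xs[:-1] < line_x) & (xs[1:] >= line_x)):
            n_crossing += 1
    return 60.0 * n_crossing / duration_s
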