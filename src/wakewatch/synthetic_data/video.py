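"""Synthetic overhead wake scenes with exhaustive ground truth.

Emulates nadir drone footage over a tidal-structure wake: terns are compact
bright Gaussian blobs flying correlated random walks, foam patches are larger
textured blobs advecting with the surface current (and, when a shedding
frequency is set, spawned periodically from a shed line like the eddies of a
vortex street), and sun glint appears as single-frame 1-2 px speckles.  Every
rendered object is recorded per frame so detector, classifier and tracker can
be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "SceneConfig",
    "SceneGroundTruth",
    "FrameSequence",
    "generate_wake_video",
    "generate_chip_dataset",
]


@dataclass
class SceneConfig:
    """Scene generator settings.

    Sizes are in pixels, speeds in metres per second; the ground-sample
    distance converts between the two.  ``bird_sinuosity`` >= 1 sets the
    turning-angle spread of the correlated random walk (1 = straight flight).
    ``shedding_frequency`` (eddies per minute) spawns foam patches from a
    shed line; 0 disables shedding.
    """

    frame_size: Tuple[int, int] = (240, 320)   # (H, W)
    fps: float = 25.0
    duration: float = 4.0                      # s
    ground_sample_distance: float = 0.25       # m / pixel
    n_birds: int = 3
    bird_size_px: float = 5.0
    bird_speed: float = 6.0                    # m/s
    bird_sinuosity: float = 1.3
    bird_contrast: float = 90.0                # counts above background
    n_foam_patches: int = 3
    foam_size_px: float = 26.0
    foam_contrast: float = 70.0
    glint_rate: float = 2.0                    # speckles per frame
    advection_speed: float = 1.2               # m/s, +x
    shedding_frequency: float = 0.0            # eddies / min
    street_halfwidth_px: float = 18.0          # lateral offset of shed eddies
    background_level: float = 60.0
    background_texture_sd: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.fps <= 0 or self.duration <= 0:
            raise ValueError(
                f"fps ({self.fps}) and duration ({self.duration}) must be > 0")
        if not self.bird_size_px < self.foam_size_px:
            raise ValueError("foam patches must be larger than birds")
        if self.shedding_frequency < 0:
            raise ValueError("shedding_frequency must be >= 0")
        if self.bird_sinuosity < 1.0:
            raise ValueError("bird_sinuosity must be >= 1")

    @property
    def n_frames(self) -> int:
        return max(int(round(self.fps * self.duration)), 1)

    @property
    def extent_m(self) -> Tuple[float, float]:
        h, w = self.frame_size
        g = self.ground_sample_distance
        return (h * g, w * g)


@dataclass
class SceneGroundTruth:
    """Per-frame truth: (id, frame, x_m, y_m) rows for birds and foam."""

    bird_tracks: List[Tuple[int, int, float, float]]
    foam_tracks: List[Tuple[int, int, float, float]]
    glint_events: List[Tuple[int, float, float]]
    true_shedding_frequency: float

    def bird_positions(self, frame: int) -> np.ndarray:
        return np.array([(x, y) for (i, f, x, y) in self.bird_tracks
                         if f == frame]).reshape(-1, 2)


@dataclass
class FrameSequence:
    """Stack of 8-bit grey frames plus acquisition metadata."""

    frames: np.ndarray              # (n_frames, H, W) uint8
    fps: float
    ground_sample_distance: float   # m / pixel

    def __len__(self) -> int:
        return self.frames.shape[0]

    def timestamps(self) -> np.ndarray:
        return np.arange(len(self)) / self.fps


def _textured_background(shape, level, sd, rng, smooth=3.0):
    noise = rng.standard_normal(shape)
    tex = ndimage.gaussian_filter(noise, smooth)
    tex *= sd / max(tex.std(), 1e-12)
    return level + tex


def _stamp(frame: np.ndarray, patch: np.ndarray, cx: float, cy: float) -> None:
    """Add ``patch`` (odd-sided) into ``frame`` centred at pixel (cx, cy)."""
    h, w = frame.shape
    ph, pw = patch.shape
    r0 = int(round(cy)) - ph // 2
    c0 = int(round(cx)) - pw // 2
    r1, c1 = r0 + ph, c0 + pw
    pr0, pc0 = max(0, -r0), max(0, -c0)
    pr1, pc1 = ph - max(0, r1 - h), pw - max(0, c1 - w)
    if pr0 >= pr1 or pc0 >= pc1:
        return
    frame[max(r0, 0):min(r1, h), max(c0, 0):min(c1, w)] += patch[pr0:pr1, pc0:pc1]


def _gaussian_patch(size_px: float, amplitude: float) -> np.ndarray:
    sigma = size_px / 3.0
    half = int(np.ceil(3 * sigma))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    return amplitude * np.exp(-(xx ** 2 + yy ** 2) / (2 * sigma ** 2))


def _foam_patch(size_px: float, amplitude: float, rng, phase: float = 0.0) -> np.ndarray:
    """Textured bright patch: smoothed noise under a raised-cosine window.

    ``phase`` slides the sampling window through a larger noise field so a
    patch deforms slowly from frame to frame while keeping its identity.
    """
    half = int(np.ceil(size_px / 2))
    side = 2 * half + 1
    big = ndimage.gaussian_filter(rng.standard_normal((side + 40, side + 40)), 2.0)
    off = int(phase) % 40
    tex = big[off:off + side, off:off + side]
    tex = (tex - tex.min()) / max(np.ptp(tex), 1e-12)
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    r = np.sqrt(xx ** 2 + yy ** 2) / max(half, 1)
    window = np.where(r <= 1.0, 0.5 * (1 + np.cos(np.pi * r)), 0.0)
    return amplitude * tex * window


class _CRWWalker:
    """Correlated random walk with reflecting boundaries, fixed step length."""

    def __init__(self, x, y, heading, step_len, turn_sd, bounds):
        self.x, self.y, self.heading = x, y, heading
        self.step_len, self.turn_sd = step_len, turn_sd
        self.bounds = bounds  # (xmax_m, ymax_m)

    def advance(self, rng):
        self.heading += self.turn_sd * rng.standard_normal()
        nx = self.x + self.step_len * np.cos(self.heading)
        ny = self.y + self.step_len * np.sin(self.heading)
        xmax, ymax = self.bounds
        if nx < 0 or nx > xmax:
            self.heading = np.pi - self.heading
            nx = np.clip(nx, 0, xmax)
        if ny < 0 or ny > ymax:
            self.heading = -self.heading
            ny = np.clip(ny, 0, ymax)
        self.x, self.y = nx, ny


def _turn_sd_from_sinuosity(sinuosity: float) -> float:
    # Monotone heuristic map: straight flight at 1, ~1 rad/step around 2.
    return float(np.sqrt(2.0 * (sinuosity - 1.0)))


def generate_wake_video(config: SceneConfig):
    """Render a wake scene; returns (FrameSequence, SceneGroundTruth).

    Bit-reproducible for a fixed seed.  Objects are stamped additively onto a
    static textured background; the ground truth lists every rendered bird
    and foam patch per frame (metre coordinates, x = cross-frame/right,
    y = down) and every glint speckle.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    H, W = config.frame_size
    g = config.ground_sample_distance
    ymax_m, xmax_m = config.extent_m
    dt = 1.0 / config.fps
    n_frames = config.n_frames

    background = _textured_background((H, W), config.background_level,
                                      config.background_texture_sd, rng)

    # --- birds ---------------------------------------------------------
    turn_sd = _turn_sd_from_sinuosity(config.bird_sinuosity)
    birds = [
        _CRWWalker(
            x=rng.uniform(0.15 * xmax_m, 0.85 * xmax_m),
            y=rng.uniform(0.15 * ymax_m, 0.85 * ymax_m),
            heading=rng.uniform(0, 2 * np.pi),
            step_len=config.bird_speed * dt,
            turn_sd=turn_sd,
            bounds=(xmax_m, ymax_m),
        )
        for _ in range(config.n_birds)
    ]
    bird_patch = _gaussian_patch(config.bird_size_px, config.bird_contrast)

    # --- foam patches (advecting; shed periodically if configured) -----
    foam = []  # list of dicts: id, x, y, rng-phase, side sign
    next_foam_id = 0
    shed_x_m = 0.1 * xmax_m            # shed line near the upstream edge
    street_half_m = config.street_halfwidth_px * g
    for _ in range(config.n_foam_patches):
        foam.append({
            "id": next_foam_id,
            "x": rng.uniform(0.0, xmax_m),
            "y": (ymax_m / 2 + (1 if next_foam_id % 2 == 0 else -1) * street_half_m
                  if config.shedding_frequency > 0
                  else rng.uniform(0.1 * ymax_m, 0.9 * ymax_m)),
            "seed": int(rng.integers(2 ** 31)),
        })
        next_foam_id += 1
    shed_interval = (60.0 / config.shedding_frequency
                     if config.shedding_frequency > 0 else np.inf)
    next_shed_t = shed_interval if np.isfinite(shed_interval) else np.inf

    frames = np.empty((n_frames, H, W), dtype=np.uint8)
    bird_tracks, foam_tracks, glint_events = [], [], []

    for k in range(n_frames):
        t = k * dt
        img = background.copy()

        # shed new eddies
        while t >= next_shed_t - 1e-9:
            foam.append({
                "id": next_foam_id,
                "x": shed_x_m,
                "y": ymax_m / 2 + (1 if next_foam_id % 2 == 0 else -1) * street_half_m,
                "seed": int(rng.integers(2 ** 31)),
            })
            next_foam_id += 1
            next_shed_t += shed_interval

        # advect + render foam
        keep = []
        for p in foam:
            patch = _foam_patch(config.foam_size_px, config.foam_contrast,
                                np.random.default_rng(p["seed"]),
                                phase=t * 4.0)
            _stamp(img, patch, p["x"] / g, p["y"] / g)
            foam_tracks.append((p["id"], k, p["x"], p["y"]))
            p["x"] += config.advection_speed * dt
            if p["x"] / g < W + config.foam_size_px:
                keep.append(p)
        foam = keep

        # render + advance birds
        for i, b in enumerate(birds):
            _stamp(img, bird_patch, b.x / g, b.y / g)
            bird_tracks.append((i, k, b.x, b.y))
            b.advance(rng)

        # glint speckles: single frame, 1-2 px
        n_glint = rng.poisson(config.glint_rate)
        for _ in range(n_glint):
            gx = rng.uniform(0, W - 1)
            gy = rng.uniform(0, H - 1)
            r, c = int(round(gy)), int(round(gx))
            img[r, c] += 150.0
            if rng.random() < 0.5 and c + 1 < W:
                img[r, c + 1] += 120.0
            glint_events.append((k, gx * g, gy * g))

        frames[k] = np.clip(img, 0, 255).astype(np.uint8)

    gt = SceneGroundTruth(
        bird_tracks=bird_tracks,
        foam_tracks=foam_tracks,
        glint_events=glint_events,
        true_shedding_frequency=config.shedding_frequency,
    )
    seq = FrameSequence(frames=frames, fps=config.fps,
                        ground_sample_distance=g)
    return seq, gt


def generate_chip_dataset(
    n_per_class: int,
    config: SceneConfig | None = None,
    chip_side: int = 32,
    seed: int = 0,
):
    """Labelled tern/foam chips rendered with the scene appearance model.

    Returns ``(chips, labels)`` where chips is (2*n, side, side) float in
    [0, 1] (the same normalisation the detector's chip extractor applies) and
    labels is an int array (1 = tern, 0 = foam).  Object centres are jittered
    inside the chip as they would be after detection.
    """
    if config is None:
        config = SceneConfig()
    rng = np.random.default_rng(seed)
    chips = np.empty((2 * n_per_class, chip_side, chip_side), dtype=float)
    labels = np.empty(2 * n_per_class, dtype=int)
    for i in range(2 * n_per_class):
        is_tern = i < n_per_class
        img = _textured_background((chip_side, chip_side),
                                   config.background_level,
                                   config.background_texture_sd, rng)
        jx, jy = rng.uniform(-2, 2, size=2)
        if is_tern:
            patch = _gaussian_patch(config.bird_size_px, config.bird_contrast)
        else:
            patch = _foam_patch(config.foam_size_px, config.foam_contrast,
                                np.random.default_rng(int(rng.integers(2 ** 31))),
                                phase=rng.uniform(0, 40))
        _stamp(img, patch, chip_side / 2 + jx, chip_side / 2 + jy)
        img = np.clip(img, 0, 255)
        lo, hi = img.min(), img.max()
        chips[i] = (img - lo) / (hi - lo) if hi > lo else 0.0
        labels[i] = int(is_tern)
    return chips, labels
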