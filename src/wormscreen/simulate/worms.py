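"""Synthetic multi-worm crawl recordings with ground truth.

Each worm is a midline curve rendered as a filled band (discs of radius
worm_width/2 stamped along the curve) on a light agar-like background,
dark-on-light with Gaussian pixel noise. Per frame each worm adopts one
of three postures:

* ``sinusoidal`` — an undulating open curve (two full body waves), the
  normal crawl; discrete circularity ~0.2-0.3.
* ``turn`` — an omega turn: the head crosses over the body, rendered as
  a closed loop of 3/4 body length with the remaining quarter as an
  outward tail; circularity ~0.5.
* ``coil`` — a closed loop of the whole body; circularity ~0.7-0.8.

Worms advance at a configured speed with heading noise and reflect off
the arena edge (standing in for the copper-ring chemorepellent that
keeps real animals in frame). Posture is a per-frame draw from
(coil_prob, turn_prob), optionally with a geometric dwell time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..imaging import FrameStack

POSTURE_NAMES = ("sinusoidal", "turn", "coil")

_FOREGROUND = 0.2
_BACKGROUND = 0.9
_PIXEL_NOISE_SD = 0.02


@dataclass
class WormSimConfig:
    """Recording conditions for a simulated worm population.

    Defaults mirror a population assay: ten adult animals filmed at
    2 frames/s on a 1936 x 1456 px field. ``worm_length``/``worm_width``
    are in pixels; ``mean_speed`` is the centroid speed in px/s.
    ``dwell_frames`` > 1 gives postures a geometric holding time with
    that mean; the default of 1 makes posture draws independent across
    frames.
    """

    n_worms: int = 10
    n_frames: int = 720
    fps: float = 2.0
    arena: tuple[int, int] = (1936, 1456)  # (width, height) px
    worm_length: float = 100.0
    worm_width: float = 10.0
    coil_prob: float = 0.0
    turn_prob: float = 0.0
    mean_speed: float = 3.0
    heading_noise_sd: float = 0.15  # rad per frame
    dwell_frames: float = 1.0
    pixel_noise_sd: float = _PIXEL_NOISE_SD
    avoidance: bool = True  # worms steer apart to keep bodies separable
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coil_prob < 0 or self.turn_prob < 0:
            raise ValueError("posture probabilities must be nonnegative")
        if self.coil_prob + self.turn_prob > 1:
            raise ValueError("coil_prob + turn_prob must not exceed 1")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not self.worm_length > self.worm_width > 0:
            raise ValueError("need worm_length > worm_width > 0")
        if self.dwell_frames < 1:
            raise ValueError("dwell_frames must be >= 1")
        margin = self.worm_length / 2 + self.worm_width
        if min(self.arena) <= 2 * margin:
            raise ValueError(
                f"arena {self.arena} too small for worm_length {self.worm_length}"
            )


@dataclass
class GroundTruth:
    """What the simulator actually did, for recovery tests."""

    posture: np.ndarray  # (n_worms, n_frames) of POSTURE_NAMES strings
    centroids: np.ndarray  # (n_worms, n_frames, 2) as (x, y)
    true_speeds: np.ndarray  # px/s per worm (true path length / duration)
    true_coil_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        self.true_coil_fraction = float(np.mean(self.posture == "coil"))


def _sinusoidal_midline(length: float, phase: float, n_pts: int) -> np.ndarray:
    """Open undulating curve in body coordinates, centred at the origin.

    Two full waves along the body keep the continuous centroid at the
    body centre for every phase.
    """
    s = np.linspace(-0.5, 0.5, n_pts)
    # transverse amplitude 10% of body length, foreshorten the axis so
    # arc length stays close to the body length
    amp = 0.1 * length
    x = s * length * 0.92
    y = amp * np.sin(4.0 * np.pi * s + phase)
    y -= y.mean()
    return np.column_stack([x, y])


def _coil_midline(length: float, n_pts: int) -> np.ndarray:
    """Closed loop: the whole body on a circle of circumference = length."""
    r = length / (2.0 * math.pi)
    t = np.linspace(0.0, 2.0 * math.pi, n_pts)
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


def _turn_midline(length: float, n_pts: int) -> np.ndarray:
    """Omega shape: 3/4 of the body closes a loop, 1/4 trails outward."""
    loop_len = 0.75 * length
    r = loop_len / (2.0 * math.pi)
    n_loop = int(n_pts * 0.75)
    t = np.linspace(0.0, 2.0 * math.pi, n_loop)
    loop = np.column_stack([r * np.cos(t), r * np.sin(t)])
    tail_len = length - loop_len
    s = np.linspace(0.0, tail_len, n_pts - n_loop)
    tail = np.column_stack([r + s, np.zeros_like(s)])
    pts = np.vstack([loop, tail])
    pts -= pts.mean(axis=0)
    return pts


def _rotate(points: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return points @ np.array([[c, -s], [s, c]]).T


_DISC_CACHE: dict[float, tuple[np.ndarray, np.ndarray]] = {}


def _disc_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    offsets = _DISC_CACHE.get(radius)
    if offsets is None:
        r = int(math.ceil(radius))
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        inside = (xx**2 + yy**2) <= radius**2
        offsets = (yy[inside].ravel(), xx[inside].ravel())
        _DISC_CACHE[radius] = offsets
    return offsets


def _stamp_discs(
    frame: np.ndarray, points: np.ndarray, radius: float, value: float
) -> None:
    """Paint filled discs of ``radius`` at each midline point, in place."""
    h, w = frame.shape
    dy, dx = _disc_offsets(radius)
    cy = np.rint(points[:, 1]).astype(np.intp)[:, None] + dy[None, :]
    cx = np.rint(points[:, 0]).astype(np.intp)[:, None] + dx[None, :]
    ok = (cy >= 0) & (cy < h) & (cx >= 0) & (cx < w)
    frame[cy[ok], cx[ok]] = value


def _place_worms(config: WormSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Initial centres, pairwise at least one body length apart."""
    width, height = config.arena
    margin = config.worm_length / 2 + config.worm_width
    placed: list[tuple[float, float]] = []
    for _ in range(config.n_worms):
        for _attempt in range(1000):
            x = rng.uniform(margin, width - margin)
            y = rng.uniform(margin, height - margin)
            if all(math.dist((x, y), p) >= config.worm_length for p in placed):
                placed.append((x, y))
                break
        else:
            raise RuntimeError(
                "could not place worms without overlap; arena too crowded"
            )
    return np.array(placed)


def _draw_postures(config: WormSimConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_worms, n_frames) posture names; geometric dwell when configured."""
    p_coil, p_turn = config.coil_prob, config.turn_prob
    probs = [1.0 - p_coil - p_turn, p_turn, p_coil]
    draws = rng.choice(3, size=(config.n_worms, config.n_frames), p=probs)
    if config.dwell_frames > 1:
        stay = 1.0 - 1.0 / config.dwell_frames
        keep = rng.random(size=draws.shape) < stay
        for j in range(1, config.n_frames):
            held = keep[:, j]
            draws[held, j] = draws[held, j - 1]
    return np.array(POSTURE_NAMES, dtype="U10")[draws]


def simulate_worm_recording(
    config: WormSimConfig,
) -> tuple[FrameStack, GroundTruth]:
    """Render a full synthetic recording and its ground truth.

    Returns the grayscale frame stack (float32 in [0, 1], dark worms on a
    light background with Gaussian pixel noise) and the per-worm per-frame
    posture, centroid and speed record.
    """
    rng = np.random.default_rng(config.seed)
    width, height = config.arena
    margin = config.worm_length / 2 + config.worm_width

    positions = _place_worms(config, rng)
    headings = rng.uniform(0.0, 2.0 * math.pi, size=config.n_worms)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=config.n_worms)
    postures = _draw_postures(config, rng)

    step = config.mean_speed / config.fps
    n_pts = max(16, int(config.worm_length))
    frames = np.empty((config.n_frames, height, width), dtype=np.float32)
    centroids = np.zeros((config.n_worms, config.n_frames, 2))

    for j in range(config.n_frames):
        frame = np.full((height, width), _BACKGROUND, dtype=np.float32)
        for i in range(config.n_worms):
            headings[i] += rng.normal(0.0, config.heading_noise_sd)
            if config.avoidance:
                for k in range(config.n_worms):
                    if k == i:
                        continue
                    dx = positions[i, 0] - positions[k, 0]
                    dy = positions[i, 1] - positions[k, 1]
                    if math.hypot(dx, dy) < 1.3 * config.worm_length:
                        headings[i] = math.atan2(dy, dx)  # steer apart
                        break
            x = positions[i, 0] + step * math.cos(headings[i])
            y = positions[i, 1] + step * math.sin(headings[i])
            # reflecting boundary (chemorepellent ring stand-in)
            if x < margin or x > width - margin:
                headings[i] = math.pi - headings[i]
                x = min(max(x, margin), width - margin)
            if y < margin or y > height - margin:
                headings[i] = -headings[i]
                y = min(max(y, margin), height - margin)
            positions[i] = (x, y)
            phases[i] += 2.0 * math.pi / config.fps  # one body wave per second

            posture = postures[i, j]
            if posture == "coil":
                midline = _coil_midline(config.worm_length, n_pts)
            elif posture == "turn":
                midline = _turn_midline(config.worm_length, n_pts)
            else:
                midline = _sinusoidal_midline(config.worm_length, phases[i], n_pts)
            pts = _rotate(midline, headings[i]) + positions[i]
            _stamp_discs(frame, pts, config.worm_width / 2.0, _FOREGROUND)
            centroids[i, j] = positions[i]
        if config.pixel_noise_sd > 0:
            frame += config.pixel_noise_sd * rng.standard_normal(
                frame.shape, dtype=np.float32
            )
        np.clip(frame, 0.0, 1.0, out=frames[j])

    durations = (config.n_frames - 1) / config.fps
    path = np.linalg.norm(np.diff(centroids, axis=1), axis=2).sum(axis=1)
    true_speeds = path / durations if durations > 0 else np.zeros(config.n_worms)

    stack = FrameStack(frames=frames, fps=config.fps)
    truth = GroundTruth(posture=postures, centroids=centroids, true_speeds=true_speeds)
    return stack, truth
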