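"""Synthetic dish-recorded worm sequences with exported ground truth.

The simulated animal is an elastic body of half-width ``half_width`` laid
backward along a smooth arc-length-parameterized guide path inside a
circular arena.  Its arc length breathes sinusoidally,

    L(t) = rest_length * (1 + stretch_amplitude * sin(2*pi*t / stretch_period)),

emulating peristaltic stretch (amplitude is capped at 0.5, i.e. a maximum
stretch of 1.5x rest length, the elastic limit reported for earthworms),
while the head advances along the path at constant ``speed``.  Rendering
mirrors the recording setup: 640x480 frames at 0.2 mm/px and 1 s intervals,
a light dish interior on a black exterior, worm/background contrast highest
in the red channel, and small dark specks below the fragment-removal
threshold.

Physical model coordinates are mm with origin at the arena center;
conversion to pixels happens at render time.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Callable, Optional

import imageio.v3 as iio
import numpy as np

from .imaging_io import Calibration, FrameSequence, TrajectoryRecord, write_trajectory_csv
from .preprocessing import CircleROI

__all__ = [
    "ArcLengthPath",
    "NoiseSpec",
    "RenderSettings",
    "WormModel",
    "WormOutOfArenaError",
    "WormPose",
    "arc_path",
    "coil_path",
    "default_arena",
    "generate_sequence",
    "preset",
    "render_frame",
    "simulate_pose",
    "simulate_sequence",
    "spiral_path",
]


class WormOutOfArenaError(ValueError):
    """Raised when a simulated pose would leave the arena."""


class ArcLengthPath:
    """A planar curve parameterized by arc length (mm).

    Built from a dense polyline; ``path(s)`` interpolates the position at
    cumulative length ``s`` from the start.
    """

    def __init__(self, points_mm: np.ndarray):
        pts = np.asarray(points_mm, dtype=float).reshape(-1, 2)
        if len(pts) < 2:
            raise ValueError("a path needs at least 2 points")
        seg = np.hypot(*np.diff(pts, axis=0).T)
        self._cum = np.concatenate([[0.0], np.cumsum(seg)])
        self._pts = pts
        self.total_length = float(self._cum[-1])

    def __call__(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        x = np.interp(s, self._cum, self._pts[:, 0])
        y = np.interp(s, self._cum, self._pts[:, 1])
        return np.stack([x, y], axis=-1)


def arc_path(radius_mm: float, span_rad: float, center_mm=(0.0, 0.0),
             start_angle: float = 0.0, step_mm: float = 0.05) -> ArcLengthPath:
    """Circular arc of given radius and angular span."""
    n = max(int(radius_mm * span_rad / step_mm), 2)
    theta = start_angle + np.linspace(0.0, span_rad, n)
    cx, cy = center_mm
    return ArcLengthPath(np.stack([
        cx + radius_mm * np.cos(theta), cy + radius_mm * np.sin(theta)
    ], axis=1))


def spiral_path(r_outer_mm: float = 36.0, r_inner_mm: float = 12.0,
                gap_mm: float = 9.0, center_mm=(0.0, 0.0),
                start_angle: float = 0.0, step_mm: float = 0.05) -> ArcLengthPath:
    """Inward Archimedean spiral; ring gap sets worm-to-worm clearance."""
    theta_max = 2 * math.pi * (r_outer_mm - r_inner_mm) / gap_mm
    approx_len = 0.5 * (r_outer_mm + r_inner_mm) * theta_max
    n = max(int(approx_len / step_mm), 2)
    theta = np.linspace(0.0, theta_max, n)
    r = r_outer_mm - gap_mm * theta / (2 * math.pi)
    cx, cy = center_mm
    return ArcLengthPath(np.stack([
        cx + r * np.cos(start_angle + theta), cy + r * np.sin(start_angle + theta)
    ], axis=1))


def coil_path(loop_radius_mm: float = 9.0, lead_mm: float = 25.0,
              step_mm: float = 0.05) -> ArcLengthPath:
    """A path with a self-crossing loop, for coiling/self-overlap scenarios.

    Straight lead-in, a full circular loop re-crossing the lead, straight
    lead-out.  A worm spanning the crossing overlaps itself, the regime in
    which endpoint-based tracking is expected to fail.
    """
    n1 = max(int(lead_mm / step_mm), 2)
    lead_in = np.stack([
        np.linspace(-lead_mm, 0.0, n1), np.zeros(n1)
    ], axis=1)
    nl = max(int(2 * math.pi * loop_radius_mm / step_mm), 2)
    phi = np.linspace(-math.pi / 2, 3 * math.pi / 2, nl)
    loop = np.stack([
        loop_radius_mm * np.cos(phi),
        loop_radius_mm + loop_radius_mm * np.sin(phi),
    ], axis=1)
    lead_out = np.stack([
        np.linspace(0.0, lead_mm, n1), np.zeros(n1)
    ], axis=1)
    return ArcLengthPath(np.concatenate([lead_in, loop[1:], lead_out[1:]]))


@dataclass(frozen=True)
class RenderSettings:
    """Raster geometry and colors of the simulated recording."""

    shape: tuple[int, int] = (480, 640)
    mm_per_pixel: float = 0.2
    background_rgb: tuple[int, int, int] = (210, 160, 150)
    worm_rgb: tuple[int, int, int] = (60, 110, 120)

    @property
    def calibration(self) -> Calibration:
        return Calibration(mm_per_pixel=self.mm_per_pixel)


@dataclass(frozen=True)
class NoiseSpec:
    """Speck noise: Poisson count per frame of small dark disks.

    Disk radii are kept small enough that every speck's area stays below the
    default 50 px fragment-removal threshold.
    """

    rate: float = 5.0
    min_radius_px: float = 1.0
    max_radius_px: float = 2.2


@dataclass
class WormModel:
    """Elastic worm: geometry, stretch dynamics, and guide path.

    ``start_offset_mm`` is the head's arc-length position at t=0; it
    defaults to the maximum body length so the body always fits behind it.
    """

    guide_path: ArcLengthPath
    rest_length_mm: float = 160.0
    stretch_amplitude: float = 0.2
    stretch_period_s: float = 30.0
    speed_mm_s: float = 2.0
    half_width_mm: float = 2.5
    start_offset_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rest_length_mm <= 0:
            raise ValueError("rest_length_mm must be positive")
        if not 0.0 <= self.stretch_amplitude <= 0.5:
            raise ValueError("stretch_amplitude must lie in [0, 0.5] "
                             "(stretch is limited to 1.5x rest length)")
        if self.stretch_period_s <= 0:
            raise ValueError("stretch_period_s must be positive")
        if self.half_width_mm <= 0:
            raise ValueError("half_width_mm must be positive")
        if self.start_offset_mm is None:
            self.start_offset_mm = self.max_length_mm

    @property
    def max_length_mm(self) -> float:
        return self.rest_length_mm * (1.0 + self.stretch_amplitude)

    def length_at(self, t: float) -> float:
        """Body arc length L(t), mm."""
        return self.rest_length_mm * (
            1.0 + self.stretch_amplitude
            * math.sin(2 * math.pi * t / self.stretch_period_s)
        )


@dataclass
class WormPose:
    """Discretized centerline (head first) and true feature points, pixels."""

    centerline_px: np.ndarray  # (M, 2) float, (x, y), head -> tail
    head_px: tuple[float, float]
    center_px: tuple[float, float]
    tail_px: tuple[float, float]
    arc_length_mm: float
    t: float


def default_arena(settings: RenderSettings = RenderSettings()) -> CircleROI:
    """The study dish: 85 mm inner diameter centered in the frame."""
    h, w = settings.shape
    return CircleROI(
        center_xy=((w - 1) / 2.0, (h - 1) / 2.0),
        radius=42.5 / settings.mm_per_pixel,
    )


def _mm_to_px(points_mm: np.ndarray, arena: CircleROI,
              settings: RenderSettings) -> np.ndarray:
    cx, cy = arena.center_xy
    return points_mm / settings.mm_per_pixel + np.array([cx, cy])


def simulate_pose(
    model: WormModel,
    t: float,
    arena: CircleROI,
    settings: RenderSettings = RenderSettings(),
    sample_ds_mm: float = 0.4,
    check_arena: bool = True,
) -> WormPose:
    """Pose at time ``t``: centerline laid backward from the head.

    The head sits at guide-path arc position ``start_offset + speed*t``; the
    body occupies the preceding L(t) mm of path; the true center is the
    arc-length midpoint.  Raises :class:`WormOutOfArenaError` if any part of
    the body (including its half-width) would leave the arena, and
    ``ValueError`` if the body runs off either end of the guide path.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    L = model.length_at(t)
    s_head = model.start_offset_mm + model.speed_mm_s * t
    if s_head > model.guide_path.total_length + 1e-9:
        raise ValueError("guide path exhausted: head ran off its end")
    if s_head - L < -1e-9:
        raise ValueError("guide path exhausted: tail ran off its start")
    n = max(int(math.ceil(L / sample_ds_mm)) + 1, 2)
    s = np.linspace(s_head, s_head - L, n)
    pts_mm = model.guide_path(np.clip(s, 0.0, None))
    if check_arena:
        arena_r_mm = arena.radius * settings.mm_per_pixel
        margin = model.half_width_mm + 2 * settings.mm_per_pixel
        if np.any(np.hypot(pts_mm[:, 0], pts_mm[:, 1]) > arena_r_mm - margin):
            raise WormOutOfArenaError("worm out of arena")
    pts_px = _mm_to_px(pts_mm, arena, settings)
    center_px = _mm_to_px(model.guide_path(max(s_head - L / 2.0, 0.0)),
                          arena, settings)
    return WormPose(
        centerline_px=pts_px,
        head_px=(float(pts_px[0, 0]), float(pts_px[0, 1])),
        center_px=(float(center_px[0]), float(center_px[1])),
        tail_px=(float(pts_px[-1, 0]), float(pts_px[-1, 1])),
        arc_length_mm=L, t=t,
    )


def _stamp_polyline(mask: np.ndarray, polyline_px: np.ndarray, radius_px: float) -> None:
    """Set mask pixels whose centers lie within radius of the polyline.

    Exact point-to-segment distances, evaluated only inside each segment's
    bounding window for speed.
    """
    h, w = mask.shape
    pad = radius_px + 2.0
    p = polyline_px[:-1]
    q = polyline_px[1:]
    for (px, py), (qx, qy) in zip(p, q):
        r0 = max(int(math.floor(min(py, qy) - pad)), 0)
        r1 = min(int(math.ceil(max(py, qy) + pad)) + 1, h)
        c0 = max(int(math.floor(min(px, qx) - pad)), 0)
        c1 = min(int(math.ceil(max(px, qx) + pad)) + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dx, dy = qx - px, qy - py
        den = dx * dx + dy * dy
        if den == 0:
            d2 = (xx - px) ** 2 + (yy - py) ** 2
        else:
            u = np.clip(((xx - px) * dx + (yy - py) * dy) / den, 0.0, 1.0)
            d2 = (xx - (px + u * dx)) ** 2 + (yy - (py + u * dy)) ** 2
        mask[r0:r1, c0:c1] |= d2 <= radius_px * radius_px


def render_frame(
    pose: WormPose,
    model: WormModel,
    arena: CircleROI,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    settings: RenderSettings = RenderSettings(),
) -> np.ndarray:
    """Render one 3-channel 8-bit frame of the pose.

    Light dish interior, black exterior, dark worm stamped as the union of
    disks of radius ``half_width`` along the centerline, plus Poisson speck
    noise positioned relative to the arena center (so integer-pixel arena
    translations translate the specks exactly).  Deterministic per seed.
    """
    hw_px = model.half_width_mm / settings.mm_per_pixel
    if hw_px < 1.5 - 1e-9:
        raise ValueError("half_width must be at least 1.5 pixels at this scale")
    img = np.zeros(settings.shape + (3,), dtype=np.uint8)
    inside = arena.mask(settings.shape)
    img[inside] = settings.background_rgb

    worm = np.zeros(settings.shape, dtype=bool)
    _stamp_polyline(worm, pose.centerline_px, hw_px)
    img[worm] = settings.worm_rgb

    rng = np.random.default_rng(seed)
    n_specks = rng.poisson(noise.rate)
    cx, cy = arena.center_xy
    for _ in range(n_specks):
        rad = arena.radius * 0.92 * math.sqrt(rng.uniform())
        ang = rng.uniform(0.0, 2 * math.pi)
        sx, sy = cx + rad * math.cos(ang), cy + rad * math.sin(ang)
        sr = rng.uniform(noise.min_radius_px, noise.max_radius_px)
        speck = np.zeros(settings.shape, dtype=bool)
        _stamp_polyline(speck, np.array([[sx, sy], [sx, sy]]), sr)
        img[speck & inside] = settings.worm_rgb
    return img


def simulate_sequence(
    model: WormModel,
    n_frames: int,
    interval: float = 1.0,
    arena: Optional[CircleROI] = None,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    settings: RenderSettings = RenderSettings(),
) -> tuple[FrameSequence, list[TrajectoryRecord]]:
    """In-memory frame sequence plus per-frame ground truth.

    Ground-truth records carry the true (sub-pixel) feature coordinates and
    the model arc length L(t); per-frame speck noise derives deterministically
    from ``(seed, frame index)``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    arena = arena if arena is not None else default_arena(settings)
    frames, truth = [], []
    for i in range(n_frames):
        t = i * interval
        pose = simulate_pose(model, t, arena, settings)
        frame_seed = np.random.SeedSequence([int(seed), i]).generate_state(1)[0]
        frames.append(render_frame(pose, model, arena, noise, int(frame_seed), settings))
        truth.append(TrajectoryRecord(
            frame_index=i, time_s=t,
            head_xy=pose.head_px, center_xy=pose.center_px, tail_xy=pose.tail_px,
            length_mm=pose.arc_length_mm, status="ok",
        ))
    return FrameSequence(frames=frames, times=[i * interval for i in range(n_frames)]), truth


def generate_sequence(
    model: WormModel,
    n_frames: int,
    interval: float = 1.0,
    arena: Optional[CircleROI] = None,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    out_dir: Optional[str] = None,
    settings: RenderSettings = RenderSettings(),
) -> tuple[FrameSequence, list[TrajectoryRecord]]:
    """Like :func:`simulate_sequence`, optionally writing frames to disk.

    With ``out_dir`` set, writes zero-padded PNG frames, ``ground_truth.csv``
    in the trajectory dialect, and ``track_config.txt`` consumable by the
    ``track`` subcommand (ROI, calibration, threshold, and a tail seed taken
    from the first frame's ground truth).
    """
    arena = arena if arena is not None else default_arena(settings)
    seq, truth = simulate_sequence(model, n_frames, interval, arena, noise, seed, settings)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for i, frame in enumerate(seq.frames):
            iio.imwrite(os.path.join(out_dir, f"frame_{i:04d}.png"), frame)
        write_trajectory_csv(truth, os.path.join(out_dir, "ground_truth.csv"))
        cx, cy = arena.center_xy
        tx, ty = truth[0].tail_xy
        with open(os.path.join(out_dir, "track_config.txt"), "w", encoding="utf-8") as fh:
            fh.write(
                f"mm_per_pixel={settings.mm_per_pixel}\n"
                f"frame_interval={interval}\n"
                "threshold=auto\n"
                "polarity=dark_object\n"
                "min_fragment_area=50\n"
                "min_spur=5\n"
                f"roi={cx},{cy},{arena.radius}\n"
                f"tail_seed={tx:.1f},{ty:.1f}\n"
            )
    return seq, truth


def preset(name: str, settings: RenderSettings = RenderSettings()):
    """Named study scenarios: ``crawl``, ``static``, or ``coil``.

    Returns ``(model, arena, noise)``.  ``crawl`` is an adult-sized worm
    (rest length 160 mm, so it necessarily coils along a gentle spiral whose
    ring gap keeps the body from self-touching); ``static`` is a motionless
    worm; ``coil`` follows a self-crossing loop and is the labeled failure
    scenario for endpoint-based tracking.
    """
    arena = default_arena(settings)
    noise = NoiseSpec()
    if name == "crawl":
        model = WormModel(
            guide_path=spiral_path(),
            rest_length_mm=160.0, stretch_amplitude=0.2,
            stretch_period_s=30.0, speed_mm_s=2.0, half_width_mm=2.5,
        )
    elif name == "static":
        model = WormModel(
            guide_path=arc_path(radius_mm=25.0, span_rad=2.8),
            rest_length_mm=60.0, stretch_amplitude=0.0,
            stretch_period_s=30.0, speed_mm_s=0.0, half_width_mm=2.5,
        )
    elif name == "coil":
        model = WormModel(
            guide_path=coil_path(),
            rest_length_mm=70.0, stretch_amplitude=0.1,
            stretch_period_s=30.0, speed_mm_s=1.0, half_width_mm=2.0,
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    return model, arena, noise
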