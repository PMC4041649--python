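"""Self-validation experiments on synthetic data.

Each function builds a seeded synthetic scenario, runs the relevant part of
the pipeline, and returns measured quantities (fractions, errors, recovered
rates).  These are the package's own correctness benchmarks: the tests
assert on them, and the reproduction script reports them.

Problem sizes follow the simulated study conditions: thin juvenile-scale
worms (half-width 0.3-0.5 mm, rest length 30-60 mm) for the geometry and
tracking benchmarks - chosen so the per-frame endpoint displacement stays
within the nearest-endpoint matcher's working regime - and 100-frame
sequences at 1 s intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .imaging_io import Calibration, FrameSequence
from .kinematics import body_length, compare_trajectories, length_series, summarize, velocities
from .preprocessing import apply_roi, binarize, largest_component, red_channel, remove_small_fragments
from .skeletonization import Skeleton, find_endpoints, hilditch_thin, prune_spurs
from .synthetic_data import (
    NoiseSpec,
    RenderSettings,
    WormModel,
    arc_path,
    default_arena,
    render_frame,
    simulate_pose,
    simulate_sequence,
    spiral_path,
)
from .tracking import track_sequence

__all__ = [
    "endpoint_length_experiment",
    "equivariance_experiment",
    "length_ratio_experiment",
    "random_blob_mask",
    "thinning_experiment",
    "tracking_experiment",
    "velocity_experiment",
]

_SETTINGS = RenderSettings()
_CAL = Calibration()


def random_blob_mask(rng: np.random.Generator, shape=(64, 64)) -> np.ndarray:
    """A random blobby foreground: union of 3-8 disks, possibly multi-part."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, dtype=bool)
    for _ in range(rng.integers(3, 9)):
        cy, cx = rng.uniform(8, h - 8), rng.uniform(8, w - 8)
        r = rng.uniform(3, 10)
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    if not mask.any():
        mask[h // 2, w // 2] = True
    return mask


def _count_components(mask: np.ndarray) -> int:
    from scipy import ndimage

    return ndimage.label(mask, structure=np.ones((3, 3), bool))[1]


def thinning_experiment(n_masks: int = 200, seed: int = 0) -> dict:
    """Idempotence, subset, and component preservation of thinning.

    Runs Hilditch thinning on ``n_masks`` random blob masks and reports the
    fraction of masks for which each property holds (all should be 1.0).
    """
    rng = np.random.default_rng([seed, 101])
    idem = subset = comps = 0
    for _ in range(n_masks):
        mask = random_blob_mask(rng)
        skel = hilditch_thin(mask)
        smask = skel.as_mask()
        again = hilditch_thin(smask)
        idem += np.array_equal(again.as_mask(), smask)
        subset += bool(np.all(mask[smask]))
        comps += _count_components(smask) == _count_components(mask)
    return {
        "idempotent_fraction": idem / n_masks,
        "subset_fraction": subset / n_masks,
        "component_preserving_fraction": comps / n_masks,
        "n": n_masks,
    }


def _random_arc_worm(rng: np.random.Generator, half_width_mm: float = 0.5):
    """A gently curved stationary worm on a random arc inside the dish."""
    while True:
        radius = rng.uniform(15, 35)
        span = rng.uniform(1.8, 2.8)
        lo, hi = 30.0, min(60.0, 0.9 * radius * span)
        if hi <= lo:
            continue
        rest = rng.uniform(lo, hi)
        start = rng.uniform(0, 2 * math.pi)
        max_off = 42.5 - radius - 3.0
        off = rng.uniform(0, max_off) if max_off > 0 else 0.0
        ang = rng.uniform(0, 2 * math.pi)
        center = (off * math.cos(ang), off * math.sin(ang))
        model = WormModel(
            guide_path=arc_path(radius, span, center_mm=center, start_angle=start),
            rest_length_mm=rest, stretch_amplitude=0.0, stretch_period_s=30.0,
            speed_mm_s=0.0, half_width_mm=half_width_mm, start_offset_mm=rest,
        )
        try:
            pose = simulate_pose(model, 0.0, default_arena(_SETTINGS), _SETTINGS)
        except ValueError:
            continue
        return model, pose


def _segment(frame, arena):
    chan = apply_roi(red_channel(frame), arena)
    mask = binarize(chan, "auto", roi_mask=arena.mask(chan.shape))
    return largest_component(remove_small_fragments(mask, 50))


def endpoint_length_experiment(n_worms: int = 50, seed: int = 0) -> dict:
    """Endpoint count and arc-length recovery on simple curved worms.

    Renders ``n_worms`` non-self-crossing worms of width >= 3 px, thins and
    prunes each, and reports the fraction with exactly two endpoints and the
    fraction whose geodesic end-to-end length recovers the generator arc
    length within 5%.
    """
    rng = np.random.default_rng([seed, 202])
    arena = default_arena(_SETTINGS)
    two_endpoints = within_5pct = 0
    errors = []
    for i in range(n_worms):
        model, pose = _random_arc_worm(rng)
        frame = render_frame(pose, model, arena, NoiseSpec(rate=0.0),
                             seed=i, settings=_SETTINGS)
        mask = _segment(frame, arena)
        skel = prune_spurs(hilditch_thin(mask), 5.0)
        eps = find_endpoints(skel)
        if len(eps) == 2:
            two_endpoints += 1
            est = body_length(skel, eps[0], eps[1], _CAL)
            err = abs(est - model.rest_length_mm) / model.rest_length_mm
            errors.append(err)
            within_5pct += err <= 0.05
    return {
        "two_endpoint_fraction": two_endpoints / n_worms,
        "length_within_5pct_fraction": within_5pct / n_worms,
        "median_length_error_pct": float(100 * np.median(errors)) if errors else math.nan,
        "n": n_worms,
    }


def _crawl_model(rest: float, amplitude: float, period: float, speed: float,
                 half_width: float) -> WormModel:
    return WormModel(
        guide_path=spiral_path(r_outer_mm=36.0, r_inner_mm=12.0, gap_mm=6.0),
        rest_length_mm=rest, stretch_amplitude=amplitude,
        stretch_period_s=period, speed_mm_s=speed, half_width_mm=half_width,
    )


def _run_tracked(model: WormModel, n_frames: int, seed: int,
                 noise_rate: float = 5.0):
    arena = default_arena(_SETTINGS)
    seq, truth = simulate_sequence(model, n_frames, arena=arena,
                                   noise=NoiseSpec(rate=noise_rate), seed=seed,
                                   settings=_SETTINGS)
    cfg = RunConfig.resolve(flags={
        "roi": f"{arena.center_xy[0]},{arena.center_xy[1]},{arena.radius}",
        "tail_seed": f"{truth[0].tail_xy[0]},{truth[0].tail_xy[1]}",
    })
    records = track_sequence(seq, cfg, cfg.tail_seed)
    return records, truth, cfg


def tracking_experiment(n_frames: int = 100, seed: int = 0) -> dict:
    """Label stability and positional accuracy on a peristaltic crawl.

    The worm (rest length 40 mm, stretch amplitude 0.1 at 40 s period, head
    speed 1.2 mm/s, half-width 0.3 mm) keeps every endpoint's per-frame
    displacement at or under 10 px.  Reports the fraction of frames in which
    the head/tail labels match ground truth, the RMS position error over all
    three points, and coordinate correlations against ground truth.
    """
    model = _crawl_model(rest=40.0, amplitude=0.1, period=40.0, speed=1.2,
                         half_width=0.3)
    records, truth, _ = _run_tracked(model, n_frames, seed)
    label_ok = 0
    sq = []
    for r, g in zip(records, truth):
        d_head = math.dist(r.head_xy, g.head_xy)
        d_swap = math.dist(r.head_xy, g.tail_xy)
        label_ok += d_head < d_swap
        sq += [
            d_head ** 2,
            math.dist(r.center_xy, g.center_xy) ** 2,
            math.dist(r.tail_xy, g.tail_xy) ** 2,
        ]
    stats = compare_trajectories(records, truth, _CAL)
    return {
        "label_match_fraction": label_ok / n_frames,
        "rms_position_error_px": float(math.sqrt(np.mean(sq))),
        "head_r_x": stats["head"].pearson_r_x,
        "head_r_y": stats["head"].pearson_r_y,
        "tail_r_x": stats["tail"].pearson_r_x,
        "tail_r_y": stats["tail"].pearson_r_y,
        "n": n_frames,
    }


def velocity_experiment(n_frames: int = 100, seed: int = 0) -> dict:
    """Recovery of a constant 2.0 mm/s head speed from tracked output."""
    model = _crawl_model(rest=40.0, amplitude=0.15, period=25.0, speed=2.0,
                         half_width=0.3)
    records, truth, cfg = _run_tracked(model, n_frames, seed)
    est = summarize(velocities(records, "head", cfg.calibration))
    return {
        "mean_head_speed_mm_s": est.mean,
        "true_head_speed_mm_s": model.speed_mm_s,
        "n": n_frames,
    }


def length_ratio_experiment(n_frames: int = 90, seed: int = 0) -> dict:
    """Max/min body-length ratio under full-amplitude (0.5) stretch.

    L(t) spans 0.5x to 1.5x rest length, so the true max/min ratio is 3.0;
    the sequence covers just over two stretch cycles and hits the sine's
    peak and trough exactly at the 1 s sampling grid.
    """
    model = _crawl_model(rest=60.0, amplitude=0.5, period=40.0, speed=0.5,
                         half_width=0.3)
    records, truth, _ = _run_tracked(model, n_frames, seed)
    s = length_series(records).summary
    return {
        "length_ratio_max_min": s.max / s.min,
        "true_ratio": 3.0,
        "n": n_frames,
    }


def equivariance_experiment(n_frames: int = 20, seed: int = 0) -> dict:
    """Translation equivariance, calibration scaling, and determinism.

    Tracks a sequence, then (a) the same frames shifted by (+5, +7) px with
    a shifted ROI and seed, (b) the original at doubled mm-per-pixel, and
    (c) the original a second time.  Reports the worst coordinate deviation
    from exact translation, the worst relative deviation of lengths and
    velocities from exact doubling, and whether the rerun is identical.
    """
    import io

    from .imaging_io import write_trajectory_csv

    model = _crawl_model(rest=40.0, amplitude=0.1, period=40.0, speed=1.2,
                         half_width=0.3)
    arena = default_arena(_SETTINGS)
    seq, truth = simulate_sequence(model, n_frames, arena=arena,
                                   noise=NoiseSpec(rate=5.0), seed=seed,
                                   settings=_SETTINGS)
    dx, dy = 5, 7
    shifted = FrameSequence(
        frames=[np.roll(f, (dy, dx), axis=(0, 1)) for f in seq.frames],
        times=list(seq.times),
    )

    def cfg_for(cx, cy, seed_xy, mmpx=0.2):
        return RunConfig.resolve(flags={
            "roi": f"{cx},{cy},{arena.radius}",
            "tail_seed": f"{seed_xy[0]},{seed_xy[1]}",
            "mm_per_pixel": mmpx,
        })

    cx, cy = arena.center_xy
    seed_xy = truth[0].tail_xy
    base_cfg = cfg_for(cx, cy, seed_xy)
    base = track_sequence(seq, base_cfg, base_cfg.tail_seed)

    shift_cfg = cfg_for(cx + dx, cy + dy, (seed_xy[0] + dx, seed_xy[1] + dy))
    shifted_recs = track_sequence(shifted, shift_cfg, shift_cfg.tail_seed)
    trans_err = 0.0
    for a, b in zip(base, shifted_recs):
        for pa, pb in ((a.head_xy, b.head_xy), (a.center_xy, b.center_xy),
                       (a.tail_xy, b.tail_xy)):
            trans_err = max(trans_err, abs(pb[0] - pa[0] - dx), abs(pb[1] - pa[1] - dy))

    double_cfg = cfg_for(cx, cy, seed_xy, mmpx=0.4)
    doubled = track_sequence(seq, double_cfg, double_cfg.tail_seed)
    scale_err = max(
        abs(d.length_mm / b.length_mm - 2.0)
        for b, d in zip(base, doubled) if b.length_mm > 0
    )
    vb = velocities(base, "head", base_cfg.calibration).values
    vd = velocities(doubled, "head", double_cfg.calibration).values
    ok = np.isfinite(vb) & (vb > 0)
    scale_err = max(scale_err, float(np.max(np.abs(vd[ok] / vb[ok] - 2.0))))

    rerun = track_sequence(seq, base_cfg, base_cfg.tail_seed)
    buf1, buf2 = io.StringIO(), io.StringIO()
    # compare through the serialized form, the on-disk contract
    import csv as _csv
    for buf, recs in ((buf1, base), (buf2, rerun)):
        w = _csv.writer(buf)
        for r in recs:
            w.writerow([r.frame_index, r.time_s, r.head_xy, r.center_xy,
                        r.tail_xy, r.length_mm, r.status])
    return {
        "translation_max_error_px": trans_err,
        "calibration_scaling_max_rel_error": float(scale_err),
        "rerun_identical": float(buf1.getvalue() == buf2.getvalue()),
        "n": n_frames,
    }
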