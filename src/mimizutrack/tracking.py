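"""Feature-point initialization and frame-to-frame tracking.

Tracking starts from a user-supplied tail seed on the first frame: the tail
is the skeleton endpoint nearest the seed, the head is the geodesically
farthest skeleton pixel from the tail, and the center is the halfway point
of the tail-to-head path.  On subsequent frames the tail is matched first
(tails move slowest), to the endpoint nearest the previous tail in Euclidean
pixel distance; the head is the nearest remaining endpoint to the previous
head; the center is re-derived geodesically each frame.

All pixel coordinates in this module are ``(row, col)``; conversion to the
``(x, y)`` CSV convention happens when records are built.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .imaging_io import FrameSequence, TrajectoryRecord
from .preprocessing import (
    NoWormFoundError,
    apply_roi,
    binarize,
    largest_component,
    red_channel,
    remove_small_fragments,
)
from .skeletonization import (
    Skeleton,
    farthest_point,
    find_endpoints,
    geodesic_map,
    hilditch_thin,
    midpoint_on_path,
    prune_spurs,
)

__all__ = ["FeaturePoints", "init_feature_points", "track_step", "track_sequence"]

log = logging.getLogger(__name__)


@dataclass
class FeaturePoints:
    """Head, center, and tail pixels of one frame, with a tracking status."""

    head: tuple[int, int]
    center: tuple[int, int]
    tail: tuple[int, int]
    frame_index: int = 0
    status: str = "ok"


def _nearest(candidates, ref) -> tuple[int, int]:
    """Candidate with smallest Euclidean distance to ref; ties to (row, col)."""
    ref = (float(ref[0]), float(ref[1]))
    return min(
        candidates,
        key=lambda p: ((p[0] - ref[0]) ** 2 + (p[1] - ref[1]) ** 2, p),
    )


def init_feature_points(skel: Skeleton, tail_seed) -> FeaturePoints:
    """Seed the tracker on the first frame from a manual tail coordinate.

    The seed snaps to the nearest skeleton endpoint (nearest skeleton pixel
    if the skeleton is a closed loop with no endpoints).
    """
    if len(skel) == 0:
        raise ValueError("cannot initialize from an empty skeleton")
    endpoints = find_endpoints(skel)
    candidates = endpoints if endpoints else [tuple(p) for p in skel.pixels.tolist()]
    tail = _nearest(candidates, tail_seed)
    gmap = geodesic_map(skel, tail)
    head, _ = farthest_point(gmap)
    center = midpoint_on_path(gmap, head)
    return FeaturePoints(head=head, center=center, tail=tail, status="seeded")


def track_step(prev: FeaturePoints, skel: Skeleton) -> FeaturePoints:
    """Propagate feature points onto the next frame's skeleton.

    Tail first (slowest-moving point), matched by shortest Euclidean
    displacement; then the head among the remaining endpoints, nearest the
    previous head, ties broken by larger geodesic separation from the tail
    and then by (row, col).  The center is recomputed as the geodesic
    halfway point rather than matched.
    """
    if len(skel) == 0:
        return replace(prev, status="carried_forward")
    endpoints = find_endpoints(skel)
    if not endpoints:
        # closed-loop skeleton (coiled worm): best effort from nearest pixel
        tail = _nearest([tuple(p) for p in skel.pixels.tolist()], prev.tail)
        gmap = geodesic_map(skel, tail)
        head, _ = farthest_point(gmap)
    else:
        tail = _nearest(endpoints, prev.tail)
        gmap = geodesic_map(skel, tail)
        head_candidates = [e for e in endpoints if e != tail]
        if not head_candidates:
            head, _ = farthest_point(gmap)
        else:
            ref = (float(prev.head[0]), float(prev.head[1]))
            head = min(
                head_candidates,
                key=lambda p: (
                    (p[0] - ref[0]) ** 2 + (p[1] - ref[1]) ** 2,
                    -gmap.dist[gmap.index[p]],
                    p,
                ),
            )
    center = midpoint_on_path(gmap, head)
    return FeaturePoints(head=head, center=center, tail=tail, status="ok")


def _segment_frame(frame, config) -> Optional[np.ndarray]:
    """Raw frame -> largest-blob worm mask, or None when nothing is found."""
    chan = red_channel(frame)
    chan = apply_roi(chan, config.roi)
    roi_mask = config.roi.mask(chan.shape)
    mask = binarize(chan, config.threshold, config.polarity, roi_mask=roi_mask)
    mask = remove_small_fragments(mask, config.min_fragment_area)
    try:
        return largest_component(mask)
    except NoWormFoundError:
        return None


def track_sequence(frames: FrameSequence, config, tail_seed,
                   debug_dir: Optional[str] = None) -> list[TrajectoryRecord]:
    """Run the full pipeline over a frame sequence.

    Per frame: segment -> thin -> prune spurs -> initialize (frame 0) or
    track, then measure the geodesic tail-to-head body length.  Frames with
    no segmentable worm are emitted as ``carried_forward`` records repeating
    the last coordinates; tracking resumes on the next good frame.  A first
    frame with no worm aborts.

    ``tail_seed`` is ``(row, col)``; ``config`` is a resolved
    :class:`~mimizutrack.config.RunConfig`.  With ``debug_dir`` set, a PNG
    overlay of the skeleton and feature points is written per frame.
    """
    from .kinematics import body_length  # local import avoids a cycle

    records: list[TrajectoryRecord] = []
    prev: Optional[FeaturePoints] = None
    prev_length = 0.0
    for i, (frame, t) in enumerate(zip(frames.frames, frames.times)):
        mask = _segment_frame(frame, config)
        if mask is None:
            if prev is None:
                raise ValueError("cannot initialize: first frame contains no worm")
            log.debug("frame %d: no worm found, carrying forward", i)
            records.append(_to_record(prev, i, t, prev_length, "carried_forward"))
            continue
        skel = prune_spurs(hilditch_thin(mask), config.min_spur)
        if prev is None:
            fp = init_feature_points(skel, tail_seed)
        else:
            fp = track_step(prev, skel)
        length = body_length(skel, fp.tail, fp.head, config.calibration)
        log.debug(
            "frame %d: status=%s head=%s tail=%s length=%.2fmm",
            i, fp.status, fp.head, fp.tail, length,
        )
        records.append(_to_record(fp, i, t, length, fp.status))
        if debug_dir is not None:
            _write_overlay(frame, skel, fp, i, debug_dir)
        prev, prev_length = fp, length
    return records


def _write_overlay(frame, skel, fp: FeaturePoints, index: int, debug_dir: str) -> None:
    import os

    import imageio.v3 as iio

    os.makedirs(debug_dir, exist_ok=True)
    img = frame.copy() if frame.ndim == 3 else np.stack([frame] * 3, axis=-1)
    img[skel.pixels[:, 0], skel.pixels[:, 1]] = (0, 255, 0)
    for p, color in ((fp.head, (255, 0, 0)), (fp.center, (255, 255, 0)),
                     (fp.tail, (0, 0, 255))):
        r0, r1 = max(p[0] - 1, 0), min(p[0] + 2, img.shape[0])
        c0, c1 = max(p[1] - 1, 0), min(p[1] + 2, img.shape[1])
        img[r0:r1, c0:c1] = color
    iio.imwrite(os.path.join(debug_dir, f"overlay_{index:04d}.png"), img)


def _to_record(fp: FeaturePoints, index: int, t: float, length_mm: float,
               status: str) -> TrajectoryRecord:
    def xy(p):
        return (float(p[1]), float(p[0]))  # (row, col) -> (x, y)

    return TrajectoryRecord(
        frame_index=index, time_s=float(t),
        head_xy=xy(fp.head), center_xy=xy(fp.center), tail_xy=xy(fp.tail),
        length_mm=float(length_mm), status=status,
    )
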