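"""Frame-sequence input and trajectory CSV input/output.

Coordinate convention used on disk: ``x`` is the column index and ``y`` the
row index, both 0-based, referring to pixel centers.  In memory, raster
operations use ``(row, col)`` order as usual for numpy images; conversion
happens only at the CSV boundary.
"""

from __future__ import annotations

import csv
import glob as _glob
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Calibration",
    "FrameSequence",
    "TrajectoryRecord",
    "TRAJECTORY_HEADER",
    "TWO_POINT_HEADER",
    "load_frames",
    "read_trajectory_csv",
    "write_trajectory_csv",
]

#: Statuses a per-frame record may carry.  ``seeded`` marks the manually
#: initialized first frame, ``ok`` a normally tracked frame, ``lost`` a frame
#: with no segmentable worm, and ``carried_forward`` a lost frame whose
#: coordinates repeat the last known position.
VALID_STATUSES = ("ok", "seeded", "lost", "carried_forward")

TRAJECTORY_HEADER = [
    "frame", "time_s", "head_x", "head_y", "center_x", "center_y",
    "tail_x", "tail_y", "length_mm", "status",
]
#: Dialect produced by two-point (head/tail only) manual tracking.
TWO_POINT_HEADER = [
    "frame", "time_s", "head_x", "head_y", "tail_x", "tail_y",
    "length_mm", "status",
]

_IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff")


@dataclass(frozen=True)
class Calibration:
    """Physical scale of a recording: mm per pixel and seconds per frame."""

    mm_per_pixel: float = 0.2
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be strictly positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be strictly positive")


@dataclass
class FrameSequence:
    """An ordered, timestamped stack of same-sized 8-bit rasters."""

    frames: list[np.ndarray]
    times: list[float]

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("empty sequence")
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames must have equal length")
        h, w = self.frames[0].shape[:2]
        for i, f in enumerate(self.frames):
            if f.shape[:2] != (h, w):
                raise ValueError(
                    f"frame {i} has dimensions {f.shape[:2]}, expected {(h, w)}"
                )
        diffs = np.diff(self.times)
        if len(diffs) and not np.all(diffs > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def height(self) -> int:
        return self.frames[0].shape[0]

    @property
    def width(self) -> int:
        return self.frames[0].shape[1]


@dataclass
class TrajectoryRecord:
    """Per-frame feature-point coordinates, body length, and status.

    ``center_xy`` may be ``None`` when the record comes from a two-point
    (head/tail only) reference trajectory.
    """

    frame_index: int
    time_s: float
    head_xy: tuple[float, float]
    center_xy: Optional[tuple[float, float]]
    tail_xy: tuple[float, float]
    length_mm: float
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.status not in VALID_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.length_mm < 0:
            raise ValueError("length_mm must be non-negative")


def load_frames(path: str, interval: float = 1.0) -> FrameSequence:
    """Load an ordered frame sequence from a directory or glob pattern.

    Frames are ordered by lexicographic filename (zero-padded names are
    therefore required for >9 frames) and timestamped ``index * interval``
    seconds.

    Parameters
    ----------
    path:
        Directory containing image files, or a glob pattern.
    interval:
        Seconds between consecutive frames.
    """
    if interval <= 0:
        raise ValueError("interval must be strictly positive")
    if os.path.isdir(path):
        names = [
            os.path.join(path, n)
            for n in os.listdir(path)
            if n.lower().endswith(_IMAGE_EXTENSIONS)
        ]
    else:
        names = _glob.glob(path)
    names.sort()
    if not names:
        raise ValueError(f"empty sequence: no image files under {path!r}")
    frames = [np.asarray(iio.imread(n)) for n in names]
    h, w = frames[0].shape[:2]
    for name, f in zip(names, frames):
        if f.shape[:2] != (h, w):
            raise ValueError(
                f"dimension mismatch: {name} is {f.shape[:2]}, expected {(h, w)}"
            )
    times = [i * interval for i in range(len(frames))]
    return FrameSequence(frames=frames, times=times)


def _fmt(v: float) -> str:
    # repr gives the shortest string that round-trips the float exactly
    return repr(float(v))


def write_trajectory_csv(records: Sequence[TrajectoryRecord], path: str) -> None:
    """Write records to ``path`` in the canonical trajectory dialect.

    Comma-separated, '.' decimal, UTF-8, LF line endings.  Round-trips
    losslessly through :func:`read_trajectory_csv`.
    """
    if not records:
        raise ValueError("cannot write an empty trajectory")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(TRAJECTORY_HEADER)
        for r in records:
            cx, cy = ("", "") if r.center_xy is None else (
                _fmt(r.center_xy[0]), _fmt(r.center_xy[1]))
            writer.writerow([
                r.frame_index, _fmt(r.time_s),
                _fmt(r.head_xy[0]), _fmt(r.head_xy[1]),
                cx, cy,
                _fmt(r.tail_xy[0]), _fmt(r.tail_xy[1]),
                _fmt(r.length_mm), r.status,
            ])


def read_trajectory_csv(path: str) -> list[TrajectoryRecord]:
    """Read a trajectory CSV (full or two-point head/tail dialect).

    Two-point files lack the ``center_x``/``center_y`` columns; their records
    come back with ``center_xy=None``.  Malformed rows raise ``ValueError``
    naming the 1-based line number.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected a header row")
        if header == TRAJECTORY_HEADER:
            has_center = True
        elif header == TWO_POINT_HEADER:
            has_center = False
        else:
            raise ValueError(f"{path}: unrecognized header {header!r}")
        n_cols = len(header)
        records: list[TrajectoryRecord] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != n_cols:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_cols} fields, got {len(row)}"
                )
            try:
                frame = int(row[0])
                t = float(row[1])
                head = (float(row[2]), float(row[3]))
                if has_center:
                    if row[4] == "" and row[5] == "":
                        center = None
                    else:
                        center = (float(row[4]), float(row[5]))
                    tail = (float(row[6]), float(row[7]))
                    length = float(row[8])
                    status = row[9]
                else:
                    center = None
                    tail = (float(row[4]), float(row[5]))
                    length = float(row[6])
                    status = row[7]
                records.append(TrajectoryRecord(
                    frame_index=frame, time_s=t, head_xy=head,
                    center_xy=center, tail_xy=tail,
                    length_mm=length, status=status,
                ))
            except ValueError as exc:
                if "line" in str(exc) and path in str(exc):
                    raise
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
        return records
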