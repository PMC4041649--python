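"""Segmentation of the worm from a raw frame.

The pipeline is: restrict to the circular dish interior, keep the red channel
(where worm/background contrast is highest under the recording lighting),
threshold to a binary mask with the worm as foreground, drop small noise
fragments, and keep the single largest blob.

Foreground connectivity is 8-connected throughout, so a thin diagonal worm
never splits into fragments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "CircleROI",
    "NoWormFoundError",
    "apply_roi",
    "binarize",
    "circle_from_marks",
    "largest_component",
    "red_channel",
    "remove_small_fragments",
]

log = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)


class NoWormFoundError(Exception):
    """Raised when a frame contains no foreground after segmentation."""


@dataclass(frozen=True)
class CircleROI:
    """Circular region of interest: the dish interior.

    ``center_xy`` is ``(x, y)`` in pixels (x = column, y = row).
    """

    center_xy: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be strictly positive")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean raster of pixel centers inside (or on) the circle."""
        h, w = shape[:2]
        yy, xx = np.mgrid[0:h, 0:w]
        cx, cy = self.center_xy
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= self.radius ** 2


def circle_from_marks(p1, p2, p3) -> CircleROI:
    """Circumcircle through three rim marks ``(x, y)``.

    The dish outline is marked at three positions on its edge; the circle
    through them is the ROI.  Collinear or coincident marks raise
    ``ValueError("degenerate marks")``.
    """
    (x1, y1), (x2, y2), (x3, y3) = (map(float, p) for p in (p1, p2, p3))
    # Circumcenter from the two perpendicular-bisector equations.
    a = np.array([[x2 - x1, y2 - y1], [x3 - x1, y3 - y1]])
    b = 0.5 * np.array([
        x2 ** 2 - x1 ** 2 + y2 ** 2 - y1 ** 2,
        x3 ** 2 - x1 ** 2 + y3 ** 2 - y1 ** 2,
    ])
    det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
    scale = max(abs(a).max(), 1.0) ** 2
    if abs(det) < 1e-9 * scale:
        raise ValueError("degenerate marks: points are collinear or coincident")
    cx, cy = np.linalg.solve(a, b)
    r = float(np.hypot(x1 - cx, y1 - cy))
    return CircleROI(center_xy=(float(cx), float(cy)), radius=r)


def apply_roi(frame: np.ndarray, roi: CircleROI) -> np.ndarray:
    """Zero every pixel whose center lies outside the circle; idempotent."""
    out = frame.copy()
    inside = roi.mask(frame.shape[:2])
    if frame.ndim == 3:
        out[~inside, :] = 0
    else:
        out[~inside] = 0
    return out


def red_channel(frame: np.ndarray) -> np.ndarray:
    """Project a 3-channel frame to its red component.

    Worm/background contrast is highest in red under the recording's
    lighting, so only this component is segmented.  Grayscale input passes
    through unchanged (with a logged note).
    """
    if frame.ndim == 2:
        log.info("red_channel: input already single-channel, passing through")
        return frame
    if frame.ndim != 3 or frame.shape[2] < 3:
        raise ValueError(f"expected a 3-channel frame, got shape {frame.shape}")
    return frame[:, :, 0]


def binarize(
    channel: np.ndarray,
    threshold: Union[int, float, str] = "auto",
    polarity: str = "dark_object",
    roi_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Threshold a single-channel raster to a boolean worm mask.

    With ``polarity="dark_object"`` (default) pixels strictly below the
    threshold become foreground; with ``"bright_object"`` pixels strictly
    above it do.  ``threshold="auto"`` computes Otsu's threshold over the
    in-ROI pixels (all pixels when ``roi_mask`` is None).  When a
    ``roi_mask`` is given the foreground is restricted to it, so the black
    exterior left by :func:`apply_roi` can never masquerade as worm.
    """
    if polarity not in ("dark_object", "bright_object"):
        raise ValueError(f"unknown polarity {polarity!r}")
    if channel.ndim != 2:
        raise ValueError("binarize expects a single-channel raster")
    sel = roi_mask if roi_mask is not None else np.ones(channel.shape, bool)
    auto = threshold == "auto"
    if auto:
        vals = channel[sel]
        if vals.size == 0:
            raise ValueError("empty ROI: cannot compute automatic threshold")
        if vals.min() == vals.max():
            # no contrast inside the ROI: there is nothing to segment
            return np.zeros(channel.shape, dtype=bool)
        t = float(threshold_otsu(vals))
    else:
        t = float(threshold)
        if not 0 <= t <= 255:
            raise ValueError("threshold must lie in [0, 255]")
    if polarity == "dark_object":
        # Otsu's threshold bin belongs to the dark class, so the automatic
        # threshold is inclusive; explicit thresholds use the strict-<
        # contract.
        fg = channel <= t if auto else channel < t
    else:
        fg = channel > t
    return fg & sel


def remove_small_fragments(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop every 8-connected component with area < ``min_area`` pixels.

    The threshold is inclusive: a component of exactly ``min_area`` pixels
    survives.  Never increases the foreground; identity for ``min_area=1``.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if min_area == 1 or not mask.any():
        return mask.copy()
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    keep = areas >= min_area
    return keep[labels]


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Area ties resolve to the component whose first pixel in raster order is
    smallest (row, col).  An empty mask raises :class:`NoWormFoundError` so
    the caller can mark the frame lost.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        raise NoWormFoundError("no worm found: mask has no foreground")
    areas = np.bincount(labels.ravel())[1:]
    # ndimage assigns labels in raster order of first pixel, so argmax's
    # first-maximum rule is exactly the (row, col) tie-break.
    keep = int(np.argmax(areas)) + 1
    return labels == keep
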