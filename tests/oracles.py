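"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: BFS flood fill for components, exhaustive 256-way search
for Otsu, repeated edge relaxation (no priority queue) for shortest paths,
and direct point-to-segment geometry for rendering.  None of these share
code with the package.
"""

from __future__ import annotations

import math

import numpy as np

_NB8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def flood_fill_components(mask: np.ndarray) -> list[set]:
    """8-connected components of a boolean mask via BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    for r, c in np.argwhere(mask):
        if seen[r, c]:
            continue
        comp = set()
        stack = [(int(r), int(c))]
        seen[r, c] = True
        while stack:
            y, x = stack.pop()
            comp.add((y, x))
            for dy, dx in _NB8:
                ny, nx = y + dy, x + dx
                if (0 <= ny < mask.shape[0] and 0 <= nx < mask.shape[1]
                        and mask[ny, nx] and not seen[ny, nx]):
                    seen[ny, nx] = True
                    stack.append((ny, nx))
        comps.append(comp)
    return comps


def brute_otsu(values: np.ndarray) -> tuple[int, float]:
    """Exhaustive Otsu: the integer threshold t (class0 = values <= t)
    maximizing between-class variance, searched over all 256 levels.

    Returns (t, max between-class variance); ties go to the smallest t.
    """
    values = np.asarray(values).ravel().astype(float)
    best_t, best_var = 0, -1.0
    for t in range(256):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / values.size
        w1 = hi.size / values.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-12:
            best_t, best_var = t, var
    return best_t, best_var


def between_class_variance(values: np.ndarray, t: float) -> float:
    """Between-class variance of splitting ``values`` at threshold ``t``."""
    values = np.asarray(values).ravel().astype(float)
    lo = values[values <= t]
    hi = values[values > t]
    if lo.size == 0 or hi.size == 0:
        return 0.0
    w0 = lo.size / values.size
    w1 = hi.size / values.size
    return w0 * w1 * (lo.mean() - hi.mean()) ** 2


def relax_shortest_paths(pixels, source, diagonal_weight=math.sqrt(2)) -> dict:
    """Single-source shortest paths by repeated relaxation over all edges.

    Quadratic and queue-free, usable for skeletons up to a few hundred
    pixels.  Returns {pixel: distance}; unreachable pixels get inf.
    """
    pixels = [tuple(p) for p in pixels]
    pset = set(pixels)
    dist = {p: math.inf for p in pixels}
    dist[tuple(source)] = 0.0
    edges = []
    for r, c in pixels:
        for dr, dc in _NB8:
            q = (r + dr, c + dc)
            if q in pset:
                w = 1.0 if dr == 0 or dc == 0 else diagonal_weight
                edges.append(((r, c), q, w))
    changed = True
    while changed:
        changed = False
        for p, q, w in edges:
            if dist[p] + w < dist[q] - 1e-12:
                dist[q] = dist[p] + w
                changed = True
    return dist


def point_segment_distance(x, y, ax, ay, bx, by) -> float:
    """Euclidean distance from (x, y) to the segment (a, b)."""
    dx, dy = bx - ax, by - ay
    den = dx * dx + dy * dy
    if den == 0:
        return math.hypot(x - ax, y - ay)
    u = max(0.0, min(1.0, ((x - ax) * dx + (y - ay) * dy) / den))
    return math.hypot(x - (ax + u * dx), y - (ay + u * dy))


def polyline_disk_union(shape, polyline, radius) -> np.ndarray:
    """Brute-force union of disks swept along a polyline (all pixels, all
    segments)."""
    h, w = shape
    out = np.zeros(shape, dtype=bool)
    pts = np.asarray(polyline, dtype=float)
    for r in range(h):
        for c in range(w):
            for (ax, ay), (bx, by) in zip(pts[:-1], pts[1:]):
                if point_segment_distance(c, r, ax, ay, bx, by) <= radius:
                    out[r, c] = True
                    break
    return out
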