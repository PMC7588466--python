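"""Small planar-geometry helpers shared across the pipeline.

Conventions (used everywhere in the package): image origin is the top-left
corner, x increases rightward (columns), y increases downward (rows).
Angles are measured with ``atan2(dy, dx)`` in this frame; perimeter angles
are reported relative to the front direction and wrapped as documented by
each caller.
"""

from __future__ import annotations

import numpy as np


def wrap_angle_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to [0, 360)."""
    return np.mod(angle, 360.0)


def wrap_signed_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to (-180, 180]."""
    a = np.mod(np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0
    # map -180 -> 180 so the interval is half-open on the left
    a = np.where(a == -180.0, 180.0, a)
    if np.isscalar(angle):
        return float(a)
    return a


def fold_angle_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Fold angle(s) to [0, 180] (unsigned deviation)."""
    a = np.abs(wrap_signed_deg(angle))
    if np.isscalar(angle):
        return float(a)
    return a


def polygon_signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon given as (N, 2) xy vertices.

    Positive for counterclockwise orientation in the (x right, y down)
    coordinate frame.
    """
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(points: np.ndarray) -> np.ndarray:
    """Area centroid of a simple closed polygon, (N, 2) xy vertices."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-12:
        return p.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def polygon_perimeter(points: np.ndarray) -> float:
    """Total arc length of the closed polygon."""
    p = np.asarray(points, dtype=float)
    d = np.roll(p, -1, axis=0) - p
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def cumulative_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length at each vertex of a closed polygon.

    Returns an array of length N + 1; the last entry is the full perimeter
    (the closing segment back to vertex 0).
    """
    p = np.asarray(points, dtype=float)
    d = np.roll(p, -1, axis=0) - p
    seg = np.hypot(d[:, 0], d[:, 1])
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_closed_polyline(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed polygon to n_points equally spaced by arc length.

    The first output vertex coincides with the first input vertex;
    orientation is preserved.
    """
    p = np.asarray(points, dtype=float)
    s = cumulative_arclength(p)
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate polygon: zero perimeter")
    closed = np.vstack([p, p[:1]])
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return np.column_stack([x, y])


def outward_normals(points: np.ndarray) -> np.ndarray:
    """Unit outward normals at each vertex of a closed polygon.

    Uses central differences for the tangent; outward is defined for a
    counterclockwise-oriented polygon (positive shoelace area) in the
    image frame.
    """
    p = np.asarray(points, dtype=float)
    t = np.roll(p, -1, axis=0) - np.roll(p, 1, axis=0)
    norm = np.hypot(t[:, 0], t[:, 1])
    norm[norm == 0] = 1.0
    t = t / norm[:, None]
    # rotate tangent by -90deg (x right, y down): n = (t_y, -t_x) points
    # outward for a CCW (positive-area) polygon in this frame
    n = np.column_stack([t[:, 1], -t[:, 0]])
    c = polygon_centroid(p)
    # orientation guard: flip if normals point inward on average
    if np.mean(np.sum((p - c) * n, axis=1)) < 0:
        n = -n
    return n
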