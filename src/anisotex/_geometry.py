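"""Shared computational-geometry helpers: convex hulls, calipers, sphere sampling."""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError


def pixel_corner_points(coords: np.ndarray) -> np.ndarray:
    """Corner lattice points of a set of unit pixels given by (row, col) indices.

    Caliper measurements on digitized shapes use pixel *corners*, not centers,
    so a 40x20 px rectangle measures 40 and 20, not 39 and 19.
    """
    coords = np.asarray(coords, dtype=float)
    offsets = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    pts = (coords[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    return np.unique(pts, axis=0)


def convex_hull_points(points: np.ndarray) -> np.ndarray:
    """Vertices of the 2D convex hull in counterclockwise order.

    Degenerate (collinear) inputs fall back to the two extreme points.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        return points
    try:
        hull = ConvexHull(points)
    except QhullError:
        # collinear: extreme points along the principal direction
        d = points - points.mean(axis=0)
        v = np.linalg.svd(d, full_matrices=False)[2][0]
        t = d @ v
        return points[[int(np.argmin(t)), int(np.argmax(t))]]
    return points[hull.vertices]


def max_caliper(hull_pts: np.ndarray) -> float:
    """Maximum caliper (Feret) diameter: largest pairwise distance of hull vertices."""
    hull_pts = np.asarray(hull_pts, dtype=float)
    if len(hull_pts) == 1:
        return 0.0
    d2 = np.sum((hull_pts[:, None, :] - hull_pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def min_caliper(hull_pts: np.ndarray) -> float:
    """Minimum caliper width by rotating calipers over hull edges.

    For each hull edge, the caliper width is the maximum distance of any
    vertex from the edge's supporting line; the minimum over edges is the
    width of the shape.
    """
    hull_pts = np.asarray(hull_pts, dtype=float)
    n = len(hull_pts)
    if n == 1:
        return 0.0
    if n == 2:
        return 0.0
    widths = []
    for i in range(n):
        p, q = hull_pts[i], hull_pts[(i + 1) % n]
        edge = q - p
        norm = np.linalg.norm(edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        widths.append(np.abs((hull_pts - p) @ normal).max())
    return float(min(widths))


def fibonacci_directions(n: int = 162) -> np.ndarray:
    """Quasi-uniform unit directions on the sphere (Fibonacci lattice), shape (n, 3)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5.0**0.5) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([z, r * np.sin(phi), r * np.cos(phi)])


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle_rad) * k + (1.0 - np.cos(angle_rad)) * (k @ k)


def orthonormal_frame(v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (v, u1, u2) with v normalized and u1, u2 completing a right-handed frame."""
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(v @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u1 = np.cross(v, helper)
    u1 /= np.linalg.norm(u1)
    u2 = np.cross(v, u1)
    return v, u1, u2
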