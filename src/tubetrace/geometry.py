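"""Small 3D geometry helpers shared across modules.

All world coordinates are (z, y, x) in micrometres, matching the axis order
of chunked microscopy volumes; voxel index * spacing = world position.
"""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector has no direction")
    return v / n


def orthonormal_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return a right-handed orthonormal frame (n, u, v) with u x v = n."""
    n = unit(normal)
    # pick the world axis least aligned with n to seed u
    seed = np.zeros(3)
    seed[int(np.argmin(np.abs(n)))] = 1.0
    u = unit(np.cross(seed, n))
    v = np.cross(n, u)
    return n, u, v


def rotate_about_axis(vec: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of `vec` about unit `axis`."""
    a = unit(axis)
    v = np.asarray(vec, dtype=float)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return v * c + np.cross(a, v) * s + a * np.dot(a, v) * (1.0 - c)


def transport_frame(
    u: np.ndarray, v: np.ndarray, n_old: np.ndarray, n_new: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-minimizing transport of in-plane axes (u, v) onto a new normal.

    Applies the smallest rotation taking n_old to n_new (about their common
    perpendicular); keeps the in-plane orientation stable between consecutive
    tracking steps so the ellipse angle phi is comparable frame to frame.
    """
    n0, n1 = unit(n_old), unit(n_new)
    c = float(np.clip(np.dot(n0, n1), -1.0, 1.0))
    axis = np.cross(n0, n1)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if c > 0:
            return np.array(u, float), np.array(v, float)
        # antiparallel: rotate 180 deg about u
        return np.array(u, float), -np.array(v, float)
    angle = np.arctan2(s, c)
    u2 = rotate_about_axis(u, axis, angle)
    v2 = rotate_about_axis(v, axis, angle)
    # re-orthogonalize against drift
    u2 = unit(u2 - np.dot(u2, n1) * n1)
    v2 = np.cross(n1, u2)
    return u2, v2


def polyline_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length of an (N, 3) polyline, starting at 0."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("expected (N, 3) points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at uniform arc-length step; returns (points, arcs).

    The final point is always included, so the last interval may be shorter.
    """
    pts = np.asarray(points, dtype=float)
    s = polyline_arclength(pts)
    total = s[-1]
    if total == 0:
        return pts[:1].copy(), np.array([0.0])
    grid = np.arange(0.0, total, step)
    if total - grid[-1] > 1e-9:
        grid = np.concatenate([grid, [total]])
    out = np.empty((grid.size, 3))
    for k in range(3):
        out[:, k] = np.interp(grid, s, pts[:, k])
    return out, grid
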