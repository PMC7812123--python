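"""Low-level geometric queries shared across the pipeline.

Distances are Euclidean, in millimetres, in whatever world frame the inputs
share.  Point-to-polyline distances project onto segments (not vertices only)
so results do not depend on how densely a curve is sampled.  Point-to-surface
distances are exact point-to-triangle queries, with candidate faces found
through a k-d tree on face centroids.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "point_segment_distances",
    "min_distance_to_polyline",
    "min_distance_to_polylines",
    "resample_polyline",
    "polyline_length",
    "closest_point_on_surface",
]


def polyline_length(points: np.ndarray) -> float:
    """Total arc length of an ordered polyline (n, 3)."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample an ordered polyline at (approximately) uniform arc spacing.

    Endpoints are preserved exactly.  ``spacing`` must be positive.
    """
    points = np.asarray(points, dtype=float)
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if len(points) < 2:
        return points.copy()
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return points[:1].copy()
    n = max(2, int(np.ceil(total / spacing)) + 1)
    t = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(t, s, points[:, k])
    return out


def point_segment_distances(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances from ``points`` (n, 3) to one segment [a, b]."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def min_distance_to_polyline(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Min distance from each query point to a polyline (segments included)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    poly = np.asarray(polyline, dtype=float)
    if len(poly) == 1:
        return np.linalg.norm(points - poly[0], axis=1)
    a = poly[:-1]  # (m, 3)
    b = poly[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)  # (m,)
    denom_safe = np.where(denom == 0.0, 1.0, denom)
    # (n, m) parameter of the projection of each point onto each segment
    t = np.clip(
        np.einsum("nk,mk->nm", points, ab) - np.einsum("mk,mk->m", a, ab),
        None,
        None,
    )
    t = np.clip(t / denom_safe, 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    return d.min(axis=1)


def min_distance_to_polylines(points: np.ndarray, polylines: list[np.ndarray]) -> np.ndarray:
    """Min distance from each query point to the union of several polylines."""
    if not polylines:
        raise ValueError("need at least one polyline")
    d = min_distance_to_polyline(points, polylines[0])
    for poly in polylines[1:]:
        d = np.minimum(d, min_distance_to_polyline(points, poly))
    return d


def _point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact closest points on triangles.

    ``p``: (n, 3) query points; ``tri``: (n, 3, 3) one triangle per point.
    Returns (closest points (n, 3), distances (n,)).  Region classification
    follows the standard barycentric clamping construction.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1 - d3
    v = np.where(denom != 0, d1 / np.where(denom == 0, 1, denom), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2 - d6
    w = np.where(denom != 0, d2 / np.where(denom == 0, 1, denom), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    w = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1, denom), 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]

    dist = np.linalg.norm(p - out, axis=1)
    return out, dist


class SurfaceDistanceQuery:
    """Closest-point-on-surface queries against a fixed triangle soup.

    Candidate triangles are the ``k`` whose centroids are nearest the query
    point (k-d tree); the exact point-to-triangle distance is then minimised
    over candidates.  ``k`` = 16 is exact for the well-shaped, near-uniform
    meshes this pipeline produces; raise it for pathological triangulations.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k: int = 16):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.k = min(k, len(self.faces))
        centroids = self.vertices[self.faces].mean(axis=1)
        self._tree = cKDTree(centroids)

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (closest surface points (n, 3), distances (n,))."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        _, idx = self._tree.query(points, k=self.k)
        idx = np.atleast_2d(idx)
        n, k = idx.shape
        flat_pts = np.repeat(points, k, axis=0)
        flat_tris = self.vertices[self.faces[idx.ravel()]]
        cp, d = _point_triangle_distance(flat_pts, flat_tris)
        d = d.reshape(n, k)
        best = d.argmin(axis=1)
        rows = np.arange(n)
        return cp.reshape(n, k, 3)[rows, best], d[rows, best]


def closest_point_on_surface(
    points: np.ndarray, vertices: np.ndarray, faces: np.ndarray, k: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """One-shot wrapper around :class:`SurfaceDistanceQuery`."""
    return SurfaceDistanceQuery(vertices, faces, k=k).query(points)
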