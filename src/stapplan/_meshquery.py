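"""Vectorized mesh queries: ray-triangle intersection and point-triangle distance.

Both are core primitives of the planner (trajectory/surface intersections and
3D clearance checks) and operate on plain ``(m, 3, 3)`` triangle arrays so that
they work on open, non-indexed soups exactly as on watertight meshes.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def ray_hits(origin, direction, triangles):
    """Parameters ``t`` of all intersections of a ray with a triangle soup.

    Moller-Trumbore, vectorized over triangles.  Returns a sorted 1D array of
    signed ray parameters ``t`` (point = origin + t * direction) for every hit
    with ``t`` anywhere on the LINE; callers filter by sign if they want a
    half-line.  Degenerate (parallel) triangles yield no hit.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    tri = np.asarray(triangles, dtype=float)
    if tri.size == 0:
        return np.empty(0)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > _EPS
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origin - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1)
    v = np.einsum("j,ij->i", direction, qvec) * inv_det
    t = np.einsum("ij,ij->i", e2, qvec) * inv_det
    # small tolerance on barycentric bounds so edge-grazing rays still count
    bary_tol = 1e-9
    hit = ok & (u >= -bary_tol) & (v >= -bary_tol) & (u + v <= 1.0 + bary_tol)
    return np.sort(t[hit])


def point_triangle_closest(points, triangles, chunk=256):
    """Closest point on a triangle soup for each query point.

    Implements the standard closest-point-on-triangle region test (Ericson,
    *Real-Time Collision Detection*) with full broadcasting; chunked over
    triangles to bound memory.

    Returns ``(distances, closest_points)`` with shapes ``(n,)`` / ``(n, 3)``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tri = np.asarray(triangles, dtype=float)
    n = len(pts)
    best_d2 = np.full(n, np.inf)
    best_pt = np.zeros((n, 3))
    for start in range(0, len(tri), chunk):
        t = tri[start : start + chunk]
        cp = _closest_on_triangles(pts, t)  # (n, k, 3)
        d2 = np.sum((cp - pts[:, None, :]) ** 2, axis=2)
        k_idx = np.argmin(d2, axis=1)
        rows = np.arange(n)
        d2min = d2[rows, k_idx]
        better = d2min < best_d2
        best_d2[better] = d2min[better]
        best_pt[better] = cp[rows[better], k_idx[better]]
    return np.sqrt(best_d2), best_pt


def point_mesh_distance(points, triangles, chunk=256):
    """Unsigned distance from each query point to the triangle soup."""
    return point_triangle_closest(points, triangles, chunk=chunk)[0]


def _closest_on_triangles(pts, tri):
    """Closest point on each triangle for each point; shapes (n,3),(k,3,3)->(n,k,3)."""
    a = tri[None, :, 0, :]  # (1, k, 3)
    b = tri[None, :, 1, :]
    c = tri[None, :, 2, :]
    p = pts[:, None, :]  # (n, 1, 3)

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)

    bp = p - b
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)

    cp_ = p - c
    d5 = np.sum(ab * cp_, axis=-1)
    d6 = np.sum(ac * cp_, axis=-1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    out = np.empty(np.broadcast_shapes(p.shape, a.shape))
    done = np.zeros(out.shape[:2], dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        out[m] = np.broadcast_to(value, out.shape)[m]
        done[m] = True

    # vertex regions
    assign((d1 <= 0) & (d2 <= 0), a)
    assign((d3 >= 0) & (d4 <= d3), b)
    assign((d6 >= 0) & (d5 <= d6), c)
    # edge AB
    denom_ab = np.where(np.abs(d1 - d3) > _EPS, d1 - d3, 1.0)
    v_ab = np.clip(d1 / denom_ab, 0.0, 1.0)[..., None]
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab * ab)
    # edge AC
    denom_ac = np.where(np.abs(d2 - d6) > _EPS, d2 - d6, 1.0)
    w_ac = np.clip(d2 / denom_ac, 0.0, 1.0)[..., None]
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac * ac)
    # edge BC
    denom_bc = (d4 - d3) + (d5 - d6)
    denom_bc = np.where(np.abs(denom_bc) > _EPS, denom_bc, 1.0)
    w_bc = np.clip((d4 - d3) / denom_bc, 0.0, 1.0)[..., None]
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc * (c - b))
    # face interior
    denom = va + vb + vc
    denom = np.where(np.abs(denom) > _EPS, denom, 1.0)
    v = (vb / denom)[..., None]
    w = (vc / denom)[..., None]
    assign(np.ones_like(done), a + v * ab + w * ac)
    return out
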