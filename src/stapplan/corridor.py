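"""Truncated-cone surgical corridor: entry point, maximal angle, mesh, depths.

The corridor is a truncated cone whose small base (diameter = drill tip)
sits on the target at the SM's proximal surface and whose axis follows the
optimal linear trajectory.  Its half-angle is the largest value for which
every point of the lateral surface keeps the minimum safety distance from
the facial nerve, sigmoid sinus and vestibulocochlear system, found by
bisection against full 3D mesh distances (the 2D drillable region only seeds
the trajectory; clearance is certified in 3D because the cone sweeps
territory off the projection plane).  The temporal bone is the material
being drilled and the SM is the target, so neither is a clearance obstacle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._meshquery import point_mesh_distance, point_triangle_closest, ray_hits
from .errors import CorridorError
from .geometry_io import AnatomySet, SurfaceMesh
from .orientation import PlanningConfig

#: bisection tolerance on the cone half-angle, degrees
ANGLE_TOL_DEG = 0.05

#: default clearance sampling of the lateral cone surface
N_CIRCUMFERENTIAL = 64
N_AXIAL = 32


@dataclass
class SurgicalCorridor:
    """A clearance-certified truncated-cone corridor in RAS mm."""

    target_3d: np.ndarray
    entry_3d: np.ndarray
    axis: np.ndarray  # unit vector, entry -> target
    half_angle_deg: float
    tip_diameter_mm: float
    skull_diameter_mm: float
    mesh: SurfaceMesh

    @property
    def depth_mm(self) -> float:
        return float(np.linalg.norm(self.entry_3d - self.target_3d))


def entry_point(tb_mesh: SurfaceMesh, target_3d, axis) -> np.ndarray:
    """Most lateral intersection of the trajectory line with the TB surface.

    The ray runs from the target opposite to the drilling axis; the last hit
    is the outer cortex where drilling starts.
    """
    target = np.asarray(target_3d, dtype=float)
    direction = -_unit(axis)
    ts = ray_hits(target, direction, tb_mesh.triangles)
    ts = ts[ts > 1e-9]
    if len(ts) == 0:
        raise CorridorError("trajectory does not intersect the temporal bone surface")
    return target + ts[-1] * direction


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise CorridorError("zero-length trajectory axis")
    return v / n


def _basis_perpendicular(axis: np.ndarray):
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def cone_surface_points(target_3d, axis, length_mm, tip_radius_mm,
                        half_angle_deg, n_circ=N_CIRCUMFERENTIAL,
                        n_axial=N_AXIAL) -> np.ndarray:
    """Sample the lateral surface of the truncated cone.

    The cone opens laterally (away from the target): at arc length ``s``
    from the tip the radius is ``tip_radius + tan(half_angle) * s``.
    """
    target = np.asarray(target_3d, dtype=float)
    axis = _unit(axis)
    e1, e2 = _basis_perpendicular(axis)
    s = np.linspace(0.0, length_mm, n_axial)
    radii = tip_radius_mm + math.tan(math.radians(half_angle_deg)) * s
    phi = np.linspace(0.0, 2.0 * math.pi, n_circ, endpoint=False)
    ring = np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2  # (n_circ, 3)
    centers = target - axis * s[:, None]  # (n_axial, 3)
    pts = centers[:, None, :] + radii[:, None, None] * ring[None, :, :]
    return pts.reshape(-1, 3)


def _obstacle_triangles(anatomy: AnatomySet) -> np.ndarray:
    return np.concatenate(
        [anatomy[r].triangles for r in ("FN", "SS", "VC")], axis=0
    )


def min_clearance(points: np.ndarray, obstacle_tris: np.ndarray) -> float:
    """Minimum distance from sampled corridor points to the obstacle meshes."""
    return float(point_mesh_distance(points, obstacle_tris).min())


def violates_clearance(points: np.ndarray, obstacle_tris: np.ndarray,
                       msd_mm: float) -> bool:
    """Whether any sampled point lies closer than ``msd`` to the obstacles.

    Triangles and points that cannot possibly come within the MSD of each
    other (axis-aligned bounding-box argument) are discarded before the
    exact distance test, which keeps the bisection fast.
    """
    tlo = obstacle_tris.min(axis=1)
    thi = obstacle_tris.max(axis=1)
    plo = points.min(axis=0)
    phi = points.max(axis=0)
    gap = np.maximum(np.maximum(tlo - phi, plo - thi), 0.0)
    near = np.linalg.norm(gap, axis=1) <= msd_mm
    if not near.any():
        return False
    tris = obstacle_tris[near]
    lo = tris.reshape(-1, 3).min(axis=0) - msd_mm
    hi = tris.reshape(-1, 3).max(axis=0) + msd_mm
    keep = np.all((points >= lo) & (points <= hi), axis=1)
    if not keep.any():
        return False
    return bool(point_mesh_distance(points[keep], tris).min() < msd_mm)


def max_half_angle(anatomy: AnatomySet, target_3d, axis, config: PlanningConfig,
                   n_circ=N_CIRCUMFERENTIAL, n_axial=N_AXIAL) -> float:
    """Largest half-angle whose lateral surface keeps the MSD, by bisection.

    Raises :class:`CorridorError` when even the straight drill cylinder
    (half-angle 0) violates clearance: no corridor exists on this trajectory.
    """
    target = np.asarray(target_3d, dtype=float)
    axis = _unit(axis)
    entry = entry_point(anatomy["TB"], target, axis)
    length = float(np.linalg.norm(entry - target))
    tip_radius = config.drill_diameter_mm / 2.0
    obstacles = _obstacle_triangles(anatomy)

    def clear(theta_deg: float) -> bool:
        pts = cone_surface_points(target, axis, length, tip_radius, theta_deg,
                                  n_circ, n_axial)
        return not violates_clearance(pts, obstacles, config.msd_mm)

    if not clear(0.0):
        raise CorridorError(
            "even a straight drill cylinder violates the minimum safety "
            "distance; the corridor is infeasible on this trajectory"
        )
    cap = config.max_cone_half_angle_deg
    if clear(cap):
        return cap
    lo, hi = 0.0, cap  # invariant: clear(lo), not clear(hi)
    while hi - lo > ANGLE_TOL_DEG:
        mid = 0.5 * (lo + hi)
        if clear(mid):
            lo = mid
        else:
            hi = mid
    return lo


def build_cone(target_3d, entry_3d, half_angle_deg, tip_diameter_mm,
               sections=64):
    """Watertight truncated-cone mesh plus the skull-plane diameter.

    ``skull_diameter = tip_diameter + 2 tan(half_angle) |entry - target|``.
    """
    target = np.asarray(target_3d, dtype=float)
    entry = np.asarray(entry_3d, dtype=float)
    depth = float(np.linalg.norm(entry - target))
    if depth <= 1e-9:
        raise CorridorError("entry and target coincide; cannot build a corridor")
    axis = (target - entry) / depth
    tip_r = tip_diameter_mm / 2.0
    skull_r = tip_r + math.tan(math.radians(half_angle_deg)) * depth
    # right-handed basis (e1, e2, w) with w pointing tip -> skull; rings
    # traversed with increasing phi are CCW seen from the skull side
    w = -axis
    e1 = np.cross(w, _basis_perpendicular(w)[0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(w, e1)
    phi = np.linspace(0.0, 2.0 * math.pi, sections, endpoint=False)
    ring = np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2

    tip_ring = target + tip_r * ring
    skull_ring = entry + skull_r * ring
    vertices = np.vstack([tip_ring, skull_ring, target[None, :], entry[None, :]])
    i_tip_center, i_skull_center = 2 * sections, 2 * sections + 1

    faces = []
    for k in range(sections):
        k2 = (k + 1) % sections
        a, b = k, k2                      # tip ring
        c, d = sections + k, sections + k2  # skull ring
        faces.append([a, b, d])  # lateral surface, outward normals
        faces.append([a, d, c])
        faces.append([i_tip_center, b, a])    # tip cap faces -w
        faces.append([i_skull_center, c, d])  # skull cap faces +w
    mesh = SurfaceMesh(vertices, np.asarray(faces, dtype=np.int64))
    return mesh, 2.0 * skull_r


def depth_measurements(anatomy: AnatomySet, target_3d, axis,
                       config: PlanningConfig) -> dict:
    """Axial depth guidelines at the target.

    * ``sm_thickness_mm``: chord of the axis line through the SM surface;
    * ``sm_depth_behind_fn_mm``: how much deeper the target lies than the FN
      along the drilling direction (FN points inside the drill perimeter, or
      the FN point nearest to the axis when none project inside);
    * ``tb_to_target_mm``: drilling depth from the outer cortex.
    """
    target = np.asarray(target_3d, dtype=float)
    axis = _unit(axis)
    sm = anatomy["SM"]

    thickness = _sm_thickness(sm, target, axis)
    entry = entry_point(anatomy["TB"], target, axis)
    tb_to_target = float(np.linalg.norm(entry - target))
    behind = _depth_behind_fn(anatomy["FN"], target, axis,
                              config.drill_diameter_mm / 2.0, tb_to_target)
    return {
        "sm_thickness_mm": thickness,
        "sm_depth_behind_fn_mm": behind,
        "tb_to_target_mm": tb_to_target,
    }


def _sm_thickness(sm: SurfaceMesh, target: np.ndarray, axis: np.ndarray,
                  jitter_mm: float = 0.05) -> float:
    tris = sm.triangles
    for origin in (target, target + jitter_mm * _jitter_dir(axis)):
        ts = ray_hits(origin - 2.0 * axis, axis, tris)
        if len(ts) >= 2:
            return float(ts[-1] - ts[0])
    raise CorridorError("drilling axis does not pass through the SM surface")


def _jitter_dir(axis: np.ndarray) -> np.ndarray:
    e1, _ = _basis_perpendicular(axis)
    return e1


def _fn_surface_samples(fn: SurfaceMesh) -> np.ndarray:
    tris = fn.triangles
    centroids = tris.mean(axis=1)
    mids = 0.5 * (tris + np.roll(tris, 1, axis=1)).reshape(-1, 3)
    return np.vstack([fn.vertices, centroids, mids])


def _depth_behind_fn(fn: SurfaceMesh, target: np.ndarray, axis: np.ndarray,
                     drill_radius_mm: float, length_mm: float) -> float:
    """Depth difference along the axis between the target and the FN."""
    samples = _fn_surface_samples(fn)
    rel = samples - target
    depth = rel @ axis  # target is depth 0; lateral points are negative
    radial = np.linalg.norm(rel - depth[:, None] * axis[None, :], axis=1)
    inside = radial <= drill_radius_mm
    if inside.any():
        return float(-depth[inside].max())
    # no FN point in the drill perimeter: use the surface point nearest the axis
    s = np.arange(0.0, length_mm + 0.05, 0.05)
    axis_pts = target - s[:, None] * axis[None, :]
    dists, closest = point_triangle_closest(axis_pts, fn.triangles)
    best = closest[int(np.argmin(dists))]
    return float(-(best - target) @ axis)


__all__ = [
    "ANGLE_TOL_DEG",
    "SurgicalCorridor",
    "entry_point",
    "cone_surface_points",
    "min_clearance",
    "max_half_angle",
    "build_cone",
    "depth_measurements",
]
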