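"""Orthographic projection of the anatomy and the seven-polygon analysis.

For one candidate orientation the scene is rotated about the SM centroid and
projected orthographically onto the view plane (depth = coordinate along the
viewing axis, which is simply dropped).  Seven silhouette polygons are built:

1. the projected SM,
2-4. the *proximal* (in front of the SM) parts of FN, SS and VC,
5-7. the *distal* (behind the SM) parts of FN, SS and VC.

A structure face counts as proximal when its centroid is strictly shallower
than the most lateral SM vertex -- the conservative reading: anything that
could possibly stand in front of any part of the muscle is treated as
blocking.  From these polygons the module derives:

a. the SM silhouette area,
b. the exposed SM (SM minus the other six polygons),
c. the exposure ratio b/a,
d. the drillable region (exposed SM minus obstacle silhouettes dilated by the
   minimum safety distance) and its target center,
e. minimum target-to-structure distances, plus the exposed-SM-to-proximal
   distances used by the safety score.

All 2D geometry is exact polygon clipping (shapely/GEOS); silhouettes are
unions of projected triangles, so their accuracy is set by the tessellation
density of the input meshes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point, Polygon
from shapely.ops import polylabel

from ._meshquery import ray_hits
from .geometry_io import AnatomySet, SurfaceMesh
from .orientation import (
    Orientation,
    PlanningConfig,
    ReferenceFrame,
    apply_rotation,
    rotation_for,
)

#: structures that can obstruct the SM
OBSTACLES = ("FN", "SS", "VC")

EMPTY = Polygon()


def _project(points: np.ndarray, frame: ReferenceFrame):
    """(u, v) view-plane coordinates and depth along the viewing axis."""
    pts = np.asarray(points, dtype=float)
    uv = np.column_stack((pts @ frame.right, pts @ frame.up))
    depth = pts @ frame.view
    return uv, depth


def _union_triangles(uv: np.ndarray, faces: np.ndarray):
    """Union of projected triangles as a cleaned shapely geometry."""
    if len(faces) == 0:
        return EMPTY
    tris = uv[faces]  # (m, 3, 2)
    e1 = tris[:, 1] - tris[:, 0]
    e2 = tris[:, 2] - tris[:, 0]
    signed = 0.5 * (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    keep = np.abs(signed) > 1e-12
    if not keep.any():
        return EMPTY  # mesh seen edge-on: empty silhouette, not an error
    tris = tris[keep]
    flip = signed[keep] < 0
    tris[flip] = tris[flip, ::-1]  # CCW winding for valid rings
    polys = shapely.polygons(tris)
    union = shapely.union_all(polys)
    if not union.is_valid:
        union = shapely.make_valid(union)
    return union


def silhouette(mesh: SurfaceMesh, frame: ReferenceFrame, orientation: Orientation,
               pivot=None):
    """Silhouette polygon of one mesh in the given oriented view.

    ``pivot`` defaults to the mesh's own centroid; inside a scene projection
    the SM centroid is used for every structure so views stay comparable.
    """
    R = rotation_for(orientation, frame)
    if pivot is None:
        pivot = mesh.centroid
    rotated = apply_rotation(mesh.vertices, R, np.asarray(pivot, float))
    uv, _ = _project(rotated, frame)
    return _union_triangles(uv, mesh.faces)


def split_proximal_distal(structure_mesh: SurfaceMesh, sm_mesh: SurfaceMesh,
                          frame: ReferenceFrame, orientation: Orientation,
                          pivot=None):
    """Partition a structure's faces into (proximal, distal) index arrays.

    Proximal: face centroid strictly shallower than the minimum depth over
    all SM vertices (the most lateral SM point).  Faces exactly at the
    threshold are distal.
    """
    R = rotation_for(orientation, frame)
    if pivot is None:
        pivot = sm_mesh.centroid
    pivot = np.asarray(pivot, float)
    _, sm_depth = _project(apply_rotation(sm_mesh.vertices, R, pivot), frame)
    threshold = sm_depth.min()
    rot = apply_rotation(structure_mesh.vertices, R, pivot)
    _, depth = _project(rot, frame)
    face_depth = depth[structure_mesh.faces].mean(axis=1)
    prox = np.nonzero(face_depth < threshold)[0]
    dist = np.nonzero(face_depth >= threshold)[0]
    return prox, dist


def drillable_region(exposed_sm, obstacle_polys, msd_mm: float):
    """Exposed SM minus the ``msd``-dilation of every proximal obstacle.

    The margin is kept only against *other structures*; the SM's own boundary
    is not eroded.  An empty result simply means no safe drilling target in
    this view.
    """
    if msd_mm <= 0:
        raise ValueError("msd_mm must be positive")
    # buffer discs are inscribed polygons; inflate the radius by the secant
    # factor so the dilation covers the true disc and the safety margin holds
    quad_segs = 64
    radius = msd_mm / math.cos(math.pi / (4 * quad_segs))
    region = exposed_sm
    for poly in obstacle_polys:
        if poly is None or poly.is_empty:
            continue
        region = region.difference(poly.buffer(radius, quad_segs=quad_segs))
        if region.is_empty:
            return EMPTY
    return region


def _largest_component(geom):
    if geom.geom_type == "Polygon":
        return geom
    parts = [g for g in geom.geoms if g.geom_type == "Polygon"]
    return max(parts, key=lambda g: g.area) if parts else EMPTY


def target_center(drillable):
    """Drilling target: centroid of the drillable region.

    If the centroid falls outside a non-convex or multi-part region, the
    pole of inaccessibility of the largest component is used instead so the
    target always lies strictly inside drillable area.
    """
    if drillable is None or drillable.is_empty:
        return None
    centroid = drillable.centroid
    if drillable.contains(centroid):
        return np.array([centroid.x, centroid.y])
    best = _largest_component(drillable)
    if best.is_empty:
        return None
    pole = polylabel(best, tolerance=1e-3)
    return np.array([pole.x, pole.y])


def structure_distances(target_uv, proximal: dict, distal: dict) -> dict:
    """Minimum 2D distance from the target to each structure's polygons.

    Proximal and distal parts both count.  A structure absent from the view
    maps to ``inf`` (reported downstream as "not present").
    """
    pt = Point(float(target_uv[0]), float(target_uv[1]))
    out = {}
    for role in OBSTACLES:
        polys = [p for p in (proximal.get(role), distal.get(role))
                 if p is not None and not p.is_empty]
        out[role] = min((p.distance(pt) for p in polys), default=math.inf)
    return out


@dataclass
class ProjectionResult:
    """All polygons and measurements for one candidate orientation."""

    orientation: Orientation
    sm_poly: object
    proximal: dict
    distal: dict
    exposed_sm: object
    drillable: object
    sm_area_mm2: float
    exposed_area_mm2: float
    exposure_ratio: float
    target_uv: np.ndarray | None
    target_3d: np.ndarray | None
    #: measurement (e): min distance target -> structure (prox or distal), mm
    distances_mm: dict = field(default_factory=dict)
    #: scoring inputs DFN/DSS/DVC: exposed SM -> proximal polygon, mm
    exposed_to_proximal_mm: dict = field(default_factory=dict)

    @property
    def feasible(self) -> bool:
        """An orientation is feasible when a drillable target exists."""
        return self.target_uv is not None


def _recover_target_3d(sm_mesh: SurfaceMesh, frame: ReferenceFrame,
                       R: np.ndarray, pivot: np.ndarray, target_uv) -> np.ndarray | None:
    """Cast the view ray through the 2D target onto the original SM surface.

    The first (most lateral) intersection is the drilling end point; returned
    in the input RAS frame so downstream overlays align.
    """
    rotated = apply_rotation(sm_mesh.vertices, R, pivot)
    tris = rotated[sm_mesh.faces]
    depth_min = float((rotated @ frame.view).min())
    origin = (target_uv[0] * frame.right + target_uv[1] * frame.up
              + (depth_min - 1.0) * frame.view)
    ts = ray_hits(origin, frame.view, tris)
    ts = ts[ts > 0]
    if len(ts) == 0:
        return None
    hit = origin + ts[0] * frame.view
    return (hit - pivot) @ R + pivot  # inverse rotation: R^T applied on the left


def project_scene(anatomy: AnatomySet, frame: ReferenceFrame,
                  orientation: Orientation, config: PlanningConfig) -> ProjectionResult:
    """Build the seven polygons and all per-orientation measurements."""
    R = rotation_for(orientation, frame)
    sm_mesh = anatomy["SM"]
    pivot = sm_mesh.centroid

    sm_rot = apply_rotation(sm_mesh.vertices, R, pivot)
    sm_uv, sm_depth = _project(sm_rot, frame)
    sm_poly = _union_triangles(sm_uv, sm_mesh.faces)
    threshold = sm_depth.min()

    proximal, distal = {}, {}
    for role in OBSTACLES:
        mesh = anatomy[role]
        rot = apply_rotation(mesh.vertices, R, pivot)
        uv, depth = _project(rot, frame)
        face_depth = depth[mesh.faces].mean(axis=1)
        prox_mask = face_depth < threshold
        proximal[role] = _union_triangles(uv, mesh.faces[prox_mask])
        distal[role] = _union_triangles(uv, mesh.faces[~prox_mask])

    if sm_poly.is_empty:
        return ProjectionResult(
            orientation, sm_poly, proximal, distal, EMPTY, EMPTY,
            0.0, 0.0, 0.0, None, None, {}, {},
        )

    exposed = sm_poly
    for role in OBSTACLES:
        exposed = exposed.difference(proximal[role])
        if config.subtract_distal_from_exposure:
            exposed = exposed.difference(distal[role])
    sm_area = sm_poly.area
    exposed_area = exposed.area
    ratio = min(max(exposed_area / sm_area, 0.0), 1.0) if sm_area > 0 else 0.0

    drillable = (
        drillable_region(exposed, [proximal[r] for r in OBSTACLES], config.msd_mm)
        if not exposed.is_empty
        else EMPTY
    )
    target_uv = target_center(drillable)

    distances = {}
    exposed_to_prox = {}
    target_3d = None
    if target_uv is not None:
        distances = structure_distances(target_uv, proximal, distal)
        for role in OBSTACLES:
            poly = proximal[role]
            exposed_to_prox[role] = (
                float(exposed.distance(poly)) if not poly.is_empty else None
            )
        target_3d = _recover_target_3d(sm_mesh, frame, R, pivot, target_uv)

    return ProjectionResult(
        orientation=orientation,
        sm_poly=sm_poly,
        proximal=proximal,
        distal=distal,
        exposed_sm=exposed,
        drillable=drillable,
        sm_area_mm2=float(sm_area),
        exposed_area_mm2=float(exposed_area),
        exposure_ratio=float(ratio),
        target_uv=target_uv,
        target_3d=target_3d,
        distances_mm=distances,
        exposed_to_proximal_mm=exposed_to_prox,
    )


def polygon_rings(geom) -> list:
    """Rings of a (multi)polygon as coordinate lists (debug/GeoJSON dumps)."""
    if geom is None or geom.is_empty:
        return []
    polys = [geom] if geom.geom_type == "Polygon" else [
        g for g in geom.geoms if g.geom_type == "Polygon"
    ]
    rings = []
    for p in polys:
        rings.append(list(p.exterior.coords))
        rings.extend(list(r.coords) for r in p.interiors)
    return rings


__all__ = [
    "OBSTACLES",
    "ProjectionResult",
    "silhouette",
    "split_proximal_distal",
    "project_scene",
    "drillable_region",
    "target_center",
    "structure_distances",
    "polygon_rings",
]
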