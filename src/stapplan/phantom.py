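"""Parametric synthetic middle-ear anatomy with closed-form ground truth.

The phantom emulates the geometry that makes retrofacial access to the
stapedius muscle hard: a small SM (belly 2-4 mm) sitting 1-2 mm medial
("behind") to the vertical mastoid segment of the facial nerve, with the
sigmoid sinus posterior and the vestibulocochlear system anterior-medial.
All structures are analytic primitives placed in RAS millimetres for a
RIGHT ear:

* SM    -- ellipsoid at the origin, semi-axes (0.45, 0.6, belly/2) mm;
* FN    -- vertical cylinder (radius 0.6 mm) anterior to the SM, its medial
  surface ``sm_depth_behind_fn_mm`` lateral to the SM's proximal pole and
  its projected strip ``sm_fn_gap_mm`` from the SM center in the view plane;
* plate -- an optional occluding slab merged into the FN mesh that covers
  exactly ``occlusion_fraction`` of the SM silhouette from superior;
* SS    -- large posterior vertical cylinder; VC -- anterior-medial
  ellipsoid lying entirely behind the SM;
* TB    -- a flat bone slab whose outer cortex is the drilling entry plane.

Because every primitive is analytic, exposure, distances, depths and the
maximal corridor have independent closed-form / analytic-distance truths
(`PhantomTruth`), which the mesh pipeline must recover.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.optimize import brentq

from .errors import ConfigurationError
from .geometry_io import AnatomySet, SurfaceMesh, write_manifest, write_stl
from .orientation import PlanningConfig
from .report import classify_feasibility

# fixed scene constants (mm); see module docstring for the layout
SM_HALF_THICKNESS = 0.45
SM_HALF_WIDTH = 0.6
FN_RADIUS = 0.6
FN_HEIGHT = 14.0
PLATE_HALF_THICKNESS = 0.1
PLATE_HALF_WIDTH = 1.8  # covers the SM silhouette across u
SS_RADIUS = 2.0
SS_CENTER_Y = -6.5
SS_HEIGHT = 20.0
VC_CENTER = (-2.0, 5.5, 0.0)
VC_SEMI_AXES = (1.8, 2.0, 1.8)
TB_OUTER_X = 12.0
TB_EXTENT = 14.0

SCENARIOS = ("unobstructed", "partial_occlusion", "blocked", "narrow_gap")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case (defaults: a comfortably feasible ear)."""

    scenario: str = "unobstructed"
    sm_size_mm: float = 3.0            # SM belly length (superior-inferior)
    sm_fn_gap_mm: float = 2.0          # projected target-to-FN distance
    occlusion_fraction: float = 0.0    # fraction of SM silhouette covered
    sm_depth_behind_fn_mm: float = 1.7  # axial FN-to-SM-surface depth
    tb_thickness_mm: float = 3.0
    mesh_density: int = 3              # icosphere subdivisions / cylinder res
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        for name in ("sm_size_mm", "sm_fn_gap_mm", "sm_depth_behind_fn_mm",
                     "tb_thickness_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 <= self.occlusion_fraction <= 1.0:
            raise ConfigurationError("occlusion_fraction must be in [0, 1]")
        if self.sm_fn_gap_mm + 2 * FN_RADIUS > TB_EXTENT:
            raise ConfigurationError("SM-FN gap larger than the phantom scene")
        if not 1 <= self.mesh_density <= 6:
            raise ConfigurationError("mesh_density must be in 1..6")


@dataclass
class PhantomTruth:
    """Analytically derived expectations for one phantom at the (0,0) view."""

    exposure_ratio: float
    sm_area_mm2: float
    exposed_area_mm2: float
    drillable_area_mm2: float
    target_uv: tuple | None
    dist_sm_fn_mm: float | None
    sm_depth_behind_fn_mm: float | None
    sm_thickness_mm: float | None
    theta_star_deg: float | None
    skull_diameter_mm: float | None
    feasibility: str

    def to_json(self) -> str:
        doc = asdict(self)
        if doc["target_uv"] is not None:
            doc["target_uv"] = list(doc["target_uv"])
        return json.dumps(doc, indent=2)


# ---------------------------------------------------------------------------
# closed-form ellipse segments


def _segment_fn(t: float) -> float:
    """Area of {coord >= t} on the unit disc, normalized: acos t - t sqrt(1-t^2)."""
    t = min(max(t, -1.0), 1.0)
    return math.acos(t) - t * math.sqrt(1.0 - t * t)


def chord_for_fraction(fraction: float) -> float:
    """Normalized chord position t such that {coord >= t} covers ``fraction``."""
    if fraction <= 0.0:
        return 1.0
    if fraction >= 1.0:
        return -1.0
    return brentq(lambda t: _segment_fn(t) - fraction * math.pi, -1.0, 1.0,
                  xtol=1e-12)


def ellipse_low_segment(b: float, c: float, k: float):
    """Area and centroid ordinate of {v <= k} on an ellipse with semi-axes (b, c).

    Returns ``(area, v_centroid)``; the centroid of an empty segment is None.
    """
    t = min(max(k / c, -1.0), 1.0)
    area = b * c * (math.pi - _segment_fn(t))
    if area <= 0:
        return 0.0, None
    moment = -(2.0 / 3.0) * b * c * c * (1.0 - t * t) ** 1.5
    return area, moment / area


# ---------------------------------------------------------------------------
# mesh construction


def _ellipsoid(center, semi_axes, subdivisions: int) -> SurfaceMesh:
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.asarray(m.vertices) * np.asarray(semi_axes) + np.asarray(center)
    return SurfaceMesh(v, np.asarray(m.faces))


def _cylinder(center, radius, height, sections: int) -> SurfaceMesh:
    """Closed z-axis cylinder with a mirror-symmetric triangulation.

    Side quads are fanned around an on-surface mid-height vertex instead of
    split along a diagonal, so the face set (and hence every face centroid)
    is exactly symmetric under z -> -z; the planner's proximal/distal face
    split then respects the phantom's axial mirror symmetry.
    """
    k = np.arange(sections)
    ang = 2.0 * np.pi * k / sections
    ring = np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])
    mid_ang = ang + np.pi / sections
    mid = np.column_stack([radius * np.cos(mid_ang), radius * np.sin(mid_ang)])
    h = height / 2.0
    bot = np.column_stack([ring, np.full(sections, -h)])
    top = np.column_stack([ring, np.full(sections, h)])
    waist = np.column_stack([mid, np.zeros(sections)])
    centers = np.array([[0.0, 0.0, -h], [0.0, 0.0, h]])
    vertices = np.vstack([bot, top, waist, centers])
    i_bot, i_top = 3 * sections, 3 * sections + 1

    faces = []
    for j in range(sections):
        j2 = (j + 1) % sections
        b0, b1 = j, j2
        t0, t1 = sections + j, sections + j2
        m = 2 * sections + j
        faces += [[b0, b1, m], [b1, t1, m], [t1, t0, m], [t0, b0, m]]
        faces += [[i_bot, b1, b0], [i_top, t0, t1]]
    return SurfaceMesh(vertices + np.asarray(center, float),
                       np.asarray(faces, dtype=np.int64))


def _box(bounds_min, bounds_max) -> SurfaceMesh:
    lo = np.asarray(bounds_min, float)
    hi = np.asarray(bounds_max, float)
    m = trimesh.creation.box(extents=hi - lo)
    return SurfaceMesh(np.asarray(m.vertices) + (lo + hi) / 2.0, np.asarray(m.faces))


def _merge(*meshes: SurfaceMesh) -> SurfaceMesh:
    offsets = np.cumsum([0] + [m.n_vertices for m in meshes[:-1]])
    verts = np.vstack([m.vertices for m in meshes])
    faces = np.vstack([m.faces + off for m, off in zip(meshes, offsets)])
    return SurfaceMesh(verts, faces)


def _fn_geometry(spec: PhantomSpec):
    """Positions of the FN tube and (optionally) the occluding plate."""
    x_fn = SM_HALF_THICKNESS + spec.sm_depth_behind_fn_mm
    y_fn = spec.sm_fn_gap_mm + FN_RADIUS
    c = spec.sm_size_mm / 2.0
    z_cut = None
    if spec.occlusion_fraction > 0.0:
        t = chord_for_fraction(spec.occlusion_fraction)
        z_cut = t * c if spec.occlusion_fraction < 1.0 else -c - 0.3
    return x_fn, y_fn, z_cut


def make_phantom(spec: PhantomSpec):
    """Build the five structure meshes and the analytic truth.

    Deterministic: identical specs produce identical meshes.
    """
    density = spec.mesh_density
    sections = max(16, 16 * 2 ** (density - 1))
    c = spec.sm_size_mm / 2.0
    x_fn, y_fn, z_cut = _fn_geometry(spec)

    sm = _ellipsoid((0, 0, 0), (SM_HALF_THICKNESS, SM_HALF_WIDTH, c), density)
    fn = _cylinder((x_fn, y_fn, 0.0), FN_RADIUS, FN_HEIGHT, sections)
    if z_cut is not None:
        plate = _box(
            (x_fn - PLATE_HALF_THICKNESS, -PLATE_HALF_WIDTH, z_cut),
            (x_fn + PLATE_HALF_THICKNESS, PLATE_HALF_WIDTH, c + 1.2),
        )
        fn = _merge(fn, plate)
    ss = _cylinder((0.0, SS_CENTER_Y, 0.0), SS_RADIUS, SS_HEIGHT, sections)
    vc = _ellipsoid(VC_CENTER, VC_SEMI_AXES, density)
    tb = _box(
        (TB_OUTER_X - spec.tb_thickness_mm, -TB_EXTENT, -TB_EXTENT),
        (TB_OUTER_X, TB_EXTENT, TB_EXTENT),
    )
    anatomy = AnatomySet(
        structures={"SM": sm, "FN": fn, "SS": ss, "VC": vc, "TB": tb},
        side="right",
    )
    return anatomy, phantom_truth(spec)


# ---------------------------------------------------------------------------
# analytic truth


def _analytic_fn_distance(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Exact distance from 3D points to the FN surface (tube + plate)."""
    x_fn, y_fn, z_cut = _fn_geometry(spec)
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    radial = np.hypot(x - x_fn, y - y_fn)
    dz = np.maximum(np.abs(z) - FN_HEIGHT / 2.0, 0.0)
    outside = np.hypot(np.maximum(radial - FN_RADIUS, 0.0), dz)
    inside = np.where(dz == 0.0, FN_RADIUS - radial, np.inf)
    d = np.where(radial >= FN_RADIUS, outside, np.minimum(np.abs(inside), outside))
    if z_cut is not None:
        c = spec.sm_size_mm / 2.0
        lo = np.array([x_fn - PLATE_HALF_THICKNESS, -PLATE_HALF_WIDTH, z_cut])
        hi = np.array([x_fn + PLATE_HALF_THICKNESS, PLATE_HALF_WIDTH, c + 1.2])
        q = np.maximum(np.maximum(lo - points, points - hi), 0.0)
        box_out = np.linalg.norm(q, axis=1)
        interior = np.all((points > lo) & (points < hi), axis=1)
        box_in = np.min(np.minimum(points - lo, hi - points), axis=1)
        d_box = np.where(interior, box_in, box_out)
        d = np.minimum(d, d_box)
    return d


def _analytic_ss_distance(points: np.ndarray) -> np.ndarray:
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    radial = np.hypot(x, y - SS_CENTER_Y)
    dz = np.maximum(np.abs(z) - SS_HEIGHT / 2.0, 0.0)
    return np.hypot(np.maximum(radial - SS_RADIUS, 0.0), dz)


def _analytic_vc_lower_bound(points: np.ndarray) -> np.ndarray:
    center = np.asarray(VC_CENTER)
    return np.linalg.norm(points - center, axis=1) - max(VC_SEMI_AXES)


def _truth_theta_star(spec: PhantomSpec, target_3d: np.ndarray,
                      config: PlanningConfig) -> float | None:
    """Maximal cone half-angle against the analytic primitives (None: infeasible)."""
    length = TB_OUTER_X - target_3d[0]
    tip_r = config.drill_diameter_mm / 2.0
    s = np.linspace(0.0, length, 768)
    phi = np.linspace(0.0, 2.0 * math.pi, 192, endpoint=False)
    cos_p, sin_p = np.cos(phi), np.sin(phi)

    def clearance(theta_deg: float) -> float:
        radii = tip_r + math.tan(math.radians(theta_deg)) * s
        x = (target_3d[0] + s)[:, None] * np.ones_like(phi)[None, :]
        y = target_3d[1] + radii[:, None] * cos_p[None, :]
        z = target_3d[2] + radii[:, None] * sin_p[None, :]
        pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
        d = _analytic_fn_distance(pts, spec)
        d = np.minimum(d, _analytic_ss_distance(pts))
        d = np.minimum(d, _analytic_vc_lower_bound(pts))
        return float(d.min())

    msd = config.msd_mm
    if clearance(0.0) < msd:
        return None
    cap = config.max_cone_half_angle_deg
    if clearance(cap) >= msd:
        return cap
    lo, hi = 0.0, cap
    while hi - lo > 0.01:
        mid = 0.5 * (lo + hi)
        if clearance(mid) >= msd:
            lo = mid
        else:
            hi = mid
    return lo


def phantom_truth(spec: PhantomSpec, config: PlanningConfig | None = None) -> PhantomTruth:
    """Expected planner outputs at the (0, 0) reference view, in closed form.

    Exposure and drillable geometry reduce to ellipse-chord segments because
    every occluder projects to an axis-aligned strip; the corridor angle uses
    exact point-to-primitive distances.  The truth never calls the mesh
    pipeline.
    """
    config = config or PlanningConfig()
    b, c = SM_HALF_WIDTH, spec.sm_size_mm / 2.0
    msd = config.msd_mm
    sm_area = math.pi * b * c
    x_fn, y_fn, z_cut = _fn_geometry(spec)
    gap = spec.sm_fn_gap_mm
    if z_cut is not None and gap < b:
        raise ConfigurationError(
            "phantom truth needs occlusion and a silhouette-crossing FN to be "
            "mutually exclusive; widen sm_fn_gap_mm or drop the occluder"
        )

    # exposure: the plate covers {v >= z_cut}; the FN tube strip covers
    # {u <= -gap} and only reaches the silhouette when gap < b
    exposed = sm_area
    if z_cut is not None:
        exposed -= spec.occlusion_fraction * sm_area
    if gap < b:
        exposed -= b * c * _segment_fn(gap / b)
    exposed = max(exposed, 0.0)
    exposure = exposed / sm_area

    # drillable region: single-chord ellipse segment (suite scenarios never
    # activate both cuts at once; assert to guard the closed form)
    u_cut_active = (gap - msd) < b
    v_cut_active = z_cut is not None and z_cut - msd > -c
    drillable_area = 0.0
    target = None
    if z_cut is not None and z_cut - msd <= -c:
        drillable_area = 0.0  # occluder margin swallows the whole silhouette
    elif v_cut_active and u_cut_active:
        raise ConfigurationError(
            "phantom truth supports one active safety cut at a time; "
            "choose a wider SM-FN gap or less occlusion"
        )
    elif v_cut_active:
        drillable_area, v_c = ellipse_low_segment(b, c, z_cut - msd)
        if drillable_area > 0:
            target = (0.0, v_c)
    elif u_cut_active:
        # {u >= msd - gap}: mirror of a low segment along the u axis
        drillable_area, w_c = ellipse_low_segment(c, b, gap - msd)
        if drillable_area > 0:
            target = (-w_c, 0.0)
    else:
        drillable_area = sm_area
        target = (0.0, 0.0)

    if target is None:
        return PhantomTruth(
            exposure_ratio=exposure, sm_area_mm2=sm_area,
            exposed_area_mm2=exposed, drillable_area_mm2=0.0,
            target_uv=None, dist_sm_fn_mm=None, sm_depth_behind_fn_mm=None,
            sm_thickness_mm=None, theta_star_deg=None, skull_diameter_mm=None,
            feasibility="unfeasible",
        )

    u_c, v_c = target
    # distance from the target to the FN: the tube strip lies at u <= -gap
    # (any v); the plate edge at v = z_cut (any u over the silhouette)
    dist = u_c + gap
    if z_cut is not None:
        dist = min(dist, z_cut - v_c)

    # 3D target on the SM proximal surface
    x_t = SM_HALF_THICKNESS * math.sqrt(
        max(1.0 - (u_c / b) ** 2 - (v_c / c) ** 2, 0.0)
    )
    target_3d = np.array([x_t, -u_c, v_c])
    thickness = 2.0 * x_t

    # axial depth of the SM behind the FN: nearest FN surface point to the
    # drilling axis is on the tube at x = x_fn (the plate, when closer, is
    # x-centered on the tube, so the truth depth is the same within its
    # half-thickness)
    depth_behind = x_fn - x_t

    theta = _truth_theta_star(spec, target_3d, config)
    if theta is None:
        skull_diam = None
        feas = "unfeasible"
    else:
        length = TB_OUTER_X - x_t
        skull_diam = config.drill_diameter_mm + 2.0 * math.tan(
            math.radians(theta)) * length
        feas = classify_feasibility(100.0 * exposure, dist, skull_diam,
                                    config.thresholds)
    return PhantomTruth(
        exposure_ratio=exposure,
        sm_area_mm2=sm_area,
        exposed_area_mm2=exposed,
        drillable_area_mm2=drillable_area,
        target_uv=target,
        dist_sm_fn_mm=dist,
        sm_depth_behind_fn_mm=depth_behind,
        sm_thickness_mm=thickness,
        theta_star_deg=theta,
        skull_diameter_mm=skull_diam,
        feasibility=feas,
    )


# ---------------------------------------------------------------------------
# scenario catalogue


def scenario_suite(seed: int = 0) -> list:
    """Fixed catalogue spanning the clinically relevant envelope.

    Exposure anchors {0, 25, 30, 40, 50, 100} %, SM-FN gaps
    {0.5, 0.8, 1.0, 2.0} mm and FN-to-SM depths {0.1, 1.7, 4.7} mm.
    Returns ``[(spec, anatomy, truth), ...]``; deterministic for a fixed seed.
    """
    specs = [
        PhantomSpec("unobstructed", seed=seed),
        PhantomSpec("partial_occlusion", occlusion_fraction=0.5, seed=seed),
        PhantomSpec("partial_occlusion", occlusion_fraction=0.6, seed=seed),
        PhantomSpec("partial_occlusion", occlusion_fraction=0.7, seed=seed),
        PhantomSpec("partial_occlusion", occlusion_fraction=0.75, seed=seed),
        PhantomSpec("blocked", occlusion_fraction=1.0, seed=seed),
        PhantomSpec("narrow_gap", sm_fn_gap_mm=0.5, seed=seed),
        PhantomSpec("narrow_gap", sm_fn_gap_mm=0.8, seed=seed),
        PhantomSpec("narrow_gap", sm_fn_gap_mm=1.0, seed=seed),
        PhantomSpec("unobstructed", sm_depth_behind_fn_mm=0.1, seed=seed),
        PhantomSpec("unobstructed", sm_depth_behind_fn_mm=4.7, seed=seed),
    ]
    return [(spec, *make_phantom(spec)) for spec in specs]


def write_phantom(out_dir, spec: PhantomSpec):
    """Write STL set + manifest + truth JSON for external use."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    anatomy, truth = make_phantom(spec)
    paths = {}
    for role, mesh in anatomy.structures.items():
        name = f"{role.lower()}.stl"
        write_stl(mesh, out / name)
        paths[role] = name
    write_manifest(out / "manifest.yaml", paths, anatomy.side)
    (out / "truth.json").write_text(truth.to_json() + "\n")
    (out / "spec.json").write_text(json.dumps(asdict(spec), indent=2) + "\n")
    return out / "manifest.yaml"


__all__ = [
    "SCENARIOS",
    "PhantomSpec",
    "PhantomTruth",
    "chord_for_fraction",
    "ellipse_low_segment",
    "make_phantom",
    "phantom_truth",
    "scenario_suite",
    "write_phantom",
]
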