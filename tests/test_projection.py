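"""Silhouettes, the seven-polygon split, exposure, drillable region, distances."""

import math

import numpy as np
import pytest
import shapely
import trimesh
from shapely.geometry import MultiPolygon, Point, Polygon, box

from stapplan.geometry_io import SurfaceMesh
from stapplan.orientation import Orientation, default_reference_frame
from stapplan.phantom import PhantomSpec, make_phantom
from stapplan.projection import (
    drillable_region,
    project_scene,
    silhouette,
    split_proximal_distal,
    structure_distances,
    target_center,
)

O00 = Orientation(0.0, 0.0)


@pytest.fixture(scope="module")
def frame():
    return default_reference_frame(None, side="right")


class TestSilhouette:
    def test_sphere_projects_to_disc_area(self, frame):
        mesh = SurfaceMesh.from_trimesh(trimesh.creation.icosphere(3, radius=2.0))
        area = silhouette(mesh, frame, O00).area
        assert area == pytest.approx(math.pi * 4.0, rel=0.01)

    def test_plane_parallel_triangle_is_exact(self, frame):
        # triangle in the x = 0 plane; view axis is -x, so it projects 1:1
        v = np.array([[0, 0, 0], [0, 2, 0], [0, 0, 3]], dtype=float)
        mesh = SurfaceMesh(v, np.array([[0, 1, 2]]))
        assert silhouette(mesh, frame, O00).area == pytest.approx(3.0, abs=1e-12)

    def test_edge_on_mesh_gives_empty_polygon(self, frame):
        # triangle in the y-z ... x-y plane seen along x? use plane containing view axis
        v = np.array([[0, 0, 0], [1, 1, 0], [2, 0, 0]], dtype=float)
        mesh = SurfaceMesh(v, np.array([[0, 1, 2]]))
        geom = silhouette(mesh, frame, O00)
        assert geom.is_empty

    def test_disjoint_cubes_give_two_components(self, frame):
        a = trimesh.creation.box(extents=[1, 1, 1])
        b = trimesh.creation.box(extents=[1, 1, 1])
        b.apply_translation([0.0, 5.0, 0.0])
        mesh = SurfaceMesh(
            np.vstack([a.vertices, b.vertices]),
            np.vstack([a.faces, b.faces + len(a.vertices)]),
        )
        geom = silhouette(mesh, frame, O00)
        assert isinstance(geom, MultiPolygon)
        assert len(geom.geoms) == 2


class TestProximalDistalSplit:
    def _tube(self, x_center):
        cyl = trimesh.creation.cylinder(radius=0.5, height=5.0, sections=32)
        m = SurfaceMesh(np.asarray(cyl.vertices) + [x_center, 0, 0],
                        np.asarray(cyl.faces))
        return m

    def _sm(self):
        ico = trimesh.creation.icosphere(2, radius=0.5)
        return SurfaceMesh.from_trimesh(ico)

    def test_lateral_tube_is_all_proximal(self, frame):
        # 2 mm lateral (larger x = shallower for the right-side view)
        prox, dist = split_proximal_distal(self._tube(3.0), self._sm(), frame, O00)
        assert len(dist) == 0 and len(prox) > 0

    def test_medial_tube_is_all_distal(self, frame):
        prox, dist = split_proximal_distal(self._tube(-3.0), self._sm(), frame, O00)
        assert len(prox) == 0 and len(dist) > 0

    def test_partition_is_exhaustive_and_disjoint(self, frame):
        tube = self._tube(0.2)  # straddles the threshold
        prox, dist = split_proximal_distal(tube, self._sm(), frame, O00)
        assert len(prox) > 0 and len(dist) > 0
        together = np.sort(np.concatenate([prox, dist]))
        assert np.array_equal(together, np.arange(tube.n_faces))

    def test_structure_exactly_at_threshold_is_distal(self, frame):
        # single triangle whose centroid depth equals the SM minimum depth
        sm = self._sm()  # most lateral vertex at x = +0.5
        v = np.array([[0.5, 2, 0], [0.5, 3, 0], [0.5, 2, 1]], dtype=float)
        tri = SurfaceMesh(v, np.array([[0, 1, 2]]))
        prox, dist = split_proximal_distal(tri, sm, frame, O00)
        assert len(prox) == 0 and len(dist) == 1


class TestProjectScene:
    def test_unobstructed_phantom_fully_exposed(self, default_phantom,
                                                default_frame, config):
        anatomy, _ = default_phantom
        ev = project_scene(anatomy, default_frame, O00, config)
        assert ev.exposure_ratio == pytest.approx(1.0, abs=1e-9)
        assert ev.exposed_sm.area == pytest.approx(ev.sm_poly.area, abs=1e-6)

    def test_half_occluded_phantom(self, config):
        anatomy, _ = make_phantom(PhantomSpec("partial_occlusion",
                                              occlusion_fraction=0.5))
        frame = default_reference_frame(anatomy)
        ev = project_scene(anatomy, frame, O00, config)
        assert ev.exposure_ratio == pytest.approx(0.5, abs=0.02)

    def test_fully_blocked_phantom(self, config):
        anatomy, _ = make_phantom(PhantomSpec("blocked", occlusion_fraction=1.0))
        frame = default_reference_frame(anatomy)
        ev = project_scene(anatomy, frame, O00, config)
        assert ev.exposure_ratio == pytest.approx(0.0, abs=1e-3)
        assert ev.drillable.is_empty
        assert not ev.feasible

    def test_area_conservation(self, default_phantom, default_frame, config):
        anatomy, _ = default_phantom
        ev = project_scene(anatomy, default_frame, Orientation(10, -20), config)
        others = shapely.union_all(
            [ev.proximal[r] for r in ("FN", "SS", "VC")]
            + [ev.distal[r] for r in ("FN", "SS", "VC")]
        )
        covered = ev.sm_poly.intersection(others).area
        assert ev.exposed_sm.area + covered == pytest.approx(
            ev.sm_poly.area, abs=1e-6
        )

    def test_target_inside_drillable_and_on_sm_surface(self, default_phantom,
                                                       default_frame, config):
        anatomy, _ = default_phantom
        ev = project_scene(anatomy, default_frame, O00, config)
        assert ev.drillable.contains(Point(*ev.target_uv))
        # recovered 3D point sits on the lateral SM surface (x = +a at center)
        assert ev.target_3d[0] == pytest.approx(0.45, abs=0.01)

    def test_safety_margin_by_construction(self, config):
        anatomy, _ = make_phantom(PhantomSpec("narrow_gap", sm_fn_gap_mm=1.0))
        frame = default_reference_frame(anatomy)
        ev = project_scene(anatomy, frame, O00, config)
        pt = Point(*ev.target_uv)
        for role in ("FN", "SS", "VC"):
            poly = ev.proximal[role]
            if not poly.is_empty:
                assert poly.distance(pt) >= config.msd_mm - 1e-6

    def test_enlarging_obstacle_never_increases_exposure(self, config):
        anatomy_lo, _ = make_phantom(PhantomSpec("partial_occlusion",
                                                 occlusion_fraction=0.5))
        anatomy_hi, _ = make_phantom(PhantomSpec("partial_occlusion",
                                                 occlusion_fraction=0.7))
        frame = default_reference_frame(anatomy_lo)
        lo = project_scene(anatomy_lo, frame, O00, config)
        hi = project_scene(anatomy_hi, frame, O00, config)
        assert hi.exposure_ratio <= lo.exposure_ratio + 1e-9
        assert hi.drillable.area <= lo.drillable.area + 1e-9


class TestDrillableRegion:
    def test_no_obstacles_keeps_exposed_region(self):
        disc = Point(0, 0).buffer(2.0)
        out = drillable_region(disc, [], 0.8)
        # no erosion against the SM's own boundary
        assert out.area == pytest.approx(disc.area, abs=1e-9)

    def test_abutting_obstacle_leaves_msd_strip(self):
        exposed = box(0, 0, 1, 1)
        obstacle = box(-1, 0, 0, 1)
        out = drillable_region(exposed, [obstacle], 0.8)
        assert out.area == pytest.approx(0.2, abs=0.01)
        assert out.bounds[0] == pytest.approx(0.8, abs=1e-3)

    def test_total_occlusion_returns_empty(self):
        exposed = box(0, 0, 1, 1)
        obstacle = box(-1, -1, 2, 2)
        assert drillable_region(exposed, [obstacle], 0.8).is_empty


class TestTargetCenter:
    def test_square_centroid(self):
        assert np.allclose(target_center(box(0, 0, 1, 1)), [0.5, 0.5])

    def test_l_shape_returns_interior_point(self):
        l_shape = Polygon([(0, 0), (4, 0), (4, 1), (1, 1), (1, 4), (0, 4)])
        assert not l_shape.contains(l_shape.centroid)  # centroid escapes the L
        pt = target_center(l_shape)
        assert l_shape.contains(Point(*pt))

    def test_multi_part_prefers_larger_component(self):
        small = box(0, 0, 1, 1)
        large = box(5, 0, 8, 1)  # 3x the area
        geom = MultiPolygon([small, large])
        # symmetric parts force the overall centroid into the gap between them
        pt = target_center(geom)
        assert large.contains(Point(*pt))

    def test_empty_region_has_no_target(self):
        assert target_center(Polygon()) is None


class TestStructureDistances:
    def test_distance_to_nearest_vertex(self):
        prox = {"FN": Polygon([(1.0, 0), (2, 1), (2, -1)])}
        d = structure_distances((0.0, 0.0), prox, {})
        assert d["FN"] == pytest.approx(1.0, abs=1e-12)

    def test_target_inside_polygon_gives_zero(self):
        prox = {"FN": box(-1, -1, 1, 1)}
        d = structure_distances((0.0, 0.0), prox, {})
        assert d["FN"] == 0.0

    def test_absent_structure_is_sentinel(self):
        d = structure_distances((0.0, 0.0), {}, {})
        assert all(math.isinf(v) for v in d.values())

    def test_proximal_and_distal_both_count(self):
        prox = {"SS": box(5, 0, 6, 1)}
        dist = {"SS": box(2, 0, 3, 1)}
        d = structure_distances((0.0, 0.5), prox, dist)
        assert d["SS"] == pytest.approx(2.0, abs=1e-9)
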