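"""Corridor entry point, maximal cone angle, frustum mesh and depth guides."""

import math

import numpy as np
import pytest
import trimesh

from stapplan.corridor import (
    build_cone,
    cone_surface_points,
    depth_measurements,
    entry_point,
    max_half_angle,
    min_clearance,
    violates_clearance,
)
from stapplan.errors import CorridorError
from stapplan.geometry_io import AnatomySet, SurfaceMesh, read_stl, write_stl
from stapplan.orientation import PlanningConfig

AXIS = np.array([-1.0, 0.0, 0.0])  # drilling direction: lateral -> medial


def _box(lo, hi):
    lo, hi = np.asarray(lo, float), np.asarray(hi, float)
    m = trimesh.creation.box(extents=hi - lo)
    return SurfaceMesh(np.asarray(m.vertices) + (lo + hi) / 2.0, np.asarray(m.faces))


def _x_cylinder(y, z, radius, length=30.0, sections=64):
    """Cylinder parallel to the x axis at in-plane offset (y, z)."""
    m = trimesh.creation.cylinder(radius=radius, height=length, sections=sections)
    v = np.asarray(m.vertices)[:, [2, 0, 1]]  # z -> x
    return SurfaceMesh(v + [0.0, y, z], np.asarray(m.faces)[:, ::-1])


@pytest.fixture()
def slab_tb():
    return _box((7.0, -15.0, -15.0), (12.0, 15.0, 15.0))


def _far(mesh, shift=100.0):
    return SurfaceMesh(mesh.vertices + [0.0, shift, 0.0], mesh.faces)


def _anatomy(tb, fn=None, ss=None, vc=None):
    filler = _box((50.0, 50.0, 50.0), (51.0, 51.0, 51.0))
    sm = _box((-0.5, -0.5, -0.5), (0.0, 0.5, 0.5))
    return AnatomySet(
        {"SM": sm, "FN": fn or filler, "SS": ss or filler, "VC": vc or filler,
         "TB": tb},
        side="right",
    )


class TestEntryPoint:
    def test_slab_entry_on_outer_face(self, slab_tb):
        target = np.zeros(3)
        entry = entry_point(slab_tb, target, AXIS)
        assert entry[0] == pytest.approx(12.0, abs=1e-9)
        assert np.linalg.norm(entry - target) == pytest.approx(12.0, abs=1e-9)

    def test_axis_parallel_to_slab_errors(self, slab_tb):
        with pytest.raises(CorridorError):
            entry_point(slab_tb, np.zeros(3), np.array([0.0, 0.0, 1.0]))

    def test_curved_shell_matches_sphere_line_closed_form(self):
        # spherical cortex of radius 60 centered so its apex is at x = 12
        shell = trimesh.creation.icosphere(5, radius=60.0)
        shell = SurfaceMesh(np.asarray(shell.vertices) + [-48.0, 0.0, 0.0],
                            np.asarray(shell.faces))
        entry = entry_point(shell, np.zeros(3), AXIS)
        assert np.linalg.norm(entry - [12.0, 0.0, 0.0]) < 0.1


class TestMaxHalfAngle:
    def test_unconstrained_scene_reaches_cap(self, slab_tb):
        cfg = PlanningConfig()
        theta = max_half_angle(_anatomy(slab_tb), np.zeros(3), AXIS, cfg)
        assert theta == pytest.approx(cfg.max_cone_half_angle_deg, abs=1e-12)

    def test_parallel_cylinder_matches_closed_form(self, slab_tb):
        # obstacle parallel to the axis at offset D: the widest cone satisfies
        # tip_r + L tan(theta) + msd + rho = D at the skull plane
        D, rho = 3.0, 0.5
        cfg = PlanningConfig()
        fn = _x_cylinder(D, 0.0, rho)
        anatomy = _anatomy(slab_tb, fn=fn)
        theta = max_half_angle(anatomy, np.zeros(3), AXIS, cfg)
        expected = math.degrees(math.atan((D - rho - cfg.msd_mm - 0.6) / 12.0))
        assert theta == pytest.approx(expected, abs=0.2)

    def test_maximality(self, slab_tb):
        cfg = PlanningConfig()
        fn = _x_cylinder(3.0, 0.0, 0.5)
        anatomy = _anatomy(slab_tb, fn=fn)
        theta = max_half_angle(anatomy, np.zeros(3), AXIS, cfg)
        pts = cone_surface_points(np.zeros(3), AXIS, 12.0, 0.6, theta + 0.5,
                                  n_circ=128, n_axial=64)
        assert violates_clearance(pts, fn.triangles, cfg.msd_mm)

    def test_blocking_cylinder_makes_corridor_infeasible(self, slab_tb):
        cfg = PlanningConfig()
        fn = _x_cylinder(1.0, 0.0, 0.5)  # hugs the drill cylinder
        with pytest.raises(CorridorError):
            max_half_angle(_anatomy(slab_tb, fn=fn), np.zeros(3), AXIS, cfg)


class TestBuildCone:
    def test_zero_angle_is_a_cylinder(self):
        mesh, skull_diam = build_cone(np.zeros(3), [10.0, 0, 0], 0.0, 1.2)
        assert skull_diam == pytest.approx(1.2, abs=1e-12)

    def test_forty_five_degree_skull_diameter(self):
        _, skull_diam = build_cone(np.zeros(3), [10.0, 0, 0], 45.0, 1.2)
        assert skull_diam == pytest.approx(1.2 + 2 * 10.0, abs=1e-9)

    def test_mesh_is_watertight_and_round_trips(self, tmp_path):
        mesh, skull_diam = build_cone(np.zeros(3), [10.0, 0, 0], 20.0, 1.2)
        tm = mesh.as_trimesh()
        assert tm.is_watertight
        assert tm.is_winding_consistent
        write_stl(mesh, tmp_path / "cone.stl")
        back = read_stl(tmp_path / "cone.stl").as_trimesh()
        r1, r2, h = 0.6, skull_diam / 2.0, 10.0
        analytic = math.pi * h / 3.0 * (r1 * r1 + r1 * r2 + r2 * r2)
        assert abs(back.volume) == pytest.approx(analytic, rel=0.01)

    def test_coincident_points_error(self):
        with pytest.raises(CorridorError):
            build_cone(np.zeros(3), np.zeros(3), 10.0, 1.2)


class TestClearanceCertificate:
    def test_dense_resample_confirms_msd(self, default_phantom, default_frame,
                                         pinned_config):
        from stapplan.pipeline import run_plan

        anatomy, _ = default_phantom
        out = run_plan(anatomy, pinned_config)
        cor = out.corridor
        obstacles = np.concatenate(
            [anatomy[r].triangles for r in ("FN", "SS", "VC")]
        )
        pts = cone_surface_points(
            cor.target_3d, cor.axis, cor.depth_mm, cor.tip_diameter_mm / 2.0,
            cor.half_angle_deg, n_circ=256, n_axial=128,
        )
        assert not violates_clearance(pts, obstacles,
                                      pinned_config.msd_mm - 0.05)

    def test_skull_diameter_grows_with_angle_and_depth(self):
        diams = [build_cone(np.zeros(3), [d, 0, 0], t, 1.2)[1]
                 for d, t in [(8, 10), (10, 10), (10, 20)]]
        assert diams[0] < diams[1] < diams[2]


class TestDepthMeasurements:
    def test_sphere_chord_thickness(self, slab_tb):
        cfg = PlanningConfig()
        sphere = SurfaceMesh.from_trimesh(trimesh.creation.icosphere(3, radius=0.5))
        anatomy = _anatomy(slab_tb)
        anatomy.structures["SM"] = sphere
        target = np.array([0.5, 0.0, 0.0])
        d = depth_measurements(anatomy, target, AXIS, cfg)
        assert d["sm_thickness_mm"] == pytest.approx(1.0, abs=0.02)

    def test_fn_depth_and_tb_distance_on_phantom(self, default_phantom,
                                                 default_frame, pinned_config):
        from stapplan.pipeline import run_plan

        anatomy, truth = default_phantom
        out = run_plan(anatomy, pinned_config)
        d = out.depths
        assert d["sm_depth_behind_fn_mm"] == pytest.approx(1.7, abs=0.05)
        assert d["tb_to_target_mm"] == pytest.approx(11.55, abs=0.01)

    def test_ray_missing_sm_errors(self, slab_tb):
        cfg = PlanningConfig()
        anatomy = _anatomy(slab_tb)
        with pytest.raises(CorridorError):
            depth_measurements(anatomy, np.array([0.0, 10.0, 0.0]), AXIS, cfg)
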