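"""End-to-end planning: grid evaluation, corridor growth, guidelines report.

Left-sided cases are mirrored across the sagittal plane onto a canonical
right-side frame before planning, so a single code path serves both ears;
reported angles are in the canonical convention (the mirror is an exact
involution, so every scalar metric is side-invariant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .corridor import (
    SurgicalCorridor,
    build_cone,
    depth_measurements,
    entry_point,
    max_half_angle,
)
from .errors import CorridorError
from .geometry_io import AnatomySet, mirror_anatomy
from .orientation import (
    PlanningConfig,
    ReferenceFrame,
    check_reference_frame,
    default_reference_frame,
    rotation_for,
)
from .report import PlanReport, assemble_report
from .scoring import TrajectoryGrid, evaluate_grid

log = logging.getLogger(__name__)


@dataclass
class PlanOutcome:
    """Everything one planning run produces."""

    grid: TrajectoryGrid
    corridor: SurgicalCorridor | None
    depths: dict | None
    report: PlanReport
    anatomy: AnatomySet  # canonical (right-side) anatomy actually planned
    frame: ReferenceFrame


def trajectory_axis(grid: TrajectoryGrid) -> np.ndarray:
    """Drilling direction of the optimal trajectory in input coordinates."""
    R = rotation_for(grid.optimal.orientation, grid.frame)
    return R.T @ grid.frame.view


def run_plan(anatomy: AnatomySet, config: PlanningConfig | None = None,
             frame: ReferenceFrame | None = None) -> PlanOutcome:
    """Plan a retrofacial access for one anatomy set.

    Returns a :class:`PlanOutcome` whose report says whether the case is
    feasible; an anatomy without any drillable orientation, or without a
    clearance-respecting corridor, yields an unfeasible report rather than
    an exception.
    """
    config = config or PlanningConfig()
    side = anatomy.side
    if side == "left":
        log.info("mirroring left-side anatomy onto the canonical right frame")
        anatomy = mirror_anatomy(anatomy)
    if frame is None:
        frame = default_reference_frame(anatomy)

    check = check_reference_frame(anatomy, frame)
    if not check.passed:
        log.warning(
            "reference-frame check failed: FN centroid depth %.2f mm is not "
            "proximal to SM centroid depth %.2f mm; the view may not be a "
            "posterior-tympanotomy view", check.fn_depth_mm, check.sm_depth_mm,
        )

    grid = evaluate_grid(anatomy, frame, config)
    corridor = None
    depths = None
    if grid.feasible and grid.optimal.target_3d is not None:
        axis = trajectory_axis(grid)
        target = grid.optimal.target_3d
        try:
            theta = max_half_angle(anatomy, target, axis, config)
            entry = entry_point(anatomy["TB"], target, axis)
            mesh, skull_diam = build_cone(target, entry, theta,
                                          config.drill_diameter_mm)
            corridor = SurgicalCorridor(
                target_3d=np.asarray(target, float),
                entry_3d=entry,
                axis=axis,
                half_angle_deg=theta,
                tip_diameter_mm=config.drill_diameter_mm,
                skull_diameter_mm=skull_diam,
                mesh=mesh,
            )
        except CorridorError as exc:
            log.info("no corridor on the optimal trajectory: %s", exc)
        try:
            depths = depth_measurements(anatomy, target, trajectory_axis(grid),
                                        config)
        except CorridorError as exc:
            log.warning("depth measurements unavailable: %s", exc)

    report = assemble_report(grid, corridor, depths, side=side)
    return PlanOutcome(grid=grid, corridor=corridor, depths=depths,
                       report=report, anatomy=anatomy, frame=frame)


__all__ = ["PlanOutcome", "run_plan", "trajectory_axis"]
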