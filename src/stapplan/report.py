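"""Surgical guidelines report, feasibility classification and skull map.

The report gathers, for the optimal trajectory, the measurements a surgeon
needs before a retrofacial approach: SM exposure, thickness at the target,
distances to the facial nerve / sigmoid sinus / vestibulocochlear system,
depth of the SM behind the FN, feasible rotation ranges, and the corridor
diameter at the skull.  Accessibility is classified with strict thresholds:

* unfeasible  -- exposure <= 25 %, or SM-FN distance <= 0.8 mm, or corridor
  diameter <= 3 mm;
* easy        -- all thresholds passed and exposure > 40 %;
* difficult   -- all thresholds passed with exposure in (25, 40].

Boundary values fail (the comparisons are strictly greater-than).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .geometry_io import SurfaceMesh
from .orientation import FeasibilityThresholds, ReferenceFrame, rotation_for
from .scoring import TrajectoryGrid, feasible_angle_ranges

__all__ = [
    "FeasibilityThresholds",
    "classify_feasibility",
    "PlanReport",
    "assemble_report",
    "SkullMapPoint",
    "skull_map",
    "save_skull_map_ply",
    "save_skull_map_png",
    "save_grid_csv",
]


def classify_feasibility(exposed_pct, dist_sm_fn_mm, skull_diameter_mm,
                         thresholds: FeasibilityThresholds | None = None) -> str:
    """Classify an access as ``easy``, ``difficult`` or ``unfeasible``.

    ``None`` (a metric that could not be measured, e.g. no corridor exists)
    counts as failing its threshold.
    """
    t = thresholds or FeasibilityThresholds()

    def ok(value, minimum):
        return value is not None and math.isfinite(value) and value > minimum

    if not (ok(exposed_pct, t.exposure_pct_min)
            and ok(dist_sm_fn_mm, t.dfn_min_mm)
            and ok(skull_diameter_mm, t.corridor_diam_min_mm)):
        return "unfeasible"
    return "easy" if exposed_pct > t.exposure_pct_easy else "difficult"


@dataclass
class PlanReport:
    """Guidelines summary for one case (all lengths mm, angles degrees).

    ``dist_sm_*_mm`` are target-center-to-structure distances; the
    ``exposed_to_*_mm`` fields are the exposed-SM-to-proximal-polygon
    distances that feed the safety score -- both definitions are reported,
    distinctly named.  ``None`` marks a quantity that is not measurable for
    this case (e.g. no feasible orientation).
    """

    feasible: bool
    difficulty: str
    side: str
    exposed_sm_pct: float | None = None
    sm_thickness_mm: float | None = None
    dist_sm_fn_mm: float | None = None
    dist_sm_ss_mm: float | None = None
    dist_sm_vc_mm: float | None = None
    sm_depth_behind_fn_mm: float | None = None
    roll_range_deg: tuple | None = None
    yaw_range_deg: tuple | None = None
    optimal_roll_deg: float | None = None
    optimal_yaw_deg: float | None = None
    skull_diameter_mm: float | None = None
    tb_to_target_mm: float | None = None
    exposed_to_fn_mm: float | None = None
    exposed_to_ss_mm: float | None = None
    exposed_to_vc_mm: float | None = None
    safety_score: float | None = None

    def to_dict(self) -> dict:
        doc = asdict(self)
        for key in ("roll_range_deg", "yaw_range_deg"):
            if doc[key] is not None:
                doc[key] = list(doc[key])
        return doc

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_dict(cls, doc: dict) -> "PlanReport":
        doc = dict(doc)
        for key in ("roll_range_deg", "yaw_range_deg"):
            if doc.get(key) is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)


def _finite_or_none(value):
    if value is None:
        return None
    value = float(value)
    return value if math.isfinite(value) else None


def assemble_report(grid: TrajectoryGrid, corridor=None, depths: dict | None = None,
                    side: str = "right") -> PlanReport:
    """Populate the guidelines report from the planning artifacts.

    For an infeasible case (no drillable orientation) the metric fields stay
    absent, mirroring how such cases are simply not measurable.
    """
    thresholds = grid.config.thresholds
    if not grid.feasible:
        return PlanReport(feasible=False, difficulty="unfeasible", side=side)

    opt = grid.optimal
    roll_range, yaw_range = feasible_angle_ranges(grid)
    exposed_pct = 100.0 * opt.exposure_ratio
    dist_fn = _finite_or_none(opt.distances_mm.get("FN"))
    skull_diam = corridor.skull_diameter_mm if corridor is not None else None
    difficulty = classify_feasibility(exposed_pct, dist_fn, skull_diam, thresholds)
    depths = depths or {}
    return PlanReport(
        feasible=difficulty != "unfeasible",
        difficulty=difficulty,
        side=side,
        exposed_sm_pct=exposed_pct,
        sm_thickness_mm=_finite_or_none(depths.get("sm_thickness_mm")),
        dist_sm_fn_mm=dist_fn,
        dist_sm_ss_mm=_finite_or_none(opt.distances_mm.get("SS")),
        dist_sm_vc_mm=_finite_or_none(opt.distances_mm.get("VC")),
        sm_depth_behind_fn_mm=_finite_or_none(depths.get("sm_depth_behind_fn_mm")),
        roll_range_deg=roll_range,
        yaw_range_deg=yaw_range,
        optimal_roll_deg=opt.orientation.roll_deg,
        optimal_yaw_deg=opt.orientation.yaw_deg,
        skull_diameter_mm=_finite_or_none(skull_diam),
        tb_to_target_mm=_finite_or_none(depths.get("tb_to_target_mm")),
        exposed_to_fn_mm=_finite_or_none(opt.exposed_to_proximal_mm.get("FN")),
        exposed_to_ss_mm=_finite_or_none(opt.exposed_to_proximal_mm.get("SS")),
        exposed_to_vc_mm=_finite_or_none(opt.exposed_to_proximal_mm.get("VC")),
        safety_score=grid.optimal_score,
    )


@dataclass(frozen=True)
class SkullMapPoint:
    """One candidate trajectory projected onto the skull surface."""

    entry_3d: tuple
    roll_deg: float
    yaw_deg: float
    score: float


def skull_map(grid: TrajectoryGrid, tb_mesh: SurfaceMesh,
              frame: ReferenceFrame | None = None) -> list:
    """Entry points of all feasible trajectories with their safety scores.

    Each feasible orientation contributes the most lateral intersection of
    its trajectory line with the temporal bone; color-coding the scores
    (safest high, least safe low) gives the skull accessibility map.
    """
    from .corridor import entry_point  # local import to avoid cycle

    frame = frame or grid.frame
    points = []
    for ev, score in zip(grid.evaluations, grid.scores):
        if score is None or ev.target_3d is None:
            continue
        R = rotation_for(ev.orientation, frame)
        axis_world = R.T @ frame.view  # drilling direction in input coordinates
        try:
            entry = entry_point(tb_mesh, ev.target_3d, axis_world)
        except Exception:
            continue  # trajectory exits the modelled bone: not mappable
        points.append(SkullMapPoint(
            entry_3d=tuple(float(c) for c in entry),
            roll_deg=ev.orientation.roll_deg,
            yaw_deg=ev.orientation.yaw_deg,
            score=float(score),
        ))
    return points


def save_skull_map_ply(points: list, path) -> None:
    """ASCII PLY point cloud with a per-vertex ``score`` property."""
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {len(points)}",
        "property float x", "property float y", "property float z",
        "property float score",
        "end_header",
    ]
    for p in points:
        x, y, z = p.entry_3d
        lines.append(f"{x:.6f} {y:.6f} {z:.6f} {p.score:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def save_skull_map_png(points: list, path, frame: ReferenceFrame) -> None:
    """Render the skull map in the reference view (blue safe, red unsafe)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    if points:
        entries = np.array([p.entry_3d for p in points])
        u = entries @ frame.right
        v = entries @ frame.up
        scores = np.array([p.score for p in points])
        sc = ax.scatter(u, v, c=scores, cmap="coolwarm_r", s=18)
        fig.colorbar(sc, ax=ax, label="safety score S(i)")
    ax.set_xlabel("screen right [mm]")
    ax.set_ylabel("superior [mm]")
    ax.set_title("trajectory entry points on the temporal bone")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_grid_csv(grid: TrajectoryGrid, path) -> None:
    """Tabular dump of every orientation's metrics and score."""
    import pandas as pd

    pd.DataFrame(grid.table()).to_csv(path, index=False)
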