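"""Grid evaluation, the safety measure S(i) and optimal-trajectory selection.

Each feasible orientation *i* receives the weighted, normalized score

    S(i) = a * ASM(i)/max ASM + b * DFN(i)/max DFN + g * DSS(i)/max DSS
         + d * DVC(i)/max DVC - t * |Roll(i)|/max |Roll|

with default weights (a, b, g, d, t) = (0.6, 0.6, 0.6, 0.3, 1.2).  ASM is
the exposure ratio; DFN/DSS/DVC are the minimum distances from the exposed
SM region to the *proximal* polygon of each structure; Roll enters by
magnitude (the penalty prices how much the head must be rotated, not which
way).  Yaw never enters the score; it only breaks ties and is reported.
Normalizer maxima run over feasible orientations only, and a term whose
normalizer is zero or undefined contributes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InfeasibleCaseError
from .geometry_io import AnatomySet
from .orientation import (
    PlanningConfig,
    ReferenceFrame,
    SafetyWeights,
    orientation_grid,
)
from .projection import ProjectionResult, project_scene


@dataclass(frozen=True)
class Normalizers:
    """Grid-wide maxima used to normalize the safety-score terms."""

    max_asm: float
    max_dfn: float | None
    max_dss: float | None
    max_dvc: float | None
    max_abs_roll: float


def compute_normalizers(evaluations: list) -> Normalizers:
    """Maxima over feasible orientations; absent distances are skipped."""
    feas = [ev for ev in evaluations if ev.feasible]

    def dist_max(role):
        vals = [ev.exposed_to_proximal_mm.get(role) for ev in feas]
        vals = [v for v in vals if v is not None]
        return max(vals) if vals else None

    return Normalizers(
        max_asm=max((ev.exposure_ratio for ev in feas), default=0.0),
        max_dfn=dist_max("FN"),
        max_dss=dist_max("SS"),
        max_dvc=dist_max("VC"),
        max_abs_roll=max((abs(ev.orientation.roll_deg) for ev in feas), default=0.0),
    )


def safety_score(evaluation: ProjectionResult, normalizers: Normalizers,
                 weights: SafetyWeights) -> float:
    """S(i) for one feasible orientation."""

    def term(weight, value, normalizer):
        if value is None or normalizer is None or normalizer <= 0:
            return 0.0
        return weight * value / normalizer

    d = evaluation.exposed_to_proximal_mm
    return (
        term(weights.alpha, evaluation.exposure_ratio, normalizers.max_asm)
        + term(weights.beta, d.get("FN"), normalizers.max_dfn)
        + term(weights.gamma, d.get("SS"), normalizers.max_dss)
        + term(weights.delta, d.get("VC"), normalizers.max_dvc)
        - term(weights.theta, abs(evaluation.orientation.roll_deg),
               normalizers.max_abs_roll)
    )


@dataclass
class TrajectoryGrid:
    """All evaluated orientations with scores and the optimal pick."""

    evaluations: list
    normalizers: Normalizers
    scores: list  # float for feasible orientations, None otherwise
    optimal_index: int | None
    config: PlanningConfig
    frame: ReferenceFrame

    @property
    def feasible(self) -> bool:
        return self.optimal_index is not None

    @property
    def optimal(self) -> ProjectionResult:
        if self.optimal_index is None:
            raise InfeasibleCaseError("no feasible orientation in the grid")
        return self.evaluations[self.optimal_index]

    @property
    def optimal_score(self) -> float:
        return self.scores[self.optimal_index]

    def table(self) -> list:
        """Row dicts (orientation, metrics, score, feasibility) for export."""
        rows = []
        for ev, score in zip(self.evaluations, self.scores):
            d = ev.distances_mm
            e = ev.exposed_to_proximal_mm
            rows.append({
                "roll_deg": ev.orientation.roll_deg,
                "yaw_deg": ev.orientation.yaw_deg,
                "feasible": ev.feasible,
                "exposure_ratio": ev.exposure_ratio,
                "sm_area_mm2": ev.sm_area_mm2,
                "exposed_area_mm2": ev.exposed_area_mm2,
                "dist_target_fn_mm": d.get("FN"),
                "dist_target_ss_mm": d.get("SS"),
                "dist_target_vc_mm": d.get("VC"),
                "dfn_mm": e.get("FN"),
                "dss_mm": e.get("SS"),
                "dvc_mm": e.get("VC"),
                "score": score,
            })
        return rows


def _tie_break_key(item):
    index, orientation, score = item
    return (
        -score,
        abs(orientation.roll_deg) + abs(orientation.yaw_deg),
        abs(orientation.roll_deg),
        index,
    )


def select_optimal_index(evaluations: list, scores: list) -> int | None:
    """Argmax of S(i); ties prefer the smallest |roll|+|yaw|, then smallest
    |roll|, then grid order."""
    candidates = [
        (i, ev.orientation, s)
        for i, (ev, s) in enumerate(zip(evaluations, scores))
        if s is not None
    ]
    if not candidates:
        return None
    return min(candidates, key=_tie_break_key)[0]


def evaluate_grid(anatomy: AnatomySet, frame: ReferenceFrame,
                  config: PlanningConfig) -> TrajectoryGrid:
    """Project and score every orientation of the configured grid.

    Deterministic for identical inputs.  A grid without a single feasible
    orientation is returned with ``feasible == False`` (the case itself is
    infeasible); callers decide whether that is an error.
    """
    evaluations = [
        project_scene(anatomy, frame, orientation, config)
        for orientation in orientation_grid(config)
    ]
    normalizers = compute_normalizers(evaluations)
    scores = [
        safety_score(ev, normalizers, config.weights) if ev.feasible else None
        for ev in evaluations
    ]
    optimal = select_optimal_index(evaluations, scores)
    return TrajectoryGrid(
        evaluations=evaluations,
        normalizers=normalizers,
        scores=scores,
        optimal_index=optimal,
        config=config,
        frame=frame,
    )


def select_optimal(grid: TrajectoryGrid) -> ProjectionResult:
    """The optimal evaluation of a grid; raises if the case is infeasible."""
    return grid.optimal


def feasible_angle_ranges(grid: TrajectoryGrid):
    """(roll, yaw) min/max over feasible orientations; ``None`` if none."""
    rolls = [ev.orientation.roll_deg for ev in grid.evaluations if ev.feasible]
    yaws = [ev.orientation.yaw_deg for ev in grid.evaluations if ev.feasible]
    if not rolls:
        return None, None
    return (min(rolls), max(rolls)), (min(yaws), max(yaws))


__all__ = [
    "Normalizers",
    "compute_normalizers",
    "safety_score",
    "TrajectoryGrid",
    "evaluate_grid",
    "select_optimal",
    "select_optimal_index",
    "feasible_angle_ranges",
]
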