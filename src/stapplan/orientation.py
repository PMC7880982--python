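"""Surgeon's reference view, rotation conventions and the orientation grid.

The reference view emulates the posterior-tympanotomy perspective: looking
from lateral to medial on the surgery side, superior up on screen.  Candidate
trajectories are generated by rotating the scene about two view-plane axes:

* roll  -- rotation about the anterior-posterior axis (cervical lateral
  flexion), range -30..+30 degrees by default;
* yaw   -- head tilt about the inferior-superior axis (cervical rotation),
  range -40..+20 degrees by default;

both sampled in 2-degree steps, which keeps the grid at 31 x 31 = 961
orientations.  Rotations pivot about the SM centroid so the target stays
fixed in every projected view.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError
from .geometry_io import AnatomySet

log = logging.getLogger(__name__)


def compute_msd(drill_diameter_mm: float, epsilon_mm: float) -> float:
    """Minimum safety distance: drill tip radius plus imaging/segmentation error.

    ``MSD = d_drill / 2 + epsilon``.  With the standard 1.2 mm posterior
    tympanotomy burr and a 0.2 mm error this gives 0.8 mm.
    """
    if drill_diameter_mm <= 0:
        raise ConfigurationError("drill diameter must be positive")
    if epsilon_mm < 0:
        raise ConfigurationError("imaging/segmentation error must be >= 0")
    return drill_diameter_mm / 2.0 + epsilon_mm


@dataclass(frozen=True)
class ReferenceFrame:
    """Right-handed orthonormal viewing triad.

    ``view_axis`` points lateral-to-medial (the drilling/depth direction),
    ``up_axis`` is superior on screen, ``right_axis = up x view`` completes
    the triad (screen-right).
    """

    view_axis: tuple
    up_axis: tuple
    right_axis: tuple

    def __post_init__(self):
        for name in ("view_axis", "up_axis", "right_axis"):
            a = np.asarray(getattr(self, name), dtype=float)
            if abs(np.linalg.norm(a) - 1.0) > 1e-6:
                raise ConfigurationError(f"{name} must be a unit vector")
            object.__setattr__(self, name, tuple(a))
        v, u, r = (np.array(x) for x in (self.view_axis, self.up_axis, self.right_axis))
        if max(abs(v @ u), abs(v @ r), abs(u @ r)) > 1e-6:
            raise ConfigurationError("reference frame axes must be pairwise orthogonal")
        if np.linalg.norm(np.cross(u, v) - r) > 1e-6:
            raise ConfigurationError("reference frame must satisfy right = up x view")

    @property
    def view(self) -> np.ndarray:
        return np.asarray(self.view_axis)

    @property
    def up(self) -> np.ndarray:
        return np.asarray(self.up_axis)

    @property
    def right(self) -> np.ndarray:
        return np.asarray(self.right_axis)


def frame_from_axes(view_axis, up_axis) -> ReferenceFrame:
    """Build a validated frame from a viewing direction and an up direction."""
    v = np.asarray(view_axis, dtype=float)
    u = np.asarray(up_axis, dtype=float)
    nv, nu = np.linalg.norm(v), np.linalg.norm(u)
    if nv == 0 or nu == 0:
        raise ConfigurationError("frame axes must be non-zero")
    v, u = v / nv, u / nu
    if abs(v @ u) > 1e-6:
        raise ConfigurationError("view and up axes must be orthogonal")
    return ReferenceFrame(tuple(v), tuple(u), tuple(np.cross(u, v)))


def default_reference_frame(anatomy: AnatomySet | None, side: str | None = None) -> ReferenceFrame:
    """Lateral-to-medial view on the surgery side, superior up.

    Right ear: view along -R; left ear: view along +R.  A user-supplied frame
    (via :func:`frame_from_axes`) overrides this default.
    """
    if side is None:
        if anatomy is None:
            raise ConfigurationError("either an anatomy set or a side is required")
        side = anatomy.side
    if side == "right":
        return frame_from_axes((-1.0, 0.0, 0.0), (0.0, 0.0, 1.0))
    if side == "left":
        return frame_from_axes((1.0, 0.0, 0.0), (0.0, 0.0, 1.0))
    raise ConfigurationError(f"unknown side {side!r}")


@dataclass(frozen=True)
class FrameCheck:
    """Outcome of the posterior-tympanotomy view sanity check."""

    passed: bool
    fn_depth_mm: float
    sm_depth_mm: float


def check_reference_frame(anatomy: AnatomySet, frame: ReferenceFrame) -> FrameCheck:
    """Verify the FN centroid sits proximal (shallower) to the SM centroid.

    In a credible retrofacial view the facial nerve lies in front of the
    stapedius muscle; equality or reversal fails the check (strictly).
    """
    fn_depth = float(anatomy["FN"].centroid @ frame.view)
    sm_depth = float(anatomy["SM"].centroid @ frame.view)
    return FrameCheck(fn_depth < sm_depth, fn_depth, sm_depth)


@dataclass(frozen=True)
class Orientation:
    """One candidate view: roll and yaw in degrees from the reference view."""

    roll_deg: float
    yaw_deg: float


@dataclass(frozen=True)
class SafetyWeights:
    """Weights of the safety measure terms (exposure, DFN, DSS, DVC, |roll|)."""

    alpha: float = 0.6
    beta: float = 0.6
    gamma: float = 0.6
    delta: float = 0.3
    theta: float = 1.2

    def __post_init__(self):
        vals = (self.alpha, self.beta, self.gamma, self.delta, self.theta)
        if not all(math.isfinite(v) for v in vals):
            raise ConfigurationError("safety weights must be finite")


@dataclass(frozen=True)
class FeasibilityThresholds:
    """Strict lower bounds an access must exceed to be surgically feasible.

    Exposure > 25 % of the SM silhouette (> 40 % for an *easy* access),
    SM-FN distance > 0.8 mm, corridor diameter at the skull > 3 mm.
    """

    exposure_pct_min: float = 25.0
    exposure_pct_easy: float = 40.0
    dfn_min_mm: float = 0.8
    corridor_diam_min_mm: float = 3.0

    def __post_init__(self):
        if self.exposure_pct_easy < self.exposure_pct_min:
            raise ConfigurationError("easy threshold must be >= minimum threshold")


@dataclass(frozen=True)
class PlanningConfig:
    """All tunable planning parameters, defaulting to the standard protocol."""

    roll_range_deg: tuple = (-30.0, 30.0)
    yaw_range_deg: tuple = (-40.0, 20.0)
    step_deg: float = 2.0
    drill_diameter_mm: float = 1.2
    epsilon_mm: float = 0.2
    weights: SafetyWeights = field(default_factory=SafetyWeights)
    thresholds: FeasibilityThresholds = field(default_factory=FeasibilityThresholds)
    max_cone_half_angle_deg: float = 45.0
    #: subtract distal polygons from the exposed SM as well as proximal ones
    subtract_distal_from_exposure: bool = True

    def __post_init__(self):
        if self.step_deg <= 0:
            raise ConfigurationError("step_deg must be positive")
        # computing the MSD validates drill diameter and epsilon
        compute_msd(self.drill_diameter_mm, self.epsilon_mm)
        for name in ("roll_range_deg", "yaw_range_deg"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ConfigurationError(f"{name} must satisfy min <= max")
        if self.max_cone_half_angle_deg <= 0 or self.max_cone_half_angle_deg >= 90:
            raise ConfigurationError("max_cone_half_angle_deg must be in (0, 90)")

    @property
    def msd_mm(self) -> float:
        return compute_msd(self.drill_diameter_mm, self.epsilon_mm)

    def to_dict(self) -> dict:
        return {
            "roll_range_deg": list(self.roll_range_deg),
            "yaw_range_deg": list(self.yaw_range_deg),
            "step_deg": self.step_deg,
            "drill_diameter_mm": self.drill_diameter_mm,
            "epsilon_mm": self.epsilon_mm,
            "msd_mm": self.msd_mm,
            "weights": {
                "alpha": self.weights.alpha,
                "beta": self.weights.beta,
                "gamma": self.weights.gamma,
                "delta": self.weights.delta,
                "theta": self.weights.theta,
            },
            "thresholds": {
                "exposure_pct_min": self.thresholds.exposure_pct_min,
                "exposure_pct_easy": self.thresholds.exposure_pct_easy,
                "dfn_min_mm": self.thresholds.dfn_min_mm,
                "corridor_diam_min_mm": self.thresholds.corridor_diam_min_mm,
            },
            "max_cone_half_angle_deg": self.max_cone_half_angle_deg,
            "subtract_distal_from_exposure": self.subtract_distal_from_exposure,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PlanningConfig":
        doc = dict(doc)
        doc.pop("msd_mm", None)  # derived, never set directly
        if "weights" in doc:
            doc["weights"] = SafetyWeights(**doc["weights"])
        if "thresholds" in doc:
            doc["thresholds"] = FeasibilityThresholds(**doc["thresholds"])
        for key in ("roll_range_deg", "yaw_range_deg"):
            if key in doc:
                doc[key] = tuple(doc[key])
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path) -> "PlanningConfig":
        doc = yaml.safe_load(open(path).read()) or {}
        return cls.from_dict(doc)


def _axis_values(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(math.floor((hi - lo) / step + 1e-9)) + 1
    vals = lo + step * np.arange(n)
    if abs(vals[-1] - hi) > 1e-9:
        log.warning(
            "step %g does not divide range [%g, %g]; grid stops at %g",
            step, lo, hi, vals[-1],
        )
    return vals


def orientation_grid(config: PlanningConfig) -> list:
    """Cartesian grid of orientations, roll-major, inclusive endpoints.

    The order is deterministic: roll is the outer loop, yaw the inner one.
    """
    rolls = _axis_values(*config.roll_range_deg, config.step_deg)
    yaws = _axis_values(*config.yaw_range_deg, config.step_deg)
    return [Orientation(float(r), float(y)) for r in rolls for y in yaws]


def rotation_for(orientation: Orientation, frame: ReferenceFrame) -> np.ndarray:
    """3x3 rotation for a candidate view: roll about the A-P axis, then yaw.

    ``R = Rot(right_axis, roll) @ Rot(up_axis, yaw)``; the identity at (0, 0).
    Callers apply it about the SM-centroid pivot (see :func:`apply_rotation`).
    """
    r_roll = Rotation.from_rotvec(np.deg2rad(orientation.roll_deg) * frame.right)
    r_yaw = Rotation.from_rotvec(np.deg2rad(orientation.yaw_deg) * frame.up)
    return (r_roll * r_yaw).as_matrix()


def apply_rotation(points: np.ndarray, R: np.ndarray, pivot: np.ndarray) -> np.ndarray:
    """Rotate points about a pivot: ``p' = R (p - pivot) + pivot``."""
    return (np.asarray(points) - pivot) @ R.T + pivot


__all__ = [
    "compute_msd",
    "ReferenceFrame",
    "frame_from_axes",
    "default_reference_frame",
    "FrameCheck",
    "check_reference_frame",
    "Orientation",
    "SafetyWeights",
    "FeasibilityThresholds",
    "PlanningConfig",
    "orientation_grid",
    "rotation_for",
    "apply_rotation",
]
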