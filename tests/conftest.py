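"""Shared fixtures: phantom scenarios, pinned configs, pre-evaluated grids."""

import dataclasses

import pytest

from stapplan.orientation import PlanningConfig, default_reference_frame
from stapplan.phantom import PhantomSpec, make_phantom, scenario_suite
from stapplan.scoring import evaluate_grid


@pytest.fixture(scope="session")
def config():
    return PlanningConfig()


@pytest.fixture(scope="session")
def pinned_config():
    """Single-orientation grid at the (0, 0) reference view.

    Phantom truths are defined at the reference view, so recovery tests pin
    the planner there.
    """
    return dataclasses.replace(
        PlanningConfig(), roll_range_deg=(0.0, 0.0), yaw_range_deg=(0.0, 0.0)
    )


@pytest.fixture(scope="session")
def coarse_config():
    """10-degree grid (7 x 7 = 49 orientations): full planning at test scale."""
    return dataclasses.replace(PlanningConfig(), step_deg=10.0)


@pytest.fixture(scope="session")
def default_phantom():
    """The comfortably feasible reference phantom with its analytic truth."""
    anatomy, truth = make_phantom(PhantomSpec())
    return anatomy, truth


@pytest.fixture(scope="session")
def default_frame(default_phantom):
    return default_reference_frame(default_phantom[0])


@pytest.fixture(scope="session")
def suite():
    """The full scenario catalogue: [(spec, anatomy, truth), ...]."""
    return scenario_suite(seed=0)


@pytest.fixture(scope="session")
def suite_grids(suite, coarse_config):
    """Coarse planning grids for every suite phantom (shared: expensive)."""
    grids = []
    for spec, anatomy, truth in suite:
        frame = default_reference_frame(anatomy)
        grids.append((spec, anatomy, truth,
                      evaluate_grid(anatomy, frame, coarse_config)))
    return grids
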