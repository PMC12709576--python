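"""Shared fixtures: cached base-case runs and synthetic tables."""

from __future__ import annotations

import numpy as np
import pytest

from pelletsink import (
    PelletBody,
    PelletGeometry,
    terminal_statistics,
    terminal_velocity,
    run_settling_simulation,
)
from pelletsink.protocol import MESH_SCALE, desk_config
from pelletsink.synthetic import GeneratorConfig, generate_measurements


@pytest.fixture(scope="session")
def base_body() -> PelletBody:
    return PelletBody(PelletGeometry(100.0, 20.0))


@pytest.fixture(scope="session")
def base_run(base_body):
    """Desk-scale transient base-case settling run (20 x 100 um, 1140)."""
    traj = run_settling_simulation(base_body, config=desk_config(seed=1))
    stats = terminal_statistics(traj, "base", base_body)
    return traj, stats


@pytest.fixture(scope="session")
def base_oracle(base_body) -> float:
    """Steady mid-column terminal speed of the base pellet, m/day."""
    return terminal_velocity(base_body, 0.0, mesh_scale=MESH_SCALE)


@pytest.fixture(scope="session")
def generator_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def balanced_table(generator_config):
    """Fixed-count (1000/treatment) calibration-mode measurement table."""
    return generate_measurements(
        generator_config, seed=0, n_per_treatment=1000, common_random_base=True
    )


@pytest.fixture(scope="session")
def independent_table(generator_config):
    """Fixed-count independent-draw measurement table."""
    return generate_measurements(generator_config, seed=0, n_per_treatment=1000)
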