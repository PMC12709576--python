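"""From trajectories to reported quantities.

Terminal sinking statistics (burn-in excluded), scenario percent changes,
time-to-depth arithmetic and the one-way +-2.5 % sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bodies import FluidMedium, PelletBody, PelletGeometry
from .oracle import SECONDS_PER_DAY, reynolds_number, terminal_velocity
from .scenarios import Scenario
from .solver import SolverConfig, Trajectory, run_settling_simulation

M_PER_DAY = SECONDS_PER_DAY  # m/s -> m/day multiplier


@dataclass(frozen=True)
class ScenarioResult:
    """Terminal-phase summary of one settling run."""

    scenario_id: str
    mean_speed: float            # m/day, post-acceleration vertical speed
    sd_speed: float              # m/day
    endpoint_speed: float        # m/day, last recorded instantaneous speed
    burn_in_time: float          # s, duration of the excluded phase
    min_speed: float             # m/day, post-burn-in instantaneous minimum
    max_speed: float             # m/day
    mean_tilt_from_vertical: float  # rad, mean |long axis vs vertical|
    reynolds: float

    def __post_init__(self):
        if self.sd_speed < 0:
            raise ValueError("sd must be non-negative")


def _tilt_from_vertical(theta: np.ndarray) -> np.ndarray:
    """Angle between the long axis and the vertical, folded to [0, pi/2]."""
    dev = np.abs(((theta - np.pi / 2) + np.pi / 2) % np.pi - np.pi / 2)
    return dev


def terminal_statistics(
    trajectory: Trajectory,
    scenario_id: str = "run",
    body: PelletBody | None = None,
    medium: FluidMedium | None = None,
    onset_fraction: float = 0.95,
) -> ScenarioResult:
    """Mean and spread of the post-acceleration sinking speed, m/day.

    Burn-in rule: samples are dropped until the vertical speed first
    reaches ``onset_fraction`` of the mean speed over the final half of
    the record; the remainder is averaged.
    """
    speed = -trajectory.uy  # positive downward
    n = len(speed)
    if n < 4:
        raise ValueError("trajectory too short for terminal statistics")
    ref = speed[n // 2:].mean()
    above = np.nonzero(speed >= onset_fraction * ref)[0]
    if len(above) == 0 or above[0] >= n - 1:
        raise ValueError("trajectory never leaves the acceleration phase")
    start = above[0]
    tail = speed[start:]
    mean_ms = float(tail.mean())
    sd_ms = float(tail.std(ddof=1)) if len(tail) > 1 else 0.0
    tilt = _tilt_from_vertical(trajectory.theta[start:])
    medium = medium or FluidMedium()
    length_scale = (
        2 * body.geometry.a if body is not None else 20e-6
    )
    return ScenarioResult(
        scenario_id=scenario_id,
        mean_speed=mean_ms * M_PER_DAY,
        sd_speed=sd_ms * M_PER_DAY,
        endpoint_speed=float(speed[-1]) * M_PER_DAY,
        burn_in_time=float(trajectory.t[start] - trajectory.t[0]),
        min_speed=float(tail.min()) * M_PER_DAY,
        max_speed=float(tail.max()) * M_PER_DAY,
        mean_tilt_from_vertical=float(tilt.mean()),
        reynolds=reynolds_number(mean_ms, length_scale, medium),
    )


def percent_change(reference: ScenarioResult | float, treated: ScenarioResult | float) -> float:
    """100 * (treated - reference) / reference; negative means slower."""
    ref = reference.mean_speed if isinstance(reference, ScenarioResult) else float(reference)
    trt = treated.mean_speed if isinstance(treated, ScenarioResult) else float(treated)
    if ref == 0:
        raise ValueError("reference speed must be nonzero")
    return 100.0 * (trt - ref) / ref


def time_to_depth(speed_m_per_day: float, depth_m: float) -> float:
    """Days for a pellet sinking at the given rate to reach the depth."""
    if speed_m_per_day <= 0:
        raise ValueError("pellet never arrives: non-positive sinking speed")
    return depth_m / speed_m_per_day


# ---------------------------------------------------------------------------
# sensitivity analysis

SENSITIVITY_FACTORS = (
    "pellet density",
    "pellet size",
    "water density",
    "water viscosity",
)


@dataclass(frozen=True)
class SensitivityRow:
    factor: str
    perturbation: float       # signed fraction, e.g. +0.025
    percent_change: float     # % change in sinking rate


def _perturbed_scenario(sc: Scenario, factor: str, eps: float) -> Scenario:
    body, medium = sc.body, sc.medium
    if factor == "pellet density":
        body = replace(body, base_density=body.base_density * (1 + eps))
    elif factor == "pellet size":
        g = body.geometry
        body = replace(
            body,
            geometry=PelletGeometry(g.length_um * (1 + eps), g.width_um * (1 + eps)),
        )
    elif factor == "water density":
        medium = replace(medium, density=medium.density * (1 + eps))
    elif factor == "water viscosity":
        medium = replace(
            medium, dynamic_viscosity=medium.dynamic_viscosity * (1 + eps)
        )
    else:
        raise ValueError(f"unknown sensitivity factor {factor!r}")
    return Scenario(name=f"{sc.name}_{factor}_{eps:+g}", body=body,
                    domain=sc.domain, medium=medium)


def sensitivity_analysis(
    base: Scenario,
    solver: str = "oracle",
    perturbation: float = 0.025,
    mesh_scale: float = 1.0,
    solver_config: SolverConfig | None = None,
) -> list[SensitivityRow]:
    """One-way sensitivity of the sinking rate to +-2.5 % factor changes.

    ``solver`` is "oracle" (steady solves, seconds) or "transient" (full
    coupled runs).  Rows are ordered by factor then sign; use
    :func:`rank_factors` for the |change| ranking.
    """

    def speed_of(sc: Scenario) -> float:
        if solver == "oracle":
            return terminal_velocity(sc.body, 0.0, sc.domain, sc.medium,
                                     mesh_scale=mesh_scale)
        if solver == "transient":
            cfg = solver_config or SolverConfig()
            traj = run_settling_simulation(sc.body, sc.domain, sc.medium, cfg)
            return terminal_statistics(traj, sc.name, sc.body, sc.medium).mean_speed
        raise ValueError(f"unknown solver mode {solver!r}")

    v0 = speed_of(base)
    rows: list[SensitivityRow] = []
    for factor in SENSITIVITY_FACTORS:
        for eps in (+perturbation, -perturbation):
            try:
                v = speed_of(_perturbed_scenario(base, factor, eps))
                rows.append(
                    SensitivityRow(factor, eps, 100.0 * (v - v0) / v0)
                )
            except Exception:
                rows.append(SensitivityRow(factor, eps, float("nan")))
    return rows


def rank_factors(rows: list[SensitivityRow]) -> list[str]:
    """Factors ranked by mean |percent change| over the +- directions."""
    scores: dict[str, list[float]] = {}
    for r in rows:
        if np.isfinite(r.percent_change):
            scores.setdefault(r.factor, []).append(abs(r.percent_change))
    return sorted(scores, key=lambda f: -float(np.mean(scores[f])))
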