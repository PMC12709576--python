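"""Steady-state terminal-velocity oracle.

Solves the steady Stokes problem (no time derivative, no convection,
dynamic pressure only) around a pellet held at a prescribed velocity in
the same channel geometry, extracts the drag through the consistent
traction reaction, and finds the terminal velocity from the force balance

    k(theta) v = (rho_bulk - rho_fluid) * area * g.

The discretisation machinery (mesh, Taylor-Hood elements) is shared with
the transient solver, but the formulation and solution path are separate:
a single symmetric steady solve with homogeneous open boundaries, against
which the transient coupling loop can be cross-checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .bodies import DomainSpec, FluidMedium, PelletBody, PelletGeometry
from .fem import (
    assemble_operators,
    build_p2,
    classify_dofs,
    interface_force_and_torque,
    rigid_interface_values,
)
from .meshing import generate_mesh

SECONDS_PER_DAY = 86_400.0


@dataclass(frozen=True)
class SteadyDragResult:
    """Drag on a pellet towed at a prescribed velocity."""

    velocity: float          # m/s, prescribed (positive = speed magnitude)
    drag_force: float        # N/m, magnitude of the hydrodynamic force
    k: float                 # N s/m^2, linear drag coefficient drag/velocity
    theta: float             # rad, pellet orientation
    force_vector: np.ndarray # (2,) signed force on the pellet
    torque: float            # N, about the geometric centre
    cell_count: int = 0


def steady_drag(
    geometry: PelletGeometry,
    theta: float,
    velocity: tuple[float, float],
    domain: DomainSpec | None = None,
    medium: FluidMedium | None = None,
    mesh_scale: float = 1.0,
    center: tuple[float, float] | None = None,
) -> SteadyDragResult:
    """Drag force on the pellet translating steadily at ``velocity``.

    The pellet is placed mid-column by default, away from the open
    top/bottom boundaries, where the steady drag is representative of the
    terminal phase.  The Reynolds number of the prescribed flow must be
    small (the result is only meaningful in the Stokes regime the model
    operates in).
    """
    domain = domain or DomainSpec()
    medium = medium or FluidMedium()
    if center is None:
        center = (0.5 * domain.width, 0.5 * domain.height)
    speed = float(np.hypot(*velocity))
    if speed > 0:
        re = reynolds_number(speed, geometry.width_um * 1e-6, medium)
        if re > 0.1:
            raise ValueError(f"prescribed flow is not in the Stokes regime (Re={re:.3g})")

    mesh = generate_mesh(geometry, domain, center=center, theta=theta,
                         scale=mesh_scale)
    space = build_p2(mesh)
    dset = classify_dofs(space, mesh.points)
    A, B, _, _ = assemble_operators(
        space, mesh.points, medium.dynamic_viscosity, medium.density, None
    )
    K = sparse.bmat([[A, B], [B.T, None]], format="csr")
    rhs = np.zeros(K.shape[0])

    center = np.asarray(center, dtype=float)
    bc = rigid_interface_values(dset, velocity, 0.0, center)
    free = dset.free
    fixed = ~free
    Kff = K[free][:, free].tocsc()
    b = rhs[free] - K[free][:, fixed] @ bc[fixed]
    sol = np.zeros(K.shape[0])
    sol[free] = splu(Kff).solve(b)
    sol[fixed] = bc[fixed]

    force, torque = interface_force_and_torque(K, rhs, sol, dset, center)
    if speed == 0.0:
        k = 0.0
    else:
        k = float(-np.dot(force, velocity) / (speed * speed))
    return SteadyDragResult(
        velocity=speed,
        drag_force=float(np.linalg.norm(force)),
        k=k,
        theta=theta,
        force_vector=force,
        torque=torque,
        cell_count=mesh.cell_count,
    )


def terminal_velocity(
    body: PelletBody,
    theta: float = 0.0,
    domain: DomainSpec | None = None,
    medium: FluidMedium | None = None,
    mesh_scale: float = 1.0,
    center: tuple[float, float] | None = None,
    rtol: float = 1e-10,
    max_iter: int = 8,
) -> float:
    """Steady terminal sinking rate in m/day (positive downward).

    Secant iteration on the vertical force balance
    ``drag_y(v) = delta_rho * area * g``; for the linear Stokes drag this
    converges in one update, the iteration simply guards the regime check.
    """
    domain = domain or DomainSpec()
    medium = medium or FluidMedium()
    delta_rho = body.bulk_density - medium.density
    if delta_rho == 0.0:
        return 0.0
    net_weight = abs(delta_rho) * body.area * medium.gravity  # N/m

    # initial guess: isotropic Stokes-like coefficient, capped in-regime
    v_cap = 0.05 * medium.dynamic_viscosity / (
        medium.density * body.geometry.width_um * 1e-6
    )
    v = float(np.clip(net_weight / (8.0 * np.pi * medium.dynamic_viscosity),
                      1e-7, v_cap))
    prev_v, prev_res = None, None
    for _ in range(max_iter):
        drag = steady_drag(
            body.geometry, theta, (0.0, -v), domain, medium, mesh_scale,
            center=center,
        )
        drag_y = drag.force_vector[1]  # positive: fluid resists downward motion
        res = drag_y - net_weight
        if abs(res) <= rtol * net_weight:
            break
        if prev_v is None:
            k = drag_y / v
            new_v = net_weight / k
        else:
            slope = (res - prev_res) / (v - prev_v)
            new_v = v - res / slope
        prev_v, prev_res = v, res
        v = float(new_v)
    speed_ms = v
    return float(np.sign(delta_rho) * speed_ms * SECONDS_PER_DAY)


def reynolds_number(speed: float, length_scale: float, medium: FluidMedium | None = None) -> float:
    """Re = rho v L / mu."""
    medium = medium or FluidMedium()
    if speed < 0 or length_scale < 0:
        raise ValueError("speed and length scale must be non-negative")
    return medium.density * speed * length_scale / medium.dynamic_viscosity
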