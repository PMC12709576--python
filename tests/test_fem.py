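"""Discrete operators: hydrostatics, buoyancy, channel flow, continuity."""

import numpy as np
import pytest
from scipy import sparse
from scipy.sparse.linalg import splu

from pelletsink.bodies import DomainSpec, FluidMedium, PelletGeometry
from pelletsink.fem import (
    assemble_operators,
    body_force_vector,
    build_p2,
    classify_dofs,
    interface_force_and_torque,
    open_boundary_vector,
    rigid_interface_values,
)
from pelletsink.meshing import generate_mesh
from pelletsink.solver import divergence_norm

MED = FluidMedium()
DOM = DomainSpec()


@pytest.fixture(scope="module")
def stokes_system():
    """Assembled steady system around the stationary base pellet."""
    mesh = generate_mesh(PelletGeometry(100, 20), DOM)
    space = build_p2(mesh)
    dset = classify_dofs(space, mesh.points)
    A, B, M, _ = assemble_operators(
        space, mesh.points, MED.dynamic_viscosity, MED.density, None
    )
    K = sparse.bmat([[A, B], [B.T, None]], format="csr")
    return mesh, space, dset, K


class TestHydrostatics:
    @pytest.fixture(scope="class")
    def hydrostatic_solution(self, stokes_system):
        mesh, space, dset, K = stokes_system
        rhs = body_force_vector(space, mesh.points, (0.0, -MED.gravity),
                                MED.density)
        rhs += open_boundary_vector(space, mesh.points, MED.density,
                                    MED.gravity, DOM.height)
        rhs_full = np.concatenate([rhs, np.zeros(space.n_vertices)])
        free = dset.free
        sol = np.zeros(K.shape[0])
        sol[free] = splu(K[free][:, free].tocsc()).solve(rhs_full[free])
        return mesh, space, dset, K, rhs_full, sol

    def test_quiescent_velocity(self, hydrostatic_solution):
        mesh, space, dset, K, rhs_full, sol = hydrostatic_solution
        n2 = space.n_p2
        p_scale = MED.density * MED.gravity * DOM.height
        assert np.abs(sol[: 2 * n2]).max() < 1e-9 * p_scale

    def test_pressure_linear_in_depth(self, hydrostatic_solution):
        mesh, space, dset, K, rhs_full, sol = hydrostatic_solution
        n2 = space.n_p2
        p = sol[2 * n2:]
        p_exact = MED.density * MED.gravity * (DOM.height - mesh.points[:, 1])
        assert np.abs(p - p_exact).max() < 1e-8 * p_exact.max()

    def test_archimedes_buoyancy_on_stationary_ellipse(self, hydrostatic_solution):
        """Traction integral equals rho_f * area * g upward, within 1%."""
        mesh, space, dset, K, rhs_full, sol = hydrostatic_solution
        force, torque = interface_force_and_torque(
            K, rhs_full, sol, dset, np.asarray(DOM.release_point())
        )
        buoy = MED.density * PelletGeometry(100, 20).area * MED.gravity
        assert force[1] == pytest.approx(buoy, rel=0.01)
        assert abs(force[0]) < 0.01 * buoy
        assert abs(torque) < 0.01 * buoy * 50e-6


class TestInterfaceAndWalls:
    def test_interface_values_equal_rigid_motion(self, stokes_system):
        mesh, space, dset, K = stokes_system
        center = np.asarray(DOM.release_point())
        vals = rigid_interface_values(dset, (1e-4, -2e-4), 3.0, center)
        r = dset.interface_coords - center
        assert np.allclose(vals[dset.interface_x], 1e-4 - 3.0 * r[:, 1])
        assert np.allclose(vals[dset.interface_y], -2e-4 + 3.0 * r[:, 0])

    def test_literal_interface_variant_vertical_only(self, stokes_system):
        mesh, space, dset, K = stokes_system
        center = np.asarray(DOM.release_point())
        vals = rigid_interface_values(dset, (1e-4, -2e-4), 3.0, center,
                                      literal_interface=True)
        assert np.allclose(vals[dset.interface_x], 0.0)
        assert np.allclose(vals[dset.interface_y], -2e-4)

    def test_wall_dofs_are_constrained(self, stokes_system):
        mesh, space, dset, K = stokes_system
        fixed = ~dset.free
        assert fixed[mesh.wall_nodes].all()
        assert fixed[mesh.wall_nodes + space.n_p2].all()


class TestChannelFlow:
    def test_body_force_poiseuille_with_prescribed_ends(self):
        """Gravity-driven channel flow reproduces the parabolic profile.

        The exact profile is prescribed on the open ends (it is not the
        natural solution of the zero-tangential-traction condition); the
        interior solve must then return the parabola to <1% away from the
        small held pellet.
        """
        geo = PelletGeometry(10, 10)
        dom = DomainSpec(release_depth_um=500)
        mesh = generate_mesh(geo, dom)
        space = build_p2(mesh)
        dset = classify_dofs(space, mesh.points)
        A, B, _, _ = assemble_operators(
            space, mesh.points, MED.dynamic_viscosity, MED.density, None
        )
        K = sparse.bmat([[A, B], [B.T, None]], format="csr")
        g = 1e-4
        rhs = body_force_vector(space, mesh.points, (0.0, -g), MED.density)
        rhs_full = np.concatenate([rhs, np.zeros(space.n_vertices)])

        coords = space.node_coords(mesh.points)
        n2 = space.n_p2
        W, H = dom.width, dom.height
        parabola = -(MED.density * g / (2 * MED.dynamic_viscosity)) \
            * coords[:, 0] * (W - coords[:, 0])

        free = dset.free.copy()
        vals = np.zeros(K.shape[0])
        ends = (np.abs(coords[:, 1]) < 1e-9) | (np.abs(coords[:, 1] - H) < 1e-9)
        idx = np.nonzero(ends)[0]
        free[idx] = False           # ux on ends
        free[idx + n2] = False      # uy on ends
        vals[idx + n2] = parabola[idx]
        fixed = ~free
        sol = np.zeros(K.shape[0])
        sol[free] = splu(K[free][:, free].tocsc()).solve(
            rhs_full[free] - K[free][:, fixed] @ vals[fixed]
        )
        sol[fixed] = vals[fixed]

        # compare mid-column, away from the held pellet
        pellet = np.asarray(dom.release_point())
        far = (
            (np.hypot(coords[:, 0] - pellet[0], coords[:, 1] - pellet[1]) > 5e-4)
            & (np.abs(coords[:, 1] - 3e-3) < 1e-3)
        )
        err = np.abs(sol[n2: 2 * n2][far] - parabola[far]).max()
        assert err < 0.01 * np.abs(parabola).max()


class TestContinuity:
    def test_projected_divergence_vanishes(self, stokes_system):
        """The continuity constraint rows are satisfied to solver precision."""
        mesh, space, dset, K = stokes_system
        center = np.asarray(DOM.release_point())
        bc = rigid_interface_values(dset, (0.0, -2e-4), 0.0, center)
        free = dset.free
        fixed = ~free
        sol = np.zeros(K.shape[0])
        sol[free] = splu(K[free][:, free].tocsc()).solve(
            -K[free][:, fixed] @ bc[fixed]
        )
        sol[fixed] = bc[fixed]
        n2 = space.n_p2
        cont = K[2 * n2:, : 2 * n2] @ sol[: 2 * n2]
        assert np.abs(cont).max() < 1e-10 * np.abs(sol[: 2 * n2]).max()

    def test_pointwise_divergence_small_and_convergent(self, stokes_system):
        mesh, space, dset, K = stokes_system
        center = np.asarray(DOM.release_point())
        bc = rigid_interface_values(dset, (0.0, -2e-4), 0.0, center)
        free = dset.free
        fixed = ~free
        sol = np.zeros(K.shape[0])
        sol[free] = splu(K[free][:, free].tocsc()).solve(
            -K[free][:, fixed] @ bc[fixed]
        )
        sol[fixed] = bc[fixed]
        assert divergence_norm(space, mesh.points, sol) < 0.05
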