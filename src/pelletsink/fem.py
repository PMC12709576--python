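"""Taylor-Hood (P2 velocity / P1 pressure) finite elements on triangles.

Implements the discrete operators of the incompressible laminar momentum
balance

    rho (du/dt + (c . grad) u) = -grad p
        + div[ mu (grad u + grad u^T) - (2/3) mu (div u) I ] + rho g

together with continuity ``div u = 0``.  The (2/3) mu (div u) I term is
retained verbatim even though it vanishes for incompressible flow.

Global degree-of-freedom layout: ``ux`` on P2 nodes ``[0, n2)``, ``uy`` on
``[n2, 2 n2)``, pressure on vertices ``[2 n2, 2 n2 + nv)``.  P2 nodes are
the mesh vertices followed by edge midpoints.

Boundary conditions, per the water-column model: left/right walls no-slip;
top and bottom open with the hydrostatic traction ``-p_hydro n`` applied as
the natural condition; pellet interface velocity prescribed (full rigid
body motion, or the vertical-only variant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .meshing import Mesh2D

# 7-point Gauss rule on the reference triangle, exact to degree 5
_A1, _B1 = 0.0597158717897698, 0.4701420641051151
_A2, _B2 = 0.7974269853530873, 0.1012865073234563
_QP = np.array(
    [
        [1 / 3, 1 / 3],
        [_A1, _B1], [_B1, _A1], [_B1, _B1],
        [_A2, _B2], [_B2, _A2], [_B2, _B2],
    ]
)
_QW = np.array([0.225, 0.1323941527885062, 0.1323941527885062, 0.1323941527885062,
                0.1259391805448271, 0.1259391805448271, 0.1259391805448271]) * 0.5


def _p2_basis(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P2 shape functions and reference gradients at points (nq, 2).

    Local ordering: vertices (1-L2-L3, L2, L3) then midpoints of edges
    (v0,v1), (v1,v2), (v2,v0).
    """
    l2, l3 = xi[:, 0], xi[:, 1]
    l1 = 1.0 - l2 - l3
    N = np.stack(
        [
            l1 * (2 * l1 - 1),
            l2 * (2 * l2 - 1),
            l3 * (2 * l3 - 1),
            4 * l1 * l2,
            4 * l2 * l3,
            4 * l3 * l1,
        ],
        axis=1,
    )
    z = np.zeros_like(l1)
    dl1 = np.stack([-np.ones_like(l1), -np.ones_like(l1)], 1)
    dl2 = np.stack([np.ones_like(l1), z], 1)
    dl3 = np.stack([z, np.ones_like(l1)], 1)
    dN = np.stack(
        [
            (4 * l1 - 1)[:, None] * dl1,
            (4 * l2 - 1)[:, None] * dl2,
            (4 * l3 - 1)[:, None] * dl3,
            4 * (l1[:, None] * dl2 + l2[:, None] * dl1),
            4 * (l2[:, None] * dl3 + l3[:, None] * dl2),
            4 * (l3[:, None] * dl1 + l1[:, None] * dl3),
        ],
        axis=1,
    )  # (nq, 6, 2)
    return N, dN


_N2, _DN2 = _p2_basis(_QP)
_N1 = np.stack([1 - _QP[:, 0] - _QP[:, 1], _QP[:, 0], _QP[:, 1]], axis=1)


@dataclass
class P2Space:
    """P2 node structure on a mesh: vertices then edge midpoints."""

    mesh: Mesh2D
    edges: np.ndarray        # (ne, 2) vertex pairs, sorted
    tri_dofs: np.ndarray     # (m, 6) P2 dofs per triangle
    n_vertices: int
    edge_of_pair: dict

    @property
    def n_p2(self) -> int:
        return self.n_vertices + len(self.edges)

    def node_coords(self, points: np.ndarray | None = None) -> np.ndarray:
        pts = self.mesh.points if points is None else points
        mid = 0.5 * (pts[self.edges[:, 0]] + pts[self.edges[:, 1]])
        return np.vstack([pts, mid])

    def edge_dof(self, i: int, j: int) -> int:
        return self.n_vertices + self.edge_of_pair[(min(i, j), max(i, j))]


def build_p2(mesh: Mesh2D) -> P2Space:
    tris = mesh.triangles
    pairs = np.concatenate(
        [tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]], axis=0
    )
    pairs.sort(axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    m = len(tris)
    tri_edge = inverse.reshape(3, m).T
    nv = len(mesh.points)
    tri_dofs = np.column_stack([tris, nv + tri_edge])
    edge_of_pair = {tuple(e): k for k, e in enumerate(uniq)}
    return P2Space(mesh, uniq, tri_dofs, nv, edge_of_pair)


# ---------------------------------------------------------------------------
# assembly

def _geometry(points: np.ndarray, tris: np.ndarray):
    p = points[tris]
    j11 = p[:, 1, 0] - p[:, 0, 0]
    j12 = p[:, 2, 0] - p[:, 0, 0]
    j21 = p[:, 1, 1] - p[:, 0, 1]
    j22 = p[:, 2, 1] - p[:, 0, 1]
    det = j11 * j22 - j12 * j21
    # inv(J)^T rows: used to push reference gradients forward
    it11 = j22 / det
    it12 = -j21 / det
    it21 = -j12 / det
    it22 = j11 / det
    invJT = np.stack(
        [np.stack([it11, it12], -1), np.stack([it21, it22], -1)], axis=1
    )  # (m, 2, 2)
    return invJT, det


def assemble_operators(
    space: P2Space,
    points: np.ndarray,
    mu: float,
    rho: float,
    conv: np.ndarray | None = None,
):
    """Assemble viscous block A (2n2 x 2n2), pressure coupling B
    (2n2 x nv), P2 scalar mass matrix M, and optional convection C.

    ``conv`` is an ALE convective velocity given as a (n2, 2) nodal P2
    field; the assembled C applies rho (c . grad u, v) on both components.
    """
    mesh = space.mesh
    tris = mesh.triangles
    dofs = space.tri_dofs
    m = len(tris)
    n2 = space.n_p2
    invJT, det = _geometry(points, tris)
    absdet = np.abs(det)

    # physical gradients: g[e, q, i, k] = dN_i/dx_k
    g = np.einsum("eab,qib->eqia", invJT, _DN2)
    w = (_QW[None, :] * absdet[:, None])  # (m, nq)

    gx = g[..., 0]
    gy = g[..., 1]
    kxx = np.einsum("eq,eqi,eqj->eij", w, gx, gx)
    kyy = np.einsum("eq,eqi,eqj->eij", w, gy, gy)
    kxy = np.einsum("eq,eqi,eqj->eij", w, gx, gy)  # dNi/dx dNj/dy
    lap = kxx + kyy

    c = 2.0 / 3.0
    # A_kl[a,b] = mu (delta_kl grad.grad + dN_b/dx_k dN_a/dx_l)
    #           - (2/3) mu dN_a/dx_k dN_b/dx_l
    a11 = mu * (lap + kxx) - c * mu * kxx
    a22 = mu * (lap + kyy) - c * mu * kyy
    # A12[a,b]: test x, trial y: mu dN_b/dx dN_a/dy - (2/3) mu dN_a/dx dN_b/dy
    a12 = mu * kxy.transpose(0, 2, 1) - c * mu * kxy
    a21 = mu * kxy - c * mu * kxy.transpose(0, 2, 1)

    me = np.einsum("eq,qi,qj->eij", w, _N2, _N2)

    if conv is not None:
        cq = np.einsum("qi,eid->eqd", _N2, conv[dofs])  # velocity at qpts
        cgrad = np.einsum("eqd,eqjd->eqj", cq, g)       # (c . grad) N_j
        ce = rho * np.einsum("eq,qi,eqj->eij", w, _N2, cgrad)
    else:
        ce = None

    # pressure coupling: B_k[a, c] = -int psi_c dN_a/dx_k
    b1 = -np.einsum("eq,eqi,qc->eic", w, gx, _N1)
    b2 = -np.einsum("eq,eqi,qc->eic", w, gy, _N1)

    rows6 = np.repeat(dofs, 6, axis=1).reshape(-1)
    cols6 = np.tile(dofs, (1, 6)).reshape(-1)

    def scatter(block):
        return sparse.coo_matrix(
            (block.reshape(-1), (rows6, cols6)), shape=(n2, n2)
        )

    A = sparse.bmat(
        [[scatter(a11), scatter(a12)], [scatter(a21), scatter(a22)]]
    ).tocsr()
    M = scatter(me).tocsr()
    C = None
    if ce is not None:
        Cb = scatter(ce).tocsr()
        C = sparse.bmat([[Cb, None], [None, Cb]]).tocsr()

    rows_b = np.repeat(dofs, 3, axis=1).reshape(-1)
    cols_b = np.tile(tris, (1, 6)).reshape(-1)
    B1 = sparse.coo_matrix(
        (b1.reshape(-1), (rows_b, cols_b)), shape=(n2, space.n_vertices)
    )
    B2 = sparse.coo_matrix(
        (b2.reshape(-1), (rows_b, cols_b)), shape=(n2, space.n_vertices)
    )
    B = sparse.vstack([B1, B2]).tocsr()
    return A, B, M, C


def body_force_vector(space: P2Space, points: np.ndarray, fvec: tuple[float, float],
                      rho: float) -> np.ndarray:
    """RHS for a constant body force rho * fvec (e.g. gravity)."""
    mesh = space.mesh
    _, det = _geometry(points, mesh.triangles)
    w = _QW[None, :] * np.abs(det)[:, None]
    fe = np.einsum("eq,qi->ei", w, _N2)  # integral of each shape fn
    n2 = space.n_p2
    rhs = np.zeros(2 * n2)
    np.add.at(rhs, space.tri_dofs.reshape(-1), (rho * fvec[0] * fe).reshape(-1))
    np.add.at(rhs[n2:], space.tri_dofs.reshape(-1), (rho * fvec[1] * fe).reshape(-1))
    return rhs


def open_boundary_vector(
    space: P2Space, points: np.ndarray, medium_density: float, gravity: float,
    height: float,
) -> np.ndarray:
    """Natural-condition RHS for the open top/bottom with hydrostatic offset.

    The applied traction is ``-p_hydro n`` with ``p_hydro = rho g (H - y)``;
    it vanishes at the top (p=0) and pushes up at the bottom.
    """
    mesh = space.mesh
    n2 = space.n_p2
    rhs = np.zeros(2 * n2)
    p0 = medium_density * gravity * height
    bottom = set(mesh.bottom_nodes) | set(
        mesh.wall_nodes[np.abs(points[mesh.wall_nodes, 1]) < 1e-12]
    )
    # bottom edges: both endpoints at y=0
    for k, (i, j) in enumerate(space.edges):
        if i in bottom and j in bottom:
            h = abs(points[j, 0] - points[i, 0])
            # traction (0, +p0): quadratic edge integrals h/6, h/6, 2h/3
            rhs[n2 + i] += p0 * h / 6.0
            rhs[n2 + j] += p0 * h / 6.0
            rhs[n2 + space.n_vertices + k] += p0 * 2.0 * h / 3.0
    return rhs


# ---------------------------------------------------------------------------
# Dirichlet data

@dataclass
class DirichletSet:
    """Constrained velocity dofs and helpers to impose interface modes."""

    space: P2Space
    fixed_dofs: np.ndarray        # all constrained dof indices (into 0..2n2)
    interface_x: np.ndarray       # ux dof indices on the interface
    interface_y: np.ndarray
    interface_coords: np.ndarray  # (ni2, 2) positions of those nodes
    free: np.ndarray              # boolean over full system (incl pressure)


def classify_dofs(space: P2Space, points: np.ndarray) -> DirichletSet:
    mesh = space.mesh
    n2 = space.n_p2
    nv = space.n_vertices
    wall = np.zeros(n2, dtype=bool)
    wall[mesh.wall_nodes] = True
    iface = np.zeros(n2, dtype=bool)
    iface[mesh.interface_nodes] = True
    for k, (i, j) in enumerate(space.edges):
        if wall[i] and wall[j]:
            wall[nv + k] = True
    for i, j in mesh.interface_edges:
        iface[space.edge_dof(int(i), int(j))] = True

    coords = space.node_coords(points)
    iface_nodes = np.nonzero(iface)[0]
    fixed = np.concatenate(
        [
            np.nonzero(wall)[0],
            np.nonzero(wall)[0] + n2,
            iface_nodes,
            iface_nodes + n2,
        ]
    )
    free = np.ones(2 * n2 + nv, dtype=bool)
    free[fixed] = False
    return DirichletSet(
        space=space,
        fixed_dofs=fixed,
        interface_x=iface_nodes,
        interface_y=iface_nodes + n2,
        interface_coords=coords[iface_nodes],
        free=free,
    )


def rigid_interface_values(
    dset: DirichletSet,
    velocity: tuple[float, float],
    omega: float,
    center: np.ndarray,
    literal_interface: bool = False,
) -> np.ndarray:
    """Full-length constrained-value vector for a rigid interface motion.

    With ``literal_interface`` the printed vertical-only condition
    ``u = (0, u_solid_y)`` is imposed instead of the full no-slip coupling.
    """
    n_sys = len(dset.free)
    vals = np.zeros(n_sys)
    r = dset.interface_coords - center
    if literal_interface:
        vals[dset.interface_x] = 0.0
        vals[dset.interface_y] = velocity[1]
    else:
        vals[dset.interface_x] = velocity[0] - omega * r[:, 1]
        vals[dset.interface_y] = velocity[1] + omega * r[:, 0]
    return vals


# ---------------------------------------------------------------------------
# interface traction

def interface_force_and_torque(
    K_full: sparse.spmatrix,
    rhs_full: np.ndarray,
    solution: np.ndarray,
    dset: DirichletSet,
    center: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Hydrodynamic force (N/m) and torque (N) on the pellet.

    Uses the variationally consistent reaction: the assembled momentum
    residual at constrained interface dofs equals the traction integral
    weighted by the interface shape functions; the force on the solid is
    its negative.
    """
    res = K_full @ solution - rhs_full
    fx = -res[dset.interface_x]
    fy = -res[dset.interface_y]
    r = dset.interface_coords - center
    force = np.array([fx.sum(), fy.sum()])
    torque = float(np.sum(r[:, 0] * fy - r[:, 1] * fx))
    return force, torque


def edge_tractions(
    space: P2Space,
    points: np.ndarray,
    solution: np.ndarray,
    mu: float,
) -> np.ndarray:
    """Pointwise traction n . sigma on each interface edge (midpoint value).

    sigma = -p I + mu (grad u + grad u^T) - (2/3) mu (div u) I, evaluated in
    the cell adjacent to each interface edge.  Less accurate than the
    consistent reaction; provided for per-edge diagnostics.
    """
    mesh = space.mesh
    n2 = space.n_p2
    ux = solution[:n2]
    uy = solution[n2: 2 * n2]
    p = solution[2 * n2:]
    # locate the owning triangle of each interface edge
    edge_owner = {}
    for e_idx, t in enumerate(mesh.triangles):
        for i in range(3):
            key = (min(t[i], t[(i + 1) % 3]), max(t[i], t[(i + 1) % 3]))
            edge_owner[key] = e_idx
    invJT, _ = _geometry(points, mesh.triangles)
    out = np.zeros((len(mesh.interface_edges), 2))
    centre_ref = np.array([[1 / 3, 1 / 3]])
    _, dN = _p2_basis(centre_ref)
    N1c = np.array([1 / 3, 1 / 3, 1 / 3])
    for k, (i, j) in enumerate(mesh.interface_edges):
        e_idx = edge_owner[(min(i, j), max(i, j))]
        dofs = space.tri_dofs[e_idx]
        g = invJT[e_idx] @ dN[0].T  # (2, 6) physical gradients at centroid
        gradu = np.array([g @ ux[dofs], g @ uy[dofs]]).T  # du_i/dx_k -> [i,k]? rows
        # gradu[i, k] = du_k/dx_i as built; fix orientation:
        gradu = np.array([[g[0] @ ux[dofs], g[1] @ ux[dofs]],
                          [g[0] @ uy[dofs], g[1] @ uy[dofs]]])
        div = gradu[0, 0] + gradu[1, 1]
        pval = float(N1c @ p[mesh.triangles[e_idx]])
        sig = -pval * np.eye(2) + mu * (gradu + gradu.T) - (2.0 / 3.0) * mu * div * np.eye(2)
        tvec = points[j] - points[i]
        nvec = np.array([tvec[1], -tvec[0]])
        nvec /= np.linalg.norm(nvec)
        # orient outward from the fluid (into the solid)
        mid = 0.5 * (points[i] + points[j])
        to_centre = points[mesh.interface_nodes].mean(axis=0) - mid
        if nvec @ to_centre < 0:
            nvec = -nvec
        out[k] = sig @ nvec
    return out
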