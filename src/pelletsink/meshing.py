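"""Unstructured triangular meshing of the water column around the pellet.

The fluid region (rectangle minus ellipse) is meshed by Delaunay
triangulation of a graded point cloud: an area-matched polygon on the
ellipse, geometrically coarsening rings around it, a uniform background
grid, and the rectangle boundary.  Triangles falling inside the pellet are
removed, leaving a conforming mesh whose interface edges form a closed
polyline.

Mesh motion between remeshes uses harmonic (Laplace) smoothing: three unit
displacement modes (x-translation, y-translation, linearised rotation) are
precomputed per mesh, and interface nodes are subsequently snapped onto the
exact rigid-body map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu
from scipy.spatial import Delaunay

from .bodies import DomainSpec, PelletGeometry


def ellipse_polygon(a: float, b: float, n: int) -> np.ndarray:
    """Body-frame polygon on the ellipse, n vertices ~equally spaced by
    arc length, scaled so the polygon area equals pi*a*b exactly."""
    tt = np.linspace(0.0, 2.0 * np.pi, 4096, endpoint=False)
    dx, dy = -b * np.sin(tt), a * np.cos(tt)
    ds = np.hypot(dx, dy)
    s = np.concatenate([[0.0], np.cumsum(ds)]) * (2.0 * np.pi / len(tt))
    total = s[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    t_par = np.interp(targets, s, np.concatenate([tt, [2.0 * np.pi]]))
    pts = np.column_stack([b * np.cos(t_par), a * np.sin(t_par)])
    # area of inscribed polygon < pi*a*b; scale out to match exactly
    area = 0.5 * np.abs(
        np.sum(pts[:, 0] * np.roll(pts[:, 1], -1) - np.roll(pts[:, 0], -1) * pts[:, 1])
    )
    pts *= np.sqrt(np.pi * a * b / area)
    return pts


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def triangle_quality(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Normalised quality 4*sqrt(3)*area / sum(edge^2); 1 for equilateral."""
    p = points[tris]
    e0 = p[:, 1] - p[:, 0]
    e1 = p[:, 2] - p[:, 1]
    e2 = p[:, 0] - p[:, 2]
    area = 0.5 * np.abs(e0[:, 0] * (-e2[:, 1]) - e0[:, 1] * (-e2[:, 0]))
    denom = (e0**2).sum(1) + (e1**2).sum(1) + (e2**2).sum(1)
    return 4.0 * np.sqrt(3.0) * area / denom


def signed_areas(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = points[tris]
    return 0.5 * (
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )


@dataclass
class Mesh2D:
    """Conforming triangular mesh of the fluid region (coordinates in m)."""

    points: np.ndarray           # (n, 2)
    triangles: np.ndarray        # (m, 3), CCW
    interface_nodes: np.ndarray  # ordered, closed polyline (first follows last)
    wall_nodes: np.ndarray       # x = 0 or x = W, including corners
    top_nodes: np.ndarray        # y = H, excluding corners
    bottom_nodes: np.ndarray     # y = 0, excluding corners
    h_min: float
    h_far: float
    center: np.ndarray           # pellet centre when the mesh was built
    theta: float                 # pellet orientation when built
    body_frame_interface: np.ndarray = field(default=None)  # polygon, body frame
    _smooth: dict = field(default=None, repr=False)

    @property
    def cell_count(self) -> int:
        return len(self.triangles)

    @property
    def interface_edges(self) -> np.ndarray:
        idx = self.interface_nodes
        return np.column_stack([idx, np.roll(idx, -1)])

    def min_quality(self) -> float:
        return float(triangle_quality(self.points, self.triangles).min())

    # -- harmonic smoothing modes -------------------------------------------
    def build_smoothing(self) -> None:
        """Precompute unit displacement fields for mesh motion.

        Solves the P1 Laplace problem with unit Dirichlet data on the
        interface and zero on the outer boundary; one scalar field for
        translations and a vector field for unit rotation about the build
        centre.
        """
        n = len(self.points)
        K = _p1_stiffness(self.points, self.triangles)
        boundary = np.zeros(n, dtype=bool)
        for nodes in (self.wall_nodes, self.top_nodes, self.bottom_nodes,
                      self.interface_nodes):
            boundary[nodes] = True
        free = ~boundary
        Kff = K[free][:, free].tocsc()
        lu = splu(Kff)

        def harmonic(bvals: np.ndarray) -> np.ndarray:
            out = bvals.copy()
            rhs = -K[free][:, boundary] @ bvals[boundary]
            out[free] = lu.solve(rhs)
            return out

        unit = np.zeros(n)
        unit[self.interface_nodes] = 1.0
        phi_t = harmonic(unit)
        r = self.points - self.center
        rx = np.zeros(n)
        ry = np.zeros(n)
        rx[self.interface_nodes] = -r[self.interface_nodes, 1]
        ry[self.interface_nodes] = r[self.interface_nodes, 0]
        self._smooth = {
            "phi_t": phi_t,
            "phi_rx": harmonic(rx),
            "phi_ry": harmonic(ry),
        }

    def displaced_points(self, d_center: np.ndarray, d_theta: float,
                         new_center: np.ndarray, new_theta: float) -> np.ndarray:
        """Node positions after a cumulative rigid increment since build.

        Interior nodes follow the harmonic smoothing fields; interface nodes
        are placed by the exact rigid map.
        """
        if self._smooth is None:
            self.build_smoothing()
        s = self._smooth
        disp = np.empty_like(self.points)
        disp[:, 0] = s["phi_t"] * d_center[0] + s["phi_rx"] * d_theta
        disp[:, 1] = s["phi_t"] * d_center[1] + s["phi_ry"] * d_theta
        pts = self.points + disp
        # exact rigid placement of the interface
        pts[self.interface_nodes] = (
            new_center + self.body_frame_interface @ _rot(new_theta).T
        )
        return pts


def _p1_stiffness(points: np.ndarray, tris: np.ndarray) -> sparse.csr_matrix:
    """Standard P1 Laplace stiffness matrix (used only for smoothing)."""
    p = points[tris]
    x, y = p[..., 0], p[..., 1]
    bmat = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    cmat = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area = np.abs(
        0.5 * ((x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0]) - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0]))
    )
    ke = (
        bmat[:, :, None] * bmat[:, None, :] + cmat[:, :, None] * cmat[:, None, :]
    ) / (4.0 * area)[:, None, None]
    rows = np.repeat(tris, 3, axis=1).reshape(-1)
    cols = np.tile(tris, (1, 3)).reshape(-1)
    return sparse.coo_matrix(
        (ke.reshape(-1), (rows, cols)), shape=(len(points), len(points))
    ).tocsr()


def _points_in_convex_polygon(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Vectorised inside test for a CCW convex polygon."""
    a = poly
    b = np.roll(poly, -1, axis=0)
    edge = b - a
    rel = pts[:, None, :] - a[None, :, :]
    cross = edge[None, :, 0] * rel[:, :, 1] - edge[None, :, 1] * rel[:, :, 0]
    return (cross > 0).all(axis=1)


def generate_mesh(
    geometry: PelletGeometry,
    domain: DomainSpec,
    center: tuple[float, float] | None = None,
    theta: float = 0.0,
    scale: float = 1.0,
    seed: int = 0,
) -> Mesh2D:
    """Mesh the fluid region around the pellet at the given pose.

    ``scale`` multiplies the resolution everywhere (2.0 roughly quadruples
    the cell count).  The default targets ~1900-2000 cells for the base
    20 x 100 um pellet in the 2000 x 6000 um column.
    """
    a, b = geometry.a, geometry.b
    if center is None:
        center = domain.release_point()
    center = np.asarray(center, dtype=float)
    W, H = domain.width, domain.height
    margin = max(a, b)
    if not (margin < center[0] < W - margin and margin < center[1] < H - margin):
        raise ValueError(
            f"pellet at {center} with semi-axes ({a:g}, {b:g}) does not fit "
            f"inside the {W:g} x {H:g} m domain"
        )

    # resolution parameters (metres); defaults give ~1950 cells for the
    # base 20 x 100 um pellet, matching the reference discretisation
    h_min = 0.275 * a / scale         # interface edge target
    h_far = 1.3e-4 / scale            # background spacing
    perim = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
    n_int = max(40, int(round(perim / h_min)))
    poly_body = ellipse_polygon(a, b, n_int)
    R = _rot(theta)
    poly = center + poly_body @ R.T

    pts_list = [poly]
    # graded rings around the ellipse
    d = 0.9 * h_min
    growth = 1.55
    d_max = 3.0 * b
    step = d
    while d < d_max:
        ring_perim = np.pi * (
            3 * ((a + d) + (b + d))
            - np.sqrt((3 * (a + d) + (b + d)) * ((a + d) + 3 * (b + d)))
        )
        spacing = min(h_far, max(h_min, 0.62 * d))
        n_ring = max(12, int(round(ring_perim / spacing)))
        tt = np.linspace(0, 2 * np.pi, n_ring, endpoint=False) + 0.5 * (d / d_max)
        ring = np.column_stack([(b + d) * np.cos(tt), (a + d) * np.sin(tt)])
        pts_list.append(center + ring @ R.T)
        step *= growth
        d += step

    # background grid with deterministic jitter
    rng = np.random.default_rng(seed + 7919)
    nx = max(3, int(round(W / h_far)))
    ny = max(3, int(round(H / h_far)))
    gx = np.linspace(0, W, nx + 1)[1:-1]
    gy = np.linspace(0, H, ny + 1)[1:-1]
    GX, GY = np.meshgrid(gx, gy)
    grid = np.column_stack([GX.ravel(), GY.ravel()])
    grid += rng.uniform(-0.22, 0.22, grid.shape) * h_far
    # drop background points inside the refined zone or hugging the walls
    body_rel = (grid - center) @ R
    inner = (
        (body_rel[:, 0] / (b + d_max + 0.7 * h_far)) ** 2
        + (body_rel[:, 1] / (a + d_max + 0.7 * h_far)) ** 2
    ) < 1.0
    near_wall = (
        (grid[:, 0] < 0.45 * h_far)
        | (grid[:, 0] > W - 0.45 * h_far)
        | (grid[:, 1] < 0.45 * h_far)
        | (grid[:, 1] > H - 0.45 * h_far)
    )
    pts_list.append(grid[~inner & ~near_wall])

    # rectangle boundary, corners included
    bx = np.linspace(0, W, nx + 1)
    by = np.linspace(0, H, ny + 1)
    south = np.column_stack([bx, np.zeros_like(bx)])
    north = np.column_stack([bx, np.full_like(bx, H)])
    west = np.column_stack([np.zeros(ny - 1), by[1:-1]])
    east = np.column_stack([np.full(ny - 1, W), by[1:-1]])
    pts_list.extend([south, north, west, east])

    # clip ring points leaking out of the domain (pellet near a boundary)
    allpts = []
    for arr in pts_list:
        keep = (
            (arr[:, 0] >= -1e-12) & (arr[:, 0] <= W + 1e-12)
            & (arr[:, 1] >= -1e-12) & (arr[:, 1] <= H + 1e-12)
        )
        allpts.append(arr[keep])
    points = np.vstack(allpts)

    tri = Delaunay(points)
    tris = tri.simplices
    # CCW orientation
    sa = signed_areas(points, tris)
    flip = sa < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    # remove triangles inside the pellet and degenerate slivers
    centroids = points[tris].mean(axis=1)
    inside = _points_in_convex_polygon(centroids, poly)
    good = (~inside) & (np.abs(sa) > 1e-6 * h_min * h_min)
    tris = tris[good]

    interface_nodes = np.arange(n_int)
    mesh = Mesh2D(
        points=points,
        triangles=tris,
        interface_nodes=interface_nodes,
        wall_nodes=np.array([], dtype=int),
        top_nodes=np.array([], dtype=int),
        bottom_nodes=np.array([], dtype=int),
        h_min=h_min,
        h_far=h_far,
        center=center,
        theta=theta,
        body_frame_interface=poly_body,
    )
    tol = 1e-9
    on_w = (np.abs(points[:, 0]) < tol) | (np.abs(points[:, 0] - W) < tol)
    on_b = np.abs(points[:, 1]) < tol
    on_t = np.abs(points[:, 1] - H) < tol
    mesh.wall_nodes = np.nonzero(on_w)[0]
    mesh.bottom_nodes = np.nonzero(on_b & ~on_w)[0]
    mesh.top_nodes = np.nonzero(on_t & ~on_w)[0]

    _check_interface_closed(mesh)
    return mesh


def _check_interface_closed(mesh: Mesh2D) -> None:
    """Every consecutive interface pair must be an edge of exactly one cell."""
    edges = {}
    for t in mesh.triangles:
        for i in range(3):
            e = (min(t[i], t[(i + 1) % 3]), max(t[i], t[(i + 1) % 3]))
            edges[e] = edges.get(e, 0) + 1
    for i, j in mesh.interface_edges:
        e = (min(i, j), max(i, j))
        if edges.get(e, 0) != 1:
            raise RuntimeError(
                "mesh interface polyline is not resolved by the triangulation; "
                "increase resolution (scale) or interface point count"
            )


def fluid_area_error(mesh: Mesh2D, geometry: PelletGeometry, domain: DomainSpec) -> float:
    """Relative error of summed triangle areas vs rectangle minus ellipse."""
    mesh_area = np.abs(signed_areas(mesh.points, mesh.triangles)).sum()
    exact = domain.width * domain.height - geometry.area
    return abs(mesh_area - exact) / exact


def move_mesh(
    mesh: Mesh2D,
    d_center: np.ndarray,
    d_theta: float,
    new_center: np.ndarray,
    new_theta: float,
    quality_threshold: float = 0.25,
) -> tuple[np.ndarray, bool]:
    """New node positions after a cumulative rigid increment since build.

    Returns ``(points, needs_remesh)``; remesh is requested when the
    smoothed mesh quality falls below the threshold or an element inverts.
    """
    pts = mesh.displaced_points(np.asarray(d_center, float), d_theta,
                                np.asarray(new_center, float), new_theta)
    sa = signed_areas(pts, mesh.triangles)
    if (sa <= 0).any():
        return pts, True
    q = triangle_quality(pts, mesh.triangles)
    return pts, bool(q.min() < quality_threshold)
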