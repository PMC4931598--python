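"""2D finite-element model of the DBS-induced electric field in the NAc shell.

Two problems are solved on a triangulated cross-section of the target region
(an annular domain between the digitized outer boundary and the electrode
contour):

* the elliptic potential problem -div(sigma grad V) = q with Dirichlet
  conditions V = 5.25 V on the electrode contour and V = 0 on the outer
  boundary, with E = -grad V;
* a scalar 2D reduction of the electromagnetic curl-curl equation for the
  out-of-plane field component,
  (eps_r / c^2) d2u/dt2 + mu0 sigma du/dt = div(mu_r^-1 grad u),
  time-stepped with an implicit Newmark scheme (or an explicit central
  difference with a CFL check).

Tissue parameters default to the gray-matter values at 130 Hz used to
parameterize the model; the permittivity/permeability entries are used
numerically as printed even though their unit labels are inconsistent for
relative quantities, which makes the 130-Hz drive deeply quasi-static.
Geometry coordinates are millimetres; fields are reported in V and V/m.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import shapely
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import spsolve, splu
from shapely.geometry import Polygon

from .errors import ConfigurationError, GeometryError, ParameterError, SolverError

MM_TO_M = 1e-3


@dataclass
class TissueParameters:
    """Electromagnetic tissue parameters (gray matter at 130 Hz).

    ``eps_r`` and ``mu_r`` are taken verbatim from the parameter source and
    used as dimensionless relative values.
    """

    sigma: float = 9.15e-2  # conductivity, S/m
    eps_r: float = 2.46e6  # relative permittivity (value as printed)
    mu_r: float = 9.3e-10  # relative permeability (value as printed)
    mu0: float = 4e-7 * np.pi  # vacuum permeability, H/m
    c: float = 299_792_458.0  # speed of light, m/s

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.eps_r <= 0 or self.mu_r <= 0:
            raise ParameterError("sigma, eps_r and mu_r must be positive")


#: gray-matter parameter set at the 130 Hz stimulation frequency
GRAY_MATTER_130HZ = TissueParameters()


@dataclass
class Geometry2D:
    """Region outline and electrode contour in one atlas plane (mm)."""

    outer: np.ndarray  # (n, 2) closed polygon (last vertex != first)
    electrode: np.ndarray  # (m, 2) contour strictly inside outer
    plane: str = "coronal_AP+1.2"

    def __post_init__(self) -> None:
        self.outer = np.asarray(self.outer, dtype=float)
        self.electrode = np.asarray(self.electrode, dtype=float)
        for name, poly in (("outer", self.outer), ("electrode", self.electrode)):
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise GeometryError(f"{name} contour must be an (n>=3, 2) vertex array")
        p_out = Polygon(self.outer)
        p_in = Polygon(self.electrode)
        if not p_out.is_valid or not p_in.is_valid:
            raise GeometryError("contours must be simple (non-self-intersecting) polygons")
        if not p_in.within(p_out) or p_in.boundary.intersects(p_out.boundary):
            raise GeometryError("electrode contour must lie strictly inside the outer boundary")

    def region(self) -> Polygon:
        return Polygon(self.outer, [self.electrode])


@dataclass
class Mesh:
    """Conforming triangulation of the annular region between the contours."""

    nodes: np.ndarray  # (N, 2) mm
    triangles: np.ndarray  # (M, 3) node indices, CCW
    electrode_nodes: np.ndarray  # indices on the electrode contour
    outer_nodes: np.ndarray  # indices on the outer boundary
    h_max: float = 0.0

    @property
    def boundary_nodes(self) -> np.ndarray:
        return np.concatenate([self.electrode_nodes, self.outer_nodes])

    def areas(self) -> np.ndarray:
        """Element areas in mm^2."""
        p = self.nodes[self.triangles]
        u, v = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]
        return 0.5 * np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])

    def min_angle_deg(self) -> float:
        p = self.nodes[self.triangles]
        angles = []
        for i in range(3):
            a = p[:, (i + 1) % 3] - p[:, i]
            b = p[:, (i + 2) % 3] - p[:, i]
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        return float(np.min(angles))


@dataclass
class FieldSolution:
    """Nodal potential and element-wise field of the elliptic problem."""

    mesh: Mesh
    V: np.ndarray  # volts per node
    E: np.ndarray  # (M, 2) V/m per element, = -grad V
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry helpers and packaged outline
# ---------------------------------------------------------------------------


def circle_polygon(center: Sequence[float], radius: float, n: int = 64) -> np.ndarray:
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )


def annulus_geometry(r_in: float, r_out: float, h: float, center=(0.0, 0.0)) -> Geometry2D:
    """Concentric-circle geometry with vertex spacing tied to the mesh size."""
    n_in = max(16, int(np.ceil(2 * np.pi * r_in / h)))
    n_out = max(32, int(np.ceil(2 * np.pi * r_out / h)))
    return Geometry2D(
        outer=circle_polygon(center, r_out, n_out),
        electrode=circle_polygon(center, r_in, n_in),
        plane="analytic_annulus",
    )


def electrode_contour(center: Sequence[float], diameter_mm: float = 0.25, n: int = 24) -> np.ndarray:
    """Default electrode cross-section: 250 um diameter circle at the site."""
    return circle_polygon(center, diameter_mm / 2.0, n)


def save_geometry(geometry: Geometry2D, path) -> None:
    payload = {
        "units": "mm",
        "plane": geometry.plane,
        "outer": geometry.outer.tolist(),
        "electrode": geometry.electrode.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_geometry(path_or_file) -> Geometry2D:
    if hasattr(path_or_file, "read"):
        payload = json.load(path_or_file)
    else:
        with open(path_or_file) as fh:
            payload = json.load(fh)
    return Geometry2D(
        outer=np.asarray(payload["outer"], dtype=float),
        electrode=np.asarray(payload["electrode"], dtype=float),
        plane=payload.get("plane", "unknown"),
    )


def nacs_coronal_geometry() -> Geometry2D:
    """Packaged approximate NAc-shell outline (synthetic stand-in).

    A smooth crescent-like outline on the scale of the rat NAc shell in the
    coronal plane ~1.2 mm anterior to bregma, with the default 250-um
    electrode contour at the stimulation site.  It is a hand-constructed
    approximation for simulation and testing, not digitized atlas data.
    """
    with resources.files("adedbs.data").joinpath("nacs_coronal_synthetic.json").open() as fh:
        return load_geometry(fh)


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------


def _resample_closed(poly: np.ndarray, h: float) -> np.ndarray:
    """Points along a closed polygon with spacing <= h (original vertices kept)."""
    pts = []
    n = poly.shape[0]
    for i in range(n):
        a, b = poly[i], poly[(i + 1) % n]
        seg = np.linalg.norm(b - a)
        k = max(1, int(np.ceil(seg / h)))
        for j in range(k):
            pts.append(a + (b - a) * (j / k))
    return np.asarray(pts)


def _hex_lattice(bounds, h: float) -> np.ndarray:
    x0, y0, x1, y1 = bounds
    dy = h * np.sqrt(3) / 2
    rows = []
    y = y0
    row = 0
    while y <= y1:
        xs = np.arange(x0 + (h / 2 if row % 2 else 0.0), x1 + h / 2, h)
        rows.append(np.column_stack([xs, np.full(xs.size, y)]))
        y += dy
        row += 1
    return np.vstack(rows) if rows else np.empty((0, 2))


def _offset_ring(loop: np.ndarray, region: Polygon, h: float) -> np.ndarray:
    """Movable point ring just inside a boundary loop that is sampled finer
    than the interior lattice, so element sizes can grade smoothly."""
    seg = np.linalg.norm(np.roll(loop, -1, axis=0) - loop, axis=1)
    s = float(np.median(seg))
    if s >= 0.8 * h:
        return np.empty((0, 2))
    tang = np.roll(loop, -1, axis=0) - np.roll(loop, 1, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    for sign in (1.0, -1.0):
        cand = loop + sign * s * normal
        inside = shapely.contains_xy(region, cand[:, 0], cand[:, 1])
        if inside.mean() > 0.5:
            cand = cand[inside]
            dist = shapely.distance(shapely.points(cand), region.boundary)
            return cand[dist >= 0.45 * s]
    return np.empty((0, 2))


def _kept_triangles(points: np.ndarray, region: Polygon) -> np.ndarray:
    from scipy.spatial import Delaunay

    tri = Delaunay(points)
    simp = tri.simplices
    cent = points[simp].mean(axis=1)
    inside = shapely.contains_xy(region, cent[:, 0], cent[:, 1])
    p = points[simp]
    u, v = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]
    area = 0.5 * (u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
    keep = inside & (np.abs(area) > 1e-12)
    simp = simp[keep]
    # enforce CCW orientation
    flip = area[keep] < 0
    simp[flip] = simp[flip][:, ::-1]
    return simp


def build_mesh(geometry: Geometry2D, h_max: float, n_smooth: int = 4) -> Mesh:
    """Triangulate the annular region between the contours.

    Boundary contours are resampled at spacing <= ``h_max``; the interior is
    seeded with a hexagonal lattice kept clear of the boundaries, Delaunay-
    triangulated, restricted to the region, and Laplacian-smoothed (interior
    nodes only) for element quality.
    """
    if h_max <= 0:
        raise ParameterError("h_max must be positive")
    region = geometry.region()
    b_elec = _resample_closed(geometry.electrode, h_max)
    b_outer = _resample_closed(geometry.outer, h_max)
    rings = []
    clearances = []  # per-loop lattice keep-out distance
    for b in (b_elec, b_outer):
        ring = _offset_ring(b, region, h_max)
        seg = float(np.median(np.linalg.norm(np.roll(b, -1, axis=0) - b, axis=1)))
        if ring.size:
            rings.append(ring)
            clearances.append(seg + 0.5 * h_max)  # keep the lattice beyond the ring
        else:
            clearances.append(0.55 * h_max)
    lattice = _hex_lattice(region.bounds, h_max)
    if lattice.size:
        inside = shapely.contains_xy(region, lattice[:, 0], lattice[:, 1])
        lattice = lattice[inside]
    if lattice.size:
        pts = shapely.points(lattice)
        keep = np.ones(lattice.shape[0], dtype=bool)
        for loop, clr in zip((b_elec, b_outer), clearances):
            ring_line = shapely.linestrings(np.vstack([loop, loop[:1]]))
            keep &= shapely.distance(pts, ring_line) >= clr
        lattice = lattice[keep]
    n_e, n_o = b_elec.shape[0], b_outer.shape[0]
    interior = [lattice] + rings if lattice.size else rings
    interior_pts = np.vstack(interior) if interior else np.empty((0, 2))
    points = np.vstack([b_elec, b_outer, interior_pts])
    n_bound = n_e + n_o
    simp = _kept_triangles(points, region)
    for _ in range(n_smooth):
        # Laplacian smoothing of interior nodes over the current triangulation
        rows = np.concatenate([simp[:, [0, 1, 2]].ravel()])
        cols = np.concatenate([simp[:, [1, 2, 0]].ravel()])
        adj = coo_matrix(
            (
                np.ones(2 * rows.size),
                (np.concatenate([rows, cols]), np.concatenate([cols, rows])),
            ),
            shape=(points.shape[0],) * 2,
        ).tocsr()
        adj.data[:] = 1.0
        deg = np.asarray(adj.sum(axis=1)).ravel()
        used = deg > 0
        new = points.copy()
        num = adj @ points
        interior = used & (np.arange(points.shape[0]) >= n_bound)
        new[interior] = num[interior] / deg[interior, None]
        points = new
        simp = _kept_triangles(points, region)
    used = np.zeros(points.shape[0], dtype=bool)
    used[simp.ravel()] = True
    used[:n_bound] = True
    remap = -np.ones(points.shape[0], dtype=int)
    remap[used] = np.arange(used.sum())
    mesh = Mesh(
        nodes=points[used],
        triangles=remap[simp],
        electrode_nodes=remap[np.arange(n_e)],
        outer_nodes=remap[np.arange(n_e, n_bound)],
        h_max=h_max,
    )
    return mesh


# ---------------------------------------------------------------------------
# P1 finite-element assembly
# ---------------------------------------------------------------------------


def _tri_gradients(nodes: np.ndarray, tris: np.ndarray):
    """Barycentric gradient coefficients and areas (length unit of ``nodes``)."""
    p = nodes[tris]
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area = 0.5 * (x[:, 0] * b[:, 0] + x[:, 1] * b[:, 1] + x[:, 2] * b[:, 2])
    return b, c, area


def _stiffness(nodes: np.ndarray, tris: np.ndarray, coeff: float) -> csr_matrix:
    """Assemble coeff * grad-grad; scale-invariant in 2D."""
    b, c, area = _tri_gradients(nodes, tris)
    n = nodes.shape[0]
    ke = coeff * (b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]) / (
        4.0 * area[:, None, None]
    )
    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    return coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def _mass(nodes: np.ndarray, tris: np.ndarray, coeff: float = 1.0, lumped: bool = False):
    """Consistent (or lumped) P1 mass matrix; area unit follows ``nodes``."""
    _, _, area = _tri_gradients(nodes, tris)
    n = nodes.shape[0]
    if lumped:
        diag = np.zeros(n)
        np.add.at(diag, tris.ravel(), np.repeat(area / 3.0, 3) * coeff)
        return diag
    me = (np.full((3, 3), 1.0) + np.eye(3)) / 12.0
    ke = coeff * area[:, None, None] * me[None]
    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    return coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def solve_poisson(
    mesh: Mesh,
    tissue: TissueParameters = GRAY_MATTER_130HZ,
    bc_electrode: float = 5.25,
    bc_outer: float = 0.0,
    q: float = 0.0,
) -> FieldSolution:
    """P1 FEM solution of -div(sigma grad V) = q with Dirichlet boundaries.

    ``q`` is a constant volumetric current source (A/m^3), zero by default:
    the electrode enters purely through its boundary potential.  The field
    ``E = -grad V`` is returned per element in V/m.
    """
    n = mesh.nodes.shape[0]
    fixed = np.zeros(n, dtype=bool)
    fixed[mesh.electrode_nodes] = True
    fixed[mesh.outer_nodes] = True
    if not fixed.any():
        raise SolverError("no Dirichlet nodes: the system is singular")
    K = _stiffness(mesh.nodes, mesh.triangles, tissue.sigma)
    vals = np.zeros(n)
    vals[mesh.electrode_nodes] = bc_electrode
    vals[mesh.outer_nodes] = bc_outer
    f = np.zeros(n)
    if q != 0.0:
        f = q * _mass(mesh.nodes, mesh.triangles, coeff=MM_TO_M**2, lumped=True)
    free = ~fixed
    rhs = f[free] - K[free][:, fixed] @ vals[fixed]
    V = vals.copy()
    V[free] = spsolve(K[free][:, free].tocsc(), rhs)
    b, c, area = _tri_gradients(mesh.nodes, mesh.triangles)
    vt = V[mesh.triangles]
    gx = np.einsum("ij,ij->i", vt, b) / (2.0 * area)  # V/mm
    gy = np.einsum("ij,ij->i", vt, c) / (2.0 * area)
    E = -np.column_stack([gx, gy]) / MM_TO_M  # V/m
    return FieldSolution(
        mesh=mesh,
        V=V,
        E=E,
        metadata={
            "bc_electrode_V": bc_electrode,
            "bc_outer_V": bc_outer,
            "q": q,
            "sigma_S_per_m": tissue.sigma,
        },
    )


def nodal_l2_error(mesh: Mesh, V: np.ndarray, exact: Callable[[np.ndarray], np.ndarray]) -> float:
    """Relative L2 error of a nodal field against a callable exact solution.

    Integrals use the lumped P1 mass matrix as quadrature weights.
    """
    w = _mass(mesh.nodes, mesh.triangles, lumped=True)
    v_ex = exact(mesh.nodes)
    err = V - v_ex
    return float(np.sqrt((w * err**2).sum() / (w * v_ex**2).sum()))


# ---------------------------------------------------------------------------
# field extent
# ---------------------------------------------------------------------------


def _boundary_loops(mesh: Mesh, selected: np.ndarray) -> list[np.ndarray]:
    """Closed node-coordinate loops bounding a set of selected elements."""
    edges: dict[tuple[int, int], int] = {}
    for t in mesh.triangles[selected]:
        for i in range(3):
            e = tuple(sorted((int(t[i]), int(t[(i + 1) % 3]))))
            edges[e] = edges.get(e, 0) + 1
    bnd = [e for e, cnt in edges.items() if cnt == 1]
    nbr: dict[int, list[int]] = {}
    for u, v in bnd:
        nbr.setdefault(u, []).append(v)
        nbr.setdefault(v, []).append(u)
    unused = set(map(tuple, bnd))
    loops = []
    while unused:
        u0, v = next(iter(unused))
        loop = [u0]
        prev, cur = u0, v
        unused.discard((u0, v))
        while cur != u0:
            loop.append(cur)
            nxt = [w for w in nbr[cur] if tuple(sorted((cur, w))) in unused]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            unused.discard(tuple(sorted((prev, cur))))
        loops.append(mesh.nodes[np.asarray(loop)])
    return loops


def field_extent(solution: FieldSolution, threshold: float):
    """Area (mm^2) where |E| >= threshold (V/m), and its bounding contours.

    The area is monotone non-increasing in the threshold by construction.
    """
    if threshold < 0:
        raise ParameterError("threshold must be non-negative")
    emag = np.linalg.norm(solution.E, axis=1)
    selected = emag >= threshold
    area = float(solution.mesh.areas()[selected].sum())
    contour = _boundary_loops(solution.mesh, selected) if selected.any() else []
    return area, contour


# ---------------------------------------------------------------------------
# time-dependent (hyperbolic) problem
# ---------------------------------------------------------------------------


def sinusoidal_drive(amplitude: float = 5.25, freq_hz: float = 130.0) -> Callable[[float], float]:
    """Electrode boundary drive a(t) = A sin(2 pi f t), with a ``period`` attribute."""

    def drive(t: float) -> float:
        return amplitude * np.sin(2 * np.pi * freq_hz * t)

    drive.period = 1.0 / freq_hz  # type: ignore[attr-defined]
    return drive


@dataclass
class WaveSolution:
    """Time-resolved out-of-plane field on the mesh."""

    mesh: Mesh
    times: np.ndarray
    u: np.ndarray  # (n_stored, N)
    udot: np.ndarray  # (n_stored, N)
    _A: csr_matrix | None = None
    _K: csr_matrix | None = None

    def energy(self) -> np.ndarray:
        """Discrete field energy 1/2 udot' A udot + 1/2 u' K u per stored step."""
        out = np.empty(self.times.size)
        for i in range(self.times.size):
            out[i] = 0.5 * self.udot[i] @ (self._A @ self.udot[i]) + 0.5 * self.u[i] @ (
                self._K @ self.u[i]
            )
        return out


def _estimate_omega_max(K: csr_matrix, m_lumped: np.ndarray, iters: int = 30) -> float:
    """Power iteration on M^-1 K for the largest generalized eigenvalue."""
    rng = np.random.default_rng(7)
    x = rng.standard_normal(m_lumped.size)
    lam = 0.0
    for _ in range(iters):
        y = (K @ x) / m_lumped
        lam = np.linalg.norm(y)
        if lam == 0:
            return 0.0
        x = y / lam
    return float(np.sqrt(lam))


def solve_wave(
    mesh: Mesh,
    tissue: TissueParameters = GRAY_MATTER_130HZ,
    drive: Callable[[float], float] | None = None,
    dt: float = 1e-5,
    t_end: float = 2e-2,
    scheme: str = "newmark",
    bc_outer: float = 0.0,
    beta: float = 0.25,
    gamma: float = 0.5,
    store_every: int = 1,
    lumped: bool = False,
) -> WaveSolution:
    """Damped scalar wave problem driven by a time-dependent electrode value.

    Discretizes (eps_r/c^2) M u'' + mu0 sigma M u' + (1/mu_r) K u = 0 with
    the drive imposed as a Dirichlet value on the electrode nodes and
    ``bc_outer`` on the outer boundary.  Default integrator is implicit
    Newmark (beta=1/4, gamma=1/2: unconditionally stable); ``scheme=
    "explicit"`` uses lumped-mass central differences and raises with a
    suggested step when the CFL limit is exceeded.
    """
    if drive is None:
        drive = sinusoidal_drive()
    if dt <= 0 or t_end <= dt:
        raise ParameterError("need 0 < dt < t_end")
    period = getattr(drive, "period", None)
    if period is not None and dt > period / 20:
        raise ConfigurationError(
            f"dt={dt:g} s does not resolve the drive; use dt <= {period / 20:g} s"
        )
    n = mesh.nodes.shape[0]
    K = _stiffness(mesh.nodes, mesh.triangles, 1.0 / tissue.mu_r)
    coeff_a = tissue.eps_r / tissue.c**2
    coeff_c = tissue.mu0 * tissue.sigma
    fixed = np.zeros(n, dtype=bool)
    fixed[mesh.electrode_nodes] = True
    fixed[mesh.outer_nodes] = True
    free = ~fixed

    def bc_vec(t: float) -> np.ndarray:
        g = np.zeros(n)
        g[mesh.electrode_nodes] = drive(t)
        g[mesh.outer_nodes] = bc_outer
        return g

    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    store_idx = np.arange(0, n_steps + 1, store_every)
    u = np.zeros(n)
    v = np.zeros(n)
    acc = np.zeros(n)
    u[fixed] = bc_vec(0.0)[fixed]
    U = np.zeros((store_idx.size, n))
    Vd = np.zeros((store_idx.size, n))
    U[0] = u
    si = 1

    if scheme == "newmark":
        if lumped:
            from scipy.sparse import diags

            M = diags(_mass(mesh.nodes, mesh.triangles, coeff=MM_TO_M**2, lumped=True)).tocsr()
        else:
            M = _mass(mesh.nodes, mesh.triangles, coeff=MM_TO_M**2)
        A = coeff_a * M
        C = coeff_c * M
        S = (A / (beta * dt**2) + C * (gamma / (beta * dt)) + K).tocsc()
        lu = splu(S[free][:, free].tocsc())
        S_fc = S[free][:, fixed]
        for step in range(1, n_steps + 1):
            t1 = times[step]
            g1 = bc_vec(t1)
            rhs_full = A @ (u / (beta * dt**2) + v / (beta * dt) + acc * (1 / (2 * beta) - 1)) + C @ (
                u * (gamma / (beta * dt))
                - v * (1 - gamma / beta)
                - acc * dt * (1 - gamma / (2 * beta))
            )
            u1 = g1.copy()
            u1[free] = lu.solve(rhs_full[free] - S_fc @ g1[fixed])
            acc1 = (u1 - u) / (beta * dt**2) - v / (beta * dt) - acc * (1 / (2 * beta) - 1)
            v1 = v + dt * ((1 - gamma) * acc + gamma * acc1)
            u, v, acc = u1, v1, acc1
            if step % store_every == 0:
                U[si], Vd[si] = u, v
                si += 1
        return WaveSolution(mesh, times[store_idx], U, Vd, _A=A.tocsr(), _K=K)

    if scheme == "explicit":
        mL = _mass(mesh.nodes, mesh.triangles, coeff=MM_TO_M**2, lumped=True)
        aL = coeff_a * mL
        cL = coeff_c * mL
        omega = _estimate_omega_max(K, aL)
        dt_crit = 2.0 / omega if omega > 0 else np.inf
        if dt > dt_crit:
            raise ConfigurationError(
                f"explicit scheme unstable at dt={dt:g} s; use dt <= {0.9 * dt_crit:g} s"
            )
        u_prev = u.copy()  # start from rest: u_{-1} = u_0
        lhs = aL / dt**2 + cL / (2 * dt)
        for step in range(1, n_steps + 1):
            g1 = bc_vec(times[step])
            rhs = (2 * aL / dt**2) * u - (aL / dt**2 - cL / (2 * dt)) * u_prev - K @ u
            u1 = rhs / lhs
            u1[fixed] = g1[fixed]
            u_prev, u = u, u1
            v = (u - u_prev) / dt
            if step % store_every == 0:
                U[si], Vd[si] = u, v
                si += 1
        from scipy.sparse import diags

        return WaveSolution(mesh, times[store_idx], U, Vd, _A=diags(aL).tocsr(), _K=K)

    raise ParameterError(f"unknown scheme {scheme!r}")
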