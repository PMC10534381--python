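"""Steady incompressible creeping-flow (Stokes) solver.

Taylor-Hood discretisation (quadratic velocity, linear pressure) of

    0 = -grad p + mu lap u,     div u = 0

with no-slip walls, plug velocity inlets and traction-free (0 Pa) outlets.
Assembly is in SI units (metres); the public sampling API takes points in
micrometres and returns velocities in m/s and pressures in Pa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import FieldSampler, P2Space, edge_quadrature_nodes
from .meshing import Mesh

__all__ = ["MediumProps", "FlowBC", "FlowField", "solve_stokes", "sample_flow", "SolverError"]

UM = 1e-6  # metres per micrometre

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class MediumProps:
    """Carrier fluid: a dilute aqueous DEP buffer by default.

    dynamic_viscosity in Pa s, density in kg/m3, electrical conductivity
    in S/m and relative permittivity (dimensionless).
    """

    dynamic_viscosity: float = 1.0e-3
    density: float = 1000.0
    electrical_conductivity: float = 55e-3
    relative_permittivity: float = 80.0

    def __post_init__(self) -> None:
        for name in (
            "dynamic_viscosity",
            "density",
            "electrical_conductivity",
            "relative_permittivity",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def permittivity(self) -> float:
        """Absolute permittivity, F/m."""
        return self.relative_permittivity * EPS0


@dataclass(frozen=True)
class FlowBC:
    """Inlet mean speeds (um/s); outlets fixed at 0 Pa; no-slip walls."""

    v_blood: float = 134.0
    v_buffer: float = 850.0
    outlet_pressure: float = 0.0
    profile: str = "plug"  # or "parabolic"

    def __post_init__(self) -> None:
        if self.v_blood < 0 or self.v_buffer < 0:
            raise ValueError("inlet speeds must be >= 0")
        if self.outlet_pressure != 0.0:
            raise ValueError("outlets are fixed at 0 Pa")
        if self.profile not in ("plug", "parabolic"):
            raise ValueError(f"unknown inlet profile {self.profile!r}")


@dataclass
class FlowField:
    """Discrete Stokes solution with a continuous evaluation contract."""

    mesh: Mesh
    space: P2Space
    ux: np.ndarray  # P2 dofs, m/s
    uy: np.ndarray
    p: np.ndarray   # P1 vertex values, Pa
    bc: FlowBC
    medium: MediumProps
    sampler: FieldSampler = field(default=None)

    def __post_init__(self) -> None:
        if self.sampler is None:
            self.sampler = FieldSampler(self.mesh)

    def velocity(self, pts_um: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Velocity (m/s) at points given in um."""
        u = np.column_stack([self.ux, self.uy])
        return self.sampler.eval_p2(self.space, u, pts_um, clamp=clamp)

    def pressure(self, pts_um: np.ndarray, clamp: bool = False) -> np.ndarray:
        return self.sampler.eval_p1(self.p, pts_um, clamp=clamp)

    def boundary_flux(self, tag: str) -> float:
        """Outward volume flux (m2/s per unit depth) through a tagged face."""
        return _boundary_flux(self, tag)

    def divergence_norm(self) -> float:
        """Area-weighted RMS of the element-wise divergence (1/s)."""
        gx = self.space.gradient_at_centroids(self.ux)[:, 0]
        gy = self.space.gradient_at_centroids(self.uy)[:, 1]
        div = gx + gy
        a = self.space.area
        return float(np.sqrt(np.sum(a * div**2) / np.sum(a)))


def _inlet_profile(space: P2Space, mesh: Mesh, tag: str, mean_speed: float,
                   inward: np.ndarray, profile: str) -> dict[int, np.ndarray]:
    """Dirichlet values on one inlet face.

    The plug profile is uniform at the stated mean with a fixed-width
    linear rolloff to zero at the wall corners (one tenth of the face
    width at each side, mesh-independent for grid convergence of the
    streamlines) and is rescaled so the discrete flux equals
    mean_speed * face width exactly.  The parabolic profile is the
    plane-Poiseuille shape with the same mean.
    """
    edges = mesh.edges_with_tag(tag)
    if len(edges) == 0:
        raise SolverError(f"no boundary edges tagged {tag}")
    verts = np.unique(edges)
    # order face nodes by arclength along the face
    pts = mesh.points[verts]
    t = pts[-1] - pts[0]
    # robust tangent: use PCA direction
    c = pts - pts.mean(axis=0)
    _, _, vh = np.linalg.svd(c, full_matrices=False)
    tdir = vh[0]
    s = c @ tdir
    smin, smax = s.min(), s.max()
    width = (smax - smin) * UM

    all_dofs = []
    for e in edges:
        for v in e:
            all_dofs.append(int(v))
        all_dofs.append(space.edge_dof(e[0], e[1]))
    all_dofs = np.unique(all_dofs)
    dof_pts = space.dof_coords[all_dofs] / UM  # back to um
    ds = (dof_pts - pts.mean(axis=0)) @ tdir
    xi = (ds - smin) / (smax - smin)  # 0..1 across the face

    if profile == "parabolic":
        shape = 6.0 * xi * (1.0 - xi)
    else:
        delta = 0.1  # rolloff width as a fraction of the face width
        shape = np.minimum(1.0, np.minimum(xi, 1.0 - xi) / delta)
        shape = np.clip(shape, 0.0, 1.0)

    # discrete flux of the interpolated shape across the face
    flux = _face_scalar_flux(space, mesh, edges, dict(zip(all_dofs, shape)))
    target = mean_speed * UM * width
    if flux <= 0:
        raise SolverError(f"degenerate inlet face {tag}")
    scale = target / flux
    return {int(d): sh * scale * inward for d, sh in zip(all_dofs, shape)}


def _face_scalar_flux(space, mesh, edges, nodal: dict[int, float]) -> float:
    """Integral of a scalar P2 boundary field over the given edges (SI)."""
    xq, wq = edge_quadrature_nodes(4)
    total = 0.0
    for e in edges:
        d0, d1 = int(e[0]), int(e[1])
        dm = space.edge_dof(d0, d1)
        p0 = mesh.points[d0] * UM
        p1 = mesh.points[d1] * UM
        L = np.hypot(*(p1 - p0))
        v0, v1, vm = nodal.get(d0, 0.0), nodal.get(d1, 0.0), nodal.get(dm, 0.0)
        # quadratic on the edge through endpoint/midpoint values
        phi = (
            v0 * (1 - xq) * (1 - 2 * xq)
            + v1 * xq * (2 * xq - 1)
            + vm * 4 * xq * (1 - xq)
        )
        total += L * np.sum(wq * phi)
    return float(total)


def _boundary_flux(flow: FlowField, tag: str) -> float:
    """Outward flux of u through a tagged face (m2/s per unit depth)."""
    mesh, space = flow.mesh, flow.space
    edges = mesh.edges_with_tag(tag)
    if len(edges) == 0:
        raise SolverError(f"unknown or empty boundary tag {tag!r}")
    xq, wq = edge_quadrature_nodes(4)
    # outward normal: boundary edges come from CCW triangles; the domain is
    # on the left of (v0 -> v1) for edges stored as they appear in the
    # triangle, but _boundary_edges_of sorted them.  Use geometry: normal
    # points away from the adjacent triangle centroid.
    total = 0.0
    tri_lookup = _adjacent_triangle_map(mesh)
    for e in edges:
        d0, d1 = int(e[0]), int(e[1])
        dm = space.edge_dof(d0, d1)
        p0 = mesh.points[d0] * UM
        p1 = mesh.points[d1] * UM
        tvec = p1 - p0
        L = np.hypot(*tvec)
        n = np.array([tvec[1], -tvec[0]]) / L
        tri = tri_lookup[(min(d0, d1), max(d0, d1))]
        cent = mesh.points[mesh.triangles[tri]].mean(axis=0) * UM
        if np.dot(cent - 0.5 * (p0 + p1), n) > 0:
            n = -n
        for comp, nc in ((flow.ux, n[0]), (flow.uy, n[1])):
            if nc == 0.0:
                continue
            v0, v1, vm = comp[d0], comp[d1], comp[dm]
            phi = (
                v0 * (1 - xq) * (1 - 2 * xq)
                + v1 * xq * (2 * xq - 1)
                + vm * 4 * xq * (1 - xq)
            )
            total += nc * L * np.sum(wq * phi)
    return float(total)


def _adjacent_triangle_map(mesh: Mesh) -> dict:
    out = {}
    tris = mesh.triangles
    for k, tri in enumerate(tris):
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            key = (min(int(a), int(b)), max(int(a), int(b)))
            out[key] = k
    return out


def solve_stokes(mesh: Mesh, bc: FlowBC, medium: MediumProps) -> FlowField:
    """Solve the creeping-flow problem on a tagged mesh.

    Velocity Dirichlet data: zero on walls and electrode faces, inlet
    profiles on the two inlets; outlets are traction-free which pins the
    pressure to 0 Pa there.
    """
    outlet_tags = [t for t in mesh.tag_names if t.startswith("outlet")]
    if not outlet_tags:
        raise SolverError("mesh has no outlet-tagged boundary (singular system)")
    space = P2Space(mesh, scale=UM)
    mu = medium.dynamic_viscosity

    A = space.stiffness(coeff=mu)
    Bx, By = space.divergence()
    n2, nv = space.n_dofs, space.n_vertex

    # Dirichlet sets
    wall_tags = ["wall"] + [t for t in mesh.tag_names if t.startswith("electrode")]
    wall_dofs = space.boundary_dofs(wall_tags)
    diri: dict[int, tuple[float, float]] = {int(d): (0.0, 0.0) for d in wall_dofs}

    for tag, speed in (("blood_inlet", bc.v_blood), ("buffer_inlet", bc.v_buffer)):
        if tag not in mesh.tag_names:
            continue
        edges = mesh.edges_with_tag(tag)
        # inward unit normal: opposite the outward one
        seg_pts = mesh.points[np.unique(edges)]
        # face normal from any edge; orient into the domain via adjacent triangle
        tri_lookup = _adjacent_triangle_map(mesh)
        e0 = edges[0]
        p0, p1 = mesh.points[e0[0]], mesh.points[e0[1]]
        tvec = p1 - p0
        n = np.array([tvec[1], -tvec[0]]) / np.hypot(*tvec)
        tri = tri_lookup[(min(int(e0[0]), int(e0[1])), max(int(e0[0]), int(e0[1])))]
        cent = mesh.points[mesh.triangles[tri]].mean(axis=0)
        if np.dot(cent - 0.5 * (p0 + p1), n) < 0:
            n = -n  # ensure inward
        if speed == 0.0:
            vals = {int(d): np.zeros(2) for d in space.boundary_dofs([tag])}
        else:
            vals = _inlet_profile(space, mesh, tag, speed, n, bc.profile)
        # walls win at shared corner nodes
        for d, v in vals.items():
            if d not in diri:
                diri[d] = (float(v[0]), float(v[1]))

    ndof = 2 * n2 + nv
    K = sp.bmat(
        [
            [A, None, -Bx.T],
            [None, A, -By.T],
            [-Bx, -By, None],
        ],
        format="csr",
    )
    rhs = np.zeros(ndof)

    fixed = np.fromiter(diri.keys(), dtype=int)
    fixed_vals_x = np.array([diri[int(d)][0] for d in fixed])
    fixed_vals_y = np.array([diri[int(d)][1] for d in fixed])
    fixed_all = np.concatenate([fixed, n2 + fixed])
    fixed_vals = np.concatenate([fixed_vals_x, fixed_vals_y])

    # eliminate Dirichlet dofs
    u_full = np.zeros(ndof)
    u_full[fixed_all] = fixed_vals
    rhs = rhs - K @ u_full
    keep = np.setdiff1d(np.arange(ndof), fixed_all)
    Kr = K[keep][:, keep].tocsc()
    rr = rhs[keep]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", spla.MatrixRankWarning)
        try:
            sol = spla.spsolve(Kr, rr)
        except Exception as exc:  # pragma: no cover
            raise SolverError(f"sparse solve failed: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise SolverError("Stokes solve did not converge (non-finite solution)")
    u_full[keep] = sol
    resid = np.linalg.norm(Kr @ sol - rr)
    scale = np.linalg.norm(rr) + 1e-300
    if bc.v_blood > 0 or bc.v_buffer > 0:
        if resid / scale > 1e-8:
            raise SolverError(f"Stokes residual too large: {resid / scale:.2e}")

    ux = u_full[:n2]
    uy = u_full[n2: 2 * n2]
    p = u_full[2 * n2:]
    return FlowField(mesh=mesh, space=space, ux=ux, uy=uy, p=p, bc=bc, medium=medium)


def sample_flow(flow: FlowField, point_um) -> tuple[np.ndarray, float]:
    """Velocity vector (m/s) and pressure (Pa) at one point given in um."""
    pt = np.atleast_2d(np.asarray(point_um, dtype=float))
    u = flow.velocity(pt)[0]
    p = flow.pressure(pt)[0]
    return u, float(p)
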