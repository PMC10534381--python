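"""Minimal continuous-Galerkin FEM kernels on triangle meshes.

Provides P1 (linear) and P2 (quadratic) scalar spaces, vectorised
assembly of stiffness/divergence operators, boundary-edge quadrature and
continuous point evaluation via a trapezoid-map point locator.  Geometry
lives in micrometres; callers decide the physical unit scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from matplotlib.tri import Triangulation, TrapezoidMapTriFinder

from .meshing import Mesh

__all__ = ["P2Space", "FieldSampler", "edge_quadrature_nodes"]

# 6-point (degree 4) triangle quadrature in barycentric coordinates
_QW = np.array([0.109951743655322] * 3 + [0.223381589678011] * 3)
_a, _b = 0.091576213509771, 0.445948490915965
_QP = np.array(
    [
        [1 - 2 * _a, _a, _a],
        [_a, 1 - 2 * _a, _a],
        [_a, _a, 1 - 2 * _a],
        [1 - 2 * _b, _b, _b],
        [_b, 1 - 2 * _b, _b],
        [_b, _b, 1 - 2 * _b],
    ]
)


def _p2_basis(lmb: np.ndarray) -> np.ndarray:
    """P2 basis values at barycentric points lmb (q, 3) -> (q, 6)."""
    l1, l2, l3 = lmb[:, 0], lmb[:, 1], lmb[:, 2]
    return np.column_stack(
        [
            l1 * (2 * l1 - 1),
            l2 * (2 * l2 - 1),
            l3 * (2 * l3 - 1),
            4 * l1 * l2,
            4 * l2 * l3,
            4 * l3 * l1,
        ]
    )


def _p2_basis_grad_bary(lmb: np.ndarray) -> np.ndarray:
    """Gradients of the 6 P2 basis functions w.r.t. (l1, l2, l3): (q, 6, 3)."""
    q = len(lmb)
    g = np.zeros((q, 6, 3))
    l1, l2, l3 = lmb[:, 0], lmb[:, 1], lmb[:, 2]
    g[:, 0, 0] = 4 * l1 - 1
    g[:, 1, 1] = 4 * l2 - 1
    g[:, 2, 2] = 4 * l3 - 1
    g[:, 3, 0], g[:, 3, 1] = 4 * l2, 4 * l1
    g[:, 4, 1], g[:, 4, 2] = 4 * l3, 4 * l2
    g[:, 5, 2], g[:, 5, 0] = 4 * l1, 4 * l3
    return g


@dataclass
class P2Space:
    """Quadratic Lagrange space: vertex dofs then edge-midpoint dofs."""

    mesh: Mesh
    scale: float = 1.0  # multiply um coordinates by this (1e-6 for SI)

    def __post_init__(self) -> None:
        tris = self.mesh.triangles
        edges = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
        edges_sorted = np.sort(edges, axis=1)
        uniq, inverse = np.unique(edges_sorted, axis=0, return_inverse=True)
        self.edges = uniq
        nv = self.mesh.n_points
        nt = len(tris)
        # element dof map: [v0, v1, v2, m01, m12, m20]
        mid = nv + inverse.reshape(3, nt).T
        self.element_dofs = np.hstack([tris, mid])
        self.n_vertex = nv
        self.n_dofs = nv + len(uniq)
        pts = self.mesh.points * self.scale
        self.dof_coords = np.vstack([pts, 0.5 * (pts[uniq[:, 0]] + pts[uniq[:, 1]])])

        # affine map data per element
        p = pts[tris]
        self.v0 = p[:, 0]
        J = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=2)  # (t, 2, 2)
        self.detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        self.area = 0.5 * self.detJ
        # gradients of barycentric coords (t, 3, 2)
        inv = np.empty_like(J)
        inv[:, 0, 0] = J[:, 1, 1]
        inv[:, 0, 1] = -J[:, 0, 1]
        inv[:, 1, 0] = -J[:, 1, 0]
        inv[:, 1, 1] = J[:, 0, 0]
        inv /= self.detJ[:, None, None]
        # l2, l3 are the reference coords; l1 = 1 - l2 - l3
        gl23 = inv  # rows: d(ref)/d(x)
        self.grad_lambda = np.empty((nt, 3, 2))
        self.grad_lambda[:, 1] = gl23[:, 0]
        self.grad_lambda[:, 2] = gl23[:, 1]
        self.grad_lambda[:, 0] = -gl23[:, 0] - gl23[:, 1]

    # -- assembly ---------------------------------------------------------

    def stiffness(self, coeff: float = 1.0) -> sp.csr_matrix:
        """Assemble  coeff * int grad(u) . grad(v)."""
        nt = len(self.mesh.triangles)
        gb = _p2_basis_grad_bary(_QP)  # (q, 6, 3)
        # physical gradients per element/quad point: (t, q, 6, 2)
        G = np.einsum("qib,tbd->tqid", gb, self.grad_lambda)
        w = (_QW[None, :] * self.area[:, None])  # (t, q)
        Ke = coeff * np.einsum("tq,tqid,tqjd->tij", w, G, G)
        dofs = self.element_dofs
        rows = np.repeat(dofs, 6, axis=1).ravel()
        cols = np.tile(dofs, (1, 6)).ravel()
        return sp.coo_matrix(
            (Ke.ravel(), (rows, cols)), shape=(self.n_dofs, self.n_dofs)
        ).tocsr()

    def divergence(self) -> tuple[sp.csr_matrix, sp.csr_matrix]:
        """P1 pressure test vs P2 velocity:  Bx[q, u] = int q d(u)/dx  etc."""
        gb = _p2_basis_grad_bary(_QP)
        G = np.einsum("qib,tbd->tqid", gb, self.grad_lambda)  # (t,q,6,2)
        phi_p1 = _QP  # P1 basis values = barycentric coords (q, 3)
        w = (_QW[None, :] * self.area[:, None])
        Bx_e = np.einsum("tq,qj,tqi->tji", w, phi_p1, G[:, :, :, 0])
        By_e = np.einsum("tq,qj,tqi->tji", w, phi_p1, G[:, :, :, 1])
        tris = self.mesh.triangles
        dofs = self.element_dofs
        rows = np.repeat(tris, 6, axis=1).ravel()
        cols = np.tile(dofs, (1, 3)).ravel()
        shape = (self.n_vertex, self.n_dofs)
        Bx = sp.coo_matrix((Bx_e.ravel(), (rows, cols)), shape=shape).tocsr()
        By = sp.coo_matrix((By_e.ravel(), (rows, cols)), shape=shape).tocsr()
        return Bx, By

    # -- boundary handling ------------------------------------------------

    def edge_dof(self, v0: int, v1: int) -> int:
        """Dof index of the midpoint node of boundary edge (v0, v1)."""
        key = np.sort([v0, v1])
        idx = np.searchsorted(
            self.edges[:, 0] * self.n_vertex + self.edges[:, 1],
            key[0] * self.n_vertex + key[1],
        )
        return self.n_vertex + int(idx)

    def boundary_dofs(self, tags: list[str] | None = None) -> np.ndarray:
        """All P2 dofs (vertices + midpoints) on boundary edges with tags."""
        mesh = self.mesh
        if tags is None:
            edges = mesh.boundary_edges
        else:
            sel = np.isin(mesh.boundary_tags, [mesh.tag_names.index(t) for t in tags])
            edges = mesh.boundary_edges[sel]
        if len(edges) == 0:
            return np.array([], dtype=int)
        keys = np.sort(edges, axis=1)
        flat = self.edges[:, 0].astype(np.int64) * self.n_vertex + self.edges[:, 1]
        mids = self.n_vertex + np.searchsorted(
            flat, keys[:, 0].astype(np.int64) * self.n_vertex + keys[:, 1]
        )
        return np.unique(np.concatenate([edges.ravel(), mids]))

    # -- evaluation -------------------------------------------------------

    def gradient_at_centroids(self, u: np.ndarray) -> np.ndarray:
        """Element-wise gradient of a P2 field at element centroids (t, 2)."""
        lmb = np.full((1, 3), 1.0 / 3.0)
        gb = _p2_basis_grad_bary(lmb)[0]  # (6, 3)
        G = np.einsum("ib,tbd->tid", gb, self.grad_lambda)  # (t, 6, 2)
        return np.einsum("ti,tid->td", u[self.element_dofs], G)

    def interpolate(self, f) -> np.ndarray:
        """Nodal interpolant of f(x, y) on all P2 dofs."""
        c = self.dof_coords
        return np.asarray(f(c[:, 0], c[:, 1]), dtype=float)

    def mass_matrix(self) -> sp.csr_matrix:
        phi = _p2_basis(_QP)  # (q, 6)
        w = (_QW[None, :] * self.area[:, None])  # (t, q)
        Me = np.einsum("tq,qi,qj->tij", w, phi, phi)
        dofs = self.element_dofs
        rows = np.repeat(dofs, 6, axis=1).ravel()
        cols = np.tile(dofs, (1, 6)).ravel()
        return sp.coo_matrix(
            (Me.ravel(), (rows, cols)), shape=(self.n_dofs, self.n_dofs)
        ).tocsr()

    def project(self, elem_func) -> np.ndarray:
        """L2 projection onto the P2 space of a function given per element.

        ``elem_func(t_idx, lmb)`` returns values at barycentric points
        ``lmb`` (q, 3) for all elements at once, shape (t, q).
        """
        phi = _p2_basis(_QP)
        w = (_QW[None, :] * self.area[:, None])
        vals = elem_func(_QP)  # (t, q)
        be = np.einsum("tq,qi->ti", w * vals, phi)
        b = np.zeros(self.n_dofs)
        np.add.at(b, self.element_dofs.ravel(), be.ravel())
        M = self.mass_matrix().tocsc()
        import scipy.sparse.linalg as spla

        return spla.spsolve(M, b)

    def gradient_at_bary(self, u: np.ndarray, lmb: np.ndarray) -> np.ndarray:
        """Gradient of a P2 field at barycentric points, all elements: (t, q, 2)."""
        gb = _p2_basis_grad_bary(lmb)  # (q, 6, 3)
        G = np.einsum("qib,tbd->tqid", gb, self.grad_lambda)
        return np.einsum("ti,tqid->tqd", u[self.element_dofs], G)


def edge_quadrature_nodes(n: int = 4):
    """Gauss-Legendre nodes/weights on [0, 1] for boundary-edge integrals."""
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


class FieldSampler:
    """Continuous evaluation of P1/P2 fields at arbitrary points (um).

    Uses matplotlib's trapezoid-map point locator on the triangulation.
    Points outside the domain raise OutOfDomainError unless ``clamp`` is
    requested, in which case the value at the nearest mesh vertex is used
    (transient integrator stages only).
    """

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self._tri = Triangulation(
            mesh.points[:, 0], mesh.points[:, 1], mesh.triangles
        )
        self._finder = TrapezoidMapTriFinder(self._tri)
        from scipy.spatial import cKDTree

        self._tree = cKDTree(mesh.points)
        p = mesh.points[mesh.triangles]
        self._v0 = p[:, 0]
        T = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=2)
        det = T[:, 0, 0] * T[:, 1, 1] - T[:, 0, 1] * T[:, 1, 0]
        self._inv = np.empty_like(T)
        self._inv[:, 0, 0] = T[:, 1, 1]
        self._inv[:, 0, 1] = -T[:, 0, 1]
        self._inv[:, 1, 0] = -T[:, 1, 0]
        self._inv[:, 1, 1] = T[:, 0, 0]
        self._inv /= det[:, None, None]

    def locate(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Triangle index (-1 outside) and barycentric coords for points."""
        pts = np.atleast_2d(pts)
        t = self._finder(pts[:, 0], pts[:, 1]).astype(int)
        lmb = np.zeros((len(pts), 3))
        ok = t >= 0
        if ok.any():
            rel = pts[ok] - self._v0[t[ok]]
            ref = np.einsum("nij,nj->ni", self._inv[t[ok]], rel)
            lmb[ok, 1] = ref[:, 0]
            lmb[ok, 2] = ref[:, 1]
            lmb[ok, 0] = 1.0 - ref.sum(axis=1)
        return t, lmb

    def nearest_vertex(self, pts: np.ndarray) -> np.ndarray:
        _, idx = self._tree.query(np.atleast_2d(pts))
        return idx

    def eval_p1(self, nodal: np.ndarray, pts: np.ndarray, clamp: bool = False):
        """Evaluate a vertex-based (P1) field; nodal (n,) or (n, k)."""
        pts = np.atleast_2d(pts)
        t, lmb = self.locate(pts)
        out_shape = (len(pts),) + np.shape(nodal)[1:]
        out = np.zeros(out_shape)
        ok = t >= 0
        if ok.any():
            tri = self.mesh.triangles[t[ok]]
            vals = nodal[tri]  # (n, 3[, k])
            out[ok] = np.einsum("nj,nj...->n...", lmb[ok], vals)
        if (~ok).any():
            if not clamp:
                bad = pts[~ok][0]
                raise OutOfDomainError(f"point {tuple(bad)} outside the domain")
            out[~ok] = nodal[self.nearest_vertex(pts[~ok])]
        return out

    def eval_p2(self, space: P2Space, u: np.ndarray, pts: np.ndarray,
                clamp: bool = False):
        """Evaluate a P2 field (dof vector u, shape (ndofs,) or (ndofs, k))."""
        pts = np.atleast_2d(pts)
        t, lmb = self.locate(pts)
        out_shape = (len(pts),) + np.shape(u)[1:]
        out = np.zeros(out_shape)
        ok = t >= 0
        if ok.any():
            phi = _p2_basis(lmb[ok])  # (n, 6)
            dofs = space.element_dofs[t[ok]]
            out[ok] = np.einsum("nj,nj...->n...", phi, u[dofs])
        if (~ok).any():
            if not clamp:
                bad = pts[~ok][0]
                raise OutOfDomainError(f"point {tuple(bad)} outside the domain")
            out[~ok] = u[self.nearest_vertex(pts[~ok])]
        return out

    def locate_clamped(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Locate points, mapping outside points to the nearest vertex's
        triangle centroid; returns (tri, barycentric, outside_mask).

        Non-finite coordinates (e.g. from an implicit solver's Jacobian
        probing) are treated as outside and pinned to the first vertex.
        """
        pts = np.atleast_2d(pts)
        if not hasattr(self, "_bbox"):
            self._bbox = (
                self.mesh.points.min(axis=0) - 1.0,
                self.mesh.points.max(axis=0) + 1.0,
            )
        lo, hi = self._bbox
        if not np.isfinite(pts).all() or (pts < lo).any() or (pts > hi).any():
            pts = np.clip(np.nan_to_num(pts, nan=lo[0]), lo, hi)
        t, lmb = self.locate(pts)
        outside = t < 0
        if outside.any():
            if not hasattr(self, "_vertex_tri"):
                vt = np.full(self.mesh.n_points, -1, dtype=int)
                for k, tri in enumerate(self.mesh.triangles):
                    vt[tri] = k
                self._vertex_tri = vt
            near = self.nearest_vertex(pts[outside])
            t[outside] = self._vertex_tri[near]
            lmb[outside] = 1.0 / 3.0
        return t, lmb, outside

    def eval_p2_gradient(self, space: P2Space, u: np.ndarray, pts: np.ndarray,
                         clamp: bool = False) -> np.ndarray:
        """Gradient of a scalar P2 field at points (um); piecewise linear,
        discontinuous across element edges."""
        pts = np.atleast_2d(pts)
        if clamp:
            t, lmb, _ = self.locate_clamped(pts)
        else:
            t, lmb = self.locate(pts)
            if (t < 0).any():
                bad = pts[t < 0][0]
                raise OutOfDomainError(f"point {tuple(bad)} outside the domain")
        return p2_gradients_at(space, u, t, lmb)

    def inside(self, pts: np.ndarray) -> np.ndarray:
        t, _ = self.locate(pts)
        return t >= 0


def p2_values_at(space: P2Space, u: np.ndarray, tri: np.ndarray,
                 lmb: np.ndarray) -> np.ndarray:
    """Evaluate a P2 field at located points (tri index + barycentric)."""
    phi = _p2_basis(lmb)
    return np.einsum("nj,nj...->n...", phi, u[space.element_dofs[tri]])


def p2_gradients_at(space: P2Space, u: np.ndarray, tri: np.ndarray,
                    lmb: np.ndarray) -> np.ndarray:
    """Gradient of a scalar P2 field at located points."""
    gb = _p2_basis_grad_bary(lmb)       # (n, 6, 3)
    gl = space.grad_lambda[tri]         # (n, 3, 2)
    G = np.einsum("nib,nbd->nid", gb, gl)
    return np.einsum("ni,nid->nd", u[space.element_dofs[tri]], G)


class OutOfDomainError(ValueError):
    """Requested evaluation point lies outside the meshed domain."""
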