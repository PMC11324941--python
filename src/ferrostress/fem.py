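"""Minimal linear (P1) triangular finite-element core.

Everything downstream (magnetostatics, vessel flow, poroelasticity)
assembles its weak forms from the primitives here: per-element basis
gradients, scalar/vector stiffness and mass matrices, boundary-edge
integrals, Dirichlet elimination, and patch-averaged nodal gradient
recovery.  Point location and P1 interpolation delegate to
``matplotlib.tri``.

Conventions
-----------
* nodes: ``(N, 2)`` float array of coordinates (m)
* triangles: ``(M, 3)`` int array, counter-clockwise
* per-triangle region tags and per-boundary-edge tags are strings
* vector fields use interleaved dofs ``[ux0, uy0, ux1, uy1, ...]``
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from matplotlib.tri import LinearTriInterpolator, Triangulation


class FemError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# mesh container
# ----------------------------------------------------------------------

@dataclass
class Mesh:
    """Conforming triangulation with tagged regions and boundary edges."""

    points: np.ndarray              # (N, 2)
    triangles: np.ndarray           # (M, 3) CCW
    region: np.ndarray              # (M,) str tags
    edges: np.ndarray = None        # (K, 2) boundary edge node pairs
    edge_tag: np.ndarray = None     # (K,) str tags
    _cache: dict = field(default_factory=dict, repr=False)

    # -- geometry ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    @property
    def n_tris(self) -> int:
        return self.triangles.shape[0]

    def _geom(self):
        if "geom" not in self._cache:
            pts = self.points
            t = self.triangles
            x = pts[t, 0]
            y = pts[t, 1]
            # edge vectors opposite each local node
            det = ((x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0])
                   - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0]))
            area = 0.5 * det
            if np.any(area <= 0):
                raise FemError("mesh contains non-CCW or degenerate triangle")
            # gradients of the three barycentric basis functions
            b = np.empty((self.n_tris, 3, 2))
            b[:, 0, 0] = y[:, 1] - y[:, 2]
            b[:, 1, 0] = y[:, 2] - y[:, 0]
            b[:, 2, 0] = y[:, 0] - y[:, 1]
            b[:, 0, 1] = x[:, 2] - x[:, 1]
            b[:, 1, 1] = x[:, 0] - x[:, 2]
            b[:, 2, 1] = x[:, 1] - x[:, 0]
            b /= det[:, None, None]
            self._cache["geom"] = (area, b)
        return self._cache["geom"]

    @property
    def areas(self) -> np.ndarray:
        return self._geom()[0]

    @property
    def basis_grads(self) -> np.ndarray:
        """(M, 3, 2) gradients of the P1 basis on each triangle."""
        return self._geom()[1]

    @property
    def centroids(self) -> np.ndarray:
        return self.points[self.triangles].mean(axis=1)

    def tris_in(self, *tags) -> np.ndarray:
        return np.isin(self.region, tags)

    # -- boundary ----------------------------------------------------

    def edge_nodes(self, *tags) -> np.ndarray:
        sel = np.isin(self.edge_tag, tags)
        return np.unique(self.edges[sel])

    def edge_lengths(self, sel=None) -> np.ndarray:
        e = self.edges if sel is None else self.edges[sel]
        d = self.points[e[:, 1]] - self.points[e[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])

    # -- interpolation ----------------------------------------------

    def _tri_obj(self):
        if "tri" not in self._cache:
            tri = Triangulation(self.points[:, 0], self.points[:, 1],
                                self.triangles)
            self._cache["tri"] = tri
            self._cache["finder"] = tri.get_trifinder()
        return self._cache["tri"], self._cache["finder"]

    def find(self, pts: np.ndarray) -> np.ndarray:
        """Triangle index containing each query point (-1 outside)."""
        _, finder = self._tri_obj()
        return finder(pts[:, 0], pts[:, 1])

    def interpolate(self, nodal: np.ndarray, pts: np.ndarray) -> np.ndarray:
        """P1-interpolate a nodal field at arbitrary points.

        Points that fall outside the triangulation (only possible through
        floating-point grazing of the hull) take the nearest node value.
        """
        tri, _ = self._tri_obj()
        interp = LinearTriInterpolator(tri, nodal)
        vals = np.asarray(interp(pts[:, 0], pts[:, 1]))
        bad = ~np.isfinite(vals)
        if np.any(bad):
            from scipy.spatial import cKDTree
            kd = self._cache.setdefault("kdtree", cKDTree(self.points))
            _, idx = kd.query(pts[bad])
            vals[bad] = nodal[idx]
        return vals


def orient_ccw(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Return a copy of ``triangles`` with counter-clockwise orientation."""
    t = np.array(triangles, copy=True)
    p = points
    det = ((p[t[:, 1], 0] - p[t[:, 0], 0]) * (p[t[:, 2], 1] - p[t[:, 0], 1])
           - (p[t[:, 2], 0] - p[t[:, 0], 0]) * (p[t[:, 1], 1] - p[t[:, 0], 1]))
    flip = det < 0
    t[flip, 1], t[flip, 2] = t[flip, 2].copy(), t[flip, 1].copy()
    return t


def boundary_edges(triangles: np.ndarray) -> np.ndarray:
    """Edges that belong to exactly one triangle, as (K, 2) node pairs."""
    e = np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]],
                   triangles[:, [2, 0]]])
    key = np.sort(e, axis=1)
    _, first, counts = np.unique(key, axis=0, return_index=True,
                                 return_counts=True)
    return e[first[counts == 1]]


# ----------------------------------------------------------------------
# assembly primitives
# ----------------------------------------------------------------------

def _coo(mesh, rows, cols, vals, shape):
    return sp.coo_matrix(
        (np.ravel(vals), (np.ravel(rows), np.ravel(cols))), shape=shape
    ).tocsr()


def stiffness(mesh: Mesh, coeff=1.0) -> sp.csr_matrix:
    """Assemble ``\\int c grad(u) . grad(v)`` with per-triangle ``c``."""
    c = np.broadcast_to(np.asarray(coeff, float), (mesh.n_tris,))
    b = mesh.basis_grads
    a = mesh.areas * c
    ke = np.einsum("kid,kjd->kij", b, b) * a[:, None, None]
    t = mesh.triangles
    rows = np.repeat(t, 3, axis=1)
    cols = np.tile(t, (1, 3))
    return _coo(mesh, rows, cols, ke, (mesh.n_nodes, mesh.n_nodes))


def mass(mesh: Mesh, coeff=1.0) -> sp.csr_matrix:
    """Consistent P1 mass matrix with per-triangle coefficient."""
    c = np.broadcast_to(np.asarray(coeff, float), (mesh.n_tris,))
    a = mesh.areas * c
    local = (np.ones((3, 3)) + np.eye(3)) / 12.0
    me = a[:, None, None] * local
    t = mesh.triangles
    rows = np.repeat(t, 3, axis=1)
    cols = np.tile(t, (1, 3))
    return _coo(mesh, rows, cols, me, (mesh.n_nodes, mesh.n_nodes))


def load_nodal(mesh: Mesh, f_nodal: np.ndarray) -> np.ndarray:
    """``\\int f v`` for a P1 nodal density ``f`` (consistent quadrature)."""
    return mass(mesh) @ f_nodal


def load_tri(mesh: Mesh, f_tri: np.ndarray) -> np.ndarray:
    """``\\int f v`` for a piecewise-constant density ``f``."""
    contrib = (mesh.areas * f_tri)[:, None] / 3.0
    out = np.zeros(mesh.n_nodes)
    np.add.at(out, mesh.triangles, np.broadcast_to(contrib, (mesh.n_tris, 3)))
    return out


def load_flux(mesh: Mesh, F_tri: np.ndarray) -> np.ndarray:
    """``\\int F . grad(v)`` for a piecewise-constant vector field ``F``."""
    b = mesh.basis_grads
    contrib = np.einsum("kid,kd->ki", b, F_tri) * mesh.areas[:, None]
    out = np.zeros(mesh.n_nodes)
    np.add.at(out, mesh.triangles, contrib)
    return out


def load_div(mesh: Mesh, p_nodal: np.ndarray) -> np.ndarray:
    """``\\int p div(v)`` against vector test functions (interleaved dofs)."""
    pbar = p_nodal[mesh.triangles].mean(axis=1)
    b = mesh.basis_grads
    contrib = b * (mesh.areas * pbar)[:, None, None]     # (M, 3, 2)
    out = np.zeros(2 * mesh.n_nodes)
    dofs = 2 * mesh.triangles[:, :, None] + np.arange(2)[None, None, :]
    np.add.at(out, dofs, contrib)
    return out


def load_vector_tri(mesh: Mesh, F_tri: np.ndarray) -> np.ndarray:
    """``\\int F . v`` for piecewise-constant vector ``F`` (interleaved)."""
    contrib = np.broadcast_to(
        (mesh.areas / 3.0)[:, None, None] * F_tri[:, None, :],
        (mesh.n_tris, 3, 2),
    )
    out = np.zeros(2 * mesh.n_nodes)
    dofs = 2 * mesh.triangles[:, :, None] + np.arange(2)[None, None, :]
    np.add.at(out, dofs, contrib)
    return out


def elastic_stiffness(mesh: Mesh, lam, mu) -> sp.csr_matrix:
    """``\\int lam div(u) div(v) + 2 mu eps(u):eps(v)`` (interleaved dofs).

    Plane-strain isotropic linear elasticity with per-triangle Lame
    coefficients.
    """
    lam = np.broadcast_to(np.asarray(lam, float), (mesh.n_tris,))
    mu = np.broadcast_to(np.asarray(mu, float), (mesh.n_tris,))
    b = mesh.basis_grads                   # (M, 3, 2)
    area = mesh.areas
    M = mesh.n_tris
    # strain-displacement matrix B (3 strain comps: xx, yy, sqrt-free xy)
    B = np.zeros((M, 3, 6))
    B[:, 0, 0::2] = b[:, :, 0]
    B[:, 1, 1::2] = b[:, :, 1]
    B[:, 2, 0::2] = b[:, :, 1]
    B[:, 2, 1::2] = b[:, :, 0]
    # constitutive matrix D for [exx, eyy, gxy]
    D = np.zeros((M, 3, 3))
    D[:, 0, 0] = lam + 2 * mu
    D[:, 1, 1] = lam + 2 * mu
    D[:, 0, 1] = D[:, 1, 0] = lam
    D[:, 2, 2] = mu
    ke = np.einsum("ksi,kst,ktj->kij", B, D, B) * area[:, None, None]
    t = mesh.triangles
    dofs = np.empty((M, 6), dtype=np.int64)
    dofs[:, 0::2] = 2 * t
    dofs[:, 1::2] = 2 * t + 1
    rows = np.repeat(dofs, 6, axis=1)
    cols = np.tile(dofs, (1, 6))
    return _coo(mesh, rows, cols, ke, (2 * mesh.n_nodes, 2 * mesh.n_nodes))


def div_matrix(mesh: Mesh) -> sp.csr_matrix:
    """``B[q, dof] = \\int phi_q div(phi_dof)`` mapping velocity to pressure."""
    b = mesh.basis_grads
    area = mesh.areas
    t = mesh.triangles
    M = mesh.n_tris
    vals = np.repeat(b[:, None, :, :], 3, axis=1) * (area / 3.0)[:, None, None, None]
    rows = np.repeat(t[:, :, None], 3, axis=2)          # pressure node q
    rows = np.repeat(rows[:, :, :, None], 2, axis=3)
    cols = 2 * t[:, None, :, None] + np.arange(2)[None, None, None, :]
    cols = np.broadcast_to(cols, (M, 3, 3, 2))
    return _coo(mesh, rows, cols, vals, (mesh.n_nodes, 2 * mesh.n_nodes))


def edge_load(mesh: Mesh, sel, g) -> np.ndarray:
    """``\\int_edge g v ds`` over selected boundary edges (scalar test)."""
    e = mesh.edges[sel]
    L = mesh.edge_lengths(sel)
    g = np.broadcast_to(np.asarray(g, float), (len(e),))
    out = np.zeros(mesh.n_nodes)
    np.add.at(out, e[:, 0], 0.5 * g * L)
    np.add.at(out, e[:, 1], 0.5 * g * L)
    return out


def edge_normal_load(mesh: Mesh, sel, traction_normal) -> np.ndarray:
    """``\\int_edge t_n (n . v) ds`` on selected edges (interleaved dofs).

    Outward normals are computed assuming CCW triangle orientation, i.e.
    the domain lies to the left of each boundary edge as stored.
    """
    e = mesh.edges[sel]
    d = mesh.points[e[:, 1]] - mesh.points[e[:, 0]]
    L = np.hypot(d[:, 0], d[:, 1])
    n = np.column_stack([d[:, 1], -d[:, 0]]) / L[:, None]
    tn = np.broadcast_to(np.asarray(traction_normal, float), (len(e),))
    out = np.zeros(2 * mesh.n_nodes)
    for k in range(2):
        np.add.at(out, 2 * e[:, 0] + k, 0.5 * tn * L * n[:, k])
        np.add.at(out, 2 * e[:, 1] + k, 0.5 * tn * L * n[:, k])
    return out


# ----------------------------------------------------------------------
# Dirichlet conditions and solving
# ----------------------------------------------------------------------

def solve_dirichlet(A: sp.spmatrix, rhs: np.ndarray, fixed_dofs,
                    fixed_vals) -> np.ndarray:
    """Solve ``A x = rhs`` with prescribed values on ``fixed_dofs``."""
    n = A.shape[0]
    fixed_dofs = np.asarray(fixed_dofs, dtype=np.int64)
    fixed_vals = np.broadcast_to(np.asarray(fixed_vals, float),
                                 fixed_dofs.shape)
    x = np.zeros(n)
    x[fixed_dofs] = fixed_vals
    free = np.ones(n, dtype=bool)
    free[fixed_dofs] = False
    A = A.tocsr()
    b = rhs - A @ x
    Aff = A[free][:, free]
    xf = spla.spsolve(Aff.tocsc(), b[free])
    if not np.all(np.isfinite(xf)):
        raise FemError("sparse direct solve produced non-finite values "
                       "(singular system?)")
    x[free] = xf
    return x


# ----------------------------------------------------------------------
# gradient recovery
# ----------------------------------------------------------------------

def tri_gradient(mesh: Mesh, nodal: np.ndarray) -> np.ndarray:
    """Per-triangle (constant) gradient of a P1 nodal field, (M, 2)."""
    return np.einsum("kid,ki->kd", mesh.basis_grads, nodal[mesh.triangles])


def nodal_average(mesh: Mesh, tri_field: np.ndarray) -> np.ndarray:
    """Area-weighted average of a per-triangle field onto nodes.

    Works for scalar ``(M,)`` or vector ``(M, d)`` fields.
    """
    tri_field = np.asarray(tri_field, float)
    scalar = tri_field.ndim == 1
    if scalar:
        tri_field = tri_field[:, None]
    w = mesh.areas
    num = np.zeros((mesh.n_nodes, tri_field.shape[1]))
    den = np.zeros(mesh.n_nodes)
    for i in range(3):
        np.add.at(num, mesh.triangles[:, i], w[:, None] * tri_field)
        np.add.at(den, mesh.triangles[:, i], w)
    out = num / den[:, None]
    return out[:, 0] if scalar else out


def nodal_gradient(mesh: Mesh, nodal: np.ndarray) -> np.ndarray:
    """Recovered (patch-averaged) nodal gradient of a P1 field, (N, 2)."""
    return nodal_average(mesh, tri_gradient(mesh, nodal))


# ----------------------------------------------------------------------
# export
# ----------------------------------------------------------------------

def write_vtk(path, mesh: Mesh, point_data=None, cell_data=None,
              comment="ferrostress field export") -> None:
    """Write the mesh and fields as a legacy ASCII VTK unstructured grid.

    ``point_data``/``cell_data`` map names to scalar ``(N,)``/``(M,)``
    or vector ``(N, 2)``/``(M, 2)`` arrays (vectors are padded to 3D).
    """
    def blocks(fh, data, n):
        for name, arr in (data or {}).items():
            arr = np.asarray(arr, float)
            if arr.ndim == 1:
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.9g}" for v in arr) + "\n")
            else:
                fh.write(f"VECTORS {name} double\n")
                for row in arr:
                    fh.write(f"{row[0]:.9g} {row[1]:.9g} 0\n")

    with open(path, "w") as fh:
        fh.write(f"# vtk DataFile Version 3.0\n{comment}\nASCII\n"
                 "DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y in mesh.points:
            fh.write(f"{x:.9g} {y:.9g} 0\n")
        fh.write(f"CELLS {mesh.n_tris} {4 * mesh.n_tris}\n")
        for a, b, c in mesh.triangles:
            fh.write(f"3 {a} {b} {c}\n")
        fh.write(f"CELL_TYPES {mesh.n_tris}\n")
        fh.write("\n".join(["5"] * mesh.n_tris) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            blocks(fh, point_data, mesh.n_nodes)
        if cell_data:
            fh.write(f"CELL_DATA {mesh.n_tris}\n")
            blocks(fh, cell_data, mesh.n_tris)
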