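"""Steady non-Newtonian blood flow in the capillary ring and feeders.

Blood laden with ferrofluid is a shear-thinning power-law fluid: the
apparent viscosity is ``mu_B = m * gamma_dot**(n-1)`` with consistency
``m`` and index ``n < 1``, the shear rate regularized to a configurable
interval so the viscosity stays finite as ``gamma_dot -> 0``.  The
momentum balance carries the Kelvin body force of the magnetized
ferrofluid; at capillary scale the Reynolds number is well below one,
so the convective term is optional (Picard-linearized when enabled) and
the default solve is the generalized-Newtonian Stokes problem.

Discretization: equal-order P1-P1 velocity/pressure with
Brezzi-Pitkaranta pressure stabilization; pressure boundary values at
the inlet (tag "2") and outlet (tag "3") enter as normal tractions,
no-slip on all vessel walls.  The nonlinearity in the viscosity is
resolved by damped Picard iteration on the shear rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .fem import (Mesh, elastic_stiffness, div_matrix, edge_normal_load,
                  load_vector_tri, solve_dirichlet, stiffness, tri_gradient)
from .params import ParamSet
from .stress import Profile


class FlowError(RuntimeError):
    pass


#: default shear-rate regularization bounds (1/s)
GAMMA_DOT_MIN = 1e-3
GAMMA_DOT_MAX = 1e5


def apparent_viscosity(gamma_dot, p: ParamSet,
                       gd_min: float = GAMMA_DOT_MIN,
                       gd_max: float = GAMMA_DOT_MAX):
    """Power-law apparent viscosity ``m * gamma_dot**(n-1)`` (Pa s).

    The shear rate is clamped to ``[gd_min, gd_max]`` before the power
    is taken; for a Newtonian index (n = 1) the value is simply ``m``.
    """
    gd = np.asarray(gamma_dot, dtype=float)
    if np.any(gd < 0):
        raise FlowError("shear rate must be non-negative")
    gd = np.clip(gd, gd_min, gd_max)
    out = p.m_pl * gd ** (p.n_pl - 1.0)
    return float(out) if np.isscalar(gamma_dot) else out


def shear_rate(mesh: Mesh, V: np.ndarray) -> np.ndarray:
    """Per-element shear rate ``sqrt(2 D:D)`` of a nodal velocity field."""
    dux = tri_gradient(mesh, V[:, 0])
    duy = tri_gradient(mesh, V[:, 1])
    dxy = 0.5 * (dux[:, 1] + duy[:, 0])
    return np.sqrt(2.0 * (dux[:, 0] ** 2 + duy[:, 1] ** 2 + 2 * dxy ** 2))


@dataclass
class FlowSolution:
    """Converged blood velocity/pressure on the vessel mesh."""

    mesh: Mesh
    V_B: np.ndarray              # (N, 2) velocity (m/s)
    P_B_vessel: np.ndarray       # (N,) pressure (Pa)
    gamma_dot: np.ndarray        # (M,) element shear rate (1/s)
    mu_B_field: np.ndarray       # (M,) element apparent viscosity (Pa s)
    iterations: int
    residual: float

    def boundary_flux(self, tag: str) -> float:
        """Volumetric flux (m^2/s per unit depth) through a tagged edge
        set, positive outward."""
        sel = self.mesh.edge_tag == tag
        e = self.mesh.edges[sel]
        d = self.mesh.points[e[:, 1]] - self.mesh.points[e[:, 0]]
        L = np.hypot(d[:, 0], d[:, 1])
        n = np.column_stack([d[:, 1], -d[:, 0]]) / L[:, None]
        vmid = 0.5 * (self.V_B[e[:, 0]] + self.V_B[e[:, 1]])
        return float(((vmid * n).sum(axis=1) * L).sum())


def _convection_matrix(mesh: Mesh, w: np.ndarray, rho: float):
    """Picard convection ``rho * (w.grad)u`` tested against v."""
    wc = w[mesh.triangles].mean(axis=1)                   # (M, 2)
    b = mesh.basis_grads
    wd = np.einsum("kjd,kd->kj", b, wc)                   # (M, 3)
    vals = (mesh.areas / 3.0)[:, None, None] * wd[:, None, :] * rho
    vals = np.broadcast_to(vals, (mesh.n_tris, 3, 3))
    t = mesh.triangles
    rows = np.repeat(t, 3, axis=1).reshape(mesh.n_tris, 3, 3)
    cols = np.repeat(t[:, None, :], 3, axis=1)
    N = sp.coo_matrix((np.ravel(vals),
                       (np.ravel(rows), np.ravel(cols))),
                      shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()
    return sp.block_diag([N, N]).tocsr()[
        _interleave(mesh.n_nodes), :][:, _interleave(mesh.n_nodes)]


def _interleave(n):
    idx = np.empty(2 * n, dtype=np.int64)
    idx[0::2] = np.arange(n)
    idx[1::2] = np.arange(n) + n
    return idx


def solve_blood_flow(mesh: Mesh, F_mag, p: ParamSet,
                     stokes: bool = True, newtonian: bool = False,
                     tol: float = 1e-6, max_iter: int = 400,
                     stab_alpha: float = 0.05,
                     inlet_pressure: float | None = None,
                     outlet_pressure: float | None = None) -> FlowSolution:
    """Solve steady (generalized-Newtonian) vessel flow.

    ``F_mag`` is the Kelvin force density per element, shape (M, 2) (or
    None for no magnetic forcing).  Pressure boundary data default to
    ``p.P_inlet`` on tag "2" and ``p.P_outlet`` on tag "3".
    """
    n = mesh.n_nodes
    if F_mag is None:
        F_mag = np.zeros((mesh.n_tris, 2))
    F_mag = np.asarray(F_mag, float)
    P_in = p.P_inlet if inlet_pressure is None else inlet_pressure
    P_out = p.P_outlet if outlet_pressure is None else outlet_pressure

    B = div_matrix(mesh)                       # (N, 2N)
    h2 = 2.0 * mesh.areas                      # element size^2 proxy

    rhs_u = load_vector_tri(mesh, F_mag)
    rhs_u += edge_normal_load(mesh, mesh.edge_tag == "2", -P_in)
    rhs_u += edge_normal_load(mesh, mesh.edge_tag == "3", -P_out)

    wall_nodes = mesh.edge_nodes("wall", "wall_inner")
    fixed = np.concatenate([2 * wall_nodes, 2 * wall_nodes + 1])
    fixed = np.concatenate([fixed, np.array([], dtype=np.int64)])
    ndof = 3 * n

    V = np.zeros((n, 2))
    P = np.zeros(n)
    gd = np.ones(mesh.n_tris)
    mu = None
    resid = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        if newtonian or p.n_pl == 1.0:
            mu = np.full(mesh.n_tris, p.m_pl)
        else:
            target = apparent_viscosity(gd, p)
            # geometric under-relaxation keeps the shear-thinning
            # update from limit-cycling
            mu = target if mu is None else np.sqrt(mu * target)
        K = elastic_stiffness(mesh, 0.0, mu)   # int 2 mu D(u):D(v)
        if not stokes:
            K = K + _convection_matrix(mesh, V, p.rho_B)
        C = stiffness(mesh, stab_alpha * h2 / mu)
        A = sp.bmat([[K, -B.T], [-B, -C]], format="csr")
        rhs = np.concatenate([rhs_u, np.zeros(n)])
        x = solve_dirichlet(A, rhs, fixed, 0.0)
        V_new = x[:2 * n].reshape(n, 2)
        P_new = x[2 * n:]
        dv = np.linalg.norm(V_new - V) / max(np.linalg.norm(V_new), 1e-300)
        V, P = V_new, P_new
        gd = shear_rate(mesh, V)
        resid = dv
        if (newtonian or p.n_pl == 1.0) and stokes:
            break
        if dv < tol:
            break
    else:
        raise FlowError(
            f"Picard iteration did not converge: last increment {resid:.3e}")

    mu = (np.full(mesh.n_tris, p.m_pl) if (newtonian or p.n_pl == 1.0)
          else apparent_viscosity(gd, p))
    return FlowSolution(mesh=mesh, V_B=V, P_B_vessel=P, gamma_dot=gd,
                        mu_B_field=mu, iterations=it, residual=resid)


# ----------------------------------------------------------------------
# wall-pressure extraction
# ----------------------------------------------------------------------

def inner_wall_pressure(flow: FlowSolution):
    """Pressure on the inner capillary wall as (theta_sorted, P) arrays.

    These are the Dirichlet data for the tissue-scale blood pressure on
    the tumor/ring interface.
    """
    nodes = flow.mesh.edge_nodes("wall_inner")
    if len(nodes) == 0:
        raise FlowError("mesh has no inner-wall edges")
    pts = flow.mesh.points[nodes]
    th = np.arctan2(pts[:, 1], pts[:, 0])
    order = np.argsort(th)
    return th[order], flow.P_B_vessel[nodes][order]


def interp_wall_pressure(theta, P, query_theta):
    """Periodic linear interpolation of the wall-pressure trace."""
    q = np.mod(np.asarray(query_theta) + np.pi, 2 * np.pi) - np.pi
    th = np.concatenate([[theta[-1] - 2 * np.pi], theta,
                         [theta[0] + 2 * np.pi]])
    Pp = np.concatenate([[P[-1]], P, [P[0]]])
    return np.interp(q, th, Pp)


def wall_pressure_trace(flow: FlowSolution, wall_arc: str = "inner_upper",
                        n: int = 201) -> Profile:
    """Arc-length pressure profile along a named wall segment.

    ``inner_upper``: upper half of the inner ring wall (the segment
    facing the magnet), ``inner_full``: the whole inner wall.  The path
    coordinate is arc length over the tumor radius (so theta for the
    inner wall).
    """
    th, P = inner_wall_pressure(flow)
    if wall_arc == "inner_upper":
        q = np.linspace(0.0, np.pi, n)
    elif wall_arc == "inner_full":
        q = np.linspace(-np.pi, np.pi, n)
    else:
        raise FlowError(f"unknown wall segment {wall_arc!r}")
    vals = interp_wall_pressure(th, P, q)
    return Profile(path_id=f"wall_{wall_arc}", L_star=q, values=vals,
                   linear_average=float(np.mean(vals)))
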