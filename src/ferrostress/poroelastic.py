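"""Coupled tissue problem: Darcy interstitium, Starling exchange,
tissue-scale blood pressure and quasi-static linear poroelasticity.

The tissue is a fluid-saturated linear-elastic porous medium.  Three
nodal fields are solved on the tissue mesh, in one-way order:

1. ``P_B`` — tissue-scale blood pressure: ``-lap(P_B) + div(F_mag) = 0``
   with Dirichlet data on the tumor/ring interface taken from the
   vessel-flow wall pressure and natural (no-flux) conditions elsewhere.
2. ``P_i`` — interstitial pressure from the steady continuity equation
   ``div(eps_i V_i) = phi_B - phi_L`` with the Darcy closure
   ``eps_i V_i = (k/mu_i) (-grad P_i + eps_i F_mag)`` and the linear
   Starling source/sink terms; ``P_i = 0`` on the top and lateral tissue
   edges, no flow through the bottom.
3. ``u_t`` — displacement from ``div(sigma_total) = 0`` where
   ``sigma_total = lam e I + 2 mu E - (P_i + P_B) I`` (plane strain),
   with rollers (``u.n = 0``) on boundaries 1, 4, 5 and an optional
   boundary load on 4.

Because the steady problem is linear and the coupling triangular
(``P_B -> P_i -> u``), the three sparse direct solves reproduce the
monolithic solution exactly.  The scalar reduced system obtained by
taking divergences of the momentum balances is retained as a residual
oracle (:func:`reduced_system_residual`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import (Mesh, elastic_stiffness, load_div, load_flux, load_tri,
                  mass, nodal_average, solve_dirichlet, stiffness,
                  tri_gradient)
from .hemodynamics import interp_wall_pressure
from .params import ParamSet


class PoroError(RuntimeError):
    pass


def _region_of(tag: str) -> str:
    """Material region of a mesh tag: the thin capillary band and any
    feeder overlap behave as healthy tissue in the porous problem."""
    return "tumor" if tag == "tumor" else "healthy"


def starling_source(P_i, P_B, p: ParamSet, region: str):
    """Blood-to-interstitium filtration rate ``phi_B`` (1/s).

    ``phi_B = (S/V)Lp [ (P_B - P_i) - delta_B (pi_B - pi_i) ]`` with
    region-specific filtration coefficient and osmotic terms.
    """
    if region not in ("tumor", "healthy"):
        raise PoroError(f"unknown region {region!r}")
    Lp = p.LpS_over_V[region]
    return Lp * ((np.asarray(P_B) - np.asarray(P_i))
                 - p.delta_B[region] * (p.pi_B - p.pi_i[region]))


def starling_sink(P_i, p: ParamSet, region: str):
    """Interstitium-to-lymph drainage rate ``phi_L`` (1/s); zero in the
    tumor, which lacks functional lymphatics."""
    if region not in ("tumor", "healthy"):
        raise PoroError(f"unknown region {region!r}")
    return p.LpLSL_over_V[region] * (np.asarray(P_i) - p.P_L)


def _tri_coeffs(mesh: Mesh, p: ParamSet, region_override=None):
    regions = (np.asarray(region_override, dtype=object)
               if region_override is not None else mesh.region)
    reg = np.array([_region_of(t) for t in regions], dtype=object)
    def per(m):
        return np.where(reg == "tumor", m["tumor"], m["healthy"]).astype(float)
    return {
        "k_mu": per(p.k_over_mu_i),
        "LpS": per(p.LpS_over_V),
        "LpL": per(p.LpLSL_over_V),
        "delta": per(p.delta_B),
        "pi_i": per(p.pi_i),
    }


# ----------------------------------------------------------------------
# stage 1: tissue-scale blood pressure
# ----------------------------------------------------------------------

def interface_nodes(mesh: Mesh, R: float, tol: float = 1e-9) -> np.ndarray:
    r = np.hypot(mesh.points[:, 0], mesh.points[:, 1])
    return np.nonzero(np.abs(r - R) < tol)[0]


def solve_tissue_blood_pressure(mesh: Mesh, F_mag, wall_pressure,
                                p: ParamSet) -> np.ndarray:
    """Poisson solve for ``P_B`` with wall-pressure Dirichlet data.

    ``wall_pressure`` is either a ``(theta, P)`` pair from
    :func:`ferrostress.hemodynamics.inner_wall_pressure` or a scalar.
    """
    if F_mag is None:
        F_mag = np.zeros((mesh.n_tris, 2))
    nodes = interface_nodes(mesh, p.R_t)
    if len(nodes) == 0:
        raise PoroError("tissue mesh has no nodes on the tumor/ring "
                        "interface circle")
    if np.isscalar(wall_pressure):
        vals = np.full(len(nodes), float(wall_pressure))
    else:
        th_nodes = np.arctan2(mesh.points[nodes, 1], mesh.points[nodes, 0])
        theta, P = wall_pressure
        vals = interp_wall_pressure(theta, P, th_nodes)
    K = stiffness(mesh)
    rhs = load_flux(mesh, np.asarray(F_mag, float))
    return solve_dirichlet(K, rhs, nodes, vals)


# ----------------------------------------------------------------------
# stage 2: interstitial pressure
# ----------------------------------------------------------------------

def solve_interstitial_pressure(mesh: Mesh, P_B: np.ndarray, F_mag,
                                p: ParamSet,
                                dirichlet_tags=("4", "5"),
                                region_override=None) -> np.ndarray:
    """Interstitial pressure from Darcy continuity with Starling terms.

    The Starling terms are linear in ``P_i`` so this is a single
    symmetric positive-definite solve.  Passing ``dirichlet_tags=()``
    yields the all-natural (no-flux) problem, which stays well posed
    through the Starling mass term and relaxes to the pointwise
    equilibrium ``P_i = P_B - delta_B (pi_B - pi_i)`` when sources are
    uniform (the zero-dimensional limit).
    """
    if F_mag is None:
        F_mag = np.zeros((mesh.n_tris, 2))
    c = _tri_coeffs(mesh, p, region_override)
    A = stiffness(mesh, c["k_mu"]) + mass(mesh, c["LpS"] + c["LpL"])
    P_B_tri = np.asarray(P_B)[mesh.triangles].mean(axis=1)
    src = (c["LpS"] * (P_B_tri - c["delta"] * (p.pi_B - c["pi_i"]))
           + c["LpL"] * p.P_L)
    rhs = load_tri(mesh, src)
    rhs += p.eps_i * load_flux(mesh, c["k_mu"][:, None]
                               * np.asarray(F_mag, float))
    if dirichlet_tags:
        nodes = mesh.edge_nodes(*dirichlet_tags)
        return solve_dirichlet(A, rhs, nodes, 0.0)
    import scipy.sparse.linalg as spla
    return spla.spsolve(A.tocsc(), rhs)


# ----------------------------------------------------------------------
# stage 3: displacement
# ----------------------------------------------------------------------

def solve_displacement(mesh: Mesh, P_i: np.ndarray, P_B: np.ndarray,
                       p: ParamSet, f_area=None) -> np.ndarray:
    """Quasi-static displacement under the two pore-pressure fields.

    Rollers on boundaries 1 and 4 (u_y = 0) and 5 (u_x = 0); the
    optional boundary load ``f_area`` (a 2-vector, Pa) acts on the top
    edge in the weak sense.
    """
    K = elastic_stiffness(mesh, p.lam, p.mu_lame)
    rhs = load_div(mesh, np.asarray(P_i) + np.asarray(P_B))
    if f_area is not None:
        fx, fy = f_area
        sel = mesh.edge_tag == "4"
        from .fem import edge_load
        ex = edge_load(mesh, sel, fx)
        ey = edge_load(mesh, sel, fy)
        rhs[0::2] += ex
        rhs[1::2] += ey
    bottom_top = mesh.edge_nodes("1", "4")
    lateral = mesh.edge_nodes("5")
    fixed = np.concatenate([2 * bottom_top + 1, 2 * lateral])
    vals = np.zeros(len(fixed))
    if len(fixed) < 3:
        raise PoroError("insufficient displacement constraints")
    x = solve_dirichlet(K, rhs, fixed, vals)
    return x.reshape(mesh.n_nodes, 2)


# ----------------------------------------------------------------------
# bundle
# ----------------------------------------------------------------------

@dataclass
class PoroSolution:
    """Displacement, strains, pressures and exchange-rate fields."""

    mesh: Mesh
    u: np.ndarray                # (N, 2) displacement (m)
    P_i: np.ndarray              # (N,) interstitial pressure (Pa)
    P_B: np.ndarray              # (N,) tissue blood pressure (Pa)
    E_tri: np.ndarray            # (M, 3): exx, eyy, exy
    e_vol_tri: np.ndarray        # (M,) volumetric strain
    V_i_tri: np.ndarray          # (M, 2) interstitial velocity (m/s)
    phi_B_tri: np.ndarray        # (M,) source rate (1/s)
    phi_L_tri: np.ndarray        # (M,) sink rate (1/s)

    @property
    def V_t(self) -> np.ndarray:
        """Solid velocity; identically zero at steady state."""
        return np.zeros_like(self.u)

    def e_vol_nodal(self) -> np.ndarray:
        return nodal_average(self.mesh, self.e_vol_tri)


def solve_poroelastic(mesh: Mesh, P_B, F_mag, p: ParamSet,
                      f_area=None) -> PoroSolution:
    """Run stages 2-3 given the blood-pressure field and Kelvin force."""
    if F_mag is None:
        F_mag = np.zeros((mesh.n_tris, 2))
    F_mag = np.asarray(F_mag, float)
    P_B = np.asarray(P_B, float)
    P_i = solve_interstitial_pressure(mesh, P_B, F_mag, p)
    u = solve_displacement(mesh, P_i, P_B, p, f_area=f_area)

    dux = tri_gradient(mesh, u[:, 0])
    duy = tri_gradient(mesh, u[:, 1])
    E_tri = np.column_stack([dux[:, 0], duy[:, 1],
                             0.5 * (dux[:, 1] + duy[:, 0])])
    e_vol = E_tri[:, 0] + E_tri[:, 1]

    c = _tri_coeffs(mesh, p)
    gPi = tri_gradient(mesh, P_i)
    V_i = (c["k_mu"][:, None] * (-gPi + p.eps_i * F_mag)) / p.eps_i
    P_i_tri = P_i[mesh.triangles].mean(axis=1)
    P_B_tri = P_B[mesh.triangles].mean(axis=1)
    phi_B = (c["LpS"] * ((P_B_tri - P_i_tri)
                         - c["delta"] * (p.pi_B - c["pi_i"])))
    phi_L = c["LpL"] * (P_i_tri - p.P_L)
    return PoroSolution(mesh=mesh, u=u, P_i=P_i, P_B=P_B, E_tri=E_tri,
                        e_vol_tri=e_vol, V_i_tri=V_i, phi_B_tri=phi_B,
                        phi_L_tri=phi_L)


# ----------------------------------------------------------------------
# reduced-system residual oracle
# ----------------------------------------------------------------------

def _bump_tests(R: float, n_poly: int = 5):
    """Smooth test functions compactly supported on the tumor disk.

    ``q = (1 - s^2)^2 * P(x/R, y/R)`` with ``s = r/R`` and low-order
    polynomials ``P``; value and gradient vanish on the disk rim, so the
    reduced equations can be tested after two integrations by parts
    using only field *values* — no derivative recovery of the discrete
    strain is required.  Returns callables for q, grad(q), lap(q).
    """
    import sympy as sp

    x, y = sp.symbols("x y")
    s2 = (x ** 2 + y ** 2) / R ** 2
    bump = (1 - s2) ** 2
    polys = [sp.Integer(1), x / R, y / R, x * y / R ** 2,
             (x ** 2 - y ** 2) / R ** 2][:n_poly]
    out = []
    for P in polys:
        q = bump * P
        qx, qy = sp.diff(q, x), sp.diff(q, y)
        lap = sp.diff(q, x, 2) + sp.diff(q, y, 2)
        out.append(tuple(sp.lambdify((x, y), f, "numpy")
                         for f in (q, qx, qy, lap)))
    return out


def reduced_residuals(mesh: Mesh, p: ParamSet, e_field, P_i, P_B,
                      F_mag=None, phi_net_tri=None,
                      region_override=None) -> dict:
    """Normalized weak residuals of the derived scalar system.

    The three equations checked on the tumor disk, with
    ``c = 2*mu + lam``:

    1. ``c grad(e) - grad(P_i) - grad(P_B) = 0``
    2. ``c lap(e) - lap(P_B) + (mu_i/k)(phi_B - phi_L)
       - eps div(F_mag) = 0``
    3. ``-lap(P_B) + div(F_mag) = 0``

    Each is tested against smooth bump-polynomial functions supported
    inside the tumor (where the coefficients are uniform and the
    capillary source sheet and outer boundary play no role), with all
    derivatives moved onto the test functions.  ``e_field`` may be
    nodal (N,) or element-wise (M,).  ``phi_net_tri`` overrides the
    Starling net rate (manufactured-solution hook).  Each residual norm
    is normalized by the norm of its largest constituent term.
    """
    if F_mag is None:
        F_mag = np.zeros((mesh.n_tris, 2))
    F_mag = np.asarray(F_mag, float)
    c = _tri_coeffs(mesh, p, region_override)
    scale = 2.0 * p.mu_lame + p.lam

    # 3-point edge-midpoint quadrature on elements inside the disk
    tri_pts = mesh.points[mesh.triangles]                  # (M, 3, 2)
    qpts = 0.5 * (tri_pts + np.roll(tri_pts, -1, axis=1))  # (M, 3, 2)
    rc = np.hypot(*mesh.centroids.T)
    sel = rc < p.R_t
    w = (mesh.areas[sel] / 3.0)
    qx = qpts[sel, :, 0]
    qy = qpts[sel, :, 1]

    def at_q(field):
        f = np.asarray(field, float)
        if f.shape[0] == mesh.n_nodes:
            fv = f[mesh.triangles]                         # (M, 3)
            return 0.5 * (fv + np.roll(fv, -1, axis=1))[sel]
        return np.repeat(f[sel, None], 3, axis=1)

    e_q = at_q(e_field)
    Pi_q = at_q(np.asarray(P_i))
    PB_q = at_q(np.asarray(P_B))
    Fx_q = at_q(F_mag[:, 0])
    Fy_q = at_q(F_mag[:, 1])

    if phi_net_tri is None:
        P_i_tri = np.asarray(P_i)[mesh.triangles].mean(axis=1)
        P_B_tri = np.asarray(P_B)[mesh.triangles].mean(axis=1)
        phi_net = (c["LpS"] * ((P_B_tri - P_i_tri)
                               - c["delta"] * (p.pi_B - c["pi_i"]))
                   - c["LpL"] * (P_i_tri - p.P_L))
    else:
        phi_net = np.asarray(phi_net_tri)
    phi_q = at_q(phi_net)
    muk_q = at_q(1.0 / c["k_mu"])                  # mu_i/k

    def integ(vals):
        return float((w[:, None] * vals).sum())

    def mag(vals):
        # term magnitude: integral of |integrand| — a nondegenerate
        # scale even when the term itself integrates to ~zero
        return float((w[:, None] * np.abs(vals)).sum())

    r1_num = r1_den = 0.0
    r2_num = r2_den = 0.0
    r3_num = r3_den = 0.0
    for q_f, qx_f, qy_f, lap_f in _bump_tests(p.R_t):
        qv = q_f(qx, qy)
        gx = qx_f(qx, qy)
        gy = qy_f(qx, qy)
        lv = lap_f(qx, qy)
        # eq 1 against w = (q, 0) and (0, q):
        #   integral (c e - P_i - P_B) * dq/dx_i, sign-flipped by parts
        for g in (gx, gy):
            parts = [-scale * e_q * g, Pi_q * g, PB_q * g]
            r1_num += sum(integ(t) for t in parts) ** 2
            r1_den += max(mag(t) for t in parts) ** 2
        # eq 2: c e lap(q) - P_B lap(q) + (mu_i/k) phi_net q + eps F.grad(q)
        parts = [scale * e_q * lv, -PB_q * lv, muk_q * phi_q * qv,
                 p.eps_i * (Fx_q * gx + Fy_q * gy)]
        r2_num += sum(integ(t) for t in parts) ** 2
        r2_den += max(mag(t) for t in parts) ** 2
        # eq 3: -P_B lap(q) - F.grad(q)  (both derivatives moved to q)
        parts = [-PB_q * lv, -(Fx_q * gx + Fy_q * gy)]
        r3_num += sum(integ(t) for t in parts) ** 2
        r3_den += max(mag(t) for t in parts) ** 2
    return {
        "momentum_gradient": np.sqrt(r1_num / max(r1_den, 1e-300)),
        "strain_pressure": np.sqrt(r2_num / max(r2_den, 1e-300)),
        "blood_pressure": np.sqrt(r3_num / max(r3_den, 1e-300)),
    }


def reduced_system_residual(sol: PoroSolution, F_mag, p: ParamSet) -> dict:
    """Evaluate the reduced-system oracle on a computed solution."""
    return reduced_residuals(sol.mesh, p, sol.e_vol_tri, sol.P_i,
                             sol.P_B, F_mag)
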