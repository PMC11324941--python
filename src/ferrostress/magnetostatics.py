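"""Current-free magnetostatics of a permanent magnet over perfused tissue.

With no free currents the field intensity is curl-free and derives from
a scalar potential, ``H = -grad(psi)``.  Flux conservation
``div(B) = 0`` with the linear constitutive law

* ``B = mu0*H + B_rem`` inside the magnet (remanence source, mu_r = 1),
* ``B = mu0*mu_r_eff*H`` in ferrofluid-bearing regions,
* ``B = mu0*H`` in plain air/tissue,

yields the weak problem ``div(mu0*mu_r*grad(psi)) = div(B_rem)`` with
``psi = 0`` on the far boundary of the air box.  The ferrofluid
magnetization is the linear closure ``M = (mu_r_eff - 1)*H`` and the
body force on it is the Kelvin force ``(M.grad)B + (B.grad)M``, which
for the linear closure reduces to ``2*mu0*mu_r*chi*(H.grad)H``.

By default both the capillary blood *and* the tissue interstitium are
treated as ferrofluid-bearing (the interstitial momentum balance admits
a magnetic body force); restricting magnetization to the vessels is a
config switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import (Mesh, load_flux, nodal_average, solve_dirichlet, stiffness,
                  tri_gradient)
from .geometry import DomainGeometry, MagnetSpec
from .params import ParamSet, effective_permeability
from .stress import Profile, sample_along_path

FERROFLUID_REGIONS_ALL = ("tumor", "healthy", "vessel_ring",
                          "vessel_feed_in", "vessel_feed_out")
FERROFLUID_REGIONS_BLOOD = ("vessel_ring", "vessel_feed_in",
                            "vessel_feed_out")


class MagnetostaticsError(RuntimeError):
    pass


@dataclass
class MagneticSolution:
    """Scalar potential and derived vector fields on the magnetics mesh."""

    mesh: Mesh
    magnet: MagnetSpec
    psi: np.ndarray              # (N,) scalar potential (A)
    H: np.ndarray                # (N, 2) nodal field intensity (A/m)
    B: np.ndarray                # (N, 2) nodal flux density (T)
    M: np.ndarray                # (N, 2) nodal magnetization (A/m)
    mu_r_tri: np.ndarray         # (M,) relative permeability per element
    chi_eff: float               # ferrofluid susceptibility used
    mu_r_eff: float
    mu_0: float

    # cached recovered gradient of H, built lazily
    _gradH: np.ndarray = None

    def grad_H_nodal(self) -> np.ndarray:
        """Recovered nodal gradient of H, shape (N, 2, 2): [i, a, b] =
        d H_a / d x_b."""
        if self._gradH is None:
            g = np.empty((self.mesh.n_nodes, 2, 2))
            for a in range(2):
                g[:, a, :] = nodal_average(
                    self.mesh, tri_gradient(self.mesh, self.H[:, a]))
            self._gradH = g
        return self._gradH

    def B_magnitude(self) -> np.ndarray:
        return np.hypot(self.B[:, 0], self.B[:, 1])

    def force_at(self, pts: np.ndarray) -> np.ndarray:
        """Kelvin force density (N/m^3) of the ferrofluid at points.

        Evaluates ``2*mu0*mu_r_eff*chi_eff*(H.grad)H`` from the
        interpolated field; the caller decides where the ferrofluid
        actually is (the force is meaningful only there).
        """
        H = np.column_stack([self.mesh.interpolate(self.H[:, a], pts)
                             for a in range(2)])
        g = self.grad_H_nodal()
        F = np.zeros((len(pts), 2))
        for a in range(2):
            for b in range(2):
                dHa_db = self.mesh.interpolate(g[:, a, b], pts)
                F[:, a] += H[:, b] * dHa_db
        return 2.0 * self.mu_0 * self.mu_r_eff * self.chi_eff * F


def solve_potential(mesh: Mesh, magnet: MagnetSpec, p: ParamSet,
                    phi_ff: float | None = None,
                    magnetize_interstitium: bool = True) -> MagneticSolution:
    """Solve the scalar-potential problem and populate H, B and M."""
    if mesh.edges is None or not np.any(mesh.edge_tag == "far"):
        raise MagnetostaticsError(
            "mesh has no far boundary; the potential would be singular")
    phi = p.phi_ff if phi_ff is None else phi_ff
    mu_r_eff = effective_permeability(p, phi)
    chi_eff = mu_r_eff - 1.0
    ff_regions = (FERROFLUID_REGIONS_ALL if magnetize_interstitium
                  else FERROFLUID_REGIONS_BLOOD)

    mu_r = np.ones(mesh.n_tris)
    in_ff = mesh.tris_in(*ff_regions)
    mu_r[in_ff] = mu_r_eff
    in_mag = mesh.tris_in("magnet")
    mu_r[in_mag] = p.mu_r_magnet

    B_rem_tri = np.zeros((mesh.n_tris, 2))
    B_rem_tri[in_mag] = magnet.B_rem_vector

    K = stiffness(mesh, p.mu_0 * mu_r)
    rhs = load_flux(mesh, B_rem_tri)
    far_nodes = mesh.edge_nodes("far")
    psi = solve_dirichlet(K, rhs, far_nodes, 0.0)

    H_tri = -tri_gradient(mesh, psi)
    B_tri = p.mu_0 * mu_r[:, None] * H_tri + B_rem_tri
    M_tri = np.zeros_like(H_tri)
    M_tri[in_ff] = chi_eff * H_tri[in_ff]

    H = nodal_average(mesh, H_tri)
    B = nodal_average(mesh, B_tri)
    M = nodal_average(mesh, M_tri)
    return MagneticSolution(mesh=mesh, magnet=magnet, psi=psi, H=H, B=B,
                            M=M, mu_r_tri=mu_r, chi_eff=chi_eff,
                            mu_r_eff=mu_r_eff, mu_0=p.mu_0)



def kelvin_force(sol: MagneticSolution) -> np.ndarray:
    """Per-element Kelvin force density ``(M.grad)B + (B.grad)M``.

    Evaluated from the recovered nodal B and M fields; identically zero
    outside ferrofluid-bearing regions (where M = 0).
    """
    if sol.B is None or sol.M is None:
        raise MagnetostaticsError("B and M must be populated")
    mesh = sol.mesh
    ff = sol.mu_r_tri == sol.mu_r_eff if sol.chi_eff != 0 else \
        np.zeros(mesh.n_tris, bool)
    Bc = sol.B[mesh.triangles].mean(axis=1)
    Mc = sol.M[mesh.triangles].mean(axis=1)
    F = np.zeros((mesh.n_tris, 2))
    for a in range(2):
        gB = tri_gradient(mesh, sol.B[:, a])
        gM = tri_gradient(mesh, sol.M[:, a])
        F[:, a] = (Mc * gB).sum(axis=1) + (Bc * gM).sum(axis=1)
    F[~ff] = 0.0
    return F


def sample_B_profiles(sol: MagneticSolution, g: DomainGeometry,
                      n: int = 201) -> dict:
    """|B| along the tumor's horizontal diameter and upper semicircle."""
    Bmag = sol.B_magnitude()
    p = g.params
    return {
        "horizontal_diameter": sample_along_path(
            sol.mesh, Bmag, "horizontal_diameter", p, n=n),
        "upper_semicircle": sample_along_path(
            sol.mesh, Bmag, "upper_semicircle", p, n=n),
    }
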