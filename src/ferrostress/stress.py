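"""Total-stress assembly, von Mises post-processing and profile extraction.

The total stress of the porous tissue is the drained elastic stress plus
two isotropic fluid contributions::

    sigma_total = lam*e*I + 2*mu*E  -  P_i*I  -  P_B*I

with ``e = tr(E)`` the volumetric strain, ``P_i`` the interstitial and
``P_B`` the tissue-scale blood pressure.  The 2D solve is plane strain
(the tumor is conceptually a long cylinder), so the out-of-plane normal
stress ``sigma_zz = lam*e - P_i - P_B`` is carried into the von Mises
invariant.  Stress is reported nondimensionally as
``sigma* = sigma_vm / (2*mu + lam)`` against the dimensionless path
coordinate ``L* = L / R_t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import Mesh, nodal_average, tri_gradient
from .params import ParamSet, stress_scale

PATH_IDS = ("horizontal_diameter", "upper_semicircle")


class StressError(ValueError):
    pass


@dataclass
class Profile:
    """A quantity sampled along one of the tumor's reference paths."""

    path_id: str
    L_star: np.ndarray          # dimensionless path coordinate L/R_t
    values: np.ndarray
    linear_average: float = 0.0
    fit: str = "mean"
    fit_coeffs: tuple = ()

    def __post_init__(self):
        if len(self.L_star) != len(self.values):
            raise StressError("profile coordinate/value length mismatch")
        if np.any(np.diff(self.L_star) <= 0):
            raise StressError("profile samples must be strictly ordered")


def _linear_summary(L_star, values, fit):
    if fit == "mean":
        return float(np.mean(values)), ()
    if fit == "least_squares":
        coeffs = np.polyfit(L_star, values, 1)
        mid = 0.5 * (L_star[0] + L_star[-1])
        return float(np.polyval(coeffs, mid)), tuple(coeffs)
    raise StressError(f"unknown linear-average fit {fit!r}")


def path_points(path_id: str, p: ParamSet, n: int = 201):
    """Sample points and L* coordinates of a tumor reference path.

    ``horizontal_diameter``: the segment y = 0, x in [-R_t, R_t], with
    L* = x/R_t in [-1, 1].  ``upper_semicircle``: the arc r = R_t,
    theta in [0, pi], with L* the arc length over R_t, i.e. theta.
    Points are pulled inward by a relative 1e-9 so they always land
    inside the triangulation.
    """
    if n < 2:
        raise StressError("need at least two samples")
    shrink = 1.0 - 1e-9
    if path_id == "horizontal_diameter":
        L = np.linspace(-1.0, 1.0, n)
        pts = np.column_stack([L * p.R_t * shrink, np.zeros(n)])
        return pts, L
    if path_id == "upper_semicircle":
        th = np.linspace(0.0, np.pi, n)
        r = p.R_t * shrink
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        return pts, th
    raise StressError(f"unknown path {path_id!r}")


def sample_along_path(mesh: Mesh, nodal_field: np.ndarray, path_id: str,
                      p: ParamSet, n: int = 201,
                      fit: str = "mean") -> Profile:
    """Sample a nodal field along a reference path into a :class:`Profile`."""
    pts, L = path_points(path_id, p, n)
    inside = mesh.find(pts)
    if np.all(inside < 0):
        raise StressError(f"path {path_id!r} lies outside the mesh")
    vals = mesh.interpolate(nodal_field, pts)
    avg, coeffs = _linear_summary(L, vals, fit)
    return Profile(path_id=path_id, L_star=L, values=vals,
                   linear_average=avg, fit=fit, fit_coeffs=coeffs)


@dataclass
class StressField:
    """Total-stress tensor and von Mises fields on the tissue mesh."""

    mesh: Mesh
    sigma_tri: np.ndarray        # (M, 4): xx, yy, xy, zz
    sigma_vm_tri: np.ndarray     # (M,)
    sigma_vm: np.ndarray         # (N,) recovered nodal von Mises
    sigma_star: np.ndarray       # (N,) sigma_vm / (2 mu + lam)
    scale: float


def von_mises(sigma: np.ndarray) -> np.ndarray:
    """Von Mises invariant of (…, 4) stress rows [xx, yy, xy, zz]."""
    sxx, syy, sxy, szz = (sigma[..., i] for i in range(4))
    return np.sqrt(0.5 * ((sxx - syy) ** 2 + (syy - szz) ** 2
                          + (szz - sxx) ** 2) + 3.0 * sxy ** 2)


def assemble_stress(sol, p: ParamSet) -> StressField:
    """Build the total-stress tensor field from a poroelastic solution.

    ``sol`` provides nodal displacement ``u`` and pressures ``P_i``,
    ``P_B`` on ``sol.mesh``; strains are element-wise constants.
    """
    mesh = sol.mesh
    dux = tri_gradient(mesh, sol.u[:, 0])
    duy = tri_gradient(mesh, sol.u[:, 1])
    exx, eyy = dux[:, 0], duy[:, 1]
    exy = 0.5 * (dux[:, 1] + duy[:, 0])
    e = exx + eyy
    P = (sol.P_i + sol.P_B)[mesh.triangles].mean(axis=1)
    lam, mu = p.lam, p.mu_lame
    sigma = np.empty((mesh.n_tris, 4))
    sigma[:, 0] = lam * e + 2 * mu * exx - P
    sigma[:, 1] = lam * e + 2 * mu * eyy - P
    sigma[:, 2] = 2 * mu * exy
    sigma[:, 3] = lam * e - P
    vm_tri = von_mises(sigma)
    vm = nodal_average(mesh, vm_tri)
    scale = stress_scale(p)
    return StressField(mesh=mesh, sigma_tri=sigma, sigma_vm_tri=vm_tri,
                       sigma_vm=vm, sigma_star=vm / scale, scale=scale)


def sample_stress_profile(fieldobj: StressField, path_id: str, p: ParamSet,
                          n: int = 201, fit: str = "mean") -> Profile:
    """Dimensionless von Mises stress along a tumor reference path."""
    return sample_along_path(fieldobj.mesh, fieldobj.sigma_star, path_id,
                             p, n=n, fit=fit)


def percent_change(avg_a: float, avg_ref: float) -> float:
    """Signed percent change of ``avg_a`` relative to ``avg_ref``."""
    if avg_ref == 0:
        raise StressError("percent change undefined for zero reference")
    return 100.0 * (avg_a - avg_ref) / avg_ref
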