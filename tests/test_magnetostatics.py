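import numpy as np
import pytest
from scipy.spatial import cKDTree

from ferrostress import (MagnetSpec, ParamSet, mesh_magnetics, place_magnet,
                         retag_magnet, sample_B_profiles, solve_potential,
                         kelvin_force, build_domain)
from ferrostress.fem import tri_gradient
from ferrostress.magnetostatics import MagnetostaticsError


def analytic_cylinder_B(pts, magnet, mu_0):
    """Closed-form field of a uniformly magnetized cylinder in free space.

    Interior: B = B_rem / 2, uniform.  Exterior: 2D line-dipole field of
    moment M0 * pi * a^2.
    """
    c = np.asarray(magnet.center)
    a = magnet.radius
    M0 = magnet.B_rem_vector / mu_0
    d = pts - c
    r2 = (d ** 2).sum(axis=1)
    inside = r2 < a * a
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = d / np.sqrt(r2)[:, None]
        B_out = (mu_0 * (a * a / (2 * r2))[:, None]
                 * (2 * rhat * (rhat @ M0)[:, None] - M0))
    B_in = np.broadcast_to(mu_0 * M0 / 2, pts.shape)
    return np.where(inside[:, None], B_in, B_out)


def cylinder_oracle_error(p, h, box=0.2):
    """L2 error of the interior field vs the analytic B_rem/2."""
    magnet = place_magnet("SC", 0.03, p, B_rem=1.5)
    mesh = mesh_magnetics(p, magnet, box_halfsize=box, h_fine=h,
                          h_mid=2.5 * h)
    sol = solve_potential(mesh, magnet, p, phi_ff=0.0)  # free space
    in_mag = mesh.tris_in("magnet")
    H_tri = -tri_gradient(mesh, sol.psi)
    B_tri = p.mu_0 * H_tri
    B_tri[in_mag] += magnet.B_rem_vector
    w = mesh.areas[in_mag]
    exact = magnet.B_rem_vector / 2
    num = (w[:, None] * (B_tri[in_mag] - exact) ** 2).sum()
    return np.sqrt(num / (w.sum() * (exact ** 2).sum()))


class TestCylinderOracle:
    def test_interior_field_matches_closed_form(self, p):
        assert cylinder_oracle_error(p, h=3e-4) < 0.02

    def test_error_decreases_under_refinement(self, p):
        assert cylinder_oracle_error(p, h=3.5e-4) < \
            cylinder_oracle_error(p, h=7e-4)

    def test_exterior_dipole_field(self, p):
        magnet = place_magnet("SC", 0.03, p, B_rem=1.5)
        mesh = mesh_magnetics(p, magnet, box_halfsize=0.2, h_fine=3e-4,
                              h_mid=7.5e-4)
        sol = solve_potential(mesh, magnet, p, phi_ff=0.0)
        pts = np.array([[0.0, 0.0], [0.0, 0.015], [0.012, 0.03]])
        B_num = np.column_stack([mesh.interpolate(sol.B[:, a], pts)
                                 for a in range(2)])
        B_ex = analytic_cylinder_B(pts, magnet, p.mu_0)
        scale = np.abs(B_ex).max()
        assert np.abs(B_num - B_ex).max() < 0.05 * scale


class TestSolvePotential:
    def test_zero_remanence_gives_zero_fields(self, p):
        magnet = place_magnet("HR", p=p, B_rem=0.0)
        mesh = mesh_magnetics(p, magnet, h_fine=8e-4, h_mid=2e-3)
        sol = solve_potential(mesh, magnet, p)
        assert np.allclose(sol.psi, 0.0)
        assert np.allclose(sol.B, 0.0)
        assert np.allclose(sol.M, 0.0)

    def test_missing_far_boundary_raises(self, p):
        magnet = place_magnet("HR", p=p)
        mesh = mesh_magnetics(p, magnet, h_fine=8e-4, h_mid=2e-3)
        mesh.edge_tag[:] = "not_far"
        with pytest.raises(MagnetostaticsError, match="far"):
            solve_potential(mesh, magnet, p)

    def test_field_decays_into_tissue(self, p):
        """|B| is largest near the magnet-side boundary and decays with
        depth below it."""
        magnet = place_magnet("HR", p=p, B_rem=1.5)
        mesh = mesh_magnetics(p, magnet, h_fine=8e-4, h_mid=2e-3)
        sol = solve_potential(mesh, magnet, p)
        ys = np.array([0.009, 0.004, 0.0, -0.005, -0.009])
        pts = np.column_stack([np.zeros_like(ys), ys])
        Bm = np.hypot(mesh.interpolate(sol.B[:, 0], pts),
                      mesh.interpolate(sol.B[:, 1], pts))
        assert np.all(np.diff(Bm) < 0)

    def test_mirrored_placement_gives_mirrored_fields(self, p):
        mR = MagnetSpec("circle", (0.02, 0.03), 1.5, (0, -1), radius=0.005)
        mL = MagnetSpec("circle", (-0.02, 0.03), 1.5, (0, -1), radius=0.005)
        mesh = mesh_magnetics(p, mR, h_fine=8e-4, h_mid=2e-3)
        kd = cKDTree(mesh.points)
        d, idx = kd.query(mesh.points * np.array([-1.0, 1.0]))
        assert d.max() == 0.0
        solR = solve_potential(mesh, mR, p, 0.5)
        solL = solve_potential(retag_magnet(mesh, p, mL), mL, p, 0.5)
        scale = np.abs(solR.psi).max()
        assert np.abs(solR.psi - solL.psi[idx]).max() < 1e-10 * scale
        B_mirr = solL.B[idx] * np.array([-1.0, 1.0])
        assert np.abs(solR.B - B_mirr).max() < 1e-10 * np.abs(solR.B).max()


class TestKelvinForce:
    def test_uniform_fields_give_zero_force(self, p):
        magnet = place_magnet("HR", p=p)
        mesh = mesh_magnetics(p, magnet, h_fine=1e-3, h_mid=2.5e-3)
        sol = solve_potential(mesh, magnet, p)
        sol.B[:] = [0.1, 0.2]
        sol.M[:] = [1000.0, -500.0]
        F = kelvin_force(sol)
        assert np.abs(F).max() < 1e-6 * 0.2 * 1000 / p.R_t

    def test_no_ferrofluid_no_force(self, p):
        magnet = place_magnet("HR", p=p, B_rem=1.5)
        mesh = mesh_magnetics(p, magnet, h_fine=8e-4, h_mid=2e-3)
        sol = solve_potential(mesh, magnet, p, phi_ff=0.0)
        assert np.allclose(kelvin_force(sol), 0.0)
        assert np.allclose(sol.force_at(np.zeros((3, 2))), 0.0)

    def test_force_matches_finite_difference_oracle(self, p):
        """(M.grad)B + (B.grad)M for linear media equals
        2 mu0 mu_r chi (H.grad)H; cross-check the field-gradient part
        against central differences of the interpolated H field."""
        magnet = place_magnet("SC", p=p, B_rem=1.5)
        mesh = mesh_magnetics(p, magnet, h_fine=5e-4, h_mid=1.25e-3)
        sol = solve_potential(mesh, magnet, p, phi_ff=0.5)
        xs = np.linspace(-2e-3, 2e-3, 5)
        pts = np.column_stack([xs, np.full_like(xs, 2e-3)])
        F = sol.force_at(pts)
        eps = 1e-4
        def H_at(q):
            return np.column_stack([mesh.interpolate(sol.H[:, a], q)
                                    for a in range(2)])
        H = H_at(pts)
        F_fd = np.zeros_like(F)
        for b, dv in ((0, np.array([eps, 0.0])), (1, np.array([0.0, eps]))):
            dH = (H_at(pts + dv) - H_at(pts - dv)) / (2 * eps)
            F_fd += H[:, [b]] * dH
        F_fd *= 2 * p.mu_0 * sol.mu_r_eff * sol.chi_eff
        assert np.abs(F - F_fd).max() < 0.15 * np.abs(F_fd).max()


@pytest.fixture(scope="module")
def profiles(p):
    out = {}
    for sid in ("HR", "VR", "SC", "BC"):
        magnet = place_magnet(sid, p=p, B_rem=1.5)
        mesh = mesh_magnetics(p, magnet, h_fine=8e-4, h_mid=2e-3)
        sol = solve_potential(mesh, magnet, p, 0.5)
        g = build_domain(p, magnet)
        out[sid] = sample_B_profiles(sol, g)
    return out


class TestBProfiles:
    def test_big_circle_dominates_small_circle_pointwise(self, profiles):
        for pid in ("horizontal_diameter", "upper_semicircle"):
            assert np.all(profiles["BC"][pid].values
                          >= profiles["SC"][pid].values)

    def test_horizontal_beats_vertical_on_diameter_mean(self, profiles):
        assert (profiles["HR"]["horizontal_diameter"].linear_average
                > profiles["VR"]["horizontal_diameter"].linear_average)

    def test_zero_remanence_flat_profiles(self, p):
        magnet = place_magnet("HR", p=p, B_rem=0.0)
        mesh = mesh_magnetics(p, magnet, h_fine=1e-3, h_mid=2.5e-3)
        sol = solve_potential(mesh, magnet, p)
        prof = sample_B_profiles(sol, build_domain(p, magnet))
        assert np.allclose(prof["horizontal_diameter"].values, 0.0)

    def test_tumor_field_decreases_with_magnet_distance(self, p):
        means = []
        for d in (0.015, 0.025, 0.035):
            magnet = place_magnet("HR", d, p, B_rem=1.5)
            mesh = mesh_magnetics(p, magnet, h_fine=8e-4, h_mid=2e-3)
            sol = solve_potential(mesh, magnet, p, 0.5)
            prof = sample_B_profiles(sol, build_domain(p, magnet))
            means.append(prof["horizontal_diameter"].linear_average)
        assert means[0] > means[1] > means[2]
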