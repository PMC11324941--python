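import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ferrostress import (ParamSet, assemble_stress, percent_change,
                         sample_along_path, sample_stress_profile,
                         solve_poroelastic, solve_tissue_blood_pressure,
                         stress_scale, von_mises)
from ferrostress.hemodynamics import inner_wall_pressure, solve_blood_flow
from ferrostress.poroelastic import PoroSolution
from ferrostress.stress import StressError


def make_solution(mesh, u, P_i, P_B):
    """Wrap prescribed fields in a PoroSolution for stress assembly."""
    z = np.zeros(mesh.n_tris)
    return PoroSolution(mesh=mesh, u=u, P_i=P_i, P_B=P_B,
                        E_tri=np.zeros((mesh.n_tris, 3)), e_vol_tri=z,
                        V_i_tri=np.zeros((mesh.n_tris, 2)),
                        phi_B_tri=z, phi_L_tri=z)


class TestAssembleStress:
    def test_zero_fields_zero_stress(self, p, tissue_mesh):
        n = tissue_mesh.n_nodes
        sf = assemble_stress(make_solution(tissue_mesh,
                                           np.zeros((n, 2)),
                                           np.zeros(n), np.zeros(n)), p)
        assert np.abs(sf.sigma_tri).max() == 0.0
        assert np.abs(sf.sigma_vm).max() == 0.0

    def test_pure_pressure_has_zero_von_mises(self, p, tissue_mesh):
        """Isotropic stress (-2 p0 I) has a vanishing deviator."""
        n = tissue_mesh.n_nodes
        p0 = 350.0
        sf = assemble_stress(make_solution(tissue_mesh,
                                           np.zeros((n, 2)),
                                           np.full(n, p0),
                                           np.full(n, p0)), p)
        assert np.allclose(sf.sigma_tri[:, 0], -2 * p0)
        assert np.allclose(sf.sigma_tri[:, 3], -2 * p0)
        assert np.abs(sf.sigma_vm_tri).max() < 1e-9 * p0

    def test_uniaxial_strain_closed_form(self, p, tissue_mesh):
        """E = diag(eps0, 0): plane-strain von Mises is 2 mu eps0."""
        eps0 = 1e-3
        n = tissue_mesh.n_nodes
        u = np.column_stack([eps0 * tissue_mesh.points[:, 0], np.zeros(n)])
        sf = assemble_stress(make_solution(tissue_mesh, u, np.zeros(n),
                                           np.zeros(n)), p)
        expect = 2 * p.mu_lame * eps0
        assert np.allclose(sf.sigma_vm_tri, expect, rtol=1e-9)
        # component check against (lam+2mu, lam, 0, lam)*eps0
        assert np.allclose(sf.sigma_tri[:, 0], (p.lam + 2 * p.mu_lame) * eps0)
        assert np.allclose(sf.sigma_tri[:, 1], p.lam * eps0)
        assert np.allclose(sf.sigma_tri[:, 3], p.lam * eps0)

    def test_dimensionless_scaling_recovers_vm(self, p, tissue_mesh):
        n = tissue_mesh.n_nodes
        u = np.column_stack([1e-4 * tissue_mesh.points[:, 1] ** 2 / p.R_t,
                             np.zeros(n)])
        sf = assemble_stress(make_solution(tissue_mesh, u, np.zeros(n),
                                           np.zeros(n)), p)
        assert np.allclose(sf.sigma_star * stress_scale(p), sf.sigma_vm,
                           rtol=1e-12)


class TestVonMisesInvariance:
    @settings(derandomize=True, max_examples=40)
    @given(sxx=st.floats(-1e5, 1e5), syy=st.floats(-1e5, 1e5),
           sxy=st.floats(-1e5, 1e5), szz=st.floats(-1e5, 1e5),
           th=st.floats(0, 2 * np.pi))
    def test_rotation_invariance(self, sxx, syy, sxy, szz, th):
        """In-plane rotation of the stress tensor leaves vm unchanged."""
        c, s = np.cos(th), np.sin(th)
        R = np.array([[c, -s], [s, c]])
        S = np.array([[sxx, sxy], [sxy, syy]])
        Sr = R @ S @ R.T
        a = von_mises(np.array([sxx, syy, sxy, szz]))
        b = von_mises(np.array([Sr[0, 0], Sr[1, 1], Sr[0, 1], szz]))
        assert a == pytest.approx(b, rel=1e-9, abs=1e-6)


@pytest.fixture(scope="module")
def baseline_stress(p, tissue_mesh, flow_no_force):
    wall = inner_wall_pressure(flow_no_force)
    P_B = solve_tissue_blood_pressure(tissue_mesh, None, wall, p)
    sol = solve_poroelastic(tissue_mesh, P_B, None, p)
    return assemble_stress(sol, p)


class TestProfiles:
    def test_boundary_exceeds_center(self, p, baseline_stress):
        prof = sample_stress_profile(baseline_stress,
                                     "horizontal_diameter", p)
        center = prof.values[len(prof.values) // 2]
        assert prof.values[0] > 2 * center
        assert prof.values[-1] > 2 * center

    def test_profile_near_symmetric(self, p, baseline_stress):
        prof = sample_stress_profile(baseline_stress,
                                     "horizontal_diameter", p)
        v = prof.values
        asym = np.abs(v - v[::-1]).max() / np.abs(v).max()
        assert asym < 0.4          # inlet/outlet asymmetry only

    def test_zero_field_flat_profile(self, p, tissue_mesh):
        n = tissue_mesh.n_nodes
        sf = assemble_stress(make_solution(tissue_mesh, np.zeros((n, 2)),
                                           np.zeros(n), np.zeros(n)), p)
        prof = sample_stress_profile(sf, "upper_semicircle", p)
        assert np.all(prof.values == 0.0)
        assert prof.linear_average == 0.0

    def test_sample_count_and_ordering(self, p, baseline_stress):
        prof = sample_stress_profile(baseline_stress, "upper_semicircle",
                                     p, n=257)
        assert len(prof.values) == 257
        assert np.all(np.diff(prof.L_star) > 0)
        assert prof.L_star[-1] == pytest.approx(np.pi)

    def test_least_squares_summary_flag(self, p, baseline_stress):
        prof = sample_stress_profile(baseline_stress,
                                     "horizontal_diameter", p,
                                     fit="least_squares")
        assert len(prof.fit_coeffs) == 2
        # symmetric path: fitted midpoint value matches the mean closely
        mean = sample_stress_profile(baseline_stress,
                                     "horizontal_diameter",
                                     p).linear_average
        assert prof.linear_average == pytest.approx(mean, rel=1e-6)

    def test_unknown_path_raises(self, p, baseline_stress):
        with pytest.raises(StressError):
            sample_stress_profile(baseline_stress, "diagonal", p)

    def test_sample_along_path_interpolates_nodal_field(self, p,
                                                        tissue_mesh):
        f = tissue_mesh.points[:, 0] / p.R_t
        prof = sample_along_path(tissue_mesh, f, "horizontal_diameter", p)
        assert np.allclose(prof.values, prof.L_star, atol=1e-6)


class TestPercentChange:
    @pytest.mark.parametrize("a,ref,expect", [(1.25, 1.0, 25.0),
                                              (1.73, 1.0, 73.0),
                                              (3.3, 3.3, 0.0),
                                              (0.5, 1.0, -50.0)])
    def test_examples(self, a, ref, expect):
        assert percent_change(a, ref) == pytest.approx(expect)

    def test_zero_reference_raises(self):
        with pytest.raises(StressError):
            percent_change(1.0, 0.0)
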