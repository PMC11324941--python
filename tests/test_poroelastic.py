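import numpy as np
import pytest

from ferrostress import (ParamSet, mesh_tissue, reduced_residuals,
                         reduced_system_residual, solve_poroelastic,
                         solve_tissue_blood_pressure, starling_sink,
                         starling_source)
from ferrostress.fem import tri_gradient
from ferrostress.hemodynamics import inner_wall_pressure
from ferrostress.poroelastic import (PoroError, solve_displacement,
                                     solve_interstitial_pressure)


class TestStarling:
    def test_tumor_source_arithmetic(self, p):
        # 42.2e-8 * (1000 - 0.82*(2666 - 1999.83))
        val = starling_source(0.0, 1000.0, p, "tumor")
        assert val == pytest.approx(1.9148e-4, rel=1e-3)

    def test_equilibrium_is_zero(self, p):
        P_B = 800.0
        P_i = P_B - p.delta_B["tumor"] * (p.pi_B - p.pi_i["tumor"])
        assert starling_source(P_i, P_B, p, "tumor") == pytest.approx(0.0,
                                                                      abs=1e-18)

    def test_zero_coefficient_zero_rate(self):
        q = ParamSet(LpS_over_V={"tumor": 0.0, "healthy": 0.0})
        assert starling_source(0.0, 5000.0, q, "healthy") == 0.0

    def test_lymph_drainage_healthy(self, p):
        assert starling_sink(500.0, p, "healthy") == pytest.approx(5.0e-5)

    def test_lymph_absent_in_tumor(self, p):
        assert starling_sink(12345.0, p, "tumor") == 0.0

    def test_lymph_equilibrium(self, p):
        assert starling_sink(p.P_L, p, "healthy") == 0.0

    def test_unknown_region_raises(self, p):
        with pytest.raises(PoroError):
            starling_source(0.0, 0.0, p, "bone")


class TestBloodPressureField:
    def test_uniform_wall_gives_constant(self, p, tissue_mesh):
        P_B = solve_tissue_blood_pressure(tissue_mesh, None, 750.0, p)
        assert np.allclose(P_B, 750.0, atol=1e-8 * 750)

    def test_harmonic_extremes_on_data(self, p, tissue_mesh):
        th = np.linspace(-np.pi, np.pi, 361)
        wall = (th, 1000.0 + 300.0 * np.sin(th))
        P_B = solve_tissue_blood_pressure(tissue_mesh, None, wall, p)
        assert P_B.max() <= 1300.0 + 1e-6
        assert P_B.min() >= 700.0 - 1e-6

    def test_interface_values_match_data(self, p, tissue_mesh):
        th = np.linspace(-np.pi, np.pi, 361)
        wall = (th, 1000.0 + 300.0 * np.sin(th))
        P_B = solve_tissue_blood_pressure(tissue_mesh, None, wall, p)
        r = np.hypot(*tissue_mesh.points.T)
        nodes = np.nonzero(np.abs(r - p.R_t) < 1e-9)[0]
        th_n = np.arctan2(tissue_mesh.points[nodes, 1],
                          tissue_mesh.points[nodes, 0])
        assert np.allclose(P_B[nodes], 1000.0 + 300.0 * np.sin(th_n),
                           atol=0.5)


class TestInterstitialPressure:
    def test_zero_dimensional_starling_equilibrium(self, p, tissue_mesh):
        """Uniform no-flux tumor limit: P_i relaxes to the pointwise
        Starling equilibrium P_B - delta_B (pi_B - pi_i)."""
        P0 = 1200.0
        override = np.full(tissue_mesh.n_tris, "tumor", dtype=object)
        P_i = solve_interstitial_pressure(
            tissue_mesh, np.full(tissue_mesh.n_nodes, P0), None, p,
            dirichlet_tags=(), region_override=override)
        expect = P0 - p.delta_B["tumor"] * (p.pi_B - p.pi_i["tumor"])
        assert np.abs(P_i - expect).max() < 5e-3 * abs(expect)

    def test_elevated_core_drops_to_boundary(self, p, tissue_mesh,
                                             flow_no_force):
        wall = inner_wall_pressure(flow_no_force)
        P_B = solve_tissue_blood_pressure(tissue_mesh, None, wall, p)
        P_i = solve_interstitial_pressure(tissue_mesh, P_B, None, p)
        center = np.argmin(np.hypot(*tissue_mesh.points.T))
        outer = tissue_mesh.edge_nodes("4", "5")
        assert P_i[center] > 10 * np.abs(P_i[outer]).max() + 1.0
        assert np.allclose(P_i[outer], 0.0, atol=1e-9)


class TestDisplacement:
    def test_zero_loads_zero_solution(self, p, tissue_mesh):
        u = solve_displacement(tissue_mesh, np.zeros(tissue_mesh.n_nodes),
                               np.zeros(tissue_mesh.n_nodes), p)
        assert np.abs(u).max() == 0.0

    def test_rollers_enforced(self, p, tissue_mesh):
        P = np.full(tissue_mesh.n_nodes, 500.0)
        u = solve_displacement(tissue_mesh, P, 0 * P, p)
        assert np.abs(u[tissue_mesh.edge_nodes("1", "4"), 1]).max() == 0.0
        assert np.abs(u[tissue_mesh.edge_nodes("5"), 0]).max() == 0.0


@pytest.fixture(scope="module")
def baseline(p, tissue_mesh, flow_no_force):
    wall = inner_wall_pressure(flow_no_force)
    P_B = solve_tissue_blood_pressure(tissue_mesh, None, wall, p)
    return solve_poroelastic(tissue_mesh, P_B, None, p)


class TestPoroSolution:
    def test_strain_consistency(self, tissue_mesh, baseline):
        """e_vol equals tr(E) equals div(u) element-wise."""
        dux = tri_gradient(tissue_mesh, baseline.u[:, 0])
        duy = tri_gradient(tissue_mesh, baseline.u[:, 1])
        div_u = dux[:, 0] + duy[:, 1]
        scale = np.abs(div_u).max()
        assert np.abs(baseline.e_vol_tri - div_u).max() < 1e-12 * scale
        assert np.abs(baseline.E_tri[:, 0] + baseline.E_tri[:, 1]
                      - baseline.e_vol_tri).max() < 1e-12 * scale

    def test_solid_velocity_zero_at_steady_state(self, baseline):
        assert np.abs(baseline.V_t).max() == 0.0

    def test_no_lymph_sink_in_tumor(self, tissue_mesh, baseline):
        in_tumor = tissue_mesh.tris_in("tumor")
        assert np.abs(baseline.phi_L_tri[in_tumor]).max() == 0.0

    def test_linearity_superposition(self, p, tissue_mesh):
        """Doubling all pressure-like inputs doubles (u, P_i)."""
        def solve(scalefac):
            q = p.copy(pi_B=p.pi_B * scalefac,
                       pi_i={r: v * scalefac for r, v in p.pi_i.items()},
                       P_L=p.P_L * scalefac)
            P_B = solve_tissue_blood_pressure(tissue_mesh, None,
                                              900.0 * scalefac, q)
            return solve_poroelastic(tissue_mesh, P_B, None, q)
        a, b = solve(1.0), solve(2.0)
        assert np.allclose(2 * a.P_i, b.P_i, rtol=1e-9, atol=1e-9)
        assert np.allclose(2 * a.u, b.u, rtol=1e-9,
                           atol=1e-12 * np.abs(b.u).max())

    def test_global_mass_balance(self, p, tissue_mesh):
        """Net Starling production equals interstitial boundary outflow.

        Checked on a weak-filtration configuration whose screening
        length exceeds the domain, so the element-wise boundary flux is
        well resolved (the study parameters put a sub-element boundary
        layer at the outer edges, where a geometric flux estimate is
        meaningless at this resolution).
        """
        q = p.copy(LpS_over_V={"tumor": 42.2e-11, "healthy": 18.9e-12},
                   LpLSL_over_V={"tumor": 0.0, "healthy": 1.0e-10})
        th = np.linspace(-np.pi, np.pi, 361)
        wall = (th, 1000.0 + 300.0 * np.sin(th))
        P_B = solve_tissue_blood_pressure(tissue_mesh, None, wall, q)
        sol = solve_poroelastic(tissue_mesh, P_B, None, q)
        src = ((sol.phi_B_tri - sol.phi_L_tri) * tissue_mesh.areas).sum()
        edge_tri = {}
        for k, tri in enumerate(tissue_mesh.triangles):
            for a, b in ((0, 1), (1, 2), (2, 0)):
                edge_tri[frozenset((tri[a], tri[b]))] = k
        out = 0.0
        for e in tissue_mesh.edges:
            k = edge_tri[frozenset(e)]
            d = tissue_mesh.points[e[1]] - tissue_mesh.points[e[0]]
            n = np.array([d[1], -d[0]])
            out += q.eps_i * sol.V_i_tri[k] @ n
        assert out == pytest.approx(src, rel=0.01)


class TestReducedSystemOracle:
    def manufactured(self, p, h):
        m = mesh_tissue(p, h_tumor=h, h_far=4 * h)
        x, y = m.points.T
        scale = 2 * p.mu_lame + p.lam
        a, b = 1e-3 / p.R_t ** 2, 50.0 / p.R_t ** 2
        e = a * (x ** 2 + y ** 2)
        P_B = b * (x ** 2 - y ** 2)                  # harmonic
        P_i = scale * e - P_B                        # satisfies eq 1
        kmu = p.k_over_mu_i["tumor"]
        phi_net = np.full(m.n_tris, -kmu * scale * 4 * a)
        return reduced_residuals(
            m, p, e, P_i, P_B, None, phi_net_tri=phi_net,
            region_override=np.full(m.n_tris, "tumor", dtype=object))

    def test_manufactured_solution_residuals_small(self, p):
        res = self.manufactured(p, 2.5e-4)
        assert res["momentum_gradient"] < 1e-12
        assert res["strain_pressure"] < 5e-3
        assert res["blood_pressure"] < 5e-3

    def test_manufactured_convergence_rate(self, p):
        coarse = self.manufactured(p, 5e-4)
        fine = self.manufactured(p, 2.5e-4)
        for key in ("strain_pressure", "blood_pressure"):
            rate = np.log2(coarse[key] / fine[key])
            assert rate > 1.0                        # ~second order

    def test_zero_solution_zero_residuals(self, p, tissue_mesh):
        z = np.zeros(tissue_mesh.n_nodes)
        res = reduced_residuals(tissue_mesh, p, z, z, z, None,
                                phi_net_tri=np.zeros(tissue_mesh.n_tris))
        assert all(v == 0.0 for v in res.values())

    def test_baseline_solve_residuals_decrease(self, p, flow_no_force):
        wall = inner_wall_pressure(flow_no_force)
        out = []
        for h in (5e-4, 2.5e-4):
            m = mesh_tissue(p, h_tumor=h, h_far=4 * h)
            P_B = solve_tissue_blood_pressure(m, None, wall, p)
            sol = solve_poroelastic(m, P_B, None, p)
            out.append(reduced_system_residual(sol, None, p))
        for key in out[0]:
            assert out[1][key] < out[0][key]
            assert out[1][key] < 0.05
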