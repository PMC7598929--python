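"""Axisymmetric membrane finite elements: assembly, tangent, continuation."""

import numpy as np
import pytest

import equigr as eg
from equigr.fem import (assemble_residual, axial_reactions, build_mesh,
                        fields_at_gauss, full_residual,
                        local_constitutive_update, solve_scenario, tangent)
from equigr.scenarios import ScenarioSpec, build_field_specs, run_scenario
from equigr.equilibrium import baseline_reference


def _s(x):
    return float(np.ravel(x)[0])


class TestMesh:
    def test_default_mesh_counts(self, params):
        mesh = build_mesh(params, 20)
        assert mesh.n_elem == 20
        assert mesh.n_nodes == 41
        assert mesh.n_gauss == 60
        assert mesh.nodes_z[-1] == pytest.approx(params.l_o)

    def test_refinement_nests_nodes(self, params):
        coarse = build_mesh(params, 10)
        fine = build_mesh(params, 20)
        assert np.allclose(np.intersect1d(np.round(fine.nodes_z, 12),
                                          np.round(coarse.nodes_z, 12)),
                           np.round(coarse.nodes_z, 12))

    def test_too_coarse_rejected(self, params):
        with pytest.raises(ValueError):
            build_mesh(params, 3)


class TestLocalUpdate:
    def test_baseline_identity(self, params, ref):
        loc = {k: np.atleast_1d(v)
               for k, v in fields_at_gauss(build_mesh(params, 4), None).items()}
        st = local_constitutive_update(1.0, 1.0,
                                       {k: v[:1] for k, v in loc.items()},
                                       params, ref.P_o, ref.sigma_o)
        assert _s(st.rho_c_ratio) == pytest.approx(1.0, abs=1e-10)

    def test_matches_uniform_solver_at_its_deformation(self, params, ref):
        st0 = eg.solve_uniform(params, P=1.3 * ref.P_o, ref=ref)
        from equigr.constitutive import local_parameter_arrays
        st = local_constitutive_update(_s(st0.lam_theta), 1.0,
                                       local_parameter_arrays(params),
                                       params, 1.3 * ref.P_o, ref.sigma_o)
        assert _s(st.rho_c_ratio) == pytest.approx(_s(st0.rho_c_ratio),
                                                   rel=1e-8)

    def test_elastin_damage_drives_compensatory_collagen(self, params, ref):
        """At the dilated deformation of a damaged wall, the local update
        deposits extra collagen (rho_c > 1)."""
        from equigr.constitutive import local_parameter_arrays
        loc = local_parameter_arrays(params, {"c_e": 0.38 * params.c_e,
                                              "K_ratio": 0.0})
        st0 = eg.solve_uniform(params, overrides={"c_e": 0.38 * params.c_e,
                                                  "K_ratio": 0.0}, ref=ref)
        st = local_constitutive_update(_s(st0.lam_theta), 1.0, loc, params,
                                       ref.P_o, ref.sigma_o,
                                       rho_init=np.atleast_1d(
                                           _s(st0.rho_c_ratio)))
        assert _s(st.rho_c_ratio) > 1.0


class TestResidualAndTangent:
    def test_baseline_is_exact_fixed_point(self, params, ref):
        mesh = build_mesh(params, 20)
        loc = fields_at_gauss(mesh, None)
        R, rho, ok = assemble_residual(mesh, mesh.reference_u(), loc,
                                       ref.P_o, ref.sigma_o)
        assert ok.all()
        assert np.abs(R).max() < 1e-9
        assert np.allclose(rho, 1.0, atol=1e-10)

    def test_tangent_element_fd_matches_global_numeric(self, params, ref):
        mesh = build_mesh(params, 4)
        spec = ScenarioSpec(insult="mechanosensing", severity="mild")
        ramped, fixed = build_field_specs(spec, params)
        res = solve_scenario(mesh, ramped, ref=ref, fixed_specs=fixed)
        U = res.metadata["U"]
        fscale = ref.P_o * params.R_o * params.l_o / mesh.n_elem
        K1 = tangent(mesh, U, res.local, res.P, ref.sigma_o, fscale,
                     mode="element-fd")
        K2 = tangent(mesh, U, res.local, res.P, ref.sigma_o, fscale,
                     mode="numeric")
        assert np.abs(K1 - K2).max() / np.abs(K2).max() < 1e-4

    def test_reactions_balance_follower_pressure(self, params, ref):
        """The end reactions carry the net axial push of the follower
        pressure on the bulged membrane (zero by symmetry, equal and
        opposite individually)."""
        mesh = build_mesh(params, 6)
        spec = ScenarioSpec(insult="mechanosensing", severity="mild")
        ramped, fixed = build_field_specs(spec, params)
        res = solve_scenario(mesh, ramped, ref=ref, fixed_specs=fixed)
        R_left, R_right = axial_reactions(mesh, res.u, res.local, res.P,
                                          ref.sigma_o,
                                          rho=res.state.rho_c_ratio)
        assert R_left == pytest.approx(-R_right, rel=1e-9)
        assert abs(R_left) > 0.1      # lesion bulge does push on the ends

    def test_virtual_work_on_three_elements(self, params, ref):
        """Pressure-only perturbation: residual change matches the
        follower-pressure virtual work on a radial test displacement."""
        mesh = build_mesh(params, 4)
        loc = fields_at_gauss(mesh, None)
        u = mesh.reference_u()
        R1, rho, _ = assemble_residual(mesh, u, loc, ref.P_o, ref.sigma_o,
                                       apply_bc=False)
        R2, _, _ = assemble_residual(mesh, u, loc, 1.01 * ref.P_o,
                                     ref.sigma_o, rho=rho, apply_bc=False)
        n = mesh.n_nodes
        dv = np.zeros(2 * n)
        dv[:n] = 1.0                   # uniform radial virtual displacement
        # d(R . dv)/dP combines the follower load (-r z' = -R_o) and the
        # mid-wall radial condition shifting sigma_tt by -1/2 (i.e. -h_o/2
        # on the resultant): total -(R_o + h_o/2) l_o per radian
        work_rate = (R2 - R1) @ dv / (0.01 * ref.P_o)
        assert work_rate == pytest.approx(
            -(params.R_o + params.h_o / 2) * params.l_o, rel=1e-9)


class TestScenarioSolve:
    def test_zero_insult_keeps_identity_at_every_step(self, params, ref):
        mesh = build_mesh(params, 6)
        res = solve_scenario(mesh, None, ref=ref)
        assert res.converged
        for step in res.steps:
            assert np.allclose(step.u, mesh.reference_u(), atol=1e-10)

    def test_uniform_fields_match_point_solver_everywhere(self, params, ref):
        mesh = build_mesh(params, 6)
        res = solve_scenario(mesh, {"c_e": 0.8 * params.c_e}, ref=ref)
        st0 = eg.solve_uniform(params, overrides={"c_e": 0.8 * params.c_e},
                               ref=ref)
        assert res.converged
        assert np.abs(res.state.lam_theta - _s(st0.lam_theta)).max() < 1e-6
        assert np.abs(res.state.rho_c_ratio - _s(st0.rho_c_ratio)).max() < 1e-6

    def test_severe_elastin_dilates_at_midlength(self, severe_elastin,
                                                 params):
        res = severe_elastin
        assert res.converged
        dr = res.diameter_ratio()
        i_max = int(np.argmax(dr))
        assert abs(res.gp_z[i_max] - params.l_o / 2) < 1.0
        assert dr.max() > 1.5          # marked aneurysmal dilatation
        # ends stay close to homeostatic
        assert dr[0] == pytest.approx(1.0, abs=0.02)

    def test_mesh_objectivity_severe_elastin(self, severe_elastin, params):
        m40 = run_scenario(ScenarioSpec(insult="elastin_integrity",
                                        severity="severe"), params,
                           n_elem=40)
        d20 = severe_elastin.diameter_ratio().max()
        d40 = m40.diameter_ratio().max()
        assert abs(d40 - d20) / d20 < 0.01

    def test_quadratic_convergence_recorded(self, severe_elastin):
        # each accepted continuation step converged in a few Newton
        # iterations to below tolerance
        for step in severe_elastin.steps:
            assert step.iterations <= 12
            assert step.residual_norm < 1e-10

    def test_instability_signature_near_critical_delta(self, params, ref):
        """Approaching the critical mechanosensing loss, the smallest
        singular value of the monolithic tangent collapses."""
        mesh = build_mesh(params, 20)
        svs = {}
        for d in (0.05, 0.225):
            ramped, fixed = build_field_specs(
                ScenarioSpec(insult="mechanosensing",
                             severity=("custom", d)), params)
            res = solve_scenario(mesh, ramped, ref=ref, fixed_specs=fixed)
            assert res.converged
            fscale = ref.P_o * params.R_o * params.l_o / mesh.n_elem
            K = tangent(mesh, res.metadata["U"], res.local, res.P,
                        ref.sigma_o, fscale)
            svs[d] = np.linalg.svd(K, compute_uv=False)[-1]
        assert svs[0.225] < 0.5 * svs[0.05]
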