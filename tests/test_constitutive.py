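"""Constituent energies, stresses, tone, reorientation, and stiffness."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from equigr.constitutive import (InvalidDeformationError,
                                 collagen_angle, elastin_stored_energy,
                                 equilibrated_active_stress, evaluate_mixture,
                                 fiber_cauchy_stress, fiber_stored_energy,
                                 local_parameter_arrays, stress_stimulus,
                                 wall_shear_ratio)


# ---------------------------------------------------------------------------
# frozen worked values
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fn, args, expected, tol", [
    (elastin_stored_energy, (89.71, (1.90, 1.62, 1 / (1.90 * 1.62))),
     149.81, 1e-3),
    (elastin_stored_energy, (123.0, (1.0, 1.0, 1.0)), 0.0, 1e-12),
    # 62% modulus reduction scales the energy linearly
    (elastin_stored_energy, (34.1, (1.90, 1.62, 1 / (1.90 * 1.62))),
     34.1 / 89.71 * 149.81, 1e-3),
    (fiber_stored_energy, (1.25, 234.9, 4.08), 37.944, 1e-3),
    (fiber_stored_energy, (1.0, 234.9, 4.08), 0.0, 1e-12),
    (fiber_stored_energy, (1.20, 261.4, 0.24), 12.950, 1e-3),
    (fiber_cauchy_stress, (1.25, 234.9, 4.08), 750.75, 1e-3),
    (fiber_cauchy_stress, (1.0, 500.0, 2.0), 0.0, 1e-12),
    (wall_shear_ratio, (1.1 * 0.647, 0.647, 1.0), 1.1 ** -3, 1e-9),
    (wall_shear_ratio, (0.647, 0.647, 1.0), 1.0, 1e-12),
    (wall_shear_ratio, (0.647, 0.647, 2.0), 2.0, 1e-12),
])
def test_worked_values(fn, args, expected, tol):
    assert float(fn(*args)) == pytest.approx(expected, rel=tol, abs=tol)


def test_active_tone_half_maximal_at_homeostasis(params):
    # C_B is chosen so that exp(-C_B^2) = 1/2: T(0) = T_max / 2
    s = equilibrated_active_stress(1.0, 0.0, params)
    parab = 1.0 - ((params.lambda_M - 1) / (params.lambda_M - params.lambda_0)) ** 2
    assert float(s) == pytest.approx(125.0 * parab, rel=1e-3)
    assert float(equilibrated_active_stress(0.33, 0.0, params)) == \
        pytest.approx(40.41, rel=1e-3)
    zero = equilibrated_active_stress(0.33, 0.7, params, T_max=0.0)
    assert float(zero) == 0.0


def test_stress_stimulus_values():
    assert stress_stimulus(np.diag([272.0, 257.0, -6.0])) == \
        pytest.approx(174.333, rel=1e-4)
    assert stress_stimulus(-3.5 * np.eye(3)) == pytest.approx(-3.5)


def test_stress_stimulus_rotation_invariant(rng):
    sigma = np.diag([272.0, 257.0, -6.0])
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    rotated = q @ sigma @ q.T
    assert stress_stimulus(rotated) == pytest.approx(stress_stimulus(sigma))


def test_collagen_angle_examples():
    a0 = np.deg2rad(29.9)
    assert float(collagen_angle(1.3, 1.3, a0)) == pytest.approx(a0)
    assert np.rad2deg(float(collagen_angle(1.2, 1.0, a0))) == \
        pytest.approx(34.62, abs=0.05)
    # circumferential fibers stay circumferential
    assert float(collagen_angle(1.4, 0.9, np.pi / 2)) == \
        pytest.approx(np.pi / 2)


def test_invalid_deformations_raise():
    with pytest.raises(InvalidDeformationError):
        fiber_stored_energy(-0.2, 234.9, 4.08)
    with pytest.raises(InvalidDeformationError):
        elastin_stored_energy(89.71, (1.0, -1.0, 1.0))
    with pytest.raises(InvalidDeformationError):
        wall_shear_ratio(-1.0, 0.647)


def test_fiber_energy_c2_zero_limit():
    lam = 1.3
    assert float(fiber_stored_energy(lam, 100.0, 0.0)) == \
        pytest.approx(100.0 * (lam ** 2 - 1) ** 2 / 4.0)


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

@given(lam=st.floats(0.5, 1.8), c1=st.floats(1.0, 500.0),
       c2=st.floats(0.0, 5.0))
def test_fiber_energy_nonnegative_and_even(lam, c1, c2):
    w = float(fiber_stored_energy(lam, c1, c2))
    assert w >= 0.0
    # even in (lam^2 - 1): the stretch with mirrored squared deviation
    x = lam ** 2 - 1
    if 1.0 - x > 0.05:
        lam_m = np.sqrt(1.0 - x)
        assert float(fiber_stored_energy(lam_m, c1, c2)) == \
            pytest.approx(w, rel=1e-9, abs=1e-12)


@given(lam=st.floats(0.6, 1.7), c1=st.floats(1.0, 400.0),
       c2=st.floats(0.0, 5.0))
def test_fiber_stress_sign_matches_extension(lam, c1, c2):
    s = float(fiber_cauchy_stress(lam, c1, c2))
    assert np.sign(s) == np.sign(lam - 1.0) or abs(lam - 1.0) < 1e-12


@given(lam=st.floats(0.7, 1.6))
def test_fiber_stress_is_energy_derivative(lam):
    c1, c2 = 234.9, 4.08
    h = 1e-6
    wp = (float(fiber_stored_energy(lam + h, c1, c2))
          - float(fiber_stored_energy(lam - h, c1, c2))) / (2 * h)
    assert float(fiber_cauchy_stress(lam, c1, c2)) == \
        pytest.approx(lam * wp, rel=1e-6)


@given(a=st.floats(0.3, 2.0), q=st.floats(0.2, 3.0))
def test_wall_shear_identity(a, q):
    a_o = 0.647
    assert float(wall_shear_ratio(a, a_o, q)) * (a / a_o) ** 3 == \
        pytest.approx(q, rel=1e-12)


@given(r1=st.floats(0.8, 1.6), r2=st.floats(0.8, 1.6))
def test_collagen_angle_monotone_in_stretch_ratio(r1, r2):
    a0 = np.deg2rad(29.9)
    lo, hi = sorted([r1, r2])
    assert float(collagen_angle(lo, 1.0, a0)) <= \
        float(collagen_angle(hi, 1.0, a0)) + 1e-12


def test_elastin_linearity_in_modulus():
    stretches = (1.9, 1.62, 0.3249)
    w1 = float(elastin_stored_energy(89.71, stretches))
    w2 = float(elastin_stored_energy(0.38 * 89.71, stretches))
    assert w2 == pytest.approx(0.38 * w1, rel=1e-12)


# ---------------------------------------------------------------------------
# mixture-level finite-difference oracles
# ---------------------------------------------------------------------------

def _hat_stresses(state, params):
    """Recover the constitutive extra stresses from a PointState."""
    p = float(state.p)
    return (float(state.sigma_rr) + p, float(state.sigma_tt) + p,
            float(state.sigma_zz) + p)


def _passive_energy_reference(params, loc, lam, rho, gamma):
    """Mixture stored energy per unit original reference volume under a
    superimposed principal stretch ``gamma`` about the equilibrated state
    (frozen composition; fibers deviate from their deposition stretches)."""
    lam_t, lam_z = lam
    eta = float(np.ravel(loc["eta"])[0])
    rho_m = rho ** eta
    J = params.phi_e + params.phi_m * rho_m + params.phi_c * rho
    lam_r = J / (lam_t * lam_z)
    g_r, g_t, g_z = gamma
    we = elastin_stored_energy(
        float(np.ravel(loc["c_e"])[0]),
        (lam_r * params.G_r_e * g_r, lam_t * params.G_theta_e * g_t,
         lam_z * params.G_z_e * g_z))
    wm = fiber_stored_energy(params.G_m * g_t, params.c1_m, params.c2_m)
    alpha = float(collagen_angle(lam_t, lam_z, params.alpha_0o))
    ell = np.sqrt((g_z * np.cos(alpha)) ** 2 + (g_t * np.sin(alpha)) ** 2)
    G_c = float(np.ravel(loc["G_c"])[0])
    c1c = float(np.ravel(loc["c1_c"])[0])
    wc = (params.beta_theta * fiber_stored_energy(G_c * g_t, c1c, params.c2_c)
          + params.beta_z * fiber_stored_energy(G_c * g_z, c1c, params.c2_c)
          + params.beta_d * fiber_stored_energy(G_c * ell, c1c, params.c2_c))
    return (params.phi_e * float(we) + params.phi_m * rho_m * float(wm)
            + params.phi_c * rho * float(wc))


def test_passive_stress_matches_energy_differentiation(params, ref, rng):
    """sigma_hat (passive) = (2/J) F dW_R/dC F^T, checked by central FD."""
    from equigr.constitutive import equilibrated_active_stress

    for _ in range(8):
        lam_t = rng.uniform(0.9, 1.5)
        lam_z = rng.uniform(0.9, 1.2)
        rho = rng.uniform(0.6, 2.0)
        loc = local_parameter_arrays(params)
        state = evaluate_mixture(lam_t, lam_z, rho, params, P=ref.P_o,
                                 local=loc)
        hat_rr, hat_tt, hat_zz = _hat_stresses(state, params)
        # subtract the (non-energetic) active contribution
        phi_m = params.phi_m * float(state.rho_m_ratio) / float(state.J)
        d_tau = float(state.tau_ratio) - 1.0
        act = float(equilibrated_active_stress(phi_m, d_tau, params))
        hat_tt -= act
        J = float(state.J)
        h = 1e-5
        for i, hat in enumerate([hat_rr, hat_tt, hat_zz]):
            gp = [1.0, 1.0, 1.0]
            gm = [1.0, 1.0, 1.0]
            gp[i] += h
            gm[i] -= h
            dW = (_passive_energy_reference(params, loc, (lam_t, lam_z), rho, gp)
                  - _passive_energy_reference(params, loc, (lam_t, lam_z), rho,
                                              gm)) / (2 * h)
            # sigma_ii = (gamma_i / (J * det gamma)) dW/dgamma_i at gamma = 1
            assert hat == pytest.approx(dW / J, rel=2e-5, abs=1e-6), \
                f"component {i} at lam=({lam_t:.3f},{lam_z:.3f}), rho={rho:.3f}"


def _passive_sigma_tt_reference(params, loc, state, g_t):
    """Passive circumferential extra stress under a superimposed stretch
    ``g_t`` (lam_z, lam_r frozen; geometric volume scales with g_t)."""
    lam_t, lam_z = float(state.lam_theta), float(state.lam_z)
    J = float(state.J)
    lam_r = J / (lam_t * lam_z)
    c_e = float(np.ravel(loc["c_e"])[0])
    c1c = float(np.ravel(loc["c1_c"])[0])
    G_c = float(np.ravel(loc["G_c"])[0])
    phi_e = params.phi_e * float(state.rho_e_ratio)
    phi_m = params.phi_m * float(state.rho_m_ratio)
    phi_c = params.phi_c * float(state.rho_c_ratio)
    alpha = float(state.alpha_0h)
    s2, c2 = np.sin(alpha) ** 2, np.cos(alpha) ** 2
    ell = np.sqrt(c2 + g_t * g_t * s2)
    s2_cur = g_t * g_t * s2 / (ell * ell)
    num = (phi_e * c_e * (lam_t * params.G_theta_e * g_t) ** 2
           + phi_m * float(fiber_cauchy_stress(params.G_m * g_t, params.c1_m,
                                               params.c2_m))
           + phi_c * (params.beta_theta
                      * float(fiber_cauchy_stress(G_c * g_t, c1c, params.c2_c))
                      + params.beta_d * s2_cur
                      * float(fiber_cauchy_stress(G_c * ell, c1c,
                                                  params.c2_c))))
    return num / (J * g_t)


def test_material_stiffness_matches_fd_oracle(params, ref, rng):
    """c_tttt equals sigma_tt + lam dsigma_tt/dlam of the passive extra
    stress at frozen composition (second-order finite difference)."""
    loc = local_parameter_arrays(params)
    for _ in range(25):
        lam_t = rng.uniform(0.85, 1.6)
        lam_z = rng.uniform(0.9, 1.25)
        rho = rng.uniform(0.5, 2.5)
        state = evaluate_mixture(lam_t, lam_z, rho, params, P=ref.P_o,
                                 local=loc)
        h = 1e-5
        s0 = _passive_sigma_tt_reference(params, loc, state, 1.0)
        sp = _passive_sigma_tt_reference(params, loc, state, 1.0 + h)
        sm = _passive_sigma_tt_reference(params, loc, state, 1.0 - h)
        c_fd = s0 + (sp - sm) / (2 * h)
        assert float(state.c_tttt) == pytest.approx(c_fd, rel=1e-4)


def test_stiffness_elastin_only_closed_form(params, ref):
    """With fiber stresses removed the stiffness reduces to the neo-Hookean
    value 2 phi_e c_e (lam_theta G_theta)^2 / J."""
    zero_fiber = params.replace(c1_m=0.0, c1_c=0.0, T_max=0.0)
    state = evaluate_mixture(1.15, 1.0, 1.0, zero_fiber, P=0.0)
    expected = 2 * zero_fiber.phi_e * zero_fiber.c_e * \
        (1.15 * zero_fiber.G_theta_e) ** 2 / float(state.J)
    assert float(state.c_tttt) == pytest.approx(expected, rel=1e-12)


def test_mixture_stress_symmetric_and_energy_nonnegative(params, ref):
    state = evaluate_mixture(1.2, 1.05, 1.3, params, P=ref.P_o)
    sigma = state.sigma_tensor()
    assert np.allclose(sigma, np.swapaxes(sigma, -1, -2))
    assert float(state.W) >= 0.0
    # mass-volume consistency
    J_expected = (params.phi_e * float(state.rho_e_ratio)
                  + params.phi_m * float(state.rho_m_ratio)
                  + params.phi_c * float(state.rho_c_ratio))
    assert float(state.J) == pytest.approx(J_expected, rel=1e-14)


def test_stored_energy_zero_without_deposition_stretch(params):
    flat = params.replace(G_theta_e=1.0, G_z_e=1.0, G_r_e=1.0, G_m=1.0,
                          G_c=1.0)
    state = evaluate_mixture(1.0, 1.0, 1.0, flat, P=0.0)
    assert float(state.W) == pytest.approx(0.0, abs=1e-12)


def test_elastin_damage_reduces_energy_linearly(params, ref):
    state0 = evaluate_mixture(1.1, 1.0, 1.0, params, P=ref.P_o)
    d = 0.4
    loc = local_parameter_arrays(params, {"c_e": (1 - d) * params.c_e})
    state1 = evaluate_mixture(1.1, 1.0, 1.0, params, P=ref.P_o, local=loc)
    phi_e = params.phi_e * 1.0 / float(state0.J)
    we = float(elastin_stored_energy(
        params.c_e, (float(state0.J) / 1.1 * params.G_r_e,
                     1.1 * params.G_theta_e, params.G_z_e)))
    assert float(state0.W) - float(state1.W) == \
        pytest.approx(d * phi_e * we, rel=1e-12)


@given(lam_t=st.floats(0.8, 1.6), lam_z=st.floats(0.8, 1.4))
def test_diagonal_families_mirror_symmetric(lam_t, lam_z):
    """Reorientation maps the +-alpha families to +-alpha': the evolved pair
    stays mirror-symmetric about the axis and its shear resultant cancels."""
    a0 = np.deg2rad(29.9)
    a_plus = float(collagen_angle(lam_t, lam_z, a0))
    a_minus = float(collagen_angle(lam_t, lam_z, -a0))
    assert a_minus == pytest.approx(-a_plus, rel=1e-12, abs=1e-12)
    shear = (np.sin(a_plus) * np.cos(a_plus)
             + np.sin(a_minus) * np.cos(a_minus))
    assert shear == pytest.approx(0.0, abs=1e-12)
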