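"""Equilibrated constitutive response of the arterial constrained mixture.

In a mechanobiologically equilibrated state, collagen and smooth-muscle fibers
are continually removed and re-deposited at their deposition stretches
``G_c, G_m``; only elastin (which is not produced in maturity) deforms
elastically with the mixture from the original homeostatic configuration.
The mixture Cauchy stress is then a rule of mixtures over evolved mass
fractions,

    sigma = sum_alpha phi^alpha sigma_hat^alpha + phi^m sigma_hat^act - p I,

with the Lagrange multiplier ``p`` fixed by the membrane radial condition
``sigma_rr = -P/2`` (mid-wall average).  Stored energy follows the analogous
rule of mixtures, and the circumferential material stiffness is the
theta-theta-theta-theta component of the spatial elasticity tensor linearized
about the loaded state at frozen composition.

All functions accept scalars or numpy arrays (broadcast over material points);
the mixture-level evaluators return a structure-of-arrays dictionary used by
the 0-D and finite-element solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .parameters import CONTROLLABLE, MixtureParameters

__all__ = [
    "PointState",
    "elastin_stored_energy",
    "fiber_stored_energy",
    "fiber_cauchy_stress",
    "fiber_stiffness_term",
    "active_tone",
    "equilibrated_active_stress",
    "wall_shear_ratio",
    "stress_stimulus",
    "collagen_angle",
    "local_parameter_arrays",
    "evaluate_mixture",
    "mixture_stress",
    "stored_energy_density",
    "material_stiffness_ctttt",
]


class InvalidDeformationError(ValueError):
    """A kinematic input is outside the admissible range."""


class InvalidParameterError(ValueError):
    """A constitutive parameter combination is degenerate."""


# ---------------------------------------------------------------------------
# constituent-level relations
# ---------------------------------------------------------------------------

def elastin_stored_energy(c_e_local, stretches):
    """Neo-Hookean stored energy of elastin per unit constituent volume [kPa].

    Parameters
    ----------
    c_e_local:
        Local elastin shear modulus [kPa] (may carry local damage).
    stretches:
        The three principal elastin stretches ``lam_i * G_i^e`` (last axis).
    """
    lam = np.asarray(stretches, dtype=float)
    if np.any(lam <= 0.0):
        raise InvalidDeformationError("elastin principal stretches must be > 0")
    i1 = np.sum(lam * lam, axis=-1)
    return np.asarray(c_e_local, dtype=float) / 2.0 * (i1 - 3.0)


def fiber_stored_energy(lam, c1, c2):
    """Fung-exponential fiber energy ``c1/(4 c2) (exp[c2 (lam^2-1)^2] - 1)``.

    The ``c2 -> 0`` limit ``c1 (lam^2-1)^2 / 4`` is taken analytically.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0):
        raise InvalidDeformationError("fiber stretch must be > 0")
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    x = lam * lam - 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        full = c1 / (4.0 * c2) * np.expm1(c2 * x * x)
    quad = c1 * x * x / 4.0
    return np.where(c2 > 0.0, full, quad)


def fiber_cauchy_stress(lam, c1, c2):
    """Uniaxial Cauchy stress of a fiber, ``lam * dW/dlam`` [kPa].

    Equals ``c1 lam^2 (lam^2-1) exp[c2 (lam^2-1)^2]``; positive in extension.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0.0):
        raise InvalidDeformationError("fiber stretch must be > 0")
    x = lam * lam - 1.0
    return np.asarray(c1, float) * lam * lam * x * np.exp(np.asarray(c2, float) * x * x)


def fiber_stiffness_term(lam, c1, c2):
    """Second-derivative stiffness coefficient ``lam^2 W'' - lam W'`` [kPa].

    This is the fiber contribution to the spatial elasticity tensor beyond the
    ``2 sigma`` stress-push term (projected by the fourth power of the current
    direction cosines).
    """
    lam = np.asarray(lam, dtype=float)
    x = lam * lam - 1.0
    e = np.exp(np.asarray(c2, float) * x * x)
    wp = c1 * lam * x * e
    wpp = c1 * e * (x + 2.0 * lam * lam + 4.0 * c2 * x * x * lam * lam)
    return lam * lam * wpp - lam * wp


def active_tone(d_tau, params: MixtureParameters, T_max=None):
    """Shear-regulated tone ``T(d_tau) = T_max (1 - exp(-(C_B - C_S d_tau)^2))``."""
    tm = params.T_max if T_max is None else T_max
    arg = params.C_B - params.C_S * np.asarray(d_tau, dtype=float)
    return tm * -np.expm1(-arg * arg)


def equilibrated_active_stress(phi_m_current, d_tau, params: MixtureParameters,
                               T_max=None):
    """Circumferential active stress at equilibrated tone (lam_theta_act = 1) [kPa].

    Returns ``phi_m T(d_tau) (1 - ((lambda_M - 1)/(lambda_M - lambda_0))^2)``.
    """
    if params.lambda_M == params.lambda_0:
        raise InvalidParameterError("lambda_M must differ from lambda_0")
    parab = 1.0 - ((params.lambda_M - 1.0) / (params.lambda_M - params.lambda_0)) ** 2
    return np.asarray(phi_m_current, float) * active_tone(d_tau, params, T_max) * parab


def wall_shear_ratio(a_current, a_o, Q_ratio=1.0):
    """Wall shear stress ratio ``tau_wh/tau_wo = Q_ratio (a_o/a)^3`` (Poiseuille)."""
    a_current = np.asarray(a_current, dtype=float)
    if np.any(a_current <= 0.0) or np.any(np.asarray(a_o) <= 0.0):
        raise InvalidDeformationError("radii must be positive")
    return np.asarray(Q_ratio, float) * (a_o / a_current) ** 3


def stress_stimulus(sigma):
    """Mean (volumetric) Cauchy stress stimulus ``sigma_v = tr(sigma)/3`` [kPa]."""
    sigma = np.asarray(sigma, dtype=float)
    return np.trace(sigma, axis1=-2, axis2=-1) / 3.0


def collagen_angle(lam_theta, lam_z, alpha_0o):
    """Evolved deposition angle of the diagonal collagen families [rad].

    ``tan(alpha_0h) = (lam_theta/lam_z) tan(alpha_0o)``, with the angle
    measured from the axial direction so growing circumferential stretch
    rotates fibers toward circumferential.  ``alpha_0o = pi/2`` stays fixed.
    """
    lam_theta = np.asarray(lam_theta, dtype=float)
    lam_z = np.asarray(lam_z, dtype=float)
    if np.any(lam_theta <= 0.0) or np.any(lam_z <= 0.0):
        raise InvalidDeformationError("stretches must be positive")
    return np.arctan2(lam_theta * np.sin(alpha_0o), lam_z * np.cos(alpha_0o))


# ---------------------------------------------------------------------------
# mixture-level state
# ---------------------------------------------------------------------------

@dataclass
class PointState:
    """Equilibrated state at a material point (or arrays of points).

    ``sigma`` components are in the local principal (radial, circumferential,
    axial/meridional) frame; use :meth:`sigma_tensor` for the full tensor.
    """

    lam_theta: Any
    lam_z: Any
    J: Any
    rho_c_ratio: Any
    rho_m_ratio: Any
    rho_e_ratio: Any
    alpha_0h: Any
    sigma_rr: Any
    sigma_tt: Any
    sigma_zz: Any
    sigma_v: Any
    p: Any
    W: Any
    c_tttt: Any
    tau_ratio: Any
    h: Any
    a: Any
    local: dict = field(default_factory=dict)

    def sigma_tensor(self):
        """Full (diagonal) Cauchy stress tensor(s), shape (..., 3, 3) [kPa]."""
        rr = np.asarray(self.sigma_rr, dtype=float)
        out = np.zeros(rr.shape + (3, 3))
        out[..., 0, 0] = rr
        out[..., 1, 1] = self.sigma_tt
        out[..., 2, 2] = self.sigma_zz
        return out


def local_parameter_arrays(params: MixtureParameters,
                           overrides: Mapping[str, Any] | None = None
                           ) -> dict[str, Any]:
    """Effective local values of the controllable parameters.

    ``overrides`` maps a controllable parameter name to its local value
    (scalar or per-point array); missing names take the baseline value.
    """
    overrides = dict(overrides or {})
    bad = set(overrides) - set(CONTROLLABLE)
    if bad:
        raise InvalidParameterError(
            f"not controllable: {sorted(bad)}; allowed: {CONTROLLABLE}")
    return {name: overrides.get(name, getattr(params, name))
            for name in CONTROLLABLE}


def evaluate_mixture(lam_theta, lam_z, rho_c_ratio, params: MixtureParameters,
                     P, local: Mapping[str, Any] | None = None,
                     stiffness: bool = True) -> PointState:
    """Evaluate the full equilibrated mixture response at given kinematics.

    Parameters
    ----------
    lam_theta, lam_z:
        Mid-surface circumferential and axial (meridional) stretches from the
        original homeostatic configuration.
    rho_c_ratio:
        Evolved referential collagen density normalized by its original value;
        smooth muscle follows as ``rho_c_ratio**eta`` and elastin mass is
        conserved (elastin damage enters through the local modulus ``c_e``).
    P:
        Transmural pressure [kPa] (sets the Lagrange multiplier through the
        mid-wall radial condition).
    local:
        Effective local controllable parameters (see
        :func:`local_parameter_arrays`); baseline values if omitted.

    Returns
    -------
    PointState
        With stress in the (r, theta, z) frame, stored energy per unit
        current volume, and (optionally) the circumferential material
        stiffness at frozen composition.
    """
    loc = local if local is not None else local_parameter_arrays(params)
    lam_theta = np.asarray(lam_theta, dtype=float)
    lam_z = np.asarray(lam_z, dtype=float)
    rho_c = np.asarray(rho_c_ratio, dtype=float)
    if np.any(lam_theta <= 0.0) or np.any(lam_z <= 0.0):
        raise InvalidDeformationError("mixture stretches must be positive")
    if np.any(rho_c < 0.0):
        raise InvalidDeformationError("collagen mass ratio must be >= 0")

    rho_m = rho_c ** np.asarray(loc["eta"], dtype=float)
    rho_e = np.ones_like(rho_c + lam_theta)
    # mass-volume consistency: J = sum_alpha phi_o^alpha rho_ratio^alpha
    J = params.phi_e * rho_e + params.phi_m * rho_m + params.phi_c * rho_c
    lam_r = J / (lam_theta * lam_z)
    h = lam_r * params.h_o
    # membrane kinematic luminal radius: the reference luminal surface scaled
    # by the circumferential stretch (the wall-shear ratio is then a pure
    # function of the local stretches, assessed pointwise)
    a = lam_theta * params.a_o

    tau_ratio = wall_shear_ratio(a, params.a_o, params.Q_ratio)
    d_tau = (1.0 - np.asarray(loc["xi"], float)) * tau_ratio - 1.0

    alpha_h = collagen_angle(lam_theta, lam_z, params.alpha_0o)
    s2 = np.sin(alpha_h) ** 2
    c2 = np.cos(alpha_h) ** 2

    # current mass fractions
    phi_e = params.phi_e * rho_e / J
    phi_m = params.phi_m * rho_m / J
    phi_c = params.phi_c * rho_c / J

    # constituent Cauchy stresses (per unit constituent current volume)
    c_e_loc = np.asarray(loc["c_e"], dtype=float)
    se_rr = c_e_loc * (lam_r * params.G_r_e) ** 2
    se_tt = c_e_loc * (lam_theta * params.G_theta_e) ** 2
    se_zz = c_e_loc * (lam_z * params.G_z_e) ** 2
    sig_m = fiber_cauchy_stress(params.G_m, params.c1_m, params.c2_m)
    G_c_loc = np.asarray(loc["G_c"], dtype=float)
    c1_c_loc = np.asarray(loc["c1_c"], dtype=float)
    sig_c = fiber_cauchy_stress(G_c_loc, c1_c_loc, params.c2_c)
    act = equilibrated_active_stress(1.0, d_tau, params,
                                     T_max=np.asarray(loc["T_max"], float))

    hat_rr = phi_e * se_rr
    hat_tt = (phi_e * se_tt + phi_m * sig_m + phi_m * act
              + phi_c * (params.beta_theta + params.beta_d * s2) * sig_c)
    hat_zz = (phi_e * se_zz
              + phi_c * (params.beta_z + params.beta_d * c2) * sig_c)

    if not (np.all(np.isfinite(hat_tt)) and np.all(np.isfinite(hat_zz))):
        raise FloatingPointError(
            "non-finite mixture stress; state: "
            f"lam_theta={lam_theta}, lam_z={lam_z}, rho_c={rho_c}")

    p = hat_rr + np.asarray(P, dtype=float) / 2.0  # sigma_rr = -P/2 mid-wall
    sigma_rr = hat_rr - p
    sigma_tt = hat_tt - p
    sigma_zz = hat_zz - p
    sigma_v = (sigma_rr + sigma_tt + sigma_zz) / 3.0

    # stored energy per unit current volume (rule of mixtures)
    We = elastin_stored_energy(
        c_e_loc, np.stack(np.broadcast_arrays(
            lam_r * params.G_r_e, lam_theta * params.G_theta_e,
            lam_z * params.G_z_e), axis=-1))
    Wm = fiber_stored_energy(params.G_m, params.c1_m, params.c2_m)
    Wc = fiber_stored_energy(G_c_loc, c1_c_loc, params.c2_c)
    W = (params.phi_e * rho_e * We + params.phi_m * rho_m * Wm
         + params.phi_c * rho_c * Wc) / J

    if stiffness:
        hat_tt_pass = hat_tt - phi_m * act
        Dm = fiber_stiffness_term(params.G_m, params.c1_m, params.c2_m)
        Dc = fiber_stiffness_term(G_c_loc, c1_c_loc, params.c2_c)
        ctttt = (2.0 * hat_tt_pass + phi_m * Dm
                 + phi_c * (params.beta_theta + params.beta_d * s2 * s2) * Dc)
        if params.stiffness_includes_active:
            ctttt = ctttt + 2.0 * phi_m * act
    else:
        ctttt = np.full_like(np.asarray(W, dtype=float), np.nan)

    return PointState(
        lam_theta=lam_theta, lam_z=lam_z, J=J,
        rho_c_ratio=rho_c, rho_m_ratio=rho_m, rho_e_ratio=rho_e,
        alpha_0h=alpha_h, sigma_rr=sigma_rr, sigma_tt=sigma_tt,
        sigma_zz=sigma_zz, sigma_v=sigma_v, p=p, W=W, c_tttt=ctttt,
        tau_ratio=tau_ratio, h=h, a=a, local=dict(loc))


# ---------------------------------------------------------------------------
# thin spec-level wrappers
# ---------------------------------------------------------------------------

def mixture_stress(state: PointState, params: MixtureParameters, P):
    """Mixture Cauchy stress tensor at a converged state [kPa].

    Re-evaluates the rule-of-mixtures stress at the state's kinematics and
    composition with the multiplier fixed by ``sigma_rr = -P/2``.
    """
    st = evaluate_mixture(state.lam_theta, state.lam_z, state.rho_c_ratio,
                          params, P, local=state.local or None,
                          stiffness=False)
    return st.sigma_tensor()


def stored_energy_density(state: PointState, params: MixtureParameters):
    """Stored energy per unit current volume, W = sum phi^alpha What^alpha [kPa]."""
    return state.W


def material_stiffness_ctttt(state: PointState, params: MixtureParameters):
    """Circumferential material stiffness at frozen composition [kPa].

    The theta-theta-theta-theta component of the spatial elasticity tensor of
    the mixture linearized about the current loaded state (small-on-large),
    with constituents at their equilibrated stretches.  By default only the
    passive response is linearized (``params.stiffness_includes_active``
    toggles the active stress-push term).
    """
    if not np.all(np.isfinite(state.c_tttt)):
        raise InvalidParameterError("stiffness not available for this state")
    return state.c_tttt
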