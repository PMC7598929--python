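"""Coupled mechanical + mechanobiological equilibrium at a material point.

The equilibrated growth-and-remodeling problem at a uniform cylindrical
segment has two unknowns -- the mid-surface circumferential stretch
``lam_theta`` and the referential collagen density ratio ``rho_c`` -- and two
residuals:

* mechanical equilibrium of the pressurized membrane,
  ``sigma_tt h = P r_mid`` with thickness ``h = J h_o/(lam_theta lam_z)``;
* mechanobiological equilibrium, production balancing removal,
  ``Delta_sigma - (K_tauw/K_sigma) Delta_tau_w = 0`` with
  ``Delta_sigma = ((1-delta) sigma_v - sigma_o)/sigma_o`` and
  ``Delta_tau_w = (1-xi) tau_w/tau_wo - 1``.

Smooth-muscle mass follows collagen through ``rho_m = rho_c**eta`` and the
volume ratio through mass-volume consistency, so the pair of residuals closes.
The same *local* density solve (at fixed deformation) is the internal-variable
update used at every Gauss point of the finite-element solver.

Everything here is deterministic; no randomness enters any solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

import numpy as np
from scipy import optimize

from .constitutive import PointState, evaluate_mixture, local_parameter_arrays
from .parameters import MixtureParameters

__all__ = [
    "NoEquilibriumError",
    "HomeostaticReference",
    "UniformSolveConfig",
    "homeostatic_baseline",
    "mass_coupling",
    "mechanobiological_residual",
    "solve_local_density",
    "solve_uniform",
    "scan_delta_instability",
]


class NoEquilibriumError(RuntimeError):
    """No mechanobiologically equilibrated solution could be found."""


@dataclass(frozen=True)
class HomeostaticReference:
    """Baseline homeostatic setpoints derived from the parameter set."""

    state: PointState
    P_o: float
    sigma_o: float
    tau_wo_ratio: float = 1.0


@dataclass
class UniformSolveConfig:
    """Solver settings for the uniform (0-D) and FEM continuation solves."""

    newton_tol: float = 1e-10
    max_iter: int = 40
    continuation_steps: int = 10
    max_halvings: int = 5
    axial_mode: str = "fixed-ends"  # or "force-controlled"

    def __post_init__(self) -> None:
        if self.newton_tol <= 0.0:
            raise ValueError("newton_tol must be positive")
        if self.continuation_steps < 1:
            raise ValueError("continuation_steps must be >= 1")
        if self.axial_mode not in ("fixed-ends", "force-controlled"):
            raise ValueError(f"unknown axial_mode {self.axial_mode!r}")


def mass_coupling(rho_c_ratio, eta):
    """Evolved muscle density from collagen, ``rho_m = rho_c**eta``."""
    rho_c_ratio = np.asarray(rho_c_ratio, dtype=float)
    if np.any(rho_c_ratio <= 0.0):
        raise ValueError("rho_c_ratio must be positive")
    return rho_c_ratio ** np.asarray(eta, dtype=float)


def homeostatic_baseline(params: MixtureParameters
                         ) -> tuple[PointState, float, float, float]:
    """Construct the original homeostatic state and derive P_o, sigma_o, tau_wo.

    The homeostatic pressure is not prescribed; it is the pressure that
    equilibrates the baseline constitutive stress of the membrane
    (``sigma_tt h_o = P_o R_o`` with the mid-wall radial condition
    ``sigma_rr = -P_o/2``), which makes the reference parameterization an
    exact fixed point of both residuals.

    Returns ``(state, P_o, sigma_o, tau_wo_ratio)``.
    """
    # at P = 0 the multiplier equals the radial extra stress, so the probe's
    # sigma_tt is exactly hat_tt - hat_rr
    probe = evaluate_mixture(1.0, 1.0, 1.0, params, P=0.0)
    P_o = probe.sigma_tt / (params.R_o / params.h_o + 0.5)
    state = evaluate_mixture(1.0, 1.0, 1.0, params, P=P_o)
    sigma_o = float(state.sigma_v)
    return state, float(P_o), sigma_o, 1.0


def baseline_reference(params: MixtureParameters) -> HomeostaticReference:
    """Convenience wrapper returning a :class:`HomeostaticReference`."""
    state, P_o, sigma_o, tau = homeostatic_baseline(params)
    return HomeostaticReference(state=state, P_o=P_o, sigma_o=sigma_o,
                                tau_wo_ratio=tau)


def mechanobiological_residual(state: PointState, params: MixtureParameters,
                               sigma_o: float):
    """Equilibrium stimulus residual ``Delta_sigma - K_ratio Delta_tau_w``.

    Zero at mechanobiological equilibrium; only the gain *ratio* enters.
    """
    if sigma_o == 0.0:
        raise ValueError("baseline stimulus sigma_o must be nonzero")
    loc = state.local or local_parameter_arrays(params)
    delta = np.asarray(loc["delta"], dtype=float)
    xi = np.asarray(loc["xi"], dtype=float)
    k_ratio = np.asarray(loc["K_ratio"], dtype=float)
    d_sigma = ((1.0 - delta) * state.sigma_v - sigma_o) / sigma_o
    d_tau = (1.0 - xi) * state.tau_ratio - 1.0
    return d_sigma - k_ratio * d_tau


# ---------------------------------------------------------------------------
# local (internal-variable) collagen density solve
# ---------------------------------------------------------------------------

def _density_bound(lam_theta, lam_z, params: MixtureParameters, local):
    """Cap on rho_c keeping the wall volume ratio physically sensible."""
    del lam_z, local
    return np.full(np.shape(lam_theta), 1e4)


def solve_local_density(lam_theta, lam_z, params: MixtureParameters, P,
                        sigma_o: float, local: Mapping[str, Any] | None = None,
                        rho_init=None, tol: float = 5e-14,
                        max_iter: int = 60):
    """Solve the mechanobiological residual for ``rho_c`` at fixed deformation.

    A damped Newton iteration in ``log(rho_c)`` warm-started from ``rho_init``
    (the previous converged density) tracks the physical solution branch;
    points that fail to converge are flagged rather than raising, so the
    caller (the FEM continuation) can halve the step or report loss of
    equilibrium existence.

    Returns ``(rho_c, ok)`` arrays.
    """
    loc = local if local is not None else local_parameter_arrays(params)
    lam_theta = np.atleast_1d(np.asarray(lam_theta, dtype=float))
    lam_z = np.broadcast_to(np.asarray(lam_z, dtype=float), lam_theta.shape)
    if rho_init is None:
        rho_init = np.ones_like(lam_theta)
    u = np.log(np.broadcast_to(np.asarray(rho_init, float), lam_theta.shape))
    u = np.array(u, dtype=float)
    u_max = np.log(_density_bound(lam_theta, lam_z, params, loc)) - 1e-3
    u = np.minimum(u, u_max)

    def g_of(u_arr):
        st = evaluate_mixture(lam_theta, lam_z, np.exp(u_arr), params, P,
                              local=loc, stiffness=False)
        return mechanobiological_residual(st, params, sigma_o)

    ok = np.zeros(lam_theta.shape, dtype=bool)
    g = g_of(u)
    for _ in range(max_iter):
        ok = np.abs(g) < tol
        if ok.all():
            break
        du = 1e-7
        gp = (g_of(u + du) - g) / du
        with np.errstate(divide="ignore", invalid="ignore"):
            step = -g / gp
        step = np.where(np.isfinite(step), step, 0.3)
        step = np.clip(step, -0.4, 0.4)
        u_new = np.minimum(u + np.where(ok, 0.0, step), u_max)
        g_new = g_of(u_new)
        # damp where the residual grew badly
        worse = (np.abs(g_new) > 2.0 * np.abs(g)) & ~ok
        for _ in range(6):
            if not worse.any():
                break
            u_new = np.where(worse, (u + u_new) / 2.0, u_new)
            g_new = g_of(u_new)
            worse = (np.abs(g_new) > 2.0 * np.abs(g)) & ~ok
        u, g = u_new, g_new
    ok = np.abs(g) < tol
    return np.exp(u), ok


# ---------------------------------------------------------------------------
# uniform (0-D) coupled solve
# ---------------------------------------------------------------------------

def _bracket_root(f: Callable[[float], float], x0: float,
                  grow: float = 1.03, max_expand: int = 70
                  ) -> tuple[float, float]:
    """Find a sign change of ``f`` on a geometric grid around ``x0``.

    Probes ``x0 * grow**k`` outward (k = 0, +1, -1, +2, ...); points where
    ``f`` is inadmissible (no local equilibrium) are skipped, so the search
    survives a starting point that has just lost its internal-variable root.
    Returns the closest admissible bracketing pair.
    """
    vals: dict[int, float] = {}

    def probe(k: int) -> tuple[int, int] | None:
        x = x0 * grow ** k
        try:
            fx = f(x)
        except (NoEquilibriumError, FloatingPointError, ValueError):
            return None
        if abs(fx) < 1e-11:
            return k, k
        vals[k] = fx
        below = [kk for kk in vals if kk < k]
        above = [kk for kk in vals if kk > k]
        for kn in ([max(below)] if below else []) + \
                  ([min(above)] if above else []):
            if np.sign(vals[kn]) != np.sign(fx):
                return min(k, kn), max(k, kn)
        return None

    hit = probe(0)
    if hit is None:
        for m in range(1, max_expand + 1):
            hit = probe(m)
            if hit is not None:
                break
            hit = probe(-m)
            if hit is not None:
                break
    if hit is None:
        raise NoEquilibriumError("mechanical residual has no sign change")
    return x0 * grow ** hit[0], x0 * grow ** hit[1]


def _solve_uniform_at(params: MixtureParameters, P: float, local,
                      ref: HomeostaticReference, lam_init: float,
                      rho_init: float, lam_z: float = 1.0
                      ) -> tuple[float, float]:
    """Simultaneous damped Newton for (lam_theta, rho_c) at fixed parameters.

    Solving both residuals together (rather than eliminating the density
    first) stays well conditioned where the local density sub-problem folds,
    e.g. under uniform elastin loss with active shear sensing.
    """

    def F(x: np.ndarray) -> np.ndarray:
        lam, rho = x[0], np.exp(x[1])
        st = evaluate_mixture(lam, lam_z, rho, params, P, local=local,
                              stiffness=False)
        f = (st.sigma_tt * st.h - P * lam * params.R_o) \
            / (ref.P_o * params.R_o)
        g = mechanobiological_residual(st, params, ref.sigma_o)
        return np.array([float(np.ravel(f)[0]), float(np.ravel(g)[0])])

    x = np.array([float(lam_init), np.log(float(rho_init))])
    r = F(x)
    norm = np.max(np.abs(r))
    for _ in range(60):
        if norm < 1e-12:
            return float(x[0]), float(np.exp(x[1]))
        J = np.empty((2, 2))
        for j in range(2):
            dx = 1e-7 * (1.0 + abs(x[j]))
            xp = x.copy()
            xp[j] += dx
            J[:, j] = (F(xp) - r) / dx
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError as exc:
            raise NoEquilibriumError(f"singular point Jacobian: {exc}") from exc
        step = np.clip(step, -0.5, 0.5)
        alpha = 1.0
        for _ in range(10):
            try:
                r_new = F(x + alpha * step)
            except (FloatingPointError, ValueError):
                alpha /= 2.0
                continue
            if np.max(np.abs(r_new)) < norm or np.max(np.abs(r_new)) < 1e-12:
                break
            alpha /= 2.0
        else:
            raise NoEquilibriumError("point Newton line search failed")
        x = x + alpha * step
        r = r_new
        norm = np.max(np.abs(r))
    raise NoEquilibriumError(
        f"point Newton did not converge (residual {norm:.3e})")


def solve_uniform(params: MixtureParameters, P: float | None = None,
                  overrides: Mapping[str, Any] | None = None,
                  config: UniformSolveConfig | None = None,
                  ref: HomeostaticReference | None = None) -> PointState:
    """Equilibrated G&R solve of a uniform cylinder (fixed-end segment).

    The insult (parameter ``overrides``) and any pressure elevation are
    advanced quasi-statically from the baseline in ``continuation_steps``
    increments, with step halving on failure; loss of existence of an
    equilibrated solution raises :class:`NoEquilibriumError`.

    Returns the converged :class:`~equigr.constitutive.PointState`.
    """
    config = config or UniformSolveConfig()
    ref = ref or baseline_reference(params)
    P_target = ref.P_o if P is None else float(P)
    base = local_parameter_arrays(params)
    target = local_parameter_arrays(params, overrides)

    lam, rho = 1.0, 1.0
    lam_z = 1.0
    ds0 = 1.0 / config.continuation_steps
    ds_min = ds0 / 2 ** config.max_halvings
    s_done, ds = 0.0, ds0
    while s_done < 1.0 - 1e-12:
        s = min(s_done + ds, 1.0)
        loc_s = {k: (1.0 - s) * np.asarray(base[k], float)
                 + s * np.asarray(target[k], float) for k in base}
        P_s = (1.0 - s) * ref.P_o + s * P_target
        try:
            if config.axial_mode == "force-controlled":
                lam_n, rho_n, lam_z = _solve_force_controlled(
                    params, P_s, loc_s, ref, lam, rho, lam_z)
            else:
                lam_n, rho_n = _solve_uniform_at(params, P_s, loc_s, ref,
                                                 lam, rho)
            lam, rho, s_done = lam_n, rho_n, s
            ds = min(2.0 * ds, ds0)
        except (NoEquilibriumError, FloatingPointError):
            ds /= 2.0
            if ds < ds_min:
                raise NoEquilibriumError(
                    "no equilibrated solution beyond insult fraction "
                    f"{s_done:.3f}")
    loc = {k: np.asarray(v, float) for k, v in target.items()}
    return evaluate_mixture(lam, lam_z, rho, params, P_target, local=loc)


def _solve_force_controlled(params, P, local, ref, lam_init, rho_init,
                            lam_z_init):
    """Axially force-controlled variant: closed-end axial force balance."""

    def axial(lam_z: float) -> float:
        lam, rho = _solve_uniform_at(params, P, local, ref, lam_init,
                                     rho_init, lam_z=lam_z)
        st = evaluate_mixture(lam, lam_z, rho, params, P, local=local,
                              stiffness=False)
        # closed-end: sigma_zz * 2 pi r h = P pi r^2
        r = lam * params.R_o
        f = (st.sigma_zz * st.h - P * r / 2.0) / (ref.P_o * params.R_o)
        return float(np.asarray(f).ravel()[0])

    a, b = _bracket_root(axial, lam_z_init)
    lam_z = a if a == b else optimize.brentq(axial, a, b, xtol=1e-12)
    lam, rho = _solve_uniform_at(params, P, local, ref, lam_init, rho_init,
                                 lam_z=lam_z)
    return lam, rho, lam_z


# ---------------------------------------------------------------------------
# mechanobiological static instability scan
# ---------------------------------------------------------------------------

def scan_delta_instability(params: MixtureParameters, delta_max: float = 0.4,
                           resolution: float = 0.005, mode: str = "fem",
                           n_elem: int = 20,
                           config: UniformSolveConfig | None = None
                           ) -> dict[str, Any]:
    """Critical mechanosensing dysfunction ``delta`` by bisection.

    Marches the central ``delta`` of a localized axisymmetric lesion
    (``mode="fem"``) or a uniform ``delta`` (``mode="uniform"``) upward and
    bisects between the last converged and first failed equilibrated solve.

    Returns a dict with ``delta_critical``, ``critical`` (False when every
    solve up to ``delta_max`` converged), and the probe history.
    """
    if resolution > 0.005 + 1e-15:
        raise ValueError("resolution must be <= 0.005")

    if mode == "fem":
        from .scenarios import ScenarioSpec, run_scenario

        def converges(delta: float) -> bool:
            spec = ScenarioSpec(insult="mechanosensing",
                                severity=("custom", delta),
                                label=f"delta-scan {delta:.4f}")
            try:
                res = run_scenario(spec, params, config=config, n_elem=n_elem)
            except NoEquilibriumError:
                return False
            return bool(res.converged)
    elif mode == "uniform":
        def converges(delta: float) -> bool:
            try:
                solve_uniform(params, overrides={"delta": delta,
                                                 "K_ratio": 0.0},
                              config=config)
            except NoEquilibriumError:
                return False
            return True
    else:
        raise ValueError(f"unknown mode {mode!r}")

    history: list[tuple[float, bool]] = []
    lo, hi = 0.0, None
    step = 0.05
    d = step
    while d <= delta_max + 1e-12:
        ok = converges(d)
        history.append((d, ok))
        if ok:
            lo = d
        else:
            hi = d
            break
        d += step
    if hi is None:
        return {"delta_critical": delta_max, "critical": False,
                "history": history}
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        ok = converges(mid)
        history.append((mid, ok))
        if ok:
            lo = mid
        else:
            hi = mid
    return {"delta_critical": lo, "critical": True, "history": history}
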