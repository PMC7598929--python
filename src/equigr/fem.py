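"""Axisymmetric nonlinear membrane finite elements for localized lesions.

The vessel is an axisymmetric membrane of revolution discretized with
quadratic 1-D elements along the reference axial coordinate ``z_o``.  Global
mechanical equilibrium (membrane stress resultants + follower pressure on the
deformed mid-surface) and local mechanobiological equilibrium (production
balancing removal at every Gauss point) are solved *simultaneously*: the
global unknown vector carries the current meridian positions ``(r, z)`` of
the nodes and the log collagen density ratio at every Gauss point.  The
monolithic coupling stays well conditioned where an internal-variable
elimination of the density would fold (e.g. lesion shoulders where the shear
gain fades), and a singular monolithic tangent is then a faithful signature
of a mechanobiological static instability.  Axial displacements are fixed at
both ends; radial motion is free everywhere.

This is a membrane reduction of a one-element-thick 3-D model: all fields are
through-thickness homogenized and bending is neglected.  The consistent
tangent -- including the deformation dependence of the wall shear stress, the
fiber reorientation, and the follower load -- is assembled by element-wise
finite differencing of the residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from typing import Any, Mapping

import numpy as np

from .constitutive import PointState, evaluate_mixture, local_parameter_arrays
from .equilibrium import (HomeostaticReference, NoEquilibriumError,
                          UniformSolveConfig, baseline_reference,
                          mechanobiological_residual, solve_local_density)
from .fields import InsultFieldSpec
from .parameters import CONTROLLABLE, MixtureParameters

__all__ = [
    "Mesh",
    "SimulationResult",
    "build_mesh",
    "fields_at_gauss",
    "local_constitutive_update",
    "assemble_residual",
    "tangent",
    "solve_scenario",
    "axial_reactions",
]

# 3-point Gauss rule on [-1, 1]
_GP = np.array([-np.sqrt(0.6), 0.0, np.sqrt(0.6)])
_GW = np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])
# quadratic Lagrange shape functions at the Gauss points: (ngp, 3)
_N = np.stack([0.5 * _GP * (_GP - 1.0), 1.0 - _GP ** 2,
               0.5 * _GP * (_GP + 1.0)], axis=1)
_DN = np.stack([_GP - 0.5, -2.0 * _GP, _GP + 0.5], axis=1)  # d/dxi


@dataclass(frozen=True)
class Mesh:
    """Quadratic 1-D axisymmetric membrane mesh of the reference cylinder."""

    params: MixtureParameters
    nodes_z: np.ndarray          # reference axial coordinates, (2 n_elem + 1,)
    elements: np.ndarray         # connectivity, (n_elem, 3)
    gauss_order: int = 3

    @property
    def n_elem(self) -> int:
        return len(self.elements)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes_z)

    @property
    def n_gauss(self) -> int:
        return 3 * self.n_elem

    @property
    def gp_z(self) -> np.ndarray:
        """Reference axial coordinate of every Gauss point, (n_elem * 3,)."""
        ze = self.nodes_z[self.elements]              # (n_elem, 3)
        return (ze @ _N.T).ravel()

    def reference_u(self) -> np.ndarray:
        """Displacement dof vector of the reference configuration [r..., z...]."""
        r = np.full(self.n_nodes, self.params.R_o)
        return np.concatenate([r, self.nodes_z])

    def reference_state_vector(self) -> np.ndarray:
        """Full monolithic vector [r, z, log rho_c] of the reference state."""
        return np.concatenate([self.reference_u(), np.zeros(self.n_gauss)])


def build_mesh(params: MixtureParameters, n_elem: int = 20) -> Mesh:
    """Uniform reference mesh of the cylinder mid-surface."""
    if n_elem < 4:
        raise ValueError("n_elem must be >= 4")
    nodes_z = np.linspace(0.0, params.l_o, 2 * n_elem + 1)
    base = 2 * np.arange(n_elem)[:, None]
    elements = base + np.array([0, 1, 2])
    return Mesh(params=params, nodes_z=nodes_z, elements=elements)


def fields_at_gauss(mesh: Mesh,
                    specs: Mapping[str, InsultFieldSpec | float] | None
                    ) -> dict[str, np.ndarray]:
    """Effective local parameter arrays at every Gauss point.

    ``specs`` maps controllable parameter names to an
    :class:`~equigr.fields.InsultFieldSpec` (evaluated at the Gauss points) or
    a uniform value; unnamed parameters take the baseline value.
    """
    z = mesh.gp_z
    out = local_parameter_arrays(mesh.params)
    out = {k: np.full_like(z, float(v)) for k, v in out.items()}
    for name, spec in (specs or {}).items():
        if name not in CONTROLLABLE:
            raise ValueError(f"{name!r} is not a controllable parameter")
        if isinstance(spec, InsultFieldSpec):
            out[name] = np.asarray(spec(z), dtype=float)
        else:
            out[name] = np.full_like(z, float(spec))
    return out


def local_constitutive_update(lam_theta, lam_s, local: Mapping[str, Any],
                              params: MixtureParameters, P: float,
                              sigma_o: float, rho_init=None) -> PointState:
    """Internal-variable update at a Gauss point (or arrays of points).

    Solves the local mechanobiological residual for the collagen density at
    fixed membrane deformation and assembles the full equilibrated state;
    wall shear stress is evaluated pointwise from the local deformed radius.
    """
    rho, ok = solve_local_density(lam_theta, lam_s, params, P, sigma_o,
                                  local, rho_init=rho_init)
    if not np.all(ok):
        raise NoEquilibriumError("local mechanobiological solve failed at "
                                 f"{int((~ok).sum())} point(s)")
    return evaluate_mixture(lam_theta, lam_s, rho, params, P, local=local)


# ---------------------------------------------------------------------------
# residual and tangent assembly
# ---------------------------------------------------------------------------

def _element_kinematics(mesh: Mesh, re: np.ndarray, ze: np.ndarray):
    """Stretches and geometry at the Gauss points, all shaped (n_elem, ngp)."""
    le = mesh.params.l_o / mesh.n_elem
    r = re @ _N.T
    rp = (re @ _DN.T) * (2.0 / le)
    zp = (ze @ _DN.T) * (2.0 / le)
    lam_s = np.sqrt(rp * rp + zp * zp)
    lam_t = r / mesh.params.R_o
    return r, rp, zp, lam_s, lam_t, le


def _element_arrays(mesh: Mesh, re, ze, rho, local, P, sigma_o):
    """Element nodal force contributions and Gauss-point stimulus residuals.

    ``rho`` is flattened over Gauss points; returns ``(Re_r, Re_z, g)`` with
    the first two shaped ``(n_elem, 3)`` and ``g`` flattened.
    """
    params = mesh.params
    r, rp, zp, lam_s, lam_t, le = _element_kinematics(mesh, re, ze)
    if np.any(lam_s <= 0.0) or np.any(lam_t <= 0.0):
        raise NoEquilibriumError("element inversion (non-positive stretch)")
    st = evaluate_mixture(lam_t.ravel(), lam_s.ravel(), rho, params, P,
                          local=local, stiffness=False)
    g = mechanobiological_residual(st, params, sigma_o)
    shape = lam_s.shape
    t_s = (st.sigma_zz * st.h).reshape(shape)
    t_t = (st.sigma_tt * st.h).reshape(shape)

    R_o = params.R_o
    w = _GW * (le / 2.0)
    dN = _DN * (2.0 / le)               # physical derivative, (ngp, 3)
    fr = t_s * lam_t * rp / lam_s       # multiplies dN_a (virtual dlam_s)
    gr = t_t * lam_s - P * r * zp       # multiplies N_a / R_o (virtual dr)
    fz = t_s * lam_t * zp / lam_s
    gz = P * r * rp
    Re_r = R_o * ((fr * w) @ dN) + (gr * w) @ _N
    Re_z = R_o * ((fz * w) @ dN) + (gz * w) @ _N
    return Re_r, Re_z, np.asarray(g, dtype=float)


def _split(mesh: Mesh, U: np.ndarray):
    n = mesh.n_nodes
    return U[:n], U[n:2 * n], np.exp(U[2 * n:])


def full_residual(mesh: Mesh, U: np.ndarray, local, P: float,
                  sigma_o: float, fscale: float,
                  apply_bc: bool = True) -> np.ndarray:
    """Monolithic residual [mechanical / fscale, stimulus] of the state ``U``."""
    r, z, rho = _split(mesh, U)
    Re_r, Re_z, g = _element_arrays(mesh, r[mesh.elements], z[mesh.elements],
                                    rho, local, P, sigma_o)
    n = mesh.n_nodes
    R = np.zeros(2 * n)
    np.add.at(R, mesh.elements, Re_r)
    np.add.at(R, n + mesh.elements, Re_z)
    if apply_bc:
        R[n] = 0.0
        R[2 * n - 1] = 0.0
    return np.concatenate([R / fscale, g])


def assemble_residual(mesh: Mesh, u: np.ndarray, local, P: float,
                      sigma_o: float, rho=None, apply_bc: bool = True):
    """Mechanical virtual-work residual at nodal dofs ``u = [r, z]``.

    When ``rho`` is omitted the Gauss-point densities are obtained from the
    local (internal-variable) mechanobiological solve.  Returns
    ``(R, rho, ok)``; with ``apply_bc`` the end-node axial rows are zeroed
    (their unconstrained values are the reactions).
    """
    n = mesh.n_nodes
    re = u[:n][mesh.elements]
    ze = u[n:][mesh.elements]
    if rho is None:
        _, _, _, lam_s, lam_t, _ = _element_kinematics(mesh, re, ze)
        rho, ok = solve_local_density(lam_t.ravel(), lam_s.ravel(),
                                      mesh.params, P, sigma_o, local)
    else:
        rho = np.asarray(rho, dtype=float)
        ok = np.ones(mesh.n_gauss, dtype=bool)
    Re_r, Re_z, _ = _element_arrays(mesh, re, ze, rho, local, P, sigma_o)
    R = np.zeros(2 * n)
    np.add.at(R, mesh.elements, Re_r)
    np.add.at(R, n + mesh.elements, Re_z)
    if apply_bc:
        R[n] = 0.0
        R[2 * n - 1] = 0.0
    return R, rho, ok


def tangent(mesh: Mesh, U: np.ndarray, local, P: float, sigma_o: float,
            fscale: float, mode: str = "element-fd",
            apply_bc: bool = True) -> np.ndarray:
    """Consistent monolithic tangent by finite differencing of the residual.

    ``mode="element-fd"`` differences the element contributions column-group
    by column-group (9 residual evaluations; used by Newton);
    ``mode="numeric"`` differences the fully assembled global residual dof by
    dof (reference oracle).  Both capture the wall-shear, reorientation and
    follower-load deformation dependence and the density coupling.
    """
    n = mesh.n_nodes
    ng = mesh.n_gauss
    ndof = 2 * n + ng
    if mode == "numeric":
        K = np.empty((ndof, ndof))
        for j in range(ndof):
            eps = 1e-7 * (1.0 + abs(U[j]))
            Up = U.copy()
            Up[j] += eps
            Um = U.copy()
            Um[j] -= eps
            Fp = full_residual(mesh, Up, local, P, sigma_o, fscale,
                               apply_bc=False)
            Fm = full_residual(mesh, Um, local, P, sigma_o, fscale,
                               apply_bc=False)
            K[:, j] = (Fp - Fm) / (2.0 * eps)
    elif mode == "element-fd":
        r, z, rho = _split(mesh, U)
        re0 = r[mesh.elements]
        ze0 = z[mesh.elements]
        rho0 = rho.reshape(mesh.n_elem, 3)
        Rr0, Rz0, g0 = _element_arrays(mesh, re0, ze0, rho, local, P,
                                       sigma_o)
        g0 = g0.reshape(mesh.n_elem, 3)
        K = np.zeros((ndof, ndof))
        rows_r = mesh.elements
        rows_z = mesh.elements + n
        rows_g = 2 * n + 3 * np.arange(mesh.n_elem)[:, None] + np.arange(3)

        def accumulate(cols, dRr, dRz, dg):
            for a in range(3):
                np.add.at(K, (rows_r[:, a], cols), dRr[:, a] / fscale)
                np.add.at(K, (rows_z[:, a], cols), dRz[:, a] / fscale)
                np.add.at(K, (rows_g[:, a], cols), dg[:, a])

        for comp in range(2):                        # nodal r then z columns
            base = re0 if comp == 0 else ze0
            for j in range(3):
                eps = 1e-7 * (1.0 + np.abs(base[:, j]))
                pert = base.copy()
                pert[:, j] = pert[:, j] + eps
                args = (pert, ze0) if comp == 0 else (re0, pert)
                Rr, Rz, g1 = _element_arrays(mesh, *args, rho, local, P,
                                             sigma_o)
                g1 = g1.reshape(mesh.n_elem, 3)
                cols = mesh.elements[:, j] + (0 if comp == 0 else n)
                accumulate(cols, (Rr - Rr0) / eps[:, None],
                           (Rz - Rz0) / eps[:, None],
                           (g1 - g0) / eps[:, None])
        for j in range(3):                           # log-density columns
            eps = 1e-7
            pert = rho0.copy()
            pert[:, j] = pert[:, j] * np.exp(eps)
            Rr, Rz, g1 = _element_arrays(mesh, re0, ze0, pert.ravel(),
                                         local, P, sigma_o)
            g1 = g1.reshape(mesh.n_elem, 3)
            cols = rows_g[:, j]
            accumulate(cols, (Rr - Rr0) / eps, (Rz - Rz0) / eps,
                       (g1 - g0) / eps)
    else:
        raise ValueError(f"unknown tangent mode {mode!r}")
    if apply_bc:
        for dof in (n, 2 * n - 1):
            K[dof, :] = 0.0
            K[:, dof] = 0.0
            K[dof, dof] = 1.0
    return K


def axial_reactions(mesh: Mesh, u: np.ndarray, local, P: float,
                    sigma_o: float, rho=None) -> tuple[float, float]:
    """Axial reaction forces (per radian, without 2 pi) at the fixed ends."""
    R, _, _ = assemble_residual(mesh, u, local, P, sigma_o, rho,
                                apply_bc=False)
    n = mesh.n_nodes
    return float(R[n]), float(R[2 * n - 1])


# ---------------------------------------------------------------------------
# quasi-static continuation solve
# ---------------------------------------------------------------------------

@dataclass
class StepRecord:
    scale: float
    P: float
    iterations: int
    residual_norm: float
    u: np.ndarray


@dataclass
class SimulationResult:
    """Evolved fields of one scenario continuation."""

    mesh: Mesh
    steps: list[StepRecord]
    u: np.ndarray                # nodal dofs [r, z]
    state: PointState            # structure-of-arrays over Gauss points
    gp_z: np.ndarray
    local: dict[str, np.ndarray]
    P: float
    converged: bool
    label: str = ""
    metadata: dict = dfield(default_factory=dict)

    @property
    def node_r(self) -> np.ndarray:
        return self.u[: self.mesh.n_nodes]

    @property
    def node_z(self) -> np.ndarray:
        return self.u[self.mesh.n_nodes:]

    def diameter_ratio(self) -> np.ndarray:
        """Deformed luminal diameter over reference, per Gauss point."""
        return self.state.a / self.mesh.params.a_o


def _newton(mesh: Mesh, U: np.ndarray, local, P: float, sigma_o: float,
            config: UniformSolveConfig, fscale: float):
    """Monolithic Newton at fixed load/insult; returns (U, iters, norm)."""
    F = full_residual(mesh, U, local, P, sigma_o, fscale)
    norm = np.max(np.abs(F))
    for it in range(config.max_iter):
        if norm < config.newton_tol:
            return U, it, norm
        K = tangent(mesh, U, local, P, sigma_o, fscale)
        try:
            dU = np.linalg.solve(K, -F)
        except np.linalg.LinAlgError as exc:
            raise NoEquilibriumError(f"singular tangent: {exc}") from exc
        if not np.all(np.isfinite(dU)):
            raise NoEquilibriumError("non-finite Newton direction")
        alpha = 1.0
        for _ in range(10):
            try:
                F_new = full_residual(mesh, U + alpha * dU, local, P,
                                      sigma_o, fscale)
            except (NoEquilibriumError, FloatingPointError, ValueError):
                alpha /= 2.0
                continue
            norm_new = np.max(np.abs(F_new))
            if norm_new < norm or norm_new < config.newton_tol:
                break
            alpha /= 2.0
        else:
            raise NoEquilibriumError("Newton line search failed")
        U = U + alpha * dU
        F, norm = F_new, norm_new
    raise NoEquilibriumError(
        f"Newton did not converge (residual {norm:.3e})")


def solve_scenario(mesh: Mesh,
                   field_specs: Mapping[str, InsultFieldSpec | float] | None,
                   P_target: float | None = None,
                   config: UniformSolveConfig | None = None,
                   ref: HomeostaticReference | None = None,
                   fixed_specs: Mapping[str, InsultFieldSpec | float] | None
                   = None,
                   label: str = "") -> SimulationResult:
    """Quasi-static continuation from the homeostatic state to the full insult.

    The insult fields and any pressure elevation are ramped together in
    ``config.continuation_steps`` increments with monolithic Newton iteration
    at each; failing steps are halved (down to the step implied by
    ``config.max_halvings``) before the partial result is returned with
    ``converged=False`` -- the signature of a mechanobiological static
    instability.

    ``fixed_specs`` (e.g. the end-region shear-gain regularization profile,
    under which the baseline state remains an exact equilibrium) are applied
    in full from the first step rather than ramped.
    """
    params = mesh.params
    config = config or UniformSolveConfig()
    ref = ref or baseline_reference(params)
    P_target = ref.P_o if P_target is None else float(P_target)

    base = fields_at_gauss(mesh, fixed_specs)
    target = fields_at_gauss(mesh, {**(fixed_specs or {}),
                                    **(field_specs or {})})

    U = mesh.reference_state_vector()
    fscale = ref.P_o * params.R_o * params.l_o / mesh.n_elem
    steps: list[StepRecord] = []
    ds0 = 1.0 / config.continuation_steps
    ds_min = ds0 / 2 ** config.max_halvings
    s_done, ds = 0.0, ds0
    converged = True
    while s_done < 1.0 - 1e-12:
        s = min(s_done + ds, 1.0)
        loc_s = {k: (1.0 - s) * base[k] + s * target[k] for k in base}
        P_s = (1.0 - s) * ref.P_o + s * P_target
        try:
            U_n, iters, norm = _newton(mesh, U, loc_s, P_s, ref.sigma_o,
                                       config, fscale)
        except (NoEquilibriumError, FloatingPointError):
            ds /= 2.0
            if ds < ds_min:
                converged = False
                break
            continue
        U, s_done = U_n, s
        ds = min(2.0 * ds, ds0)
        steps.append(StepRecord(scale=s, P=P_s, iterations=iters,
                                residual_norm=norm,
                                u=U[:2 * mesh.n_nodes].copy()))

    s_eff = s_done
    loc = {k: (1.0 - s_eff) * base[k] + s_eff * target[k] for k in base}
    P_eff = (1.0 - s_eff) * ref.P_o + s_eff * P_target
    r, z, rho = _split(mesh, U)
    _, _, _, lam_s, lam_t, _ = _element_kinematics(
        mesh, r[mesh.elements], z[mesh.elements])
    state = evaluate_mixture(lam_t.ravel(), lam_s.ravel(), rho, params,
                             P_eff, local=loc)
    return SimulationResult(mesh=mesh, steps=steps, u=U[:2 * mesh.n_nodes],
                            state=state, gp_z=mesh.gp_z, local=loc, P=P_eff,
                            converged=converged, label=label,
                            metadata={"insult_fraction": s_eff,
                                      "P_target": P_target,
                                      "P_o": ref.P_o,
                                      "sigma_o": ref.sigma_o,
                                      "U": U.copy()})
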