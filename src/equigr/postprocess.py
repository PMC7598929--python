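"""Derived metrics, virtual mechanical tests, and file output.

Summary metrics condense a converged simulation into the quantities used to
grade aneurysmal change: maximal local diameter increase (the clinical
aneurysm definition is a >= 50% increase), central stored energy and
circumferential material stiffness relative to their original homeostatic
values, and the axial extent of the lesion (full width at half maximum of the
diameter excess).  The equibiaxial test re-loads the evolved composition of a
material point passively from its traction-free configuration, mimicking an
ex vivo biaxial protocol on the remodeled tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize

from .constitutive import PointState, fiber_cauchy_stress
from .equilibrium import HomeostaticReference, baseline_reference
from .fem import SimulationResult
from .parameters import (MixtureParameters, fixture_table1, read_config,
                         write_config)

__all__ = [
    "SummaryMetrics",
    "summarize",
    "extract_point",
    "simulate_equibiaxial",
    "write_vtk",
    "write_csv",
    "fixture_table1",
    "read_config",
    "write_config",
]

_FMT = "%.9g"  # 9 significant digits, locale independent


@dataclass(frozen=True)
class SummaryMetrics:
    """Scalar summary of one evolved scenario."""

    label: str
    max_diameter_ratio: float     # max local diameter increase [%]
    central_W: float              # stored energy at the lesion center [kPa]
    central_W_change: float       # relative to the homeostatic value [%]
    central_ctttt: float          # central circumferential stiffness [kPa]
    central_ctttt_fold: float     # fold change vs homeostatic
    lesion_length: float          # FWHM of the diameter excess [mm]
    converged: bool

    def to_dict(self) -> dict:
        return asdict(self)


def _fwhm(z: np.ndarray, excess: np.ndarray, l_o: float) -> float:
    """Full width at half maximum of a (possibly flat) excess profile."""
    peak = float(np.max(excess))
    if peak <= 1e-12:
        return 0.0
    above = excess >= peak / 2.0
    zz = z[above]
    return float(min(zz.max() - zz.min(), l_o))


def summarize(result: SimulationResult,
              ref: HomeostaticReference | None = None) -> SummaryMetrics:
    """Compute summary metrics from the final (or last converged) fields."""
    params = result.mesh.params
    ref = ref or baseline_reference(params)
    W_o = float(ref.state.W)
    c_o = float(ref.state.c_tttt)
    z = result.gp_z
    a = np.asarray(result.state.a)
    diam_excess = a / params.a_o - 1.0
    i_central = int(np.argmin(np.abs(z - params.l_o / 2.0)))
    W_c = float(np.asarray(result.state.W)[i_central])
    c_c = float(np.asarray(result.state.c_tttt)[i_central])
    return SummaryMetrics(
        label=result.label,
        max_diameter_ratio=float(np.max(diam_excess)) * 100.0,
        central_W=W_c,
        central_W_change=(W_c - W_o) / W_o * 100.0,
        central_ctttt=c_c,
        central_ctttt_fold=c_c / c_o,
        lesion_length=_fwhm(z, diam_excess, params.l_o),
        converged=result.converged,
    )


# ---------------------------------------------------------------------------
# virtual equibiaxial testing of the remodeled composition
# ---------------------------------------------------------------------------

def extract_point(result: SimulationResult, z_o: float) -> PointState:
    """Scalar :class:`PointState` at the Gauss point nearest ``z_o``."""
    i = int(np.argmin(np.abs(result.gp_z - z_o)))

    def pick(v):
        v = np.asarray(v, dtype=float)
        return float(v.ravel()[i]) if v.size > 1 else float(v)

    kw = {name: pick(getattr(result.state, name))
          for name in ("lam_theta", "lam_z", "J", "rho_c_ratio",
                       "rho_m_ratio", "rho_e_ratio", "alpha_0h", "sigma_rr",
                       "sigma_tt", "sigma_zz", "sigma_v", "p", "W", "c_tttt",
                       "tau_ratio", "h", "a")}
    local = {k: pick(v) for k, v in result.local.items()}
    return PointState(**kw, local=local)


def _passive_biaxial_stress(state: PointState, params: MixtureParameters,
                            g_t, g_z):
    """Passive in-plane Cauchy stresses under a superimposed isochoric
    biaxial stretch ``(g_t, g_z)`` of the frozen remodeled composition,
    with plane stress (``sigma_rr = 0``)."""
    g_t = np.asarray(g_t, dtype=float)
    g_z = np.asarray(g_z, dtype=float)
    g_r = 1.0 / (g_t * g_z)
    loc = state.local
    J = float(state.J)
    phi_e = params.phi_e * float(state.rho_e_ratio) / J
    phi_m = params.phi_m * float(state.rho_m_ratio) / J
    phi_c = params.phi_c * float(state.rho_c_ratio) / J
    c_e = float(np.asarray(loc["c_e"]).ravel()[0]) if loc else params.c_e
    c1c = float(np.asarray(loc["c1_c"]).ravel()[0]) if loc else params.c1_c
    G_c = float(np.asarray(loc["G_c"]).ravel()[0]) if loc else params.G_c

    lam_r = float(state.J) / (float(state.lam_theta) * float(state.lam_z))
    le_r = lam_r * params.G_r_e * g_r
    le_t = float(state.lam_theta) * params.G_theta_e * g_t
    le_z = float(state.lam_z) * params.G_z_e * g_z
    se_rr = c_e * le_r ** 2
    se_tt = c_e * le_t ** 2
    se_zz = c_e * le_z ** 2

    alpha = float(state.alpha_0h)
    s2, c2 = np.sin(alpha) ** 2, np.cos(alpha) ** 2
    ell = np.sqrt(g_z * g_z * c2 + g_t * g_t * s2)
    s2_cur = g_t * g_t * s2 / (ell * ell)
    c2_cur = g_z * g_z * c2 / (ell * ell)
    f_ct = fiber_cauchy_stress(G_c * g_t, c1c, params.c2_c)
    f_cz = fiber_cauchy_stress(G_c * g_z, c1c, params.c2_c)
    f_cd = fiber_cauchy_stress(G_c * ell, c1c, params.c2_c)
    f_m = fiber_cauchy_stress(params.G_m * g_t, params.c1_m, params.c2_m)

    hat_tt = (phi_e * se_tt + phi_m * f_m
              + phi_c * (params.beta_theta * f_ct + params.beta_d * s2_cur * f_cd))
    hat_zz = (phi_e * se_zz
              + phi_c * (params.beta_z * f_cz + params.beta_d * c2_cur * f_cd))
    hat_rr = phi_e * se_rr
    return hat_tt - hat_rr, hat_zz - hat_rr


def simulate_equibiaxial(state: PointState, stretch_grid,
                         params: MixtureParameters) -> pd.DataFrame:
    """Simulated passive equibiaxial test of an evolved material point.

    The remodeled composition and properties are frozen, the point is first
    unloaded to its (passive) traction-free configuration, then stretched
    equibiaxially; returns a table with columns ``stretch`` (relative to the
    traction-free state), ``sigma_theta`` and ``sigma_z`` [kPa].
    """
    grid = np.asarray(list(stretch_grid), dtype=float)
    if np.any(grid <= 0.0):
        raise ValueError("stretches must be positive")

    def eqs(g):
        s_t, s_z = _passive_biaxial_stress(state, params, g[0], g[1])
        return [s_t, s_z]

    sol = optimize.root(eqs, x0=[0.8, 0.8], tol=1e-12)
    if not sol.success:
        raise RuntimeError("traction-free configuration not found: "
                           + sol.message)
    g_free = sol.x
    rows = []
    for s in grid:
        s_t, s_z = _passive_biaxial_stress(state, params, g_free[0] * s,
                                           g_free[1] * s)
        rows.append((s, float(s_t), float(s_z)))
    return pd.DataFrame(rows, columns=["stretch", "sigma_theta", "sigma_z"])


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def _gp_to_nodes(result: SimulationResult, values: np.ndarray) -> np.ndarray:
    """Nearest-Gauss-point transfer of a per-Gauss-point field to nodes."""
    z_nodes = result.mesh.nodes_z
    idx = np.abs(z_nodes[:, None] - result.gp_z[None, :]).argmin(axis=1)
    return np.asarray(values)[idx]


def write_vtk(result: SimulationResult, path: str,
              n_theta: int = 36) -> None:
    """Write the deformed surface as legacy-ASCII VTK polydata.

    The meridian is revolved into ``n_theta`` circumferential facets; point
    data carry stored energy ``W``, circumferential stiffness ``c_tttt``,
    volume ratio ``J``, and the local diameter ratio.
    """
    r = result.node_r
    z = result.node_z
    nn = len(r)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    pts = np.empty((nn * n_theta, 3))
    for j, th in enumerate(theta):
        sl = slice(j * nn, (j + 1) * nn)
        pts[sl, 0] = r * np.cos(th)
        pts[sl, 1] = r * np.sin(th)
        pts[sl, 2] = z
    polys = []
    for j in range(n_theta):
        jn = (j + 1) % n_theta
        for i in range(nn - 1):
            polys.append((j * nn + i, j * nn + i + 1,
                          jn * nn + i + 1, jn * nn + i))
    fields = {
        "W": _gp_to_nodes(result, result.state.W),
        "c_tttt": _gp_to_nodes(result, result.state.c_tttt),
        "J": _gp_to_nodes(result, result.state.J),
        "diameter_ratio": _gp_to_nodes(result, result.diameter_ratio()),
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"equigr scenario {result.label}\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} double\n")
        for p in pts:
            fh.write(" ".join(_FMT % v for v in p) + "\n")
        fh.write(f"POLYGONS {len(polys)} {5 * len(polys)}\n")
        for q in polys:
            fh.write("4 " + " ".join(str(i) for i in q) + "\n")
        fh.write(f"POINT_DATA {len(pts)}\n")
        for name, vals in fields.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            tiled = np.tile(np.asarray(vals, dtype=float), n_theta)
            for v in tiled:
                fh.write((_FMT % v) + "\n")


def write_csv(metrics, path: str) -> None:
    """Write summary metrics (one row per scenario/step) as CSV."""
    if isinstance(metrics, SummaryMetrics):
        metrics = [metrics]
    if isinstance(metrics, pd.DataFrame):
        df = metrics
    else:
        df = pd.DataFrame([m.to_dict() for m in metrics])
    df.to_csv(path, index=False, float_format=_FMT)


def read_metrics_csv(path: str) -> pd.DataFrame:
    """Read back a metrics CSV written by :func:`write_csv`."""
    return pd.read_csv(path)
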