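"""The knockout catalog: named insult cases mapped to parameter fields.

Five classes of localized insult are contrasted, each at a mild and a severe
grade, alone and with the systemic risk factors of hypertension (50% pressure
elevation) and aortic aging (uniform 30% loss of elastic fiber integrity)
superimposed:

========================  ==================  ======================
insult                    parameter           mild / severe grade
========================  ==================  ======================
elastin_integrity         c_e                 -32% / -62% (34.1 kPa)
collagen_crosslinking     c1_c                -9% / -23% (181 kPa)
contractility             T_max               -60% / -100%
mechanosensing            delta               0.075 / 0.185
mechanoregulation         G_c                 -0.4% / -1.2% (1.235)
collagen_degradation      eta                 1.05 (severe grade)
========================  ==================  ======================

Localized lesions use the Gaussian-like axial profile (end value = baseline)
together with the end-region gain-ratio profile (wall shear sensed only in
the insult-free regions).  Aging composes multiplicatively with localized
elastin insults, both being reductions of the same modulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from .equilibrium import (HomeostaticReference, NoEquilibriumError,
                          UniformSolveConfig, baseline_reference)
from .fem import (Mesh, SimulationResult, build_mesh, fields_at_gauss,
                  solve_scenario)
from .fields import InsultFieldSpec, end_region_profiles
from .parameters import MixtureParameters

__all__ = [
    "ScenarioSpec",
    "INSULT_PARAMETER",
    "severity_value",
    "knockout_catalog",
    "build_field_specs",
    "run_scenario",
    "sweep",
]

#: controllable parameter targeted by each insult class
INSULT_PARAMETER: dict[str, str] = {
    "elastin_integrity": "c_e",
    "collagen_crosslinking": "c1_c",
    "collagen_degradation": "eta",
    "contractility": "T_max",
    "mechanosensing": "delta",
    "mechanoregulation": "G_c",
}

#: central (or apex) values of the controlled parameter by severity grade
_SEVERITY: dict[str, dict[str, float]] = {
    # mild grades are fractional changes of the baseline values
    "elastin_integrity": {"mild": 0.68 * 89.71, "severe": 34.1,
                          "apex": 20.2},
    "collagen_crosslinking": {"mild": 0.91 * 234.9, "severe": 181.0,
                              "apex": 111.0},
    "collagen_degradation": {"mild": 1.05, "severe": 1.05},
    "contractility": {"mild": 0.40 * 250.0, "severe": 0.0},
    "mechanosensing": {"mild": 0.075, "severe": 0.185, "apex": 0.4},
    "mechanoregulation": {"mild": 1.25 * (1.0 - 0.004), "severe": 1.235,
                          "apex": 1.22},
}

#: uniform-insult variants (moderate grades applied along the whole segment)
_UNIFORM: dict[str, float] = {
    "elastin_integrity": 0.70 * 89.71,       # uniform mild 30% loss
    "collagen_crosslinking": 0.80 * 234.9,   # uniform moderate 20% decrease
    "contractility": 0.20 * 250.0,           # uniform 80% loss of tone
    "mechanosensing": 0.12,                  # uniform moderate 12% loss
    "mechanoregulation": 1.25 * (1.0 - 0.012),
}


def severity_value(insult: str, severity) -> float:
    """Central parameter value for a named severity or ``("custom", value)``."""
    if isinstance(severity, tuple):
        kind, value = severity
        if kind != "custom":
            raise ValueError(f"unknown severity {severity!r}")
        return float(value)
    try:
        return _SEVERITY[insult][severity]
    except KeyError as exc:
        raise ValueError(f"unknown insult/severity {insult!r}:{severity!r}"
                         ) from exc


@dataclass(frozen=True)
class ScenarioSpec:
    """One knockout case: insult, severity grade, and risk factors."""

    insult: str                      # key of INSULT_PARAMETER, or "none"
    severity: Any = "mild"           # "mild" | "severe" | ("custom", value)
    hypertension: bool = False
    pressure_multiplier: float = 1.5
    aging: bool = False
    aging_elastin_loss: float = 0.30
    geometry: str = "axisymmetric"   # or "asymmetric" (fields only)
    uniform: bool = False            # uniform instead of localized insult
    #: baseline smooth-muscle tone for this case; ``None`` keeps the
    #: parameter-set value except for elastic-fiber insults, which are run
    #: without vessel-level contractility (loss of elastic fibers associates
    #: with reduced vasoconstriction; a protective-tone variant uses 50 kPa)
    T_max_baseline: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.insult != "none" and self.insult not in INSULT_PARAMETER:
            raise ValueError(f"unknown insult {self.insult!r}")
        if self.geometry not in ("axisymmetric", "asymmetric"):
            raise ValueError(f"unknown geometry {self.geometry!r}")

    def describe(self) -> str:
        if self.label:
            return self.label
        sev = (self.severity if isinstance(self.severity, str)
               else f"{self.severity[1]:g}")
        tags = [self.insult, sev]
        if self.uniform:
            tags.append("uniform")
        if self.hypertension:
            tags.append("hypertension")
        if self.aging:
            tags.append("aging")
        if self.geometry != "axisymmetric":
            tags.append(self.geometry)
        return ":".join(tags)


def knockout_catalog() -> list[ScenarioSpec]:
    """Deterministically ordered catalog of knockout scenarios.

    5 localized insults x {mild, severe} x {none, hypertension, aging, both}
    axisymmetric cases, followed by the risk factors alone, the uniform-insult
    variants, and the asymmetric field specifications (fields only; the
    asymmetric solves are a documented non-goal).
    """
    localized = ["elastin_integrity", "collagen_crosslinking",
                 "contractility", "mechanosensing", "mechanoregulation"]
    specs: list[ScenarioSpec] = []
    for insult in localized:
        for severity in ("mild", "severe"):
            for ht, ag in ((False, False), (True, False), (False, True),
                           (True, True)):
                specs.append(ScenarioSpec(insult=insult, severity=severity,
                                          hypertension=ht, aging=ag))
    # localized collagen degradation (eta), severe grade with risk factors
    for ht, ag in ((False, False), (True, False), (False, True),
                   (True, True)):
        specs.append(ScenarioSpec(insult="collagen_degradation",
                                  severity="severe", hypertension=ht,
                                  aging=ag))
    # risk factors alone (uniform remodeling, no localized dilatation)
    specs.append(ScenarioSpec(insult="none", hypertension=True,
                              label="hypertension"))
    specs.append(ScenarioSpec(insult="none", aging=True, label="aging"))
    specs.append(ScenarioSpec(insult="none", hypertension=True, aging=True,
                              label="hypertension:aging"))
    # uniform-insult variants
    for insult, value in _UNIFORM.items():
        specs.append(ScenarioSpec(insult=insult,
                                  severity=("custom", value), uniform=True))
    # asymmetric field specifications (not solved)
    for insult in ("elastin_integrity", "collagen_crosslinking",
                   "mechanosensing", "mechanoregulation"):
        specs.append(ScenarioSpec(insult=insult,
                                  severity=("custom",
                                            _SEVERITY[insult]["apex"]),
                                  geometry="asymmetric"))
    return specs


def build_field_specs(spec: ScenarioSpec, params: MixtureParameters
                      ) -> tuple[dict[str, InsultFieldSpec | float],
                                 dict[str, InsultFieldSpec | float]]:
    """Map a scenario to the parameter fields fed to the membrane solver.

    Returns ``(ramped, fixed)``: the insult and risk-factor fields advanced
    by the continuation, and the end-region regularization profiles (the
    shear-gain ratio fading inside the lesion, where wall shear stress is not
    sensed) that are applied in full from the start -- the baseline state is
    an exact equilibrium under them.  Localized insults use the axial lesion
    profile with baseline end values; uniform insults and risk factors are
    spatially constant.  Aging multiplies the elastin modulus field by
    ``1 - aging_elastin_loss``.
    """
    ramped: dict[str, InsultFieldSpec | float] = {}
    fixed: dict[str, InsultFieldSpec | float] = {}
    aging_factor = 1.0 - spec.aging_elastin_loss if spec.aging else 1.0

    if spec.insult != "none":
        pname = INSULT_PARAMETER[spec.insult]
        central = severity_value(spec.insult, spec.severity)
        base = getattr(params, pname)
        if spec.uniform:
            value = central * (aging_factor if pname == "c_e" else 1.0)
            ramped[pname] = value
        else:
            end, cen = base, central
            if pname == "c_e":
                end, cen = end * aging_factor, cen * aging_factor
            ramped[pname] = InsultFieldSpec(
                pname, value_end=end, value_central=cen,
                l_o=params.l_o,
                symmetric=(spec.geometry == "axisymmetric"))
            k_spec, _ = end_region_profiles(params)
            fixed["K_ratio"] = k_spec
    if spec.aging and "c_e" not in ramped:
        ramped["c_e"] = params.c_e * aging_factor
    return ramped, fixed


def run_scenario(spec: ScenarioSpec, params: MixtureParameters,
                 config: UniformSolveConfig | None = None,
                 n_elem: int = 20, mesh: Mesh | None = None,
                 ref: HomeostaticReference | None = None
                 ) -> SimulationResult:
    """Run one knockout scenario through the membrane continuation solver."""
    if spec.geometry == "asymmetric":
        raise NotImplementedError(
            "asymmetric lesions are generated as fields only; "
            "their solves are outside this package's scope")
    t_max = spec.T_max_baseline
    if t_max is None and spec.insult == "elastin_integrity":
        t_max = 0.0
    if t_max is not None and t_max != params.T_max:
        params = params.replace(T_max=t_max)
        mesh = None   # rebuilt so its parameter set matches
        ref = None
    mesh = mesh or build_mesh(params, n_elem=n_elem)
    ref = ref or baseline_reference(params)
    P_target = ref.P_o * (spec.pressure_multiplier if spec.hypertension
                          else 1.0)
    ramped, fixed = build_field_specs(spec, params)
    try:
        result = solve_scenario(mesh, ramped, P_target=P_target,
                                config=config, ref=ref, fixed_specs=fixed,
                                label=spec.describe())
    except NoEquilibriumError as exc:
        raise NoEquilibriumError(f"[{spec.describe()}] {exc}") from exc
    result.metadata["scenario"] = spec
    return result


def sweep(parameter: str, grid: Iterable[float], base_spec: ScenarioSpec,
          params: MixtureParameters,
          config: UniformSolveConfig | None = None,
          n_elem: int = 20) -> pd.DataFrame:
    """Summary metrics over a monotone grid of one scenario parameter.

    ``parameter`` is either ``"severity"`` (central insult value),
    ``"z_od"`` or ``"nu_z"`` (lesion shape), or ``"pressure_multiplier"``.
    Returns one row per grid point with the scenario summary metrics.
    """
    from .postprocess import summarize

    grid = list(grid)
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be monotone non-decreasing")
    ref = baseline_reference(params)
    mesh = build_mesh(params, n_elem=n_elem)
    rows = []
    for value in grid:
        if parameter == "severity":
            spec = replace(base_spec, severity=("custom", float(value)))
            result = run_scenario(spec, params, config=config, mesh=mesh,
                                  ref=ref)
        elif parameter in ("z_od", "nu_z"):
            spec = base_spec
            ramped, fixed = build_field_specs(spec, params)
            pname = INSULT_PARAMETER[spec.insult]
            ramped[pname] = replace(ramped[pname], **{parameter: float(value)})
            if "K_ratio" in fixed:
                fixed["K_ratio"] = replace(fixed["K_ratio"],
                                           **{parameter: float(value)})
            P_t = ref.P_o * (spec.pressure_multiplier if spec.hypertension
                             else 1.0)
            result = solve_scenario(mesh, ramped, P_target=P_t, config=config,
                                    ref=ref, fixed_specs=fixed,
                                    label=f"{spec.describe()}"
                                    f":{parameter}={value:g}")
        elif parameter == "pressure_multiplier":
            spec = replace(base_spec, hypertension=True,
                           pressure_multiplier=float(value))
            result = run_scenario(spec, params, config=config, mesh=mesh,
                                  ref=ref)
        else:
            raise ValueError(f"unknown sweep parameter {parameter!r}")
        metrics = summarize(result, ref=ref)
        row = {"value": float(value), **metrics.to_dict()}
        rows.append(row)
    return pd.DataFrame(rows)
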