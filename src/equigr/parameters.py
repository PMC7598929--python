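"""Constitutive parameters of the aortic constrained-mixture model.

The wall is treated as a constrained mixture of three structurally significant
constituents -- elastin-dominated matrix (``e``), passive + active smooth
muscle (``m``), and four families of fibrillar collagen (``c``: axial,
circumferential, and two symmetric diagonal families).  All material constants,
homeostatic mass fractions, deposition (pre-)stretches, and mechanobiological
gain/sensing parameters live in a single frozen :class:`MixtureParameters`
record, which is the sole source of constitutive truth for every solver in the
package.

Units are kPa and mm throughout; angles are stored in radians.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Any, Mapping

import yaml

__all__ = [
    "MixtureParameters",
    "fixture_table1",
    "read_config",
    "write_config",
]

#: Names of parameters that insult fields may control locally.
CONTROLLABLE = (
    "c_e",
    "c1_c",
    "T_max",
    "delta",
    "xi",
    "G_c",
    "eta",
    "K_ratio",
)


@dataclass(frozen=True)
class MixtureParameters:
    """Geometry, composition, and material constants of the baseline vessel.

    Attributes
    ----------
    a_o, h_o, l_o:
        Reference (in vivo homeostatic) luminal radius, wall thickness and
        segment length [mm].
    phi_e, phi_m, phi_c:
        Homeostatic mass fractions of elastin, smooth muscle and collagen;
        they must sum to one.
    beta_theta, beta_z, beta_d:
        Fractions of collagen apportioned to the circumferential, axial and
        the (two, combined) symmetric diagonal families; sum to one.
    alpha_0o:
        Orientation of the diagonal collagen families, measured from the
        *axial* direction [rad].
    c_e:
        Elastin neo-Hookean shear modulus [kPa].
    c1_m, c2_m, c1_c, c2_c:
        Fung-exponential fiber constants for passive smooth muscle and
        collagen [kPa, -].
    G_theta_e, G_z_e, G_r_e:
        Elastin deposition stretches; radially determined by isochoricity,
        ``G_r_e = 1/(G_theta_e * G_z_e)``.
    G_m, G_c:
        Smooth-muscle and collagen fiber deposition stretches.
    eta:
        Smooth-muscle-to-collagen turnover ratio; couples evolved referential
        densities as ``rho_m = rho_c**eta``.
    K_ratio:
        Shear-to-intramural gain ratio ``K_tauw / K_sigma`` entering the
        mechanobiological equilibrium condition (only the ratio matters in
        equilibrium).
    delta, xi:
        Intramural mechanosensing and endothelial (shear) dysfunction
        fractions in [0, 1]; 0 is healthy.
    T_max, C_B, C_S, lambda_M, lambda_0:
        Vasoactive constants: maximal active stress [kPa], basal and
        shear-sensitivity tone constants [-], and the stretches of maximal /
        minimal contraction.
    P_o:
        Homeostatic transmural pressure [kPa].  Not a free input: it is
        derived at startup as the pressure that makes the baseline state an
        exact mechanical fixed point (``None`` until derived).
    Q_ratio:
        Flow ratio ``Q_h / Q_o`` (cardiac output held constant by default).
    """

    a_o: float = 0.647
    h_o: float = 0.040
    l_o: float = 15.0
    phi_e: float = 0.34
    phi_m: float = 0.33
    phi_c: float = 0.33
    beta_theta: float = 0.056
    beta_z: float = 0.067
    beta_d: float = 0.877
    alpha_0o: float = math.radians(29.9)
    c_e: float = 89.71
    c1_m: float = 261.4
    c2_m: float = 0.24
    c1_c: float = 234.9
    c2_c: float = 4.08
    G_theta_e: float = 1.90
    G_z_e: float = 1.62
    G_r_e: float = 1.0 / (1.90 * 1.62)
    G_m: float = 1.20
    G_c: float = 1.25
    eta: float = 1.0
    K_ratio: float = 0.35
    delta: float = 0.0
    xi: float = 0.0
    T_max: float = 250.0
    C_B: float = 0.8326
    C_S: float = 0.8326 / 2.0
    lambda_M: float = 1.1
    lambda_0: float = 0.4
    P_o: float | None = None
    Q_ratio: float = 1.0
    #: include the active stress in the material-stiffness linearization
    stiffness_includes_active: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` on violated invariants."""
        if abs(self.phi_e + self.phi_m + self.phi_c - 1.0) > 1e-9:
            raise ValueError("constituent mass fractions must sum to 1")
        if abs(self.beta_theta + self.beta_z + self.beta_d - 1.0) > 1e-9:
            raise ValueError("collagen family fractions must sum to 1")
        if abs(self.G_r_e * self.G_theta_e * self.G_z_e - 1.0) > 1e-9:
            raise ValueError("elastin deposition must be isochoric: "
                             "G_r_e = 1/(G_theta_e*G_z_e)")
        if not (0.0 <= self.delta <= 1.0 and 0.0 <= self.xi <= 1.0):
            raise ValueError("delta and xi must lie in [0, 1]")
        if not (self.lambda_0 < 1.0 < self.lambda_M):
            raise ValueError("require lambda_0 < 1 < lambda_M")
        for name in ("c_e", "c1_m", "c2_m", "c1_c", "c2_c", "T_max"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"modulus {name} must be non-negative")
        for name in ("a_o", "h_o", "l_o"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"geometry {name} must be positive")

    def replace(self, **changes: Any) -> "MixtureParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    @property
    def R_o(self) -> float:
        """Reference mid-surface radius [mm] carrying the membrane pressure."""
        return self.a_o + self.h_o / 2.0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def fixture_table1() -> MixtureParameters:
    """The baseline parameterization of a normal mouse descending thoracic aorta.

    This is the single source of the published parameter set used by every
    test and scenario; all defaults of :class:`MixtureParameters` equal it.
    """
    return MixtureParameters()


def read_config(path: str) -> MixtureParameters:
    """Read a flat key-value (YAML) parameter file.

    Unknown keys raise a schema error naming the offending key; omitted keys
    take their baseline values.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ValueError(f"config {path!r} must be a mapping of parameter: value")
    valid = {f.name for f in dataclasses.fields(MixtureParameters)}
    bad = set(raw) - valid
    if bad:
        raise ValueError(f"unknown parameter key(s) in {path!r}: {sorted(bad)}")
    return MixtureParameters(**raw)


def write_config(params: MixtureParameters, path: str) -> None:
    """Write the parameter set as a flat YAML mapping (lossless round trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
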