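"""Spatial insult profiles along the vessel segment.

A lesion is prescribed by modulating one controllable constitutive parameter
with a Gaussian-like exponential profile centered at the mid-length of the
segment,

    theta(z) = theta_end + (theta_central - theta_end)
               * exp(-|(z - l_o/2)/z_od|**nu_z),

optionally multiplied by an analogous circumferential factor centered at the
azimuthal apex (asymmetric lesions; field generation only -- asymmetric
*solves* are out of scope).  End values default to the baseline so the
proximal/distal segments remain homeostatic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import CONTROLLABLE, MixtureParameters

__all__ = [
    "InsultFieldSpec",
    "axisymmetric_field",
    "asymmetric_field",
    "end_region_profiles",
]


@dataclass(frozen=True)
class InsultFieldSpec:
    """Profile of one controlled parameter along (and around) the segment.

    ``value_end`` applies near the ends, ``value_central`` at the lesion
    center (``z = l_o/2``, and azimuth ``pi`` when asymmetric).  ``nu_z`` and
    ``z_od`` are the axial decay exponent [-] and deviation [mm]; ``nu_theta``
    and ``theta_od`` [rad] are the circumferential analogues used only when
    ``symmetric`` is False.
    """

    parameter_name: str
    value_end: float
    value_central: float
    l_o: float = 15.0
    nu_z: float = 5.0
    z_od: float = 3.0
    nu_theta: float = 5.0
    theta_od: float = math.pi / 3.0
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.parameter_name not in CONTROLLABLE:
            raise ValueError(
                f"{self.parameter_name!r} is not a controllable parameter")
        if self.nu_z <= 0.0 or self.nu_theta <= 0.0:
            raise ValueError("decay exponents must be positive")
        if not (0.0 < self.z_od <= self.l_o / 2.0):
            raise ValueError("z_od must lie in (0, l_o/2]")
        if not (0.0 < self.theta_od <= math.pi):
            raise ValueError("theta_od must lie in (0, pi]")

    def __call__(self, z_o, theta_o=None):
        if self.symmetric or theta_o is None:
            return axisymmetric_field(z_o, self)
        return asymmetric_field(z_o, theta_o, self)


def axisymmetric_field(z_o, spec: InsultFieldSpec):
    """Local parameter value of the axisymmetric lesion profile at ``z_o``."""
    z_o = np.asarray(z_o, dtype=float)
    if np.any(z_o < -1e-12) or np.any(z_o > spec.l_o + 1e-12):
        raise ValueError("z_o must lie in [0, l_o]")
    w = np.exp(-np.abs((z_o - spec.l_o / 2.0) / spec.z_od) ** spec.nu_z)
    return spec.value_end + (spec.value_central - spec.value_end) * w


def asymmetric_field(z_o, theta_o, spec: InsultFieldSpec):
    """Axially- and circumferentially-nonuniform profile, apex at (l_o/2, pi)."""
    theta_o = np.asarray(theta_o, dtype=float)
    if np.any(theta_o < -1e-12) or np.any(theta_o > 2.0 * math.pi + 1e-12):
        raise ValueError("theta_o must lie in [0, 2 pi]")
    z_o = np.asarray(z_o, dtype=float)
    wz = np.exp(-np.abs((z_o - spec.l_o / 2.0) / spec.z_od) ** spec.nu_z)
    wt = np.exp(-np.abs((theta_o - math.pi) / spec.theta_od) ** spec.nu_theta)
    return spec.value_end + (spec.value_central - spec.value_end) * wz * wt


def end_region_profiles(params: MixtureParameters,
                        k_ratio_central: float = 0.0,
                        k_ratio_end: float | None = None,
                        eta_end: float | None = None,
                        nu_z: float = 5.0, z_od: float = 3.0
                        ) -> tuple[InsultFieldSpec, InsultFieldSpec]:
    """Regularization profiles keeping the end regions homeostatic.

    Wall shear stress is sensed only in the insult-free (end) regions, so for
    localized lesions the shear-to-intramural gain ratio decays from its
    baseline end value to ``k_ratio_central`` (default 0) in the lesion
    center; the turnover ratio ``eta`` keeps its baseline value at the ends
    unless an explicit ``eta_end`` is supplied.  With the defaults the 0-D
    homeostatic residual at the ends is solved exactly by the baseline state.
    """
    k_end = params.K_ratio if k_ratio_end is None else k_ratio_end
    e_end = params.eta if eta_end is None else eta_end
    k_spec = InsultFieldSpec("K_ratio", value_end=k_end,
                             value_central=k_ratio_central, l_o=params.l_o,
                             nu_z=nu_z, z_od=z_od)
    eta_spec = InsultFieldSpec("eta", value_end=e_end,
                               value_central=params.eta, l_o=params.l_o,
                               nu_z=nu_z, z_od=z_od)
    return k_spec, eta_spec
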