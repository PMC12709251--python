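"""Moments P0-P2 of the lateral stress and the tension-correction length zD.

The three moments ``Pi = int z^i s(z) dz`` connect a stress profile to the
elastic constants:

    P0 = gamma + 2 k m^2 = Sigma
    P1 = -2 k m
    P2 = 2 k + kG0 + zD^2 Sigma,   zD^2 = (12 + pi^2)/54 * (lme/2)^2

Tabulated profiles are integrated by composite Simpson on their native
grid; closed forms are integrated adaptively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad, simpson

from .kink import TAIL_CUTOFF
from .params import ElasticConstants, InterfaceGeometry
from .stress import (
    COMPONENT_NAMES,
    StressProfile,
    component_sB0,
    component_sB1,
    component_sB2,
    component_sG,
    component_sT,
)

__all__ = [
    "MomentSet",
    "analytic_moments",
    "numeric_moments",
    "zD",
    "zD_quadrature",
    "thickness_ratio_for_neutral_plane",
    "gaussian_modulus_with_tension",
    "component_moment_table",
]

#: dimensionless constant in zD = sqrt((12 + pi^2)/54) * (lme/2).
_ZD_COEFF = math.sqrt((12.0 + math.pi**2) / 54.0)


@dataclass(frozen=True)
class MomentSet:
    """Zeroth, first and second moments of a lateral stress profile."""

    P0: float  # kBT/nm^2, total tension
    P1: float  # kBT/nm, bending torque (= -2km)
    P2: float  # kBT, 2k + kG0 + zD^2 Sigma

    def as_tuple(self) -> tuple:
        return (self.P0, self.P1, self.P2)


def analytic_moments(params: ElasticConstants, geom: InterfaceGeometry) -> MomentSet:
    """Closed-form moments of the model profile for the given constants."""
    Sigma = params.Sigma
    return MomentSet(
        P0=Sigma,
        P1=-2.0 * params.k * params.m,
        P2=2.0 * params.k + params.kG0 + zD(geom) ** 2 * Sigma,
    )


def _require_span(profile: StressProfile, geom: InterfaceGeometry) -> None:
    need = 2.0 * geom.lme
    if profile.z[0] > -need or profile.z[-1] < need:
        raise ValueError(
            f"profile grid [{profile.z[0]:g}, {profile.z[-1]:g}] nm is too narrow for "
            f"moment integration; span of at least [-{need:g}, {need:g}] nm "
            "(two membrane thicknesses) is required"
        )


def numeric_moments(profile: StressProfile, geom: InterfaceGeometry | None = None) -> MomentSet:
    """Simpson-rule moments of a tabulated profile.

    Requires the grid to span at least two membrane thicknesses on each
    side so the integrands have decayed.
    """
    if geom is None:
        geom = _geometry_from_metadata(profile)
    _require_span(profile, geom)
    z, s = profile.z, profile.total
    return MomentSet(*(float(simpson(z**i * s, x=z)) for i in range(3)))


def _geometry_from_metadata(profile: StressProfile) -> InterfaceGeometry:
    eps = profile.metadata.get("epsilon")
    if eps is not None:
        return InterfaceGeometry(epsilon=float(eps))
    return InterfaceGeometry.default()


def zD(geom: InterfaceGeometry) -> float:
    """Tension-correction length, closed form (nm).

    ``zD = sqrt((12 + pi^2)/54) * (lme/2) ~= 0.64 * (lme/2)``, the offset
    whose square multiplies Sigma in the second moment.
    """
    return _ZD_COEFF * (geom.lme / 2.0)


def zD_quadrature(geom: InterfaceGeometry) -> float:
    """zD recomputed as sqrt(P2 of sT / gamma) by adaptive quadrature."""
    span = TAIL_CUTOFF * geom.epsilon
    val, _ = quad(
        lambda z: z * z * component_sT(z, 1.0, geom),
        -span,
        span,
        limit=400,
    )
    return math.sqrt(val)


def thickness_ratio_for_neutral_plane() -> float:
    """The ratio lme/epsilon for which zD equals lme/3 (i.e. 2/3 of lme/2).

    zD in epsilon units is independent of the thickness convention, so the
    ratio is simply three times zD/epsilon (~ 5.73).
    """
    geom = InterfaceGeometry(epsilon=1.0)
    return 3.0 * zD_quadrature(geom)


def gaussian_modulus_with_tension(kG0: float, Sigma: float, z_off: float) -> float:
    """Tension-corrected Gaussian modulus ``kG = kG0 + z_off^2 * Sigma``."""
    return kG0 + z_off**2 * Sigma


def component_moment_table(
    params: ElasticConstants, geom: InterfaceGeometry
) -> pd.DataFrame:
    """Quadrature moments of each component: rows sB2..sT, columns P0-P2.

    The closed-form counterpart is::

        sB2: (0, 0, 2k)          sB1: (0, -2km, 0)
        sB0: (2km^2, 0, 2km^2 zD^2)
        sG:  (0, 0, kG0)         sT:  (gamma, 0, gamma zD^2)
    """
    funcs = {
        "sB2": lambda z: component_sB2(z, params.k, geom),
        "sB1": lambda z: component_sB1(z, params.k, params.m, geom),
        "sB0": lambda z: component_sB0(z, params.k, params.m, geom),
        "sG": lambda z: component_sG(z, params.kG0, geom),
        "sT": lambda z: component_sT(z, params.gamma, geom),
    }
    span = TAIL_CUTOFF * geom.epsilon
    rows = {}
    for name in COMPONENT_NAMES:
        f = funcs[name]
        rows[name] = [
            quad(lambda z, i=i: z**i * f(z), -span, span, limit=400)[0]
            for i in range(3)
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=["P0", "P1", "P2"])


def analytic_component_moment_table(
    params: ElasticConstants, geom: InterfaceGeometry
) -> pd.DataFrame:
    """The closed-form 5x3 moment table (see :func:`component_moment_table`)."""
    k, m, kG0, gamma = params.k, params.m, params.kG0, params.gamma
    zd2 = zD(geom) ** 2
    data = {
        "sB2": [0.0, 0.0, 2.0 * k],
        "sB1": [0.0, -2.0 * k * m, 0.0],
        "sB0": [2.0 * k * m * m, 0.0, 2.0 * k * m * m * zd2],
        "sG": [0.0, 0.0, kG0],
        "sT": [gamma, 0.0, gamma * zd2],
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=["P0", "P1", "P2"])


__all__.append("analytic_component_moment_table")
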