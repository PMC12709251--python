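"""Closed-form lateral stress components and the total profile s(z).

The lateral stress (tangential minus normal stress) of a large, nearly
planar vesicle decomposes into five contributions, each proportional to one
elastic constant.  With ``f = f0(u)``, ``u = -z/epsilon`` and primes
denoting d/du::

    sB2(z) = (3/sqrt(2))  (k / eps^3)      [ f''^2 + f' f''' ]
    sB1(z) = -3 sqrt(2)   (m k / eps^2)    f' f''
    sB0(z) = -(3/sqrt(2)) (m^2 k / eps)    f f''
    sG(z)  = (35/(16 sqrt(2))) (kG0/eps^3) [ 12 f'^2 f''^2 + 4 f'^3 f''' ]
    sT(z)  = -(3/(2 sqrt(2))) (gamma/eps)  f f''

The numeric prefactors are pinned by the moment identities (second moment
of sB2 equals 2k, first moment of sB1 equals -2km, zeroth moment of sB0
equals 2km^2, second moment of sG equals kG0, zeroth moment of sT equals
gamma); the test suite re-verifies each one by quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .kink import SQRT2, kink, kink_derivative
from .params import ElasticConstants, InterfaceGeometry

__all__ = [
    "COMPONENT_NAMES",
    "StressProfile",
    "component_sB2",
    "component_sB1",
    "component_sB0",
    "component_sG",
    "component_sT",
    "stress_components",
    "total_stress",
    "central_stress",
    "zero_bump_ratio",
    "sample_profile",
]

#: canonical ordering of the five stress components.
COMPONENT_NAMES = ("sB2", "sB1", "sB0", "sG", "sT")


@dataclass
class StressProfile:
    """A lateral stress profile sampled on a strictly increasing z-grid.

    ``components`` is either a dict holding all five named component arrays
    (in which case ``total`` equals their sum by construction) or ``None``
    for profiles where only the total is known, e.g. tabulated MD output or
    noisy synthetic data.
    """

    z: np.ndarray
    total: np.ndarray
    components: Optional[dict] = None
    units_tag: str = "kbt_nm3"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        if self.z.ndim != 1 or self.z.size < 2:
            raise ValueError("profile grid must be 1-D with at least two points")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("profile grid must be strictly increasing")
        if self.total.shape != self.z.shape:
            raise ValueError("total stress and grid shapes differ")
        if self.components is not None:
            self.components = {
                name: np.asarray(vals, dtype=float)
                for name, vals in self.components.items()
            }
            for name, vals in self.components.items():
                if vals.shape != self.z.shape:
                    raise ValueError(f"component {name!r} shape differs from grid")

    @property
    def n(self) -> int:
        return self.z.size

    def component(self, name: str) -> np.ndarray:
        if self.components is None:
            raise KeyError("profile carries no per-component data")
        return self.components[name]


def _u(z, geom: InterfaceGeometry):
    return -np.asarray(z, dtype=float) / geom.epsilon


def component_sB2(z, k: float, geom: InterfaceGeometry):
    """Bending stress term proportional to k: even, zero-mean, P2 = 2k."""
    u = _u(z, geom)
    fp = kink_derivative(u, 1)
    fpp = kink_derivative(u, 2)
    fppp = kink_derivative(u, 3)
    return (3.0 / SQRT2) * (k / geom.epsilon**3) * (fpp * fpp + fp * fppp)


def component_sB1(z, k: float, m: float, geom: InterfaceGeometry):
    """Bending stress term proportional to m k: odd, P1 = -2km."""
    u = _u(z, geom)
    fp = kink_derivative(u, 1)
    fpp = kink_derivative(u, 2)
    return -3.0 * SQRT2 * (m * k / geom.epsilon**2) * fp * fpp


def component_sB0(z, k: float, m: float, geom: InterfaceGeometry):
    """Bending stress term proportional to m^2 k: even, P0 = 2km^2."""
    u = _u(z, geom)
    f = kink(u)
    fpp = kink_derivative(u, 2)
    return -(3.0 / SQRT2) * (m * m * k / geom.epsilon) * f * fpp


def component_sG(z, kG0: float, geom: InterfaceGeometry):
    """Gaussian stress term: even, zero-mean, P2 = kG0."""
    u = _u(z, geom)
    fp = kink_derivative(u, 1)
    fpp = kink_derivative(u, 2)
    fppp = kink_derivative(u, 3)
    bracket = 12.0 * fp * fp * fpp * fpp + 4.0 * fp**3 * fppp
    return (35.0 / (16.0 * SQRT2)) * (kG0 / geom.epsilon**3) * bracket


def component_sT(z, gamma: float, geom: InterfaceGeometry):
    """Tension stress term: even, P0 = gamma; same shape as sB0."""
    u = _u(z, geom)
    f = kink(u)
    fpp = kink_derivative(u, 2)
    return -(3.0 / (2.0 * SQRT2)) * (gamma / geom.epsilon) * f * fpp


def stress_components(params: ElasticConstants, geom: InterfaceGeometry, z) -> dict:
    """All five components evaluated at ``z``, keyed by canonical name."""
    return {
        "sB2": component_sB2(z, params.k, geom),
        "sB1": component_sB1(z, params.k, params.m, geom),
        "sB0": component_sB0(z, params.k, params.m, geom),
        "sG": component_sG(z, params.kG0, geom),
        "sT": component_sT(z, params.gamma, geom),
    }


def total_stress(params: ElasticConstants, geom: InterfaceGeometry, z):
    """Total lateral stress s(z), the sum of the five components."""
    comps = stress_components(params, geom, z)
    return sum(comps[name] for name in COMPONENT_NAMES)


def central_stress(params: ElasticConstants, geom: InterfaceGeometry) -> float:
    """Stress at the bilayer mid-surface, s(0).

    The m- and gamma-dependent components all contain a factor f0(0) = 0 or
    f0''(0) = 0, so s(0) depends only on k and kG0:
    ``s(0) = -(3k/2 + 35 kG0/16) / (sqrt(2) eps^3)``.
    """
    eps3 = geom.epsilon**3
    return -(1.5 * params.k + 35.0 * params.kG0 / 16.0) / (SQRT2 * eps3)


def zero_bump_ratio(bracket: tuple = (-1.0, -0.5)) -> float:
    """Ratio kG0/k at which the central stress bump vanishes.

    Found by root bracketing of ``central_stress`` in the ratio; the value
    is exactly -24/35 and is independent of k and epsilon.
    """
    geom = InterfaceGeometry.default()

    def s0(ratio: float) -> float:
        return central_stress(ElasticConstants(k=1.0, kG0=ratio), geom)

    return float(brentq(s0, bracket[0], bracket[1], xtol=1e-14, rtol=8.9e-16))


def sample_profile(
    params: ElasticConstants,
    geom: InterfaceGeometry,
    z_min: float,
    z_max: float,
    n: int,
    units_tag: str = "kbt_nm3",
) -> StressProfile:
    """Evaluate all components on a uniform grid of ``n`` points."""
    if not z_min < z_max:
        raise ValueError(f"degenerate grid: z_min={z_min} must be < z_max={z_max}")
    if n < 2:
        raise ValueError(f"grid needs at least two points, got n={n}")
    z = np.linspace(z_min, z_max, int(n))
    comps = stress_components(params, geom, z)
    total = sum(comps[name] for name in COMPONENT_NAMES)
    meta = {
        "k": params.k,
        "kG0": params.kG0,
        "m": params.m,
        "gamma": params.gamma,
        "epsilon": geom.epsilon,
        "lme": geom.lme,
    }
    return StressProfile(z=z, total=total, components=comps, units_tag=units_tag, metadata=meta)
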