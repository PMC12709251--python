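"""Monolayer-bilayer consistency relations and insertion sign rules.

Bilayer elastic constants follow from the constants of the two leaflets
(index 1 = outer leaflet, z > 0; index 2 = inner leaflet, z < 0) whose
neutral surfaces sit at z = +z0 and z = -z0:

    Sigma = Sm1 + Sm2
    k     = km1 + km2
    m     = (km1 mm1 - km2 mm2) / k  +  z0 (Sm1 - Sm2) / (2 k)
    kG    = kGm1 + kGm2 - 4 z0 (km1 mm1 + km2 mm2) + z0^2 Sigma

The first-order z0 term in m is often dropped in the literature; it is kept
here by default and can be switched off.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import ElasticConstants

__all__ = [
    "MonolayerConstants",
    "combine_monolayers",
    "insertion_effect",
]


@dataclass(frozen=True)
class MonolayerConstants:
    """Elastic constants of one leaflet (energies in kBT, lengths in nm)."""

    Sigma_m: float  # leaflet tension, kBT/nm^2
    k_m: float      # leaflet bending rigidity, kBT
    m_m: float      # leaflet spontaneous curvature, nm^-1
    kG_m: float     # leaflet Gaussian modulus, kBT

    def __post_init__(self) -> None:
        if not self.k_m > 0:
            raise ValueError(f"monolayer bending rigidity must be positive, got {self.k_m}")


def combine_monolayers(
    outer: MonolayerConstants,
    inner: MonolayerConstants,
    z0: float,
    include_z0_curvature_term: bool = True,
) -> ElasticConstants:
    """Bilayer constants from the two leaflets and the neutral-plane offset.

    ``include_z0_curvature_term=False`` reproduces the common approximation
    that drops the first-order z0 correction to the spontaneous curvature.
    The mechanical tension gamma is back-computed as Sigma - 2 k m^2.
    """
    if z0 < 0:
        raise ValueError(f"neutral-plane offset must be non-negative, got z0={z0}")
    Sigma = outer.Sigma_m + inner.Sigma_m
    k = outer.k_m + inner.k_m
    if k <= 0:
        raise ValueError("combined bending rigidity must be positive")
    m = (outer.k_m * outer.m_m - inner.k_m * inner.m_m) / k
    if include_z0_curvature_term:
        m += z0 * (outer.Sigma_m - inner.Sigma_m) / (2.0 * k)
    kG = (
        outer.kG_m
        + inner.kG_m
        - 4.0 * z0 * (outer.k_m * outer.m_m + inner.k_m * inner.m_m)
        + z0**2 * Sigma
    )
    gamma = Sigma - 2.0 * k * m * m
    return ElasticConstants(k=k, kG0=kG, m=m, gamma=gamma)


_LEAFLETS = ("outer", "inner")
_DEPTHS = ("shallow", "deep")


def insertion_effect(leaflet: str, depth: str) -> tuple:
    """Signs of (delta m, delta kG) for molecule insertion into one leaflet.

    Convention: a shallow insertion (head region) generates a positive
    monolayer spontaneous curvature in that leaflet, a deep insertion
    (tail region) a negative one.  The signs follow mechanically from the
    consistency relations: delta m carries the leaflet sign (+ for outer,
    - for inner) times the monolayer curvature change, while delta kG goes
    as -4 z0 k_m times the curvature change regardless of leaflet.
    """
    if leaflet not in _LEAFLETS:
        raise ValueError(f"unknown leaflet {leaflet!r}; expected one of {_LEAFLETS}")
    if depth not in _DEPTHS:
        raise ValueError(f"unknown insertion depth {depth!r}; expected one of {_DEPTHS}")
    dm_mono = +1 if depth == "shallow" else -1
    leaflet_sign = +1 if leaflet == "outer" else -1
    return (leaflet_sign * dm_mono, -dm_mono)
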