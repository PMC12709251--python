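"""Parameter containers: elastic constants and interface geometry.

Canonical internal units: energies in kBT, lengths in nm, hence stresses in
kBT/nm^3 and tensions in kBT/nm^2.  Unit conversion lives in
:mod:`memstress.units`, never here.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ElasticConstants", "InterfaceGeometry", "DEFAULT_THICKNESS_NM"]

#: default membrane thickness (nm); the interface parameter follows as lme/6.
DEFAULT_THICKNESS_NM = 5.0


@dataclass(frozen=True)
class ElasticConstants:
    """Curvature-elastic constants of the bilayer.

    Attributes
    ----------
    k : float
        Bending rigidity (kBT), must be positive.
    kG0 : float
        Intrinsic Gaussian modulus at zero total tension (kBT);
        typically between -k and -0.7 k.
    m : float
        Bilayer spontaneous curvature (nm^-1); positive means the membrane
        prefers to bulge outward (toward z > 0).
    gamma : float
        Mechanical tension (kBT/nm^2).
    """

    k: float
    kG0: float = 0.0
    m: float = 0.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"bending rigidity must be positive, got k={self.k}")

    @property
    def spontaneous_tension(self) -> float:
        """Tension contribution 2 k m^2 from leaflet asymmetry (kBT/nm^2)."""
        return 2.0 * self.k * self.m**2

    @property
    def Sigma(self) -> float:
        """Total tension gamma + 2 k m^2 (kBT/nm^2); always recomputed."""
        return self.gamma + self.spontaneous_tension


@dataclass(frozen=True)
class InterfaceGeometry:
    """Diffuse-interface width parameter and membrane thickness.

    The thickness is tied to the interface parameter by
    ``lme = thickness_ratio * epsilon``.  The default ratio 6 matches the
    convention 6 epsilon = lme = 5 nm; the alternative ratio ~5.73 makes the
    tension-correction length exactly one third of the thickness.
    """

    epsilon: float
    thickness_ratio: float = 6.0

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError(f"interface parameter must be positive, got {self.epsilon}")
        if not 5.0 <= self.thickness_ratio <= 7.0:
            raise ValueError(
                "thickness_ratio (lme/epsilon) outside the accepted range [5, 7]: "
                f"{self.thickness_ratio}"
            )

    @classmethod
    def from_thickness(cls, lme: float, thickness_ratio: float = 6.0) -> "InterfaceGeometry":
        """Build from a membrane thickness in nm (epsilon = lme / ratio)."""
        if not lme > 0:
            raise ValueError(f"membrane thickness must be positive, got {lme}")
        return cls(epsilon=lme / thickness_ratio, thickness_ratio=thickness_ratio)

    @classmethod
    def default(cls) -> "InterfaceGeometry":
        return cls.from_thickness(DEFAULT_THICKNESS_NM)

    @property
    def lme(self) -> float:
        """Membrane thickness (nm)."""
        return self.thickness_ratio * self.epsilon
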