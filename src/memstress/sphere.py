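"""Radial energy quadratures for a large spherical vesicle and their
sharp-interface (Canham-Helfrich) limits, plus a 1D planar relaxation.

For a sphere of diameter ``Dve`` the phase field depends only on the radius
and the three energy contributions reduce to one-dimensional quadratures in
the dimensionless radius ``rbar = r/Dve``, localized at ``rbar = 1/2`` with
width ``lam = epsilon/Dve``.  As ``lam -> 0`` they approach the closed
forms of the sharp-interface theory:

    bending   ->  8 pi k - 8 pi m k Dve + 2 pi k m^2 Dve^2
    gaussian  ->  4 pi kG0                       (topological)
    tension   ->  gamma * pi * Dve^2             (tension times area)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .kink import SQRT2, kink_derivative
from .params import ElasticConstants, InterfaceGeometry

__all__ = [
    "SphericalVesicle",
    "bending_energy_radial",
    "gaussian_energy_radial",
    "tension_energy_radial",
    "ch_closed_forms",
    "convergence_order",
    "planar_relaxation",
    "RelaxationResult",
]

#: half-width of the radial integration window in units of lam; the
#: integrand is below 1e-24 of its peak beyond 20 interface widths.
_WINDOW = 20.0


@dataclass(frozen=True)
class SphericalVesicle:
    """A sphere of diameter ``Dve`` (nm) with interface ratio ``lam = eps/Dve``."""

    Dve: float
    lam: float

    def __post_init__(self) -> None:
        if not self.Dve > 0:
            raise ValueError(f"vesicle diameter must be positive, got {self.Dve}")
        if not 0 < self.lam < 0.2:
            raise ValueError(
                f"interface ratio lam={self.lam} outside the asymptotic range (0, 0.2)"
            )
        if self.lam > 0.05:
            warnings.warn(
                f"lam={self.lam} is large for the sharp-interface regime (> 0.05)",
                stacklevel=3,
            )

    @classmethod
    def from_geometry(cls, Dve: float, geom: InterfaceGeometry) -> "SphericalVesicle":
        return cls(Dve=Dve, lam=geom.epsilon / Dve)

    @property
    def epsilon(self) -> float:
        return self.lam * self.Dve


def _radial_window(lam: float) -> tuple:
    return max(0.0, 0.5 - _WINDOW * lam), 0.5 + _WINDOW * lam


def _quad(fn, lam: float, **quad_opts) -> float:
    lo, hi = _radial_window(lam)
    opts = {"limit": 400, "epsabs": 1e-13, "epsrel": 1e-12}
    opts.update(quad_opts)
    val, err = quad(fn, lo, hi, **opts)
    if not math.isfinite(val):
        raise RuntimeError(f"radial quadrature failed (estimated error {err:g})")
    return val


def bending_energy_radial(
    params: ElasticConstants, vesicle: SphericalVesicle, **quad_opts
) -> float:
    """Bending energy of the spherical interface, by radial quadrature.

    ``4 pi (3k/sqrt(2)) int f0'^2((1/2 - rbar)/lam)/lam (1/rbar - mbar)^2
    rbar^2 drbar`` with ``mbar = m Dve``.
    """
    lam = vesicle.lam
    mbar = params.m * vesicle.Dve

    def integrand(rbar: float) -> float:
        fp = kink_derivative((0.5 - rbar) / lam, 1)
        return fp * fp / lam * (1.0 / rbar - mbar) ** 2 * rbar * rbar

    return 4.0 * math.pi * (3.0 * params.k / SQRT2) * _quad(integrand, lam, **quad_opts)


def gaussian_energy_radial(
    kG0: float, vesicle: SphericalVesicle, **quad_opts
) -> float:
    """Gaussian energy ``4 pi (35/(8 sqrt(2))) kG0 int f0'^4/lam drbar``."""
    lam = vesicle.lam

    def integrand(rbar: float) -> float:
        fp = kink_derivative((0.5 - rbar) / lam, 1)
        return fp**4 / lam

    return 4.0 * math.pi * (35.0 / (8.0 * SQRT2)) * kG0 * _quad(integrand, lam, **quad_opts)


def tension_energy_radial(
    gamma: float, vesicle: SphericalVesicle, **quad_opts
) -> float:
    """Tension energy ``4 pi gamma Dve^2 (3/(2 sqrt(2))) int f0'^2/lam rbar^2 drbar``."""
    lam = vesicle.lam

    def integrand(rbar: float) -> float:
        fp = kink_derivative((0.5 - rbar) / lam, 1)
        return fp * fp / lam * rbar * rbar

    pref = 4.0 * math.pi * gamma * vesicle.Dve**2 * 3.0 / (2.0 * SQRT2)
    return pref * _quad(integrand, lam, **quad_opts)


def ch_closed_forms(
    params: ElasticConstants, vesicle: SphericalVesicle
) -> tuple:
    """Sharp-interface sphere energies (EB, EG, ET)."""
    k, m, D = params.k, params.m, vesicle.Dve
    EB = 8.0 * math.pi * k - 8.0 * math.pi * m * k * D + 2.0 * math.pi * k * m * m * D * D
    EG = 4.0 * math.pi * params.kG0
    ET = params.gamma * math.pi * D * D
    return EB, EG, ET


_ENERGY_KINDS = ("bending", "gaussian", "tension")

#: errors below this relative floor are considered numerically converged.
_CONVERGED_FLOOR = 1e-9


def convergence_order(
    energy_kind: str,
    lambdas,
    params: ElasticConstants,
    Dve: float = 1000.0,
) -> float:
    """Empirical convergence order of a radial quadrature toward its limit.

    Evaluates the energy at each ``lam`` (decreasing, at fixed diameter) and
    fits the log-log slope of the absolute error against the closed form.
    Returns ``math.inf`` when every error is already below a relative floor
    of the closed-form value (the quadrature is converged and no order can
    be measured; the Gaussian energy is in this regime for any practical
    ``lam`` since its reduced integrand has no radial weight).
    """
    if energy_kind not in _ENERGY_KINDS:
        raise ValueError(f"unknown energy kind {energy_kind!r}; expected one of {_ENERGY_KINDS}")
    lams = [float(l) for l in lambdas]
    if len(lams) < 3 or any(b >= a for a, b in zip(lams, lams[1:])):
        raise ValueError("need at least 3 strictly decreasing lambda values")

    errors = []
    for lam in lams:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ves = SphericalVesicle(Dve=Dve, lam=lam)
        EB, EG, ET = ch_closed_forms(params, ves)
        if energy_kind == "bending":
            err = abs(bending_energy_radial(params, ves) - EB)
            scale = max(1.0, abs(EB))
        elif energy_kind == "gaussian":
            err = abs(gaussian_energy_radial(params.kG0, ves) - EG)
            scale = max(1.0, abs(EG))
        else:
            err = abs(tension_energy_radial(params.gamma, ves) - ET)
            scale = max(1.0, abs(ET))
        errors.append((err, scale))

    if all(err <= _CONVERGED_FLOOR * scale for err, scale in errors):
        return math.inf
    slope = np.polyfit(np.log([l for l in lams]), np.log([max(e, 1e-300) for e, _ in errors]), 1)[0]
    return float(slope)


@dataclass
class RelaxationResult:
    """Outcome of the planar gradient-flow relaxation."""

    z: np.ndarray
    phi: np.ndarray
    residual: float
    steps: int
    energies: np.ndarray  # energy sampled along the iteration
    converged: bool


def _planar_energy(phi: np.ndarray, dz: float, eps: float) -> float:
    # discrete version of int [ (1 - phi^2)^2 / (2 eps^2) + phi_z^2 ] dz
    bulk = (1.0 - phi**2) ** 2 / (2.0 * eps**2)
    grad = np.diff(phi) / dz
    return float(np.trapezoid(bulk, dx=dz) + np.sum(grad**2) * dz)


def planar_relaxation(
    initial,
    z,
    geom: InterfaceGeometry,
    tol: float = 1e-6,
    max_steps: int = 400_000,
    step_size: float | None = None,
    energy_every: int = 200,
) -> RelaxationResult:
    """Relax a 1D profile to the planar kink by explicit gradient flow.

    Iterates ``phi <- phi + dt [ phi_zz - (phi^2 - 1) phi / eps^2 ]`` with
    the endpoint values held fixed (they must be +1 at the inner end and -1
    at the outer end) until the stationarity residual
    ``max | phi_zz - (phi^2 - 1) phi / eps^2 |`` drops below ``tol``.
    The explicit Euler step is CFL-limited to ``dz^2 / 4``.
    """
    z = np.asarray(z, dtype=float)
    phi = np.array(initial, dtype=float, copy=True)
    if z.shape != phi.shape or z.ndim != 1 or z.size < 5:
        raise ValueError("z and initial must be matching 1-D arrays (>= 5 points)")
    dz = z[1] - z[0]
    if not np.allclose(np.diff(z), dz):
        raise ValueError("planar relaxation requires a uniform grid")
    eps = geom.epsilon
    if z[0] > -4.0 * geom.lme or z[-1] < 4.0 * geom.lme:
        raise ValueError("relaxation domain must span at least [-4 lme, 4 lme]")
    if not (abs(phi[0] - 1.0) < 1e-9 and abs(phi[-1] + 1.0) < 1e-9):
        raise ValueError("boundary values must be +1 at z_min and -1 at z_max")

    dt_max = dz * dz / 4.0
    dt = dt_max if step_size is None else float(step_size)
    if dt > dt_max + 1e-15:
        raise ValueError(f"step_size {dt:g} exceeds the CFL limit {dt_max:g}")

    energies = [_planar_energy(phi, dz, eps)]
    residual = math.inf
    steps = 0
    while steps < max_steps:
        lap = (phi[:-2] - 2.0 * phi[1:-1] + phi[2:]) / dz**2
        force = lap - (phi[1:-1] ** 2 - 1.0) * phi[1:-1] / eps**2
        residual = float(np.max(np.abs(force)))
        if residual < tol:
            break
        phi[1:-1] += dt * force
        steps += 1
        if steps % energy_every == 0:
            e = _planar_energy(phi, dz, eps)
            if e > energies[-1] * (1.0 + 1e-12) + 1e-12:
                raise RuntimeError(
                    f"gradient flow diverged (energy increased at step {steps}); "
                    "reduce step_size"
                )
            energies.append(e)
    energies.append(_planar_energy(phi, dz, eps))
    return RelaxationResult(
        z=z,
        phi=phi,
        residual=residual,
        steps=steps,
        energies=np.asarray(energies),
        converged=residual < tol,
    )
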