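"""Planar kink solution of the phase-field model and its calculus.

The order parameter across a flat membrane is ``f0(u) = tanh(u / sqrt(2))``
in the stretched coordinate ``u = -z / epsilon`` (``z`` in nm, ``z = 0`` at
the bilayer mid-surface, ``z > 0`` the outer leaflet).  Every stress
component, moment, and energy quadrature in this package is built from
``f0`` and its first three derivatives, so the closed forms here are the
single source of truth for the profile shape.

Closed-form derivative chain (primes are d/du, ``f = f0(u)``)::

    f0'   = (1 - f^2) / sqrt(2)
    f0''  = -f (1 - f^2)
    f0''' = (1 - f^2)(3 f^2 - 1) / sqrt(2)

and the stationarity identity ``f0'' = (f0^2 - 1) f0``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad

__all__ = [
    "SQRT2",
    "KINK_SQUARE_INTEGRAL",
    "KINK_QUARTIC_INTEGRAL",
    "TAIL_CUTOFF",
    "kink",
    "kink_derivative",
    "kink_ode_residual",
    "weak_limit_constant",
]

SQRT2 = math.sqrt(2.0)

#: closed form of ``int f0'(u)^2 du`` over the real line.
KINK_SQUARE_INTEGRAL = 2.0 * SQRT2 / 3.0

#: closed form of ``int f0'(u)^4 du`` over the real line.
KINK_QUARTIC_INTEGRAL = 8.0 * SQRT2 / 35.0

#: |u| beyond which every integrand used here is < 1e-24; improper
#: integrals are truncated to [-TAIL_CUTOFF, TAIL_CUTOFF].
TAIL_CUTOFF = 40.0


def _as_finite_array(u):
    arr = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("kink profile requires finite input coordinates")
    return arr


def kink(u):
    """Kink profile ``f0(u) = tanh(u / sqrt(2))``.

    Odd, strictly increasing, with values in (-1, 1).  Accepts scalars or
    arrays; rejects non-finite input.
    """
    arr = _as_finite_array(u)
    out = np.tanh(arr / SQRT2)
    return out if out.ndim else float(out)


def kink_derivative(u, order: int = 1):
    """Derivative ``d^order f0 / du^order`` for ``order`` in {1, 2, 3}.

    Uses the closed forms obtained by repeatedly applying
    ``sqrt(2) f0' = 1 - f0^2``.
    """
    if order not in (1, 2, 3):
        raise ValueError(f"unsupported derivative order {order!r}; expected 1, 2 or 3")
    arr = _as_finite_array(u)
    f = np.tanh(arr / SQRT2)
    sech2 = 1.0 - f * f
    if order == 1:
        out = sech2 / SQRT2
    elif order == 2:
        out = -f * sech2
    else:
        out = sech2 * (3.0 * f * f - 1.0) / SQRT2
    return out if out.ndim else float(out)


def kink_ode_residual(u):
    """Residual of the planar stationarity equation ``f0'' = (f0^2 - 1) f0``.

    Vanishes identically (to rounding) for the exact kink; exposed so that
    callers can assert the identity on arbitrary grids.
    """
    arr = _as_finite_array(u)
    f = np.tanh(arr / SQRT2)
    out = kink_derivative(arr, 2) - (f * f - 1.0) * f
    return out if np.ndim(out) else float(out)


def weak_limit_constant(power: int, cutoff: float = TAIL_CUTOFF) -> float:
    """``int f0'(u)**power du`` over the real line, by adaptive quadrature.

    Only the powers appearing in the sharp-interface limits are supported:
    ``power=2`` (value ``2 sqrt(2) / 3``) and ``power=4``
    (value ``8 sqrt(2) / 35``).  The quadrature is truncated at
    ``|u| <= cutoff``; the integrand decays like ``exp(-sqrt(2) p |u|)`` so
    the default cutoff is far beyond double precision.
    """
    if power not in (2, 4):
        raise ValueError(f"unsupported power {power!r}; expected 2 or 4")
    value, _ = quad(lambda x: kink_derivative(x, 1) ** power, -cutoff, cutoff)
    return value
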