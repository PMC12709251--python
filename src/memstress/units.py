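"""Unit conversions between thermal (kBT/nm-based) and SI-style units.

All conversions are exact linear factors routed through SI.  A temperature
is needed whenever a kBT-based unit is involved; the package default is
298.15 K.
"""

from __future__ import annotations

__all__ = [
    "BOLTZMANN_J_PER_K",
    "DEFAULT_TEMPERATURE_K",
    "STRESS_UNITS",
    "TENSION_UNITS",
    "ENERGY_UNITS",
    "convert_stress",
    "convert_tension",
    "convert_energy",
]

BOLTZMANN_J_PER_K = 1.380649e-23  # exact (SI definition)
AVOGADRO_PER_MOL = 6.02214076e23  # exact (SI definition)
DEFAULT_TEMPERATURE_K = 298.15

STRESS_UNITS = ("kbt_nm3", "bar", "pa")
TENSION_UNITS = ("kbt_nm2", "mn_m")
ENERGY_UNITS = ("kbt", "kj_mol", "j")


def _kbt_joule(temperature: float) -> float:
    if temperature is None or not temperature > 0:
        raise ValueError(f"temperature must be a positive kelvin value, got {temperature}")
    return BOLTZMANN_J_PER_K * temperature


def _convert(value, from_unit, to_unit, table, kind, temperature):
    if from_unit not in table:
        raise ValueError(f"unknown {kind} unit {from_unit!r}; expected one of {tuple(table)}")
    if to_unit not in table:
        raise ValueError(f"unknown {kind} unit {to_unit!r}; expected one of {tuple(table)}")
    factor_from = table[from_unit](temperature)
    factor_to = table[to_unit](temperature)
    return value * (factor_from / factor_to)


def convert_stress(value, from_unit: str, to_unit: str,
                   temperature: float = DEFAULT_TEMPERATURE_K):
    """Convert a stress value; 1 kbt_nm3 = kB*T / 1e-27 Pa (~41.4 bar at 300 K)."""
    table = {
        "kbt_nm3": lambda T: _kbt_joule(T) / 1e-27,
        "bar": lambda T: 1e5,
        "pa": lambda T: 1.0,
    }
    return _convert(value, from_unit, to_unit, table, "stress", temperature)


def convert_tension(value, from_unit: str, to_unit: str,
                    temperature: float = DEFAULT_TEMPERATURE_K):
    """Convert a tension value; 1 kbt_nm2 = kB*T / 1e-18 N/m (~4.14 mN/m at 300 K)."""
    table = {
        "kbt_nm2": lambda T: _kbt_joule(T) / 1e-18,
        "mn_m": lambda T: 1e-3,
    }
    return _convert(value, from_unit, to_unit, table, "tension", temperature)


def convert_energy(value, from_unit: str, to_unit: str,
                   temperature: float = DEFAULT_TEMPERATURE_K):
    """Convert an energy value between kBT, kJ/mol and J."""
    table = {
        "kbt": _kbt_joule,
        "kj_mol": lambda T: 1e3 / AVOGADRO_PER_MOL,
        "j": lambda T: 1.0,
    }
    return _convert(value, from_unit, to_unit, table, "energy", temperature)
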