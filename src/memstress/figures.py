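"""Curve-data export for the six standard figure families.

Each figure id maps to a family of stress profiles evaluated with the
documented parameter sets (default geometry 6 epsilon = 5 nm, k = 20 kBT
unless overridden).  Only curve data is produced — rendering is out of
scope; files go through :mod:`memstress.profile_io`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .params import ElasticConstants, InterfaceGeometry
from .profile_io import write_profile
from .stress import StressProfile, component_sB0, component_sB1, component_sB2, component_sG, component_sT, sample_profile
from .units import DEFAULT_TEMPERATURE_K, convert_tension

__all__ = ["FIGURE_IDS", "figure_curves", "export_figure_data"]

FIGURE_IDS = (1, 2, 3, 4, 5, 6)

_DEFAULTS = {
    "k": 20.0,
    "lme": 5.0,
    "z_min": -4.0,
    "z_max": 4.0,
    "n": 801,
    "temperature": DEFAULT_TEMPERATURE_K,
}

#: tension values (mN/m) used by the tension-contribution family.
_FIG5A_GAMMAS_MN_M = (0.01, 0.02, 0.04)
_FIG5B_THICKNESSES = (4.5, 4.75, 5.0)
_FIG4_RATIOS = (-0.6, -24.0 / 35.0, -0.7, -0.8, -1.0)


def _shape_curve(z, values, name: str, meta: dict) -> StressProfile:
    meta = dict(meta)
    meta["curve"] = name
    return StressProfile(z=z, total=np.asarray(values), components=None, metadata=meta)


def figure_curves(figure_id: int, overrides: dict | None = None) -> dict:
    """Return the curves of one figure family as ``{label: StressProfile}``."""
    if figure_id not in FIGURE_IDS:
        raise ValueError(f"unknown figure id {figure_id!r}; expected one of {FIGURE_IDS}")
    opts = dict(_DEFAULTS)
    if overrides:
        unknown = set(overrides) - set(opts)
        if unknown:
            raise ValueError(f"unknown override keys: {sorted(unknown)}")
        opts.update(overrides)

    geom = InterfaceGeometry.from_thickness(opts["lme"])
    z = np.linspace(opts["z_min"], opts["z_max"], int(opts["n"]))
    k = opts["k"]
    base_meta = {"figure": figure_id, "epsilon": geom.epsilon, "lme": geom.lme}
    curves: dict = {}

    if figure_id == 1:
        # bending components normalized per unit constant (k, mk, m^2 k)
        curves["sB2_per_k"] = _shape_curve(
            z, component_sB2(z, 1.0, geom), "sB2_per_k", base_meta)
        curves["sB1_per_mk"] = _shape_curve(
            z, component_sB1(z, 1.0, 1.0, geom), "sB1_per_mk", base_meta)
        curves["sB0_per_m2k"] = _shape_curve(
            z, component_sB0(z, 1.0, 1.0, geom), "sB0_per_m2k", base_meta)
    elif figure_id == 2:
        curves["sG_per_kG"] = _shape_curve(
            z, component_sG(z, 1.0, geom), "sG_per_kG", base_meta)
    elif figure_id in (3, 6):
        ratio = -0.7 if figure_id == 3 else -0.8
        for m in (0.0, 0.1, -0.1):
            params = ElasticConstants(k=k, kG0=ratio * k, m=m, gamma=0.0)
            prof = sample_profile(params, geom, opts["z_min"], opts["z_max"], opts["n"])
            prof.metadata.update(base_meta)
            curves[f"m={m:+g}" if m else "m=0"] = prof
    elif figure_id == 4:
        for ratio in _FIG4_RATIOS:
            params = ElasticConstants(k=k, kG0=ratio * k, m=0.0, gamma=0.0)
            prof = sample_profile(params, geom, opts["z_min"], opts["z_max"], opts["n"])
            prof.metadata.update(base_meta)
            prof.metadata["kG_over_k"] = ratio
            curves[f"kG_over_k={ratio:.6g}"] = prof
    elif figure_id == 5:
        for g_mn in _FIG5A_GAMMAS_MN_M:
            gamma = convert_tension(g_mn, "mn_m", "kbt_nm2", opts["temperature"])
            meta = dict(base_meta)
            meta.update({"gamma_mN_m": g_mn, "gamma": gamma})
            curves[f"a_gamma={g_mn:g}mN_m"] = _shape_curve(
                z, component_sT(z, gamma, geom), f"sT_gamma={g_mn}", meta)
        gamma_b = convert_tension(0.02, "mn_m", "kbt_nm2", opts["temperature"])
        for lme in _FIG5B_THICKNESSES:
            g = InterfaceGeometry.from_thickness(lme)
            params = ElasticConstants(k=k, kG0=-0.7 * k, m=0.0, gamma=gamma_b)
            prof = sample_profile(params, g, opts["z_min"], opts["z_max"], opts["n"])
            prof.metadata.update({"figure": 5, "gamma_mN_m": 0.02})
            curves[f"b_lme={lme:g}"] = prof
    return curves


def export_figure_data(figure_id: int, outdir, overrides: dict | None = None) -> list:
    """Write every curve of one figure family to ``outdir``; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, prof in figure_curves(figure_id, overrides).items():
        safe = label.replace("/", "_").replace("=", "_").replace("+", "p").replace(" ", "")
        path = outdir / f"fig{figure_id}_{safe}.tsv"
        write_profile(prof, path)
        paths.append(path)
    return paths
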