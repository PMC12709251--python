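"""Text I/O for stress profiles.

The on-disk format is whitespace/tab-separated numeric columns preceded by
``#`` header lines carrying ``key = value`` metadata.  Column 1 is z (nm),
column 2 the total stress; the five per-component columns may follow, in
which case a ``columns`` metadata line names them.  The format is
greppable, diff-able and round-trips losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .stress import COMPONENT_NAMES, StressProfile

__all__ = ["ProfileFormatError", "read_profile", "write_profile"]

_FLOAT_FMT = "%.17g"  # lossless for float64


class ProfileFormatError(ValueError):
    """Raised for malformed profile files; messages carry line numbers."""


def _parse_meta_value(text: str):
    try:
        return float(text)
    except ValueError:
        return text


def read_profile(path) -> StressProfile:
    """Read a profile file; see the module docstring for the format."""
    path = Path(path)
    metadata: dict = {}
    columns: list | None = None
    z_rows: list = []
    data_rows: list = []
    ncol: int | None = None

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key, val = key.strip(), val.strip()
                    if key == "columns":
                        columns = val.split()
                    elif key:
                        metadata[key] = _parse_meta_value(val)
                continue
            fields = line.split()
            if ncol is None:
                ncol = len(fields)
                if ncol < 2:
                    raise ProfileFormatError(
                        f"{path}:{lineno}: expected at least two columns (z, stress), "
                        f"got {ncol}"
                    )
            elif len(fields) != ncol:
                raise ProfileFormatError(
                    f"{path}:{lineno}: row has {len(fields)} columns, expected {ncol}"
                )
            try:
                values = [float(f) for f in fields]
            except ValueError as exc:
                raise ProfileFormatError(
                    f"{path}:{lineno}: non-numeric value in data row: {exc}"
                ) from None
            if z_rows and values[0] <= z_rows[-1]:
                raise ProfileFormatError(
                    f"{path}:{lineno}: z column must be strictly increasing "
                    f"({values[0]:g} after {z_rows[-1]:g})"
                )
            z_rows.append(values[0])
            data_rows.append(values[1:])

    if len(z_rows) < 2:
        raise ProfileFormatError(
            f"{path}: no usable data rows (need at least two z samples)"
        )

    z = np.asarray(z_rows)
    data = np.asarray(data_rows)
    units_tag = str(metadata.pop("units", "kbt_nm3"))

    if columns is None:
        columns = ["z", "total"] + list(COMPONENT_NAMES)[: data.shape[1] - 1]
    if columns[0] != "z":
        raise ProfileFormatError(f"{path}: first declared column must be 'z'")
    names = columns[1:]
    if len(names) != data.shape[1]:
        raise ProfileFormatError(
            f"{path}: 'columns' header names {len(names) + 1} columns but data rows "
            f"have {data.shape[1] + 1}"
        )
    if "total" not in names:
        raise ProfileFormatError(f"{path}: no 'total' column declared")
    total = data[:, names.index("total")]
    components = {
        name: data[:, i] for i, name in enumerate(names) if name in COMPONENT_NAMES
    }
    return StressProfile(
        z=z,
        total=total,
        components=components or None,
        units_tag=units_tag,
        metadata=metadata,
    )


def write_profile(profile: StressProfile, path) -> Path:
    """Write a profile as annotated TSV; metadata keys are preserved."""
    path = Path(path)
    names = ["total"]
    arrays = [profile.total]
    if profile.components is not None:
        for name in COMPONENT_NAMES:
            if name in profile.components:
                names.append(name)
                arrays.append(profile.components[name])
    with path.open("w") as fh:
        fh.write("# memstress stress profile\n")
        fh.write(f"# units = {profile.units_tag}\n")
        for key, val in profile.metadata.items():
            if isinstance(val, float):
                fh.write(f"# {key} = {_FLOAT_FMT % val}\n")
            else:
                fh.write(f"# {key} = {val}\n")
        fh.write(f"# columns = z {' '.join(names)}\n")
        for i in range(profile.z.size):
            row = [_FLOAT_FMT % profile.z[i]] + [_FLOAT_FMT % a[i] for a in arrays]
            fh.write("\t".join(row) + "\n")
    return path
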