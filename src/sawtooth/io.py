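"""Curve and table file formats.

Force curves are tab-separated text with ``#key=value`` header lines
(``curve_id``, ``speed_nm_s``, ``k_N_m``, ``temperature_K``) and a
``#columns=`` declaration.  Supported column pairs:

    extension_nm  force_pN      (native)
    piezo_nm      force_pN      (converted on load: x = z - F/k_c)
    *             force_nN      (converted on load: 1 nN = 1000 pN)

Values round-trip exactly (written with 17 significant digits).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import N_PER_M_TO_PN_PER_NM
from .curves import EVENT_COLUMNS, CurveMeta, ForceCurve

__all__ = [
    "CurveFormatError",
    "read_curve",
    "write_curve",
    "read_event_table",
    "write_event_table",
]

_REQUIRED_META = ("speed_nm_s", "k_N_m")


class CurveFormatError(ValueError):
    """A curve file violates the format contract."""


def write_curve(curve: ForceCurve, path) -> None:
    """Write a curve in the native extension/force TSV format."""
    m = curve.metadata
    with open(path, "w") as fh:
        fh.write(f"#curve_id={m.curve_id}\n")
        fh.write(f"#speed_nm_s={m.speed_nm_s:.17g}\n")
        fh.write(f"#k_N_m={m.k_N_m:.17g}\n")
        fh.write(f"#temperature_K={m.temperature_K:.17g}\n")
        fh.write("#columns=extension_nm\tforce_pN\n")
        for x, f in zip(curve.extension, curve.force):
            fh.write(f"{x:.17g}\t{f:.17g}\n")


def read_curve(path) -> ForceCurve:
    """Read a curve file, converting units and coordinates as declared."""
    meta: dict[str, str] = {}
    columns: list[str] | None = None
    data: list[tuple[float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:]
                if "=" not in body:
                    continue
                key, value = body.split("=", 1)
                key = key.strip()
                if key == "columns":
                    columns = value.strip().split("\t")
                    if len(columns) == 1:
                        columns = value.strip().split()
                else:
                    meta[key] = value.strip()
                continue
            parts = line.split()
            if len(parts) < 2:
                raise CurveFormatError(f"malformed data line: {line!r}")
            data.append((float(parts[0]), float(parts[1])))
    if columns is None:
        raise CurveFormatError("missing required header field 'columns'")
    if len(columns) != 2:
        raise CurveFormatError(f"expected two columns, got {columns}")
    for key in _REQUIRED_META:
        if key not in meta:
            raise CurveFormatError(f"missing required header field '{key}'")
    xcol, fcol = columns
    if xcol not in ("extension_nm", "piezo_nm"):
        raise CurveFormatError(f"unsupported position column '{xcol}'")
    if fcol not in ("force_pN", "force_nN"):
        raise CurveFormatError(f"unsupported force column '{fcol}'")
    arr = np.array(data, dtype=float)
    x, f = arr[:, 0], arr[:, 1]
    if fcol == "force_nN":
        f = f * 1000.0
    k_n_m = float(meta["k_N_m"])
    if xcol == "piezo_nm":
        x = x - f / (k_n_m * N_PER_M_TO_PN_PER_NM)
    cm = CurveMeta(
        speed_nm_s=float(meta["speed_nm_s"]),
        k_N_m=k_n_m,
        temperature_K=float(meta.get("temperature_K", 298.0)),
        curve_id=meta.get("curve_id", "curve"),
    )
    return ForceCurve(extension=x, force=f, metadata=cm)


def write_event_table(table: pd.DataFrame, path) -> None:
    """Write an event table as CSV with the canonical column order."""
    cols = [c for c in EVENT_COLUMNS if c in table.columns]
    table.to_csv(path, index=False, columns=cols)


def read_event_table(path) -> pd.DataFrame:
    """Read an event-table CSV."""
    return pd.read_csv(path)
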