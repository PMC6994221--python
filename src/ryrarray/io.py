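"""Readers and writers for the package's table schemas.

Canonical units are nm for coordinates and distances, degrees for angles,
and ms / µm / ΔF/F₀ for spark parameters.  All writers emit a stable column
order so outputs are diffable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dstorm import Localization, PixelGrid
from .errors import InvalidInputError, SchemaError
from .geometry import Tetramer, TetramerArray

logger = logging.getLogger("ryrarray")

TETRAMER_COLUMNS = ["id", "x_nm", "y_nm", "theta_deg", "tomogram", "group"]
LOCALIZATION_COLUMNS = [
    "x_nm",
    "y_nm",
    "z_nm",
    "sigma_xy_nm",
    "sigma_z_nm",
    "gof",
    "frame",
]
SPARK_COLUMNS = ["rat", "cell", "group", "amplitude", "fdhm_ms", "fwhm_um"]
FREQUENCY_COLUMNS = ["rat", "cell", "group", "rate", "sr_content"]

#: Supported localization-table dialects: column mapping plus the factor
#: converting lengths to nm.
LOCALIZATION_DIALECTS: dict[str, dict] = {
    "canonical": {
        "columns": {c: c for c in LOCALIZATION_COLUMNS},
        "length_scale": 1.0,
    },
    "um": {
        "columns": {
            "x_um": "x_nm",
            "y_um": "y_nm",
            "z_um": "z_nm",
            "sigma_xy_um": "sigma_xy_nm",
            "sigma_z_um": "sigma_z_nm",
            "gof": "gof",
            "frame": "frame",
        },
        "length_scale": 1000.0,
    },
    "thunderstorm": {
        "columns": {
            "x [nm]": "x_nm",
            "y [nm]": "y_nm",
            "z [nm]": "z_nm",
            "uncertainty_xy [nm]": "sigma_xy_nm",
            "uncertainty_z [nm]": "sigma_z_nm",
            "chi2": "gof",
            "frame": "frame",
        },
        "length_scale": 1.0,
    },
}


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, columns: Sequence[str], path) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna() & out[col].notna() | out[col].isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based plus header line
            raise SchemaError(
                f"{path}: non-numeric or missing value in column {col!r} "
                f"(file line {row})"
            )
        out[col] = converted
    return out


# ---------------------------------------------------------------------------
# tetramer tables


def read_tetramer_table(path) -> list[TetramerArray]:
    """Read a tetramer CSV into one :class:`TetramerArray` per tomogram.

    Schema: ``id,x_nm,y_nm,theta_deg,tomogram,group``.  Orientations are
    reduced modulo 90 on load.  Duplicate ids within a tomogram are a schema
    error.
    """
    df = pd.read_csv(
        path,
        dtype={"id": str, "tomogram": str, "group": str},
        float_precision="round_trip",
    )
    _require_columns(df, TETRAMER_COLUMNS, path)
    df = _numeric(df, ["x_nm", "y_nm", "theta_deg"], path)
    arrays = []
    for tomo, sub in df.groupby("tomogram", sort=True):
        dup = sub["id"].duplicated()
        if dup.any():
            row = int(dup.idxmax()) + 2
            raise SchemaError(
                f"{path}: duplicate tetramer id {sub['id'][dup.idxmax()]!r} in "
                f"tomogram {tomo!r} (file line {row})"
            )
        tets = tuple(
            Tetramer(
                id=str(r.id),
                x=float(r.x_nm),
                y=float(r.y_nm),
                theta=float(r.theta_deg),
                tomogram_id=str(tomo),
                group=str(r.group),
            )
            for r in sub.itertuples()
        )
        arrays.append(TetramerArray(tetramers=tets))
    return arrays


def write_tetramer_table(arrays: Sequence[TetramerArray], path) -> None:
    rows = [
        {
            "id": t.id,
            "x_nm": t.x,
            "y_nm": t.y,
            "theta_deg": t.theta,
            "tomogram": t.tomogram_id,
            "group": t.group,
        }
        for array in arrays
        for t in array
    ]
    pd.DataFrame(rows, columns=TETRAMER_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# localization tables


def read_localizations(path, dialect: str = "canonical") -> list[Localization]:
    """Read a localization table, coercing units to nm.

    A missing z column is treated as z = 0 with a logged warning (z slicing
    should then be disabled in :class:`~ryrarray.dstorm.QCThresholds`).
    """
    if dialect not in LOCALIZATION_DIALECTS:
        raise InvalidInputError(
            f"unknown localization dialect {dialect!r}; supported: "
            f"{sorted(LOCALIZATION_DIALECTS)}"
        )
    spec = LOCALIZATION_DIALECTS[dialect]
    df = pd.read_csv(path, float_precision="round_trip")
    present = {src: dst for src, dst in spec["columns"].items() if src in df.columns}
    df = df[list(present)].rename(columns=present)
    for required in ("x_nm", "y_nm"):
        if required not in df.columns:
            raise SchemaError(f"{path}: missing coordinate column for {required}")
    if "z_nm" not in df.columns:
        logger.warning(
            "%s: no z column in dialect %r; z set to 0 (disable z slicing)",
            path,
            dialect,
        )
        df["z_nm"] = 0.0
    for optional, default in (
        ("sigma_xy_nm", 0.0),
        ("sigma_z_nm", 0.0),
        ("gof", 1.0),
        ("frame", 0),
    ):
        if optional not in df.columns:
            df[optional] = default
    numeric_cols = [c for c in LOCALIZATION_COLUMNS if c != "frame"]
    df = _numeric(df, numeric_cols, path)
    scale = spec["length_scale"]
    for col in ("x_nm", "y_nm", "z_nm", "sigma_xy_nm", "sigma_z_nm"):
        df[col] = df[col] * scale
    return [
        Localization(
            x=float(r.x_nm),
            y=float(r.y_nm),
            z=float(r.z_nm),
            sigma_xy=float(r.sigma_xy_nm),
            sigma_z=float(r.sigma_z_nm),
            gof=float(r.gof),
            frame=int(r.frame),
        )
        for r in df.itertuples()
    ]


def write_localizations(locs: Sequence[Localization], path) -> None:
    rows = [
        {
            "x_nm": l.x,
            "y_nm": l.y,
            "z_nm": l.z,
            "sigma_xy_nm": l.sigma_xy,
            "sigma_z_nm": l.sigma_z,
            "gof": l.gof,
            "frame": l.frame,
        }
        for l in locs
    ]
    pd.DataFrame(rows, columns=LOCALIZATION_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# spark tables


def read_spark_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"rat": str, "cell": str, "group": str},
        float_precision="round_trip",
    )
    _require_columns(df, SPARK_COLUMNS, path)
    return _numeric(df, ["amplitude", "fdhm_ms", "fwhm_um"], path)


def read_frequency_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"rat": str, "cell": str, "group": str},
        float_precision="round_trip",
    )
    _require_columns(df, FREQUENCY_COLUMNS, path)
    return _numeric(df, ["rate", "sr_content"], path)


# ---------------------------------------------------------------------------
# grid export and provenance


def write_pgm(grid: PixelGrid, path, binary_map: bool = True) -> None:
    """Export a pixel grid as a plain-text portable greymap (PGM, P2).

    With ``binary_map`` lit pixels are white (the display convention for
    dSTORM maps); otherwise the grey level encodes the blink count.
    """
    if not grid.counts:
        Path(path).write_text("P2\n1 1\n1\n0\n")
        return
    idx = np.array(sorted(grid.counts))
    ix0, iy0 = idx.min(axis=0)
    nx, ny = idx.max(axis=0) - (ix0, iy0) + 1
    img = np.zeros((ny, nx), dtype=int)
    for (ix, iy), count in grid.counts.items():
        img[iy - iy0, ix - ix0] = 1 if binary_map else count
    maxval = max(int(img.max()), 1)
    lines = ["P2", f"{nx} {ny}", str(maxval)]
    # PGM rows run top to bottom; flip so +y points up in the image.
    for row in img[::-1]:
        lines.append(" ".join(str(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_provenance(path, config: dict, seed: int | None) -> None:
    """Write a machine-readable provenance record for a pipeline run."""
    payload = json.dumps(config, sort_keys=True, default=str)
    record = {
        "config": config,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "ryrarray": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
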