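"""CSV dialects: retention measurements, system metadata, fitted coefficients.

All readers skip ``#`` comment lines, so tables written with a provenance
header round-trip.  ``fits.csv`` can be produced by :func:`write_fits_csv`
or supplied directly (already-extrapolated intercepts/slopes bypass the
fitting step).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .retention import SWFit, build_lipo_matrix

__all__ = [
    "read_retention_csv",
    "read_systems_csv",
    "read_fits_csv",
    "write_fits_csv",
    "load_lipo_matrix",
    "fits_from_frame",
    "file_digest",
    "write_table",
]

_RET_REQUIRED = ("compound_id", "system_id", "phi")
_FIT_REQUIRED = ("compound_id", "system_id", "intercept", "slope")


def read_retention_csv(path) -> pd.DataFrame:
    """Long-format measurement table; per row either ``rf`` or ``tr``+``t0``."""
    df = pd.read_csv(path, comment="#",
                     dtype={"compound_id": str, "system_id": str})
    missing = [c for c in _RET_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("phi", "rf", "tr", "t0"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    has_rf = df["rf"].notna() if "rf" in df.columns else pd.Series(False, index=df.index)
    if {"tr", "t0"} <= set(df.columns):
        has_times = df["tr"].notna() & df["t0"].notna()
    else:
        has_times = pd.Series(False, index=df.index)
    bad = ~(has_rf ^ has_times)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:5]
        raise ValueError(
            f"{path}: each row needs exactly one of rf or tr+t0 "
            f"(offending file lines include {rows})")
    return df


def read_systems_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"system_id": str})
    if "system_id" not in df.columns:
        raise ValueError(f"{path}: missing 'system_id' column")
    return df


def write_fits_csv(fits_frame: pd.DataFrame, path, comment: str | None = None) -> None:
    write_table(fits_frame, path, comment=comment, index=False)


def read_fits_csv(path) -> pd.DataFrame:
    """Fitted-coefficient table, one row per (compound, system)."""
    df = pd.read_csv(path, comment="#",
                     dtype={"compound_id": str, "system_id": str})
    missing = [c for c in _FIT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def fits_from_frame(df: pd.DataFrame) -> list[SWFit]:
    """Reconstruct SWFit records from a fits table (absent diagnostics -> NaN)."""
    out = []
    for row in df.to_dict("records"):
        kwargs = {k: float(row[k]) if k in row and not pd.isna(row.get(k, np.nan))
                  else float("nan") for k in SWFit._FIELDS if k != "n"}
        n = row.get("n", np.nan)
        out.append(SWFit(**kwargs, n=int(n) if not pd.isna(n) else 0,
                         compound_id=str(row["compound_id"]),
                         system_id=str(row["system_id"])))
    return out


def load_lipo_matrix(fits_csv) -> pd.DataFrame:
    """Read ``fits.csv`` and pivot it into the compounds x systems matrix."""
    return build_lipo_matrix(fits_from_frame(read_fits_csv(fits_csv)))


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_table(df: pd.DataFrame, path, *, comment: str | None = None,
                index: bool = True, float_format: str | None = None) -> None:
    """Write a CSV, optionally prefixed with a ``#`` provenance line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, index=index, float_format=float_format)
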