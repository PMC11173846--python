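"""Computed log P / log D tables: ingestion, cross-correlation, screening.

Partition (log P) and distribution (log D at a stated pH) coefficients
predicted by external calculators are consumed as data — one row per
compound, one column per algorithm, with explicitly missing cells allowed.
They are correlated against the chromatographic lipophilicity descriptors
and screened against standard drug-likeness windows:

* Lipinski:           Clog P < 5 (strict)
* Oprea:              -2.0 <= Mlog P <= 4
* log P window:        0 <= log P <= 3
* log D_7.4 window:    1 <= log D_7.4 <= 3

A missing input value makes the corresponding flag indeterminate (<NA>),
never a pass.
"""

from __future__ import annotations

import importlib.resources
import warnings
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .chemometrics import corr_matrix

__all__ = [
    "load_insilico",
    "bundled_insilico_table",
    "cross_correlate",
    "druglikeness",
    "DRUGLIKENESS_RULES",
]

_MISSING_MARKERS = ("", "-", "na", "NA", "NaN", "nan")


def load_insilico(source) -> pd.DataFrame:
    """Read a compounds x descriptors CSV into a typed table.

    ``source`` is a path or file-like object.  The file must have a header
    row with a ``compound_id`` column (or the first column is taken as the
    id); ``-`` and empty cells are parsed as missing.  Duplicate compound
    ids and non-numeric cells are errors.
    """
    df = pd.read_csv(source, dtype=str, comment="#",
                     keep_default_na=False, skipinitialspace=True)
    if df.empty or df.shape[1] == 0:
        raise ValueError("in-silico table is empty")
    id_col = "compound_id" if "compound_id" in df.columns else df.columns[0]
    ids = df[id_col].astype(str).str.strip()
    dup = ids[ids.duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate compound ids: {sorted(set(dup))}")
    body = df.drop(columns=[id_col])
    if body.shape[1] == 0:
        raise ValueError("in-silico table has no descriptor columns")
    if body.columns.duplicated().any():
        raise ValueError("duplicate descriptor names in header")
    out = {}
    for col in body.columns:
        vals = []
        for i, raw in enumerate(body[col]):
            raw = raw.strip()
            if raw in _MISSING_MARKERS:
                vals.append(np.nan)
                continue
            try:
                vals.append(float(raw))
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric cell at row {i + 1} (compound {ids.iloc[i]}), "
                    f"column {col!r}: {raw!r}") from exc
        out[col] = vals
    table = pd.DataFrame(out, index=pd.Index(ids, name="compound_id"))
    return table


def bundled_insilico_table() -> pd.DataFrame:
    """The packaged 18-compound x 12-algorithm log P / log D fixture."""
    text = (importlib.resources.files("lipochrom") / "data" / "insilico_logp.csv").read_text()
    return load_insilico(StringIO(text))


def cross_correlate(lipo: pd.DataFrame, insilico: pd.DataFrame, *,
                    lipo_columns=None, insilico_columns=None,
                    min_pairs: int = 3) -> pd.DataFrame:
    """Pearson r between chromatographic and computed descriptors.

    Compounds are aligned by id (inner join, with a warning listing ids
    dropped from either side); correlations use pairwise-complete
    observations.  Rows are chromatographic descriptors, columns the
    computed ones.
    """
    left = lipo if lipo_columns is None else lipo[list(lipo_columns)]
    right = insilico if insilico_columns is None else insilico[list(insilico_columns)]
    left = left.copy()
    right = right.copy()
    left.index = left.index.astype(str)
    right.index = right.index.astype(str)
    common = left.index.intersection(right.index)
    dropped = sorted(set(left.index.symmetric_difference(right.index)))
    if dropped:
        warnings.warn(f"compound ids present on one side only, dropped: {dropped}",
                      stacklevel=2)
    if len(common) < min_pairs:
        raise ValueError(f"only {len(common)} shared compounds (< {min_pairs})")
    overlap = set(left.columns) & set(right.columns)
    if overlap:
        raise ValueError(f"column names present in both tables: {sorted(overlap)}")
    joined = left.loc[common].join(right.loc[common])
    full = corr_matrix(joined, min_pairs=min_pairs)
    return full.loc[list(left.columns), list(right.columns)]


#: rule name -> (descriptor column, lower bound, upper bound, strict upper)
DRUGLIKENESS_RULES = {
    "lipinski_clogp_pass": ("Clog P", None, 5.0, True),
    "oprea_mlogp_pass": ("Mlog P", -2.0, 4.0, False),
    "logp_window_pass": ("log P", 0.0, 3.0, False),
    "logd_window_pass": ("log D_7.4", 1.0, 3.0, False),
}


def _apply_rule(value: float, lo, hi, strict_hi) -> object:
    if pd.isna(value):
        return pd.NA
    ok = True
    if lo is not None:
        ok &= value >= lo
    if hi is not None:
        ok &= (value < hi) if strict_hi else (value <= hi)
    return bool(ok)


def druglikeness(insilico: pd.DataFrame) -> pd.DataFrame:
    """Drug-likeness screen per compound.

    Returns one row per compound with, for each rule, the descriptor value
    used (``*_value``) and a nullable-boolean flag; compounds lacking the
    descriptor get an indeterminate (<NA>) flag.
    """
    out = pd.DataFrame(index=insilico.index.copy())
    for flag, (col, lo, hi, strict) in DRUGLIKENESS_RULES.items():
        vals = insilico[col] if col in insilico.columns else pd.Series(
            np.nan, index=insilico.index)
        out[flag.replace("_pass", "_value")] = vals
        out[flag] = pd.array([_apply_rule(v, lo, hi, strict) for v in vals],
                             dtype="boolean")
    return out
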