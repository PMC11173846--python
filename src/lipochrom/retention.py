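"""Isocratic retention descriptors and the linear extrapolation model.

Reversed-phase retention of a solute decreases linearly with the volume
fraction ``phi`` of organic modifier in the eluent,

    R_M   = R_Mw   + b * phi      (planar chromatography)
    log k = log k_w + b * phi     (column chromatography)

so an ordinary least-squares fit of the measured R_M (or log k) values on
phi extrapolates to the purely aqueous eluent: the intercept R_Mw (log k_w)
is the chromatographic lipophilicity parameter and the slope ``b`` reflects
the specific hydrophobic surface of the solute.  This module converts raw
plate / column measurements to R_M / log k, performs the per-series fit
with full regression diagnostics, and assembles the fitted coefficients
into the compounds x systems matrix the chemometric layer consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "DomainError",
    "InsufficientDataError",
    "SingularDesignError",
    "SWFit",
    "RetentionSeries",
    "rf_to_rm",
    "logk_from_times",
    "fit_sw",
    "build_lipo_matrix",
    "RetentionModel",
    "RetentionResults",
]


class DomainError(ValueError):
    """A measurement lies outside the physically admissible domain."""


class InsufficientDataError(ValueError):
    """Too few points to fit the retention model."""


class SingularDesignError(ValueError):
    """The regression design is singular (no spread in the regressor)."""


def rf_to_rm(rf, *, label: str | None = None):
    """Transform a plate retardation factor R_F into R_M = log10(1/R_F - 1).

    R_F is the ratio of solute to solvent-front migration distances and must
    lie strictly inside (0, 1); R_M is the planar analogue of log k.
    Accepts scalars or arrays.

    Parameters
    ----------
    rf : float or array-like
        Retardation factor(s) in (0, 1).
    label : str, optional
        Identifier interpolated into the error message for bad input.
    """
    arr = np.asarray(rf, dtype=float)
    if np.any(~((arr > 0.0) & (arr < 1.0))):
        bad = np.atleast_1d(arr)[~((np.atleast_1d(arr) > 0) & (np.atleast_1d(arr) < 1))]
        where = f" in {label}" if label else ""
        raise DomainError(
            f"R_F must lie strictly in (0, 1); got {bad.tolist()}{where}"
        )
    out = np.log10(1.0 / arr - 1.0)
    return out if arr.ndim else float(out)


def logk_from_times(tr, t0, *, label: str | None = None):
    """Retention factor logarithm log k = log10((t_R - t0) / t0).

    ``t_R`` is the solute retention time and ``t0`` the hold-up (dead) time
    of an unretained marker, in the same units.  Accepts scalars or arrays.
    """
    tr_a = np.asarray(tr, dtype=float)
    t0_a = np.asarray(t0, dtype=float)
    where = f" in {label}" if label else ""
    if np.any(t0_a <= 0):
        raise DomainError(f"dead time t0 must be positive{where}")
    if np.any(tr_a <= t0_a):
        raise DomainError(f"non-retained or invalid solute: t_R <= t0{where}")
    out = np.log10((tr_a - t0_a) / t0_a)
    return out if (tr_a.ndim or t0_a.ndim) else float(out)


@dataclass(frozen=True)
class RetentionSeries:
    """Retention of one compound in one chromatographic system.

    ``points`` are (phi, y) pairs where y is R_M (planar) or log k (column);
    they are sorted by phi on construction.
    """

    compound_id: str
    system_id: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pts = tuple(sorted((float(p), float(y)) for p, y in self.points))
        object.__setattr__(self, "points", pts)

    @property
    def phi(self) -> np.ndarray:
        return np.array([p for p, _ in self.points])

    @property
    def y(self) -> np.ndarray:
        return np.array([y for _, y in self.points])

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class SWFit:
    """OLS fit of R_M (log k) on phi with the standard diagnostic set.

    ``intercept`` is the extrapolated lipophilicity parameter R_Mw / log k_w,
    ``slope`` the coefficient b of phi.  ``r`` is reported unsigned (the
    slope sign carries the direction); ``s`` is the residual standard error
    sqrt(SSE / (n - 2)); ``f_stat`` is F(1, n-2) and ``p_value`` its upper
    tail probability.
    """

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    r: float
    r2: float
    r2_adj: float
    f_stat: float
    p_value: float
    s: float
    n: int
    compound_id: str | None = None
    system_id: str | None = None

    _FIELDS = (
        "intercept", "slope", "se_intercept", "se_slope",
        "r", "r2", "r2_adj", "f_stat", "p_value", "s", "n",
    )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self._FIELDS}
        d["compound_id"] = self.compound_id
        d["system_id"] = self.system_id
        return d


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple:
    """Closed-form simple OLS with diagnostics; returns the SWFit fields."""
    n = len(x)
    xbar = x.mean()
    ybar = y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    syy = float(((y - ybar) ** 2).sum())
    sxy = float(((x - xbar) * (y - ybar)).sum())
    if sxx == 0.0:
        raise SingularDesignError("all phi values identical; slope not identifiable")
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    sse = max(syy - slope * sxy, 0.0)
    dof = n - 2
    s = math.sqrt(sse / dof) if dof > 0 else float("nan")
    se_slope = s / math.sqrt(sxx)
    se_intercept = s * math.sqrt(1.0 / n + xbar**2 / sxx)
    if syy > 0.0:
        r2 = 1.0 - sse / syy
    else:  # constant response: the line is flat and exact
        r2 = float("nan")
    r2 = min(r2, 1.0) if not math.isnan(r2) else r2
    r = math.sqrt(r2) if not math.isnan(r2) else float("nan")
    if math.isnan(r2):
        r2_adj = f_stat = p_value = float("nan")
    else:
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / dof
        if 1.0 - r2 < 1e-14:
            f_stat, p_value = float("inf"), 0.0
        else:
            f_stat = dof * r2 / (1.0 - r2)
            p_value = float(_st.f.sf(f_stat, 1, dof))
    return intercept, slope, se_intercept, se_slope, r, r2, r2_adj, f_stat, p_value, s, n


def fit_sw(series: RetentionSeries, *, min_points: int = 3) -> SWFit:
    """Fit the linear retention model y = intercept + slope * phi by OLS.

    Requires at least ``min_points`` observations (default 3, the minimum
    that leaves a residual degree of freedom for the diagnostics) and at
    least two distinct phi levels.

    Raises
    ------
    InsufficientDataError
        Fewer than ``min_points`` points.
    SingularDesignError
        All phi values identical.
    """
    if len(series) < min_points:
        raise InsufficientDataError(
            f"series {series.compound_id}/{series.system_id}: "
            f"{len(series)} points < required {min_points}"
        )
    vals = _ols_line(series.phi, series.y)
    return SWFit(*vals, compound_id=series.compound_id, system_id=series.system_id)


def build_lipo_matrix(fits: Iterable[SWFit]) -> pd.DataFrame:
    """Assemble fitted coefficients into a compounds x systems matrix.

    Returns a DataFrame indexed by compound id with two columns per system,
    ``<system_id>-R`` (intercept, R_Mw / log k_w) and ``<system_id>-S``
    (slope).  Cells for missing (compound, system) fits are NaN.  Duplicate
    (compound, system) pairs are an error.
    """
    fits = list(fits)
    if not fits:
        return pd.DataFrame()
    seen: dict[tuple, int] = {}
    for f in fits:
        key = (f.compound_id, f.system_id)
        seen[key] = seen.get(key, 0) + 1
    dups = sorted(k for k, c in seen.items() if c > 1)
    if dups:
        raise ValueError(f"duplicate (compound, system) fits: {dups}")
    compounds = list(dict.fromkeys(f.compound_id for f in fits))
    systems = list(dict.fromkeys(f.system_id for f in fits))
    cols = [f"{s}-{tag}" for s in systems for tag in ("R", "S")]
    mat = pd.DataFrame(np.nan, index=pd.Index(compounds, name="compound_id"), columns=cols)
    for f in fits:
        mat.loc[f.compound_id, f"{f.system_id}-R"] = f.intercept
        mat.loc[f.compound_id, f"{f.system_id}-S"] = f.slope
    return mat


class RetentionModel:
    """Linear retention model for a table of isocratic measurements.

    The measurement table is long-format with columns ``compound_id``,
    ``system_id``, ``phi`` and either ``rf`` (planar technique) or
    ``tr`` + ``t0`` (column technique) per row; each row is converted to
    R_M or log k and ``fit()`` runs one OLS extrapolation per
    (compound, system) series.

    Parameters
    ----------
    measurements : pandas.DataFrame
        Long-format measurement table as above.
    systems : pandas.DataFrame, optional
        System metadata (index or column ``system_id``); used for
        technique validation and carried into results.
    """

    def __init__(self, measurements: pd.DataFrame, systems: pd.DataFrame | None = None):
        req = {"compound_id", "system_id", "phi"}
        missing = req - set(measurements.columns)
        if missing:
            raise ValueError(f"measurement table lacks columns: {sorted(missing)}")
        if not (("rf" in measurements.columns)
                or {"tr", "t0"} <= set(measurements.columns)):
            raise ValueError("measurement table needs an 'rf' column or 'tr'+'t0' columns")
        self.measurements = measurements.copy()
        if systems is not None and "system_id" in systems.columns:
            systems = systems.set_index("system_id")
        self.systems = systems

    @classmethod
    def from_csv(cls, retention_csv, systems_csv=None) -> "RetentionModel":
        from . import io as _io

        meas = _io.read_retention_csv(retention_csv)
        sysdf = _io.read_systems_csv(systems_csv) if systems_csv is not None else None
        return cls(meas, sysdf)

    @classmethod
    def from_dataframe(cls, measurements: pd.DataFrame,
                       systems: pd.DataFrame | None = None) -> "RetentionModel":
        return cls(measurements, systems)

    def _series(self) -> list[RetentionSeries]:
        out = []
        for (cid, sid), grp in self.measurements.groupby(
                ["compound_id", "system_id"], sort=True):
            pts = []
            for row in grp.itertuples(index=False):
                rf = getattr(row, "rf", None)
                if rf is not None and not pd.isna(rf):
                    y = rf_to_rm(rf, label=f"{cid}/{sid} phi={row.phi}")
                else:
                    tr = getattr(row, "tr", None)
                    t0 = getattr(row, "t0", None)
                    if tr is None or t0 is None or pd.isna(tr) or pd.isna(t0):
                        raise ValueError(
                            f"row {cid}/{sid} phi={row.phi}: neither rf nor tr+t0 present"
                        )
                    y = logk_from_times(tr, t0, label=f"{cid}/{sid} phi={row.phi}")
                pts.append((float(row.phi), float(y)))
            out.append(RetentionSeries(str(cid), str(sid), tuple(pts)))
        return out

    def fit(self, *, min_points: int = 3) -> "RetentionResults":
        """Fit every (compound, system) series; short series are excluded
        (recorded, not fatal)."""
        fits, excluded = [], []
        for ser in self._series():
            try:
                fits.append(fit_sw(ser, min_points=min_points))
            except (InsufficientDataError, SingularDesignError) as exc:
                excluded.append({"compound_id": ser.compound_id,
                                 "system_id": ser.system_id,
                                 "n_points": len(ser),
                                 "reason": str(exc)})
        return RetentionResults(self, fits, excluded)


class RetentionResults:
    """Fitted retention study: per-series coefficients plus diagnostics.

    Attributes
    ----------
    fits : dict
        (compound_id, system_id) -> :class:`SWFit`.
    lipo_matrix : pandas.DataFrame
        Compounds x systems coefficient matrix (``-R`` / ``-S`` columns).
    excluded : list of dict
        Series skipped for lack of data, with reasons.
    """

    def __init__(self, model: RetentionModel, fits: Sequence[SWFit],
                 excluded: Sequence[Mapping]):
        self.model = model
        self.fits = {(f.compound_id, f.system_id): f for f in fits}
        self.lipo_matrix = build_lipo_matrix(fits)
        self.excluded = list(excluded)

    def to_frame(self) -> pd.DataFrame:
        """All fits as one row per (compound, system)."""
        rows = [f.to_dict() for f in self.fits.values()]
        df = pd.DataFrame(rows)
        if not df.empty:
            front = ["compound_id", "system_id"]
            df = df[front + [c for c in df.columns if c not in front]]
        return df

    # -- chemometric views -------------------------------------------------

    def describe(self, columns=None) -> pd.DataFrame:
        from .chemometrics import describe_systems

        return describe_systems(self.lipo_matrix, columns)

    def corr(self, columns=None, **kw) -> pd.DataFrame:
        from .chemometrics import corr_matrix

        return corr_matrix(self.lipo_matrix, columns, **kw)

    def regress(self, x_label: str, y_label: str):
        from .chemometrics import pairwise_regression

        return pairwise_regression(self.lipo_matrix, x_label, y_label)

    def pca(self, columns=None, **kw):
        from .chemometrics import pca_scaled

        return pca_scaled(self.lipo_matrix, columns=columns, **kw)

    def cluster(self, columns=None, **kw):
        from .chemometrics import hca_corr

        return hca_corr(self.lipo_matrix, columns=columns, **kw)

    def cross_correlate(self, insilico: pd.DataFrame, **kw) -> pd.DataFrame:
        from .insilico import cross_correlate

        return cross_correlate(self.lipo_matrix, insilico, **kw)

    def summary(self) -> str:
        """Human-readable overview of the fitted study."""
        df = self.to_frame()
        lines = ["Retention model (OLS extrapolation to phi = 0)",
                 "=" * 48,
                 f"series fitted:   {len(self.fits)}",
                 f"series excluded: {len(self.excluded)}",
                 f"compounds:       {self.lipo_matrix.shape[0]}",
                 f"systems:         {self.lipo_matrix.shape[1] // 2}"]
        if not df.empty:
            per_sys = df.groupby("system_id").agg(
                n=("compound_id", "size"),
                mean_intercept=("intercept", "mean"),
                mean_slope=("slope", "mean"),
                min_r2=("r2", "min"),
            )
            lines.append("")
            lines.append(per_sys.round(4).to_string())
        for rec in self.excluded:
            lines.append(f"excluded: {rec['compound_id']}/{rec['system_id']} "
                         f"({rec['n_points']} pts)")
        return "\n".join(lines)
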