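"""Chemometric comparison of lipophilicity descriptors across systems.

Operates on the compounds x descriptors matrix (a DataFrame whose columns
are ``<system>-R`` / ``<system>-S`` coefficients and, optionally, computed
log P / log D descriptors): descriptive statistics, pairwise-complete
Pearson correlation, inter-system OLS regressions with full diagnostics,
autoscaled PCA, and agglomerative clustering under the correlation
dissimilarity d = 1 - r.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import squareform

from .retention import SingularDesignError, _ols_line

__all__ = [
    "describe_systems",
    "corr_matrix",
    "PairRegression",
    "pairwise_regression",
    "PCAResult",
    "pca_scaled",
    "HCAResult",
    "hca_corr",
]

_STAT_COLS = ["mean", "median", "min", "max", "range", "std_dev"]


def _select(matrix: pd.DataFrame, columns) -> pd.DataFrame:
    if columns is None:
        return matrix
    columns = list(columns)
    unknown = [c for c in columns if c not in matrix.columns]
    if unknown:
        raise KeyError(f"unknown columns: {unknown}")
    return matrix[columns]


def describe_systems(matrix: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Per-descriptor summary: mean, median, min, max, range, sample std.

    Statistics are computed over non-missing entries only; every selected
    column needs at least two of them.  The sample (n-1) standard deviation
    is used throughout.
    """
    sub = _select(matrix, columns)
    counts = sub.notna().sum()
    bad = counts[counts < 2]
    if len(bad):
        raise ValueError(
            f"columns with fewer than 2 non-missing values: {list(bad.index)}"
        )
    out = pd.DataFrame({
        "mean": sub.mean(),
        "median": sub.median(),
        "min": sub.min(),
        "max": sub.max(),
        "range": sub.max() - sub.min(),
        "std_dev": sub.std(ddof=1),
    })
    out.index.name = "descriptor"
    return out[_STAT_COLS]


def corr_matrix(matrix: pd.DataFrame, columns=None, *, min_pairs: int = 3) -> pd.DataFrame:
    """Pearson correlation matrix under pairwise-complete observations.

    Pairs with fewer than ``min_pairs`` complete observations are left
    missing (with a warning); the diagonal is exactly 1 and the matrix
    symmetric by construction.
    """
    sub = _select(matrix, columns)
    corr = sub.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    n_missing = int(corr.isna().sum().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} correlation cells undefined "
            f"(fewer than {min_pairs} complete pairs)", stacklevel=2)
    return corr


@dataclass(frozen=True)
class PairRegression:
    """OLS of one descriptor column on another, with SWFit-style diagnostics.

    Coefficient standard errors correspond to the parenthesised "(+/- ...)"
    uncertainties of a regression report.
    """

    x_label: str
    y_label: str
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

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "x_label", "y_label", "intercept", "slope", "se_intercept",
            "se_slope", "r", "r2", "r2_adj", "f_stat", "p_value", "s", "n")}

    def equation(self, digits: int = 4) -> str:
        d = digits
        return (f"{self.y_label} = {self.intercept:.{d}f} (+/-{self.se_intercept:.{d}f}) "
                f"+ {self.slope:.{d}f} (+/-{self.se_slope:.{d}f}) {self.x_label}")


def pairwise_regression(matrix: pd.DataFrame, x_label: str, y_label: str) -> PairRegression:
    """Regress descriptor ``y_label`` on ``x_label`` over complete pairs."""
    sub = _select(matrix, [x_label, y_label]).dropna()
    if len(sub) < 3:
        raise ValueError(
            f"{x_label} vs {y_label}: only {len(sub)} complete pairs (< 3)")
    x = sub[x_label].to_numpy(float)
    y = sub[y_label].to_numpy(float)
    if np.ptp(x) == 0.0:
        raise SingularDesignError(f"{x_label} has zero variance")
    vals = _ols_line(x, y)
    return PairRegression(x_label, y_label, *vals)


@dataclass(frozen=True)
class PCAResult:
    """Autoscaled principal component analysis of a descriptor block.

    ``scores`` (compounds x components) and ``loadings`` (descriptors x
    components) satisfy ``scaled = scores @ loadings.T``; ``explained_var``
    are variance proportions summing to one over all retained components.
    ``col_means`` / ``col_stds`` record the autoscaling applied (sample std).
    ``dropped`` lists zero-variance columns removed before the analysis.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_var: np.ndarray
    col_means: pd.Series
    col_stds: pd.Series
    dropped: tuple[str, ...] = ()

    @property
    def n_components(self) -> int:
        return len(self.explained_var)

    def reconstruct(self) -> pd.DataFrame:
        """The autoscaled matrix rebuilt from all components."""
        rec = self.scores.to_numpy() @ self.loadings.to_numpy().T
        return pd.DataFrame(rec, index=self.scores.index, columns=self.loadings.index)


def pca_scaled(matrix: pd.DataFrame, columns=None, *,
               missing: str = "error") -> PCAResult:
    """PCA of the autoscaled (zero-mean, unit sample-variance) block.

    Components come from the SVD of the scaled matrix, ordered by
    decreasing explained variance, with a deterministic sign convention:
    the largest-magnitude loading of each component is positive.

    Parameters
    ----------
    missing : {"error", "drop", "impute"}
        Policy for missing cells: refuse (default), drop affected columns,
        or impute the column mean before scaling.
    """
    sub = _select(matrix, columns).astype(float)
    if missing not in ("error", "drop", "impute"):
        raise ValueError("missing policy must be 'error', 'drop' or 'impute'")
    if sub.isna().any().any():
        if missing == "error":
            raise ValueError(
                "matrix contains missing cells; pass missing='drop' or "
                "missing='impute' to choose a policy")
        if missing == "drop":
            sub = sub.dropna(axis="columns")
        else:
            sub = sub.fillna(sub.mean())
    stds = sub.std(ddof=1)
    dead = list(stds[~(stds > 0)].index)
    if dead:
        warnings.warn(f"dropping zero-variance columns: {dead}", stacklevel=2)
        sub = sub.drop(columns=dead)
        stds = stds.drop(index=dead)
    if sub.shape[1] < 2:
        raise ValueError("need at least 2 columns with nonzero variance")
    means = sub.mean()
    scaled = (sub - means) / stds
    u, sv, vt = np.linalg.svd(scaled.to_numpy(), full_matrices=False)
    k = int(min(sub.shape[0] - 1, sub.shape[1]))
    u, sv, vt = u[:, :k], sv[:k], vt[:k]
    # deterministic orientation: dominant loading positive per component
    for j in range(k):
        i_max = int(np.argmax(np.abs(vt[j])))
        if vt[j, i_max] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    ev = sv**2 / np.sum(sv**2)
    comp = [f"PC{j + 1}" for j in range(k)]
    scores = pd.DataFrame(u * sv, index=sub.index, columns=comp)
    loadings = pd.DataFrame(vt.T, index=sub.columns, columns=comp)
    return PCAResult(scores, loadings, ev, means, stds, tuple(dead))


@dataclass(frozen=True)
class HCAResult:
    """Agglomerative clustering of descriptor columns.

    ``linkage_matrix`` is the scipy merge table over the dissimilarity
    d = 1 - r; ``labels`` are the leaf (column) names in input order.
    """

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray
    method: str

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def merges(self) -> list[dict]:
        """Merge list: children indices (leaves < n) and heights."""
        n = len(self.labels)
        return [{"step": i, "left": int(a), "right": int(b),
                 "height": float(h), "size": int(c)}
                for i, (a, b, h, c) in enumerate(self.linkage_matrix)]

    def merges_json(self) -> str:
        return json.dumps({"labels": list(self.labels),
                           "method": self.method,
                           "merges": self.merges()}, indent=2)

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, list(self.labels))
        return str(tree).strip()

    def clusters(self, height: float) -> dict[str, int]:
        """Flat cluster membership cut at the given height."""
        assignment = _hier.fcluster(self.linkage_matrix, t=height, criterion="distance")
        return dict(zip(self.labels, (int(a) for a in assignment)))


def hca_corr(matrix: pd.DataFrame, columns=None, *, linkage: str = "complete",
             min_pairs: int = 3) -> HCAResult:
    """Cluster descriptor columns under the correlation dissimilarity 1 - r.

    The signed form is used (anti-correlated columns are far apart, up to
    d = 2); linkage is one of {"complete", "average", "single"}, complete
    by default.
    """
    if linkage not in ("complete", "average", "single"):
        raise ValueError("linkage must be 'complete', 'average' or 'single'")
    corr = corr_matrix(matrix, columns, min_pairs=min_pairs)
    if corr.isna().any().any():
        raise ValueError("correlation matrix has undefined cells; cannot cluster")
    d = 1.0 - corr.to_numpy()
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    z = _hier.linkage(squareform(d, checks=False), method=linkage)
    return HCAResult(tuple(corr.columns), z, linkage)
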