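"""Ordination of vertical wood-density profiles.

Each tree contributes a six-value profile (stump to small branches). To
compare *shapes* independently of a tree's overall density level, rows are
first normalized -- either divided by the row mean (``row_mean_ratio``, the
default: a flat profile maps to six 1.0s) or row-centred (``row_center``).
A scaled (correlation-matrix) PCA of the normalized table then summarizes
the profile shapes: axis 1 opposes the tree base to the crown, so trees
with decreasing profiles score negative and increasing ones positive; axis
2 carries the relative stem WD (convex vs. straight profiles).

Axis orientation is fixed by convention -- small-branch loading positive on
axis 1, stem loading positive on axis 2 -- so scores are comparable across
runs and row orders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .compartments import COMPARTMENTS, STEM, STEM_BASE, SMALL_BRANCH, STUMP

__all__ = [
    "ProfileOrdination",
    "build_profile_matrix",
    "run_pca",
    "supplementary_correlations",
    "gradient_percent",
    "significance_code",
]

NORMALIZATION_MODES = ("row_mean_ratio", "row_center")

#: Supplementary variables correlated with the PCA axes.
SUPPLEMENTARY_VARIABLES = ("WD_Stu", "WD_GWD", "VWWD", "DBH", "H", "Ht", "Cr", "Sm")


@dataclass
class ProfileOrdination:
    """Normalized profile matrix plus (optionally) its PCA."""

    matrix: pd.DataFrame  # trees x 6, index = tree_id
    normalization_mode: str
    imputed: pd.Series | None = None  # bool per tree: Ste_b imputed
    scores: pd.DataFrame | None = None  # trees x k
    loadings: pd.DataFrame | None = None  # 6 x k
    eigenvalues: np.ndarray | None = None


def build_profile_matrix(
    compartments: pd.DataFrame,
    mode: str = "row_mean_ratio",
) -> ProfileOrdination:
    """Pivot the compartment table into a trees x 6 normalized matrix.

    Trees missing the stem base (Ste_b) get it imputed as the mean of their
    stump and stem WD before normalization (flagged in ``imputed``); trees
    missing any other compartment, or more than one, are excluded with a
    warning.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"mode must be one of {NORMALIZATION_MODES}, got {mode!r}")
    wide = compartments.pivot_table(
        index="tree_id", columns="compartment", values="WD_c", observed=True
    ).reindex(columns=list(COMPARTMENTS))

    n_missing = wide.isna().sum(axis=1)
    imputable = wide[STEM_BASE].isna() & (n_missing == 1)
    excluded = wide.index[(n_missing > 1) | ((n_missing == 1) & ~imputable)]
    if len(excluded) > 0:
        warnings.warn(
            f"{len(excluded)} trees excluded from the profile matrix "
            f"(missing non-imputable compartments): {list(excluded[:5])}...",
            stacklevel=2,
        )
        wide = wide.drop(index=excluded)
        imputable = imputable.drop(index=excluded)

    wide = wide.copy()
    wide.loc[imputable, STEM_BASE] = (
        wide.loc[imputable, STUMP] + wide.loc[imputable, STEM]
    ) / 2.0

    values = wide.to_numpy(dtype=float)
    row_means = values.mean(axis=1, keepdims=True)
    if mode == "row_mean_ratio":
        normalized = values / row_means
    else:
        normalized = values - row_means
    matrix = pd.DataFrame(normalized, index=wide.index, columns=list(COMPARTMENTS))
    return ProfileOrdination(
        matrix=matrix,
        normalization_mode=mode,
        imputed=pd.Series(imputable, index=wide.index, name="imputed"),
    )


def run_pca(
    ordination: ProfileOrdination | pd.DataFrame, n_axes: int | None = None
) -> ProfileOrdination:
    """Scaled PCA (eigendecomposition of the correlation matrix).

    Columns are standardized (mean 0, SD 1 with n-1 denominator); the
    correlation matrix is eigendecomposed; scores are the standardized
    matrix projected on the eigenvectors. Axes are sign-fixed: small-branch
    loading positive on axis 1, stem loading positive on axis 2, largest
    |loading| positive on later axes.
    """
    if isinstance(ordination, pd.DataFrame):
        ordination = ProfileOrdination(
            matrix=ordination, normalization_mode="row_mean_ratio"
        )
    X = ordination.matrix.to_numpy(dtype=float)
    n, p = X.shape
    k = p if n_axes is None else int(n_axes)
    if not 1 <= k <= p:
        raise ValueError(f"n_axes must be in [1, {p}]")
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} rows for {k} axes, got {n}")
    if np.isnan(X).any():
        raise ValueError("profile matrix contains missing values")

    sd = X.std(axis=0, ddof=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        names = [ordination.matrix.columns[j] for j in degenerate]
        raise ValueError(f"constant (degenerate) columns: {names}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)[:k]
    eigvec = eigvec[:, order][:, :k]

    cols = list(ordination.matrix.columns)
    for j in range(k):
        if j == 0 and SMALL_BRANCH in cols:
            ref = cols.index(SMALL_BRANCH)
        elif j == 1 and STEM in cols:
            ref = cols.index(STEM)
        else:
            ref = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[ref, j] < 0:
            eigvec[:, j] *= -1.0

    scores = Z @ eigvec
    axis_names = [f"pc{j + 1}" for j in range(k)]
    return ProfileOrdination(
        matrix=ordination.matrix,
        normalization_mode=ordination.normalization_mode,
        imputed=ordination.imputed,
        scores=pd.DataFrame(scores, index=ordination.matrix.index, columns=axis_names),
        loadings=pd.DataFrame(eigvec, index=cols, columns=axis_names),
        eigenvalues=eigval,
    )


def significance_code(p: float) -> str:
    """Conventional star coding: *** <=0.001, ** <=0.01, * <=0.05, else ns."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def supplementary_correlations(
    ordination: ProfileOrdination,
    trees: pd.DataFrame,
    variables: tuple[str, ...] = SUPPLEMENTARY_VARIABLES,
) -> pd.DataFrame:
    """Pearson correlations of tree variables with the first two PCA axes.

    Returns one row per variable with r, two-sided p and a star code for
    each axis. Constant variables yield NaN r with code ``na``.
    """
    if ordination.scores is None:
        raise ValueError("run_pca must be called before supplementary_correlations")
    scores = ordination.scores
    merged = trees.set_index("tree_id").reindex(scores.index)
    rows = []
    for var in variables:
        if var not in merged.columns:
            raise KeyError(f"variable {var!r} missing from the tree table")
        x = merged[var].to_numpy(dtype=float)
        row: dict = {"variable": var}
        for axis in ("pc1", "pc2"):
            y = scores[axis].to_numpy()
            ok = ~np.isnan(x)
            if np.unique(x[ok]).size < 2:
                r, p, code = np.nan, np.nan, "na"
            else:
                r, p = stats.pearsonr(x[ok], y[ok])
                code = significance_code(p)
            suffix = axis[-1]
            row[f"r_axis{suffix}"] = r
            row[f"p_axis{suffix}"] = p
            row[f"sig_axis{suffix}"] = code
        rows.append(row)
    return pd.DataFrame(rows)


def gradient_percent(WD_SB: float, WD_Stu: float) -> float:
    """Small-branch minus stump WD as a percentage of the stump WD."""
    if WD_Stu <= 0:
        raise ValueError(f"WD_Stu must be positive, got {WD_Stu}")
    return 100.0 * (WD_SB - WD_Stu) / WD_Stu
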