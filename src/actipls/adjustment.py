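"""Covariate residualization and variable standardization.

The outcome is adjusted for covariates by ordinary least squares: the PLS
stage receives the residuals, so the multivariate association reflects
activity beyond age, sex and body size. Predictors enter the PLS raw (but
standardized); residualizing X too is available as a sensitivity option.
Standardization (mean 0, SD 1, n-1 denominator) is computed within each
analysis stratum after subsetting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


class RankDeficientError(ValueError):
    pass


def residualize(y, C=None, column_names=None) -> np.ndarray:
    """OLS residuals of y on [1 | C].

    With no covariates this is mean-centering. Raises RankDeficientError,
    naming the offending columns, when the design is rank deficient.
    """
    y = np.asarray(y, dtype=float)
    if C is None or (hasattr(C, "shape") and np.size(C) == 0):
        return y - y.mean()
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    X = sm.add_constant(C, has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        names = column_names or [f"col{j}" for j in range(C.shape[1])]
        bad = [n for j, n in enumerate(names)
               if np.linalg.matrix_rank(np.delete(X, j + 1, axis=1)) == np.linalg.matrix_rank(X)]
        raise RankDeficientError(f"collinear covariate columns: {bad}")
    return np.asarray(sm.OLS(y, X).fit().resid)


def standardize(M, col_names=None):
    """Center and scale columns to unit variance (n-1 denominator).

    Zero-variance columns are dropped with a logged warning. Returns
    ``(Z, means, sds, kept_idx)``.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    means = M.mean(axis=0)
    sds = M.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.all():
        dropped = ([col_names[j] for j in np.flatnonzero(~keep)]
                   if col_names else np.flatnonzero(~keep).tolist())
        logger.warning("dropping zero-variance columns: %s", dropped)
    Z = (M[:, keep] - means[keep]) / sds[keep]
    return Z, means[keep], sds[keep], np.flatnonzero(keep)


@dataclass
class AnalysisMatrix:
    """Standardized predictors and adjusted, standardized outcome for one stratum."""

    X: np.ndarray
    y: np.ndarray
    x_means: np.ndarray
    x_sds: np.ndarray
    y_mean: float
    y_sd: float
    x_names: list[str]
    stratum: str = "total"
    covariates: tuple[str, ...] = ()
    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.n = len(self.y)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.x_names)
        df["y"] = self.y
        return df


def build_analysis_matrix(
    df: pd.DataFrame,
    x_cols: list[str],
    y_col: str,
    covariate_cols: list[str],
    stratum: str = "total",
    residualize_x: bool = False,
) -> AnalysisMatrix:
    """Residualize the outcome on covariates, then standardize X and y."""
    C = df[covariate_cols].to_numpy(dtype=float) if covariate_cols else None
    y_res = residualize(df[y_col].to_numpy(dtype=float), C, covariate_cols)
    Xraw = df[x_cols].to_numpy(dtype=float)
    if residualize_x:
        Xraw = np.column_stack([residualize(Xraw[:, j], C, covariate_cols)
                                for j in range(Xraw.shape[1])])
    Z, mx, sx, kept = standardize(Xraw, x_cols)
    yz, my, sy, _ = standardize(y_res)
    return AnalysisMatrix(
        X=Z, y=yz[:, 0],
        x_means=mx, x_sds=sx, y_mean=float(my[0]), y_sd=float(sy[0]),
        x_names=[x_cols[j] for j in kept],
        stratum=stratum, covariates=tuple(covariate_cols),
    )
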