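"""PLS regression with Monte-Carlo cross-validated component selection and
target-projection multivariate correlation coefficients.

This is the statistical core of the package. A univariate-response PLS
(PLS1) model is extracted by NIPALS deflation:

    w_a = X_a' y_a / ||X_a' y_a||      (x-weights, unit norm)
    t_a = X_a w_a                      (scores)
    p_a = X_a' t_a / (t_a' t_a)        (x-loadings)
    q_a = y_a' t_a / (t_a' t_a)        (y-loading)
    X_{a+1} = X_a - t_a p_a',  y_{a+1} = y_a - q_a t_a

with the regression vector on the standardized scale b = W (P'W)^{-1} q.
The number of components A is chosen by Monte-Carlo cross-validation:
repeated random 50/50 child-level splits (default 100 repetitions), the
candidate A minimising the median root mean squared error of prediction
(RMSEP) over repetitions; A = 0 (predict the calibration mean) is a
candidate, so "no predictive model" is a reachable outcome.

A fitted model is condensed onto its single predictive direction by target
projection, t_tp = X b / ||b||, and each predictor's association with the
outcome is reported as the Pearson correlation of that predictor with t_tp
— a multivariate correlation coefficient in [-1, 1]. 95% confidence
intervals are percentile intervals of those correlations over refits on the
Monte-Carlo calibration halves (sign-aligned to the full-data model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_EPS = np.finfo(float).eps


@dataclass
class PLSModel:
    """A fitted PLS1 model on centered/standardized data."""

    A: int
    W: np.ndarray       # p x A x-weights (unit norm columns)
    P: np.ndarray       # p x A x-loadings
    q: np.ndarray       # A y-loadings
    T: np.ndarray       # n x A scores
    b: np.ndarray       # p regression vector, standardized scale
    x_means: np.ndarray | None = None
    x_sds: np.ndarray | None = None
    y_mean: float = 0.0
    y_sd: float = 1.0


@dataclass
class MCCVResult:
    a_grid: np.ndarray
    rmsep: np.ndarray            # reps x (A_max + 1)
    median_rmsep: np.ndarray
    selected_A: int
    splits: list[np.ndarray]     # calibration index set per repetition
    seed: int | None = None


@dataclass
class MVCorrResult:
    """Per-band multivariate correlations with CIs plus model-level fit."""

    stratum: str
    status: str                      # "model" | "no_model"
    n: int
    selected_A: int
    band_names: list[str] = field(default_factory=list)
    r: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    significant: np.ndarray | None = None
    r2_cal: float | None = None
    r2_val: float | None = None
    reason: str | None = None

    def to_dict(self) -> dict:
        d = {
            "stratum": self.stratum,
            "status": self.status,
            "n": self.n,
            "selected_A": self.selected_A,
        }
        if self.status == "model":
            d["r2_cal"] = self.r2_cal
            d["r2_val"] = self.r2_val
            d["bands"] = [
                {
                    "band": name,
                    "r": float(r),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "significant": bool(sig),
                }
                for name, r, lo, hi, sig in zip(
                    self.band_names, self.r, self.ci_low, self.ci_high, self.significant
                )
            ]
        else:
            d["reason"] = self.reason
        return d


def _nipals_path(X: np.ndarray, y: np.ndarray, A_max: int):
    """Extract up to A_max components; return (W, P, q, T, B).

    B[:, a-1] is the regression vector of the a-component model, so one pass
    yields predictions for every candidate model size. Extraction stops early
    (logged) when the residual y is numerically orthogonal to the residual X.
    """
    n, p = X.shape
    Xa = X.copy()
    ya = y.astype(float).copy()
    scale = max(float(np.abs(X).max()) * float(np.abs(y).max()), 1.0)
    W = np.zeros((p, A_max))
    P = np.zeros((p, A_max))
    q = np.zeros(A_max)
    T = np.zeros((n, A_max))
    a_used = 0
    for a in range(A_max):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * scale * np.sqrt(n):
            logger.info("early stop at %d components (residual orthogonality)", a)
            break
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        if tt <= 1e-24:
            break
        P[:, a] = Xa.T @ t / tt
        q[a] = float(ya @ t) / tt
        W[:, a] = w
        T[:, a] = t
        Xa -= np.outer(t, P[:, a])
        ya -= q[a] * t
        a_used = a + 1
    W, P, q, T = W[:, :a_used], P[:, :a_used], q[:a_used], T[:, :a_used]
    B = np.zeros((p, a_used))
    for a in range(1, a_used + 1):
        # R = W (P'W)^{-1}; P'W is unit upper triangular for NIPALS PLS1
        B[:, a - 1] = W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], q[:a])
    return W, P, q, T, B


def fit_pls(X, y, A: int) -> PLSModel:
    """Fit a PLS1 model with A components on centered/standardized X, y.

    Extraction may stop early with fewer components when y becomes
    orthogonal to the deflated X; the returned model records the count used.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y disagree on n")
    if not (1 <= A <= min(p, n - 1)):
        raise ValueError(f"A must be in 1..min(p, n-1) = {min(p, n - 1)}")
    W, P, q, T, B = _nipals_path(X, y, A)
    if B.shape[1] == 0:
        raise ValueError("no component extractable: y orthogonal to X")
    return PLSModel(A=B.shape[1], W=W, P=P, q=q, T=T, b=B[:, -1])


def predict(model: PLSModel, X_new) -> np.ndarray:
    """Predictions on the standardized y scale: yhat = X_new b."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != model.b.shape[0]:
        raise ValueError("column count mismatch with fitted model")
    return X_new @ model.b


def mccv_select(
    X,
    y,
    reps: int = 100,
    cal_frac: float = 0.5,
    A_max: int = 10,
    seed=None,
    rng: np.random.Generator | None = None,
) -> MCCVResult:
    """Choose the component count by Monte-Carlo cross-validation.

    Each repetition draws a fresh random calibration subset of
    ``floor(n * cal_frac)`` children; models with A = 0..A_max are fit on the
    calibration half (A = 0 predicts the calibration mean; calibration means
    are used for centering throughout) and scored by RMSEP on the held-out
    half. ``selected_A`` is the argmin of the median RMSEP over repetitions,
    ties resolved toward the smaller A (parsimony).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 10:
        raise ValueError("n too small for 50/50 Monte-Carlo splitting")
    n_cal = int(np.floor(n * cal_frac))
    A_max = int(min(A_max, p, n_cal - 1))
    if rng is None:
        rng = np.random.default_rng(seed)
    rmsep = np.full((reps, A_max + 1), np.nan)
    splits: list[np.ndarray] = []
    for rep in range(reps):
        perm = rng.permutation(n)
        cal, val = perm[:n_cal], perm[n_cal:]
        splits.append(cal)
        mx = X[cal].mean(axis=0)
        my = y[cal].mean()
        Xc, yc = X[cal] - mx, y[cal] - my
        *_, B = _nipals_path(Xc, yc, A_max)
        resid0 = y[val] - my
        rmsep[rep, 0] = np.sqrt(np.mean(resid0 ** 2))
        if B.shape[1]:
            pred = (X[val] - mx) @ B + my
            errs = y[val][:, None] - pred
            rmsep[rep, 1:B.shape[1] + 1] = np.sqrt(np.mean(errs ** 2, axis=0))
        # components beyond an early stop inherit the last fitted model's error
        for a in range(B.shape[1] + 1, A_max + 1):
            rmsep[rep, a] = rmsep[rep, B.shape[1]]
    med = np.median(rmsep, axis=0)
    selected = int(np.argmin(med))  # argmin takes the first (smallest A) on ties
    return MCCVResult(
        a_grid=np.arange(A_max + 1), rmsep=rmsep, median_rmsep=med,
        selected_A=selected, splits=splits, seed=seed,
    )


def target_projection(model: PLSModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Project X onto the model's predictive direction and correlate each band.

    Returns ``(t_tp, r)`` where ``t_tp = X b / ||b||`` and
    ``r[k] = corr(x_k, t_tp)``. Since predictions are proportional to t_tp,
    r is numerically identical to corr(x_k, yhat).
    """
    X = np.asarray(X, dtype=float)
    nb = np.linalg.norm(model.b)
    if nb <= _EPS:
        raise ValueError("zero regression vector: no model")
    t_tp = X @ (model.b / nb)
    tc = t_tp - t_tp.mean()
    st = np.linalg.norm(tc)
    Xc = X - X.mean(axis=0)
    sx = np.linalg.norm(Xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ tc) / (sx * st)
    r = np.clip(r, -1.0, 1.0)
    return t_tp, r


def mv_correlation_ci(
    X,
    y,
    selected_A: int,
    splits: list[np.ndarray],
    level: float = 0.95,
    b_full: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percentile confidence intervals for the per-band correlations.

    The model is refit with ``selected_A`` components on each Monte-Carlo
    calibration half; per-band correlations are computed on that half via
    target projection, with each refit's regression vector sign-aligned to
    the full-data vector (PLS directions are sign-indeterminate across
    subsamples). The CI is the percentile interval across repetitions.

    Returns ``(ci_low, ci_high, r_reps)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if selected_A < 1:
        raise ValueError("CIs require at least one component")
    if b_full is None:
        b_full = fit_pls(X - X.mean(axis=0), y - y.mean(), selected_A).b
    rows = []
    failures = 0
    for cal in splits:
        Xc = X[cal] - X[cal].mean(axis=0)
        yc = y[cal] - y[cal].mean()
        try:
            m = fit_pls(Xc, yc, selected_A)
            if float(m.b @ b_full) < 0:
                m.b = -m.b
            _, r = target_projection(m, X[cal])
        except ValueError:
            failures += 1
            continue
        rows.append(r)
    if failures:
        logger.warning("CI refits: %d of %d failed; CIs use successes only",
                       failures, len(splits))
    if not rows:
        raise ValueError("no successful CI refit")
    r_reps = np.vstack(rows)
    alpha = 100.0 * (1.0 - level) / 2.0
    ci_low = np.percentile(r_reps, alpha, axis=0)
    ci_high = np.percentile(r_reps, 100.0 - alpha, axis=0)
    return ci_low, ci_high, r_reps


def explained_variance(model: PLSModel, X, y, mccv: MCCVResult) -> tuple[float, float]:
    """Calibration and validated explained variance, as fractions.

    ``R2_cal = 1 - SSE/SST`` on the full fit; ``R2_val`` is derived from the
    cross-validated error at the selected size,
    ``1 - median_rmsep(selected_A)^2 / var(y)``. The validated figure is the
    headline number: the calibration R^2 alone would overstate fit.
    """
    y = np.asarray(y, dtype=float).ravel()
    if mccv.selected_A == 0:
        raise ValueError("no model selected; R^2 undefined")
    resid = y - predict(model, np.asarray(X, float))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2_cal = 1.0 - float(resid @ resid) / sst
    var_y = sst / (len(y) - 1)
    r2_val = 1.0 - float(mccv.median_rmsep[mccv.selected_A] ** 2) / var_y
    return r2_cal, r2_val
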