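"""Scoring of Kidscreen-style HRQoL scales and in-sample psychometrics.

The physical well-being scale sums five ordinal items (1..5) into a raw
score (5..25) and maps it to a T-score (mean 50, SD 10) by a linear
transform against reference moments. The official Rasch-based norm tables
are not reproduced; reference mean/SD are configuration inputs and default
to the sample moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ScaleScore:
    child_id: str
    raw: int
    t_score: float


class MissingItemError(ValueError):
    pass


def orient_items(items: np.ndarray, reverse_mask=None) -> np.ndarray:
    items = np.asarray(items, dtype=float)
    if np.any(np.isnan(items)):
        raise MissingItemError("missing item response")
    if np.any((items < 1) | (items > 5)):
        raise ValueError("item responses must lie in 1..5")
    if reverse_mask is not None:
        items = np.where(np.asarray(reverse_mask, bool), 6 - items, items)
    return items


def score_scale(child_id, items, ref_mean: float, ref_sd: float, reverse_mask=None) -> ScaleScore:
    """Sum oriented items and map raw -> T: t = 50 + 10 * (raw - ref_mean) / ref_sd."""
    if ref_sd <= 0:
        raise ValueError("ref_sd must be positive")
    raw = int(orient_items(items, reverse_mask).sum())
    return ScaleScore(child_id, raw, 50.0 + 10.0 * (raw - ref_mean) / ref_sd)


def score_cohort(
    item_df: pd.DataFrame,
    item_cols: list[str],
    ref_mean: float | None = None,
    ref_sd: float | None = None,
    reverse_mask=None,
) -> pd.DataFrame:
    """Score a cohort of complete-case responders.

    Rows with any missing item are dropped (complete-case policy) and the
    dropped count is recorded in ``df.attrs['n_dropped_items']``. When
    reference moments are not given, the complete-case sample moments are used.
    """
    items = item_df[item_cols].to_numpy(dtype=float)
    complete = ~np.isnan(items).any(axis=1)
    items = items[complete]
    if reverse_mask is not None:
        items = np.where(np.asarray(reverse_mask, bool)[None, :], 6 - items, items)
    raw = items.sum(axis=1)
    if ref_mean is None:
        ref_mean = float(raw.mean())
    if ref_sd is None:
        ref_sd = float(raw.std(ddof=1))
    out = item_df.loc[complete, [c for c in item_df.columns if c not in item_cols]].copy()
    out["raw"] = raw.astype(int)
    out["t_score"] = 50.0 + 10.0 * (raw - ref_mean) / ref_sd
    out.attrs["n_dropped_items"] = int((~complete).sum())
    out.attrs["ref_mean"] = ref_mean
    out.attrs["ref_sd"] = ref_sd
    return out


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum item variances / variance of sums).

    Sample variances use the n-1 denominator. Undefined (ValueError) when the
    total-score variance is zero.
    """
    m = np.asarray(item_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 3:
        raise ValueError("need an n x k matrix with k >= 2, n >= 3")
    if np.isnan(m).any():
        raise MissingItemError("complete cases required")
    k = m.shape[1]
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance; alpha undefined")
    return k / (k - 1) * (1.0 - m.var(axis=0, ddof=1).sum() / total_var)


def floor_ceiling(raw_scores, min_possible: float, max_possible: float) -> tuple[float, float]:
    """Percent of scores exactly at the scale floor and ceiling."""
    s = np.asarray(raw_scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty score vector")
    if np.any((s < min_possible) | (s > max_possible)):
        raise ValueError("scores outside the possible range")
    return (
        100.0 * float(np.mean(s == min_possible)),
        100.0 * float(np.mean(s == max_possible)),
    )
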