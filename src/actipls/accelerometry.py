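"""Reduction of epoch-level accelerometer count series to intensity-spectrum exposures.

The reduction follows the standard paediatric waist-worn protocol: remove
non-wear time (runs of >= 60 min of consecutive zero counts, detected on the
full 24 h record), accumulate wear time and per-band minutes within the
06:00-23:59 analysis window, require >= 8 h wear for a valid day and >= 4
valid days for a valid child, then average band minutes per day over valid
days. Counts in sub-minute epochs are classified against cpm cut-points via
their cpm equivalent (count * 60 / epoch_s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import BandScheme, DEFAULT_SCHEME

logger = logging.getLogger(__name__)

NON_WEAR_MIN = 60          # minimal zero-run length classified as non-wear, minutes
DAY_WINDOW = (6 * 3600, 24 * 3600)   # [06:00, 24:00) in seconds since midnight
VALID_DAY_WEAR_MIN = 480   # >= 8 h wear for a valid day
VALID_CHILD_DAYS = 4       # >= 4 valid days for a valid child


@dataclass
class EpochSeries:
    """One child's raw accelerometer counts at a fixed epoch length."""

    child_id: str
    start_time: pd.Timestamp
    epoch_s: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if 60 % self.epoch_s != 0:
            raise ValueError("epoch_s must divide 60")
        self.start_time = pd.Timestamp(self.start_time)

    def __len__(self) -> int:
        return len(self.counts)

    def seconds_of_day(self) -> np.ndarray:
        """Clock time (seconds since midnight) of each epoch start."""
        offset = (
            self.start_time - self.start_time.normalize()
        ).total_seconds()
        idx = np.arange(len(self.counts), dtype=np.int64)
        return (int(offset) + idx * self.epoch_s) % 86400

    def dates(self) -> np.ndarray:
        """Calendar date of each epoch start, as numpy datetime64[D]."""
        start = np.datetime64(self.start_time.to_datetime64(), "s")
        times = start + np.arange(len(self.counts), dtype=np.int64) * self.epoch_s
        return times.astype("datetime64[D]")


@dataclass
class DaySummary:
    date: object
    wear_min: float
    band_min: np.ndarray
    broad_min: np.ndarray
    total_counts: float
    valid: bool


@dataclass
class IntensityProfile:
    """Per-child mean minutes/day in each band, over valid days only."""

    child_id: str
    band_min_mean: np.ndarray
    broad_min_mean: np.ndarray
    total_cpm: float
    n_valid_days: int
    child_valid: bool
    wear_min_mean: float = field(default=float("nan"))


def detect_non_wear(series: EpochSeries, min_duration_min: int = NON_WEAR_MIN) -> list[tuple[int, int]]:
    """Maximal runs of consecutive zero-count epochs lasting >= ``min_duration_min``.

    Returns half-open epoch-index intervals ``[start, stop)``, sorted and
    non-overlapping. Runs are strict zeros: a single non-zero epoch breaks a run.
    """
    z = series.counts == 0
    if not z.any():
        return []
    # boundaries of zero-runs
    padded = np.concatenate(([False], z, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    min_epochs = min_duration_min * 60 // series.epoch_s
    keep = (stops - starts) >= min_epochs
    return list(zip(starts[keep].tolist(), stops[keep].tolist()))


def classify_epoch(count: int, epoch_s: int, scheme: BandScheme = DEFAULT_SCHEME) -> int:
    """Band index of a single epoch count via its cpm equivalent."""
    if count < 0:
        raise ValueError("count must be non-negative")
    return int(scheme.band_of_cpm(count * (60.0 / epoch_s)))


def _wear_mask(series: EpochSeries, non_wear: list[tuple[int, int]]) -> np.ndarray:
    mask = np.ones(len(series), dtype=bool)
    for a, b in non_wear:
        mask[a:b] = False
    secs = series.seconds_of_day()
    mask &= (secs >= DAY_WINDOW[0]) & (secs < DAY_WINDOW[1])
    return mask


def summarize_day(
    series: EpochSeries,
    date,
    scheme: BandScheme = DEFAULT_SCHEME,
    non_wear: list[tuple[int, int]] | None = None,
) -> DaySummary:
    """Accumulate wear and per-band minutes for one calendar day.

    Only epochs with clock time in [06:00, 24:00) and outside detected
    non-wear intervals contribute. Non-wear detection, if not supplied, runs
    on the full series so that zero-runs straddling 06:00 still count.
    """
    if non_wear is None:
        non_wear = detect_non_wear(series)
    date64 = np.datetime64(pd.Timestamp(date).date())
    sel = (series.dates() == date64) & _wear_mask(series, non_wear)
    n_bands = scheme.n_bands
    if not sel.any():
        return DaySummary(date64, 0.0, np.zeros(n_bands), np.zeros(4), 0.0, False)
    counts = series.counts[sel]
    cpm = counts * (60.0 / series.epoch_s)
    epoch_min = series.epoch_s / 60.0
    band_min = np.bincount(scheme.band_of_cpm(cpm), minlength=n_bands) * epoch_min
    broad_min = np.bincount(scheme.broad_of_cpm(cpm), minlength=4) * epoch_min
    wear_min = counts.size * epoch_min
    return DaySummary(
        date=date64,
        wear_min=wear_min,
        band_min=band_min,
        broad_min=broad_min,
        total_counts=float(counts.sum()),
        valid=wear_min >= VALID_DAY_WEAR_MIN,
    )


def summarize_days(series: EpochSeries, scheme: BandScheme = DEFAULT_SCHEME) -> list[DaySummary]:
    """DaySummary for every calendar date covered by the series."""
    non_wear = detect_non_wear(series)
    return [
        summarize_day(series, d, scheme, non_wear)
        for d in np.unique(series.dates())
    ]


def build_profile(child_id: str, summaries: list[DaySummary]) -> IntensityProfile:
    """Average day summaries over valid days into a per-child profile.

    A child with < 4 valid days is returned flagged invalid, with NaN means.
    """
    if not summaries:
        raise ValueError("need at least one day summary")
    valid = [s for s in summaries if s.valid]
    n_bands = len(summaries[0].band_min)
    if not valid:
        nan = float("nan")
        return IntensityProfile(child_id, np.full(n_bands, nan), np.full(4, nan),
                                nan, 0, False, nan)
    band = np.mean([s.band_min for s in valid], axis=0)
    broad = np.mean([s.broad_min for s in valid], axis=0)
    wear = float(np.sum([s.wear_min for s in valid]))
    total_counts = float(np.sum([s.total_counts for s in valid]))
    return IntensityProfile(
        child_id=child_id,
        band_min_mean=band,
        broad_min_mean=broad,
        total_cpm=total_counts / wear if wear > 0 else float("nan"),
        n_valid_days=len(valid),
        child_valid=len(valid) >= VALID_CHILD_DAYS,
        wear_min_mean=wear / len(valid),
    )


def reduce_series(series: EpochSeries, scheme: BandScheme = DEFAULT_SCHEME) -> IntensityProfile:
    """Full reduction of one child's epoch series to an IntensityProfile."""
    return build_profile(series.child_id, summarize_days(series, scheme))


# ---------------------------------------------------------------------------
# CSV interfaces


def read_epoch_csv(path) -> list[EpochSeries]:
    """Read a long-format epoch CSV (child_id, timestamp_iso8601, counts).

    Epochs must be contiguous and equally spaced per child.
    """
    df = pd.read_csv(path, parse_dates=["timestamp_iso8601"])
    out = []
    for cid, g in df.groupby("child_id", sort=True):
        ts = g["timestamp_iso8601"].to_numpy()
        if len(ts) > 1:
            steps = np.unique(np.diff(ts).astype("timedelta64[s]").astype(int))
            if len(steps) != 1:
                raise ValueError(f"child {cid}: epochs not equally spaced")
            epoch_s = int(steps[0])
        else:
            epoch_s = 1
        out.append(EpochSeries(str(cid), pd.Timestamp(ts[0]), epoch_s,
                               g["counts"].to_numpy(dtype=np.int64)))
    return out


def write_epoch_csv(series_list: list[EpochSeries], path) -> None:
    frames = []
    for s in series_list:
        ts = s.start_time + pd.to_timedelta(np.arange(len(s)) * s.epoch_s, unit="s")
        frames.append(pd.DataFrame({
            "child_id": s.child_id,
            "timestamp_iso8601": ts.strftime("%Y-%m-%dT%H:%M:%S"),
            "counts": s.counts,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def profiles_to_frame(profiles: list[IntensityProfile], scheme: BandScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Tabulate profiles: one row per child, 23 band columns + broad + validity."""
    rows = []
    labels = [f"band_{lbl}" for lbl in scheme.labels()]
    from .bands import BROAD_CATEGORIES
    for p in profiles:
        row = {"child_id": p.child_id}
        row.update(dict(zip(labels, p.band_min_mean)))
        row.update({f"broad_{c}": v for c, v in zip(BROAD_CATEGORIES, p.broad_min_mean)})
        row["total_cpm"] = p.total_cpm
        row["n_valid_days"] = p.n_valid_days
        row["child_valid"] = p.child_valid
        rows.append(row)
    return pd.DataFrame(rows)
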