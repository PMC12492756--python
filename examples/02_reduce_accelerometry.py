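"""Reduce a raw 1-second accelerometer count series to intensity exposures.

Simulates one child's 7-day epoch record (including overnight zeros and
injected non-wear blocks), detects non-wear as zero-runs of >= 60 min,
applies the 06:00-23:59 window with the >= 8 h valid-day and >= 4 valid-day
child rules, and prints the resulting per-band minutes per day."""

import numpy as np

from actipls import (
    CohortConfig, generate_epoch_series, detect_non_wear, reduce_series,
    DEFAULT_SCHEME,
)

cfg = CohortConfig(n_children=1, seed=42)
series = generate_epoch_series(cfg, child_index=0)
print(f"series: {len(series)} one-second epochs over {cfg.days} days")

non_wear = detect_non_wear(series)
total_nw_h = sum(b - a for a, b in non_wear) / 3600
print(f"non-wear: {len(non_wear)} zero-runs >= 60 min, {total_nw_h:.1f} h total")

profile = reduce_series(series)
print(f"valid days: {profile.n_valid_days}  child valid: {profile.child_valid}")
print(f"mean wear: {profile.wear_min_mean:.0f} min/day   "
      f"total activity: {profile.total_cpm:.0f} cpm")
print("\nminutes/day by band (sedentary dominates; high bands are sparse):")
for lbl, v in zip(DEFAULT_SCHEME.labels(), profile.band_min_mean):
    bar = "#" * int(np.ceil(3 * np.log10(max(v, 0.01) + 1)))
    print(f"  {lbl:>10} cpm: {v:7.1f}  {bar}")
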