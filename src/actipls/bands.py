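"""Intensity band schemes for accelerometer counts-per-minute (cpm) spectra.

The default scheme divides the cpm axis into 23 contiguous bands
(0-99, 100-249, ..., 9500-9999, >=10000) with broad categories
sedentary (0-99), light (100-2295), moderate (2296-4011) and
vigorous (>=4012 cpm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Lower bounds of the 23 default bands; each band is [lower_k, lower_{k+1} - 1],
# the last band is unbounded above.
DEFAULT_BAND_LOWERS: tuple[int, ...] = (
    0, 100, 250, 500, 1000, 1500, 2000, 2500, 3000, 3500,
    4000, 4500, 5000, 5500, 6000, 6500, 7000, 7500, 8000, 8500,
    9000, 9500, 10000,
)

BROAD_CATEGORIES: tuple[str, ...] = ("sedentary", "light", "moderate", "vigorous")

# Broad cut-points: sedentary 0-99, light 100-2295, moderate 2296-4011,
# vigorous >= 4012 cpm. These do not align with the 23-band edges, so broad
# classification is done against these bounds directly, never via band index.
BROAD_LOWERS: tuple[int, ...] = (0, 100, 2296, 4012)


@dataclass(frozen=True)
class BandScheme:
    """A contiguous partition of the non-negative cpm axis.

    Parameters
    ----------
    lowers
        Strictly increasing integer lower bounds, first element 0. Band ``k``
        covers ``[lowers[k], lowers[k+1] - 1]`` cpm; the last band is open above.
    broad_lowers
        Lower bounds of the broad sedentary/light/moderate/vigorous categories.
    """

    lowers: tuple[int, ...] = DEFAULT_BAND_LOWERS
    broad_lowers: tuple[int, ...] = BROAD_LOWERS
    _lower_arr: np.ndarray = field(init=False, repr=False, compare=False)
    _broad_arr: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        lo = np.asarray(self.lowers, dtype=float)
        if lo[0] != 0 or np.any(np.diff(lo) <= 0):
            raise ValueError("band lower bounds must start at 0 and be strictly increasing")
        bl = np.asarray(self.broad_lowers, dtype=float)
        if len(bl) != 4 or bl[0] != 0 or np.any(np.diff(bl) <= 0):
            raise ValueError("broad_lowers must be 4 increasing bounds starting at 0")
        object.__setattr__(self, "_lower_arr", lo)
        object.__setattr__(self, "_broad_arr", bl)

    @property
    def n_bands(self) -> int:
        return len(self.lowers)

    def labels(self) -> list[str]:
        out = []
        for k, lo in enumerate(self.lowers):
            if k + 1 < len(self.lowers):
                out.append(f"{lo}-{self.lowers[k + 1] - 1}")
            else:
                out.append(f">={lo}")
        return out

    def band_of_cpm(self, cpm: np.ndarray | float) -> np.ndarray:
        """Band index for each cpm value (vectorised)."""
        cpm = np.asarray(cpm, dtype=float)
        if np.any(cpm < 0):
            raise ValueError("cpm values must be non-negative")
        return np.searchsorted(self._lower_arr, cpm, side="right") - 1

    def broad_of_cpm(self, cpm: np.ndarray | float) -> np.ndarray:
        """Broad category index (0=sedentary .. 3=vigorous) per cpm value."""
        cpm = np.asarray(cpm, dtype=float)
        if np.any(cpm < 0):
            raise ValueError("cpm values must be non-negative")
        return np.searchsorted(self._broad_arr, cpm, side="right") - 1

    def broad_map(self) -> list[str]:
        """Approximate band-index -> broad-category labelling by band lower bound.

        Broad cut-points need not align with band edges; this mapping is for
        table labelling only, not for accumulating broad minutes.
        """
        idx = self.broad_of_cpm(self._lower_arr)
        return [BROAD_CATEGORIES[i] for i in idx]

    def midpoints(self, top_band_mid: float = 12000.0) -> np.ndarray:
        """Representative cpm per band (midpoint; configurable for the open top band)."""
        lo = self._lower_arr
        mids = np.empty(self.n_bands)
        mids[:-1] = (lo[:-1] + lo[1:] - 1) / 2.0
        mids[-1] = top_band_mid
        return mids


DEFAULT_SCHEME = BandScheme()
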