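"""Epoch-series reduction: non-wear detection, band classification, day and
child summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from actipls import (
    EpochSeries, detect_non_wear, classify_epoch, summarize_day,
    summarize_days, build_profile, reduce_series, DEFAULT_SCHEME,
    read_epoch_csv, write_epoch_csv,
)
from actipls.accelerometry import VALID_DAY_WEAR_MIN

from conftest import brute_force_non_wear


def series_minutes(counts, start="2020-01-06 00:00:00"):
    return EpochSeries("c1", pd.Timestamp(start), 60, np.asarray(counts))


class TestDetectNonWear:
    def test_all_zero_day_is_one_interval(self):
        s = series_minutes(np.zeros(1440, dtype=int))
        assert detect_non_wear(s) == [(0, 1440)]

    def test_59_minutes_of_zeros_is_not_non_wear(self):
        counts = np.ones(120, dtype=int)
        counts[30:89] = 0  # 59 consecutive zero minutes
        assert detect_non_wear(series_minutes(counts)) == []

    def test_60_minute_boundary_inclusive(self):
        counts = np.ones(200, dtype=int)
        counts[30:90] = 0  # exactly 60 min
        assert detect_non_wear(series_minutes(counts)) == [(30, 90)]

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(7)
        for _ in range(500):
            # alternate zero / non-zero blocks of random length
            blocks = []
            zero = rng.random() < 0.5
            for _ in range(rng.integers(1, 9)):
                L = int(rng.integers(1, 120))
                blocks.append(np.zeros(L, int) if zero
                              else rng.integers(1, 50, L))
                zero = not zero
            counts = np.concatenate(blocks)
            s = series_minutes(counts)
            assert detect_non_wear(s) == brute_force_non_wear(counts, 60)

    def test_matches_brute_force_exhaustively_short(self):
        # every binary series of length 10 at 60-s epochs, 3-min threshold
        for bits in itertools.product([0, 1], repeat=10):
            counts = np.array(bits)
            s = series_minutes(counts)
            got = detect_non_wear(s, min_duration_min=3)
            assert got == brute_force_non_wear(counts, 60, 3)


class TestClassifyEpoch:
    @pytest.mark.parametrize("count,epoch_s,band", [
        (0, 1, 0),            # zero -> sedentary band
        (50, 1, 8),           # 3000 cpm -> 3000-3499
        (1, 60, 0),           # 1 count/min -> 0-99
        (10000, 60, 22),      # top band closed below only
        (99, 60, 0),
        (100, 60, 1),
    ])
    def test_band_assignment(self, count, epoch_s, band):
        assert classify_epoch(count, epoch_s) == band

    def test_broad_cut_points(self):
        # moderate 2296-4011 cpm, vigorous >= 4012 cpm
        assert DEFAULT_SCHEME.broad_of_cpm(50 * 60) == 2       # 3000 cpm
        assert DEFAULT_SCHEME.broad_of_cpm(67 * 60) == 3       # 4020 cpm
        assert DEFAULT_SCHEME.broad_of_cpm(2295) == 1
        assert DEFAULT_SCHEME.broad_of_cpm(2296) == 2

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            classify_epoch(-1, 1)


def make_day(wear_min, cpm_value=50):
    """One calendar day at 60-s epochs: zeros overnight, `wear_min` active
    minutes at `cpm_value` starting 08:00, nonzero elsewhere filled with
    interruptions to stop zero-runs reaching 60 min."""
    counts = np.zeros(1440, dtype=int)
    start = 8 * 60
    counts[start:start + wear_min] = cpm_value
    return counts


class TestSummarizeDay:
    def test_full_non_wear_day_invalid(self):
        s = series_minutes(np.zeros(1440, int))
        d = summarize_day(s, "2020-01-06")
        assert d.wear_min == 0 and not d.valid

    def test_exactly_8h_wear_is_valid(self):
        s = series_minutes(make_day(VALID_DAY_WEAR_MIN))
        d = summarize_day(s, "2020-01-06")
        assert d.wear_min == VALID_DAY_WEAR_MIN
        assert d.valid

    def test_479_min_wear_invalid(self):
        s = series_minutes(make_day(VALID_DAY_WEAR_MIN - 1))
        assert not summarize_day(s, "2020-01-06").valid

    def test_hand_counted_band_minutes(self):
        # 100 min at 3000 cpm + 30 min at 500 cpm + 20 min at 0 cpm (worn but
        # idle: the zero run is < 60 min because it is flanked by activity)
        counts = np.zeros(1440, int)
        counts[480:580] = 3000
        counts[580:610] = 500
        counts[610:630] = 0
        counts[630:700] = 120
        s = series_minutes(counts)
        d = summarize_day(s, "2020-01-06")
        # independent tally of the expectation
        expect = np.zeros(23)
        expect[8] = 100    # 3000-3499
        expect[3] = 30     # 500-999
        expect[0] += 20    # idle zeros inside wear
        expect[1] = 70     # 120 cpm -> 100-249
        np.testing.assert_allclose(d.band_min, expect)
        assert d.wear_min == 220
        assert d.total_counts == 100 * 3000 + 30 * 500 + 70 * 120

    def test_window_excludes_pre_0600(self):
        counts = np.zeros(1440, int)
        counts[4 * 60:5 * 60] = 1000   # 04:00-05:00, outside the window
        counts[7 * 60:8 * 60] = 1000
        s = series_minutes(counts)
        d = summarize_day(s, "2020-01-06")
        assert d.wear_min == 60

    def test_missing_date_gives_empty_invalid_summary(self):
        s = series_minutes(make_day(300))
        d = summarize_day(s, "2021-07-01")
        assert d.wear_min == 0 and not d.valid


class TestBuildProfile:
    def _days(self, n_valid, n_invalid=0):
        out = []
        for _ in range(n_valid):
            out.append(summarize_day(series_minutes(make_day(600)), "2020-01-06"))
        for _ in range(n_invalid):
            out.append(summarize_day(series_minutes(make_day(100)), "2020-01-06"))
        return out

    def test_three_valid_days_flags_child_invalid(self):
        p = build_profile("c", self._days(3))
        assert p.n_valid_days == 3 and not p.child_valid

    def test_four_valid_days_is_valid(self):
        assert build_profile("c", self._days(4)).child_valid

    def test_identical_days_mean_equals_single_day(self):
        days = self._days(7)
        p = build_profile("c", days)
        np.testing.assert_allclose(p.band_min_mean, days[0].band_min)

    def test_invalid_days_excluded_from_means(self):
        p = build_profile("c", self._days(5, n_invalid=2))
        assert p.n_valid_days == 5
        np.testing.assert_allclose(p.band_min_mean.sum(), 600)

    def test_conservation_band_sum_equals_wear(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 80, 1440)
        s = series_minutes(counts)
        days = summarize_days(s)
        for d in days:
            np.testing.assert_allclose(d.band_min.sum(), d.wear_min, atol=60 / 60)


def test_filling_non_wear_never_decreases_wear():
    rng = np.random.default_rng(11)
    counts = np.zeros(1440, int)
    counts[600:900] = rng.integers(1, 50, 300)
    s = series_minutes(counts)
    base = summarize_day(s, "2020-01-06").wear_min
    filled = counts.copy()
    filled[60:180] = 5   # turn part of a non-wear run into wear
    s2 = series_minutes(filled)
    assert summarize_day(s2, "2020-01-06").wear_min >= base


def test_epoch_csv_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    s = EpochSeries("kid1", pd.Timestamp("2020-03-02 00:00:00"), 60,
                    rng.integers(0, 100, 2880))
    path = tmp_path / "epochs.csv"
    write_epoch_csv([s], path)
    (back,) = read_epoch_csv(path)
    assert back.child_id == "kid1"
    assert back.epoch_s == 60
    np.testing.assert_array_equal(back.counts, s.counts)
    p1, p2 = reduce_series(s), reduce_series(back)
    np.testing.assert_allclose(p1.band_min_mean, p2.band_min_mean)
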