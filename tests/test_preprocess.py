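"""Data-reduction chain: reintegration, spikes, cropping, non-wear, validity,
inclusion."""

from datetime import date as Date

import numpy as np
import pandas as pd
import pytest

from sedtrack.epoch_io import EpochValidationError
from sedtrack.preprocess import (
    AlignmentError,
    InclusionReason,
    MinuteState,
    ResolutionError,
    build_day_record,
    crop_waking_window,
    decide_inclusion,
    detect_nonwear,
    invalidate_spikes,
    reintegrate,
    series_to_day_records,
)

from conftest import day_from_counts, make_series, oracle_zero_runs, random_day_counts

WINDOW = 1020


class TestReintegrate:
    def test_identity_at_60s(self):
        s = make_series([10, 20, 30])
        out = reintegrate(s, 60)
        np.testing.assert_array_equal(out.counts, s.counts)
        assert out.epoch_length == 60

    @pytest.mark.parametrize(
        "epoch_length,counts,expected",
        [(15, [10, 20, 30, 40], [100]), (30, [500, 700], [1200])],
    )
    def test_sums_within_minute(self, epoch_length, counts, expected):
        s = make_series(counts, epoch_length=epoch_length)
        out = reintegrate(s, 60)
        np.testing.assert_array_equal(out.counts, expected)

    def test_block_with_missing_epoch_is_missing(self):
        s = make_series([10, np.nan, 30, 40, 1, 2, 3, 4], epoch_length=15)
        out = reintegrate(s, 60)
        assert np.isnan(out.counts[0])
        assert out.counts[1] == 10

    def test_misaligned_start_raises(self):
        s = make_series([1, 2, 3, 4], epoch_length=15, start="2005-01-03 07:00:15")
        with pytest.raises(AlignmentError):
            reintegrate(s, 60)

    def test_non_multiple_target_raises(self):
        s = make_series([1, 2], epoch_length=30)
        with pytest.raises(ResolutionError):
            reintegrate(s, 45)


class TestSpikes:
    def test_boundary_is_strictly_greater(self):
        s = make_series([30000, 30001, 0])
        out = invalidate_spikes(s)
        np.testing.assert_array_equal(out.invalid, [False, True, False])

    def test_all_zero_day_unchanged(self):
        s = make_series([0] * 100)
        out = invalidate_spikes(s)
        assert not out.invalid.any()

    def test_requires_60s_resolution(self):
        s = make_series([1, 2], epoch_length=30)
        with pytest.raises(ResolutionError):
            invalidate_spikes(s)


class TestCrop:
    def test_window_boundaries(self):
        s = make_series([1, 2], start="2005-01-03 06:59:00")
        out = crop_waking_window(s)
        assert list(out.timestamps.strftime("%H:%M")) == ["07:00"]

    def test_end_of_day_kept(self):
        s = make_series([5], start="2005-01-03 23:59:00")
        assert len(crop_waking_window(s)) == 1

    def test_full_day_keeps_1020(self):
        s = make_series(np.ones(1440), start="2005-01-03 00:00:00")
        assert len(crop_waking_window(s)) == WINDOW


class TestDetectNonwear:
    def _states(self, counts, invalid=None):
        counts = np.asarray(counts, dtype=float)
        if invalid is None:
            invalid = np.zeros(len(counts), dtype=bool)
        return detect_nonwear(counts, invalid)

    def test_59_zeros_stay_worn(self):
        counts = [100] + [0] * 59 + [100]
        assert (self._states(counts) == MinuteState.WORN).all()

    def test_exactly_60_zeros_nonwear(self):
        counts = [100] + [0] * 60 + [100]
        state = self._states(counts)
        assert (state[1:61] == MinuteState.NONWEAR).all()
        assert state[0] == state[61] == MinuteState.WORN

    def test_120_zeros_single_maximal_run(self):
        state = self._states([0] * 120)
        assert (state == MinuteState.NONWEAR).all()

    def test_invalid_minute_terminates_zero_run(self):
        counts = [0] * 30 + [40000] + [0] * 30
        invalid = np.zeros(61, dtype=bool)
        invalid[30] = True
        state = self._states(counts, invalid)
        assert state[30] == MinuteState.INVALID
        assert (state[:30] == MinuteState.WORN).all()
        assert (state[31:] == MinuteState.WORN).all()

    def test_agrees_with_oracle_on_random_days(self, rng):
        for _ in range(300):
            counts = random_day_counts(rng)
            invalid = counts > 30000
            got = detect_nonwear(counts, invalid)
            want = oracle_zero_runs(counts, invalid)
            np.testing.assert_array_equal(got, want)


class TestDayRecord:
    @pytest.mark.parametrize("wear,valid", [(480, True), (479, False)])
    def test_validity_boundary(self, wear, valid):
        counts = [50] * wear + [0] * (WINDOW - wear)
        day = day_from_counts(counts)
        assert day.wear_minutes == wear
        assert day.valid is valid

    def test_all_nonwear_day(self):
        day = day_from_counts([0] * WINDOW)
        assert day.wear_minutes == 0 and not day.valid

    def test_weekend_flag(self):
        assert day_from_counts([50] * WINDOW, date=Date(2005, 1, 8)).weekend  # Sat
        assert not day_from_counts([50] * WINDOW, date=Date(2005, 1, 7)).weekend

    def test_wrong_length_raises(self):
        with pytest.raises(EpochValidationError, match="1020"):
            build_day_record(np.ones(10), np.zeros(10, dtype=np.int8), Date(2005, 1, 3))

    def test_state_partition_sums_to_window(self, rng):
        for _ in range(50):
            counts = random_day_counts(rng, n=int(rng.integers(1, WINDOW)))
            day = day_from_counts(counts)
            assert day.wear_minutes + day.nonwear_minutes + day.invalid_minutes == WINDOW


def test_pipeline_order_invariance(rng):
    """Reintegrate->spikes->crop equals crop->reintegrate->spikes on
    day-aligned input."""
    counts = rng.integers(0, 9000, 1440 * 4).astype(float)
    s = make_series(counts, start="2005-01-03 00:00:00", epoch_length=15)
    a = crop_waking_window(invalidate_spikes(reintegrate(s, 60)))
    b = invalidate_spikes(reintegrate(crop_waking_window(s), 60))
    np.testing.assert_array_equal(a.counts, b.counts)
    np.testing.assert_array_equal(a.invalid, b.invalid)
    assert list(a.timestamps) == list(b.timestamps)


def test_series_to_day_records_splits_days():
    counts = np.concatenate([np.full(1440, 200.0), np.full(1440, 300.0)])
    s = make_series(counts, start="2005-01-03 00:00:00")
    days = series_to_day_records(s)
    assert [d.date for d in days] == [Date(2005, 1, 3), Date(2005, 1, 4)]
    assert all(d.wear_minutes == WINDOW for d in days)


def _wave(n_weekday_valid, n_weekend_valid, n_invalid=0, start=Date(2005, 1, 3)):
    """Build a wave's day records: Mon-Fri weekdays then Sat/Sun weekends."""
    days = []
    weekdays = [Date(2005, 1, 3 + i) for i in range(5)]  # Mon..Fri
    weekends = [Date(2005, 1, 8), Date(2005, 1, 9)]  # Sat, Sun
    for i in range(n_weekday_valid):
        days.append(day_from_counts([50] * WINDOW, date=weekdays[i]))
    for i in range(n_weekend_valid):
        days.append(day_from_counts([50] * WINDOW, date=weekends[i]))
    for i in range(n_invalid):
        days.append(day_from_counts([50] * 100, date=weekdays[-(i + 1)]))
    return days


class TestInclusion:
    def test_weekend_missing_at_baseline(self):
        waves = {1: _wave(4, 0), 2: _wave(4, 1)}
        d = decide_inclusion(waves, "p")
        assert not d.included and d.reason == InclusionReason.NO_WEEKEND_BASELINE

    def test_baseline_and_followup_ok(self):
        waves = {1: _wave(3, 1), 2: _wave(3, 1)}
        d = decide_inclusion(waves, "p")
        assert d.included and d.reason == InclusionReason.OK
        assert d.eligible_waves == [1, 2]

    def test_too_few_days_baseline(self):
        waves = {1: _wave(3, 0), 2: _wave(4, 1)}
        d = decide_inclusion(waves, "p")
        assert d.reason == InclusionReason.TOO_FEW_DAYS_BASELINE

    def test_invalid_weekend_day_does_not_count(self):
        # weekend day present but not valid: inclusion must fail
        waves = {1: _wave(4, 0) + [day_from_counts([50] * 100, date=Date(2005, 1, 8))],
                 2: _wave(4, 1)}
        d = decide_inclusion(waves, "p")
        assert d.reason == InclusionReason.NO_WEEKEND_BASELINE

    def test_no_valid_followup(self):
        waves = {1: _wave(4, 1), 2: _wave(2, 1)}
        d = decide_inclusion(waves, "p")
        assert d.reason == InclusionReason.NO_VALID_FOLLOWUP

    def test_missing_baseline_raises(self):
        with pytest.raises(EpochValidationError, match="baseline"):
            decide_inclusion({2: _wave(4, 1)}, "p")

    def test_ineligible_wave_dropped_not_participant(self):
        waves = {1: _wave(4, 1), 2: _wave(1, 0), 3: _wave(4, 1)}
        d = decide_inclusion(waves, "p")
        assert d.included and d.eligible_waves == [1, 3]

    def test_adding_valid_days_is_monotone(self, rng):
        """An included participant never becomes excluded by adding a valid day."""
        for _ in range(30):
            waves = {
                w: _wave(int(rng.integers(0, 5)), int(rng.integers(0, 3)))
                for w in (1, 2)
            }
            base = decide_inclusion(waves, "p")
            if not base.included:
                continue
            for wave_id in (1, 2):
                for new_day in (Date(2005, 1, 7), Date(2005, 1, 9)):
                    grown = {w: list(d) for w, d in waves.items()}
                    grown[wave_id].append(day_from_counts([50] * WINDOW, date=new_day))
                    assert decide_inclusion(grown, "p").included
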