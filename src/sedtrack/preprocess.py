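"""Accelerometer data-reduction chain.

The chain, applied in order to each participant-wave epoch stream:

1. **Reintegration** of sub-minute epochs to 60-s resolution (counts summed).
2. **Spike invalidation**: 60-s epochs with intensity strictly greater than
   30,000 cpm are marked non-valid.
3. **Waking-window crop**: time between midnight and 07:00 is discarded; the
   analysis window is [07:00, 24:00), i.e. 1020 minutes per day.
4. **Non-wear detection**: maximal runs of >=60 consecutive zero-count minutes
   are non-wear, with no tolerance; invalid minutes terminate zero-runs and
   runs never cross the 07:00 boundary or midnight.
5. **Valid-day rule**: a day is valid when worn for >=480 min within the window.
6. **Inclusion rule**: a participant enters analysis when baseline (wave 1)
   and at least one follow-up wave each have >=4 valid days including >=1
   valid weekend day (Saturday/Sunday).

Invalid minutes (spikes, missing counts, unrecorded slots inside the window)
contribute to no category: they are excluded from wear time and are never
sedentary. Waves of an included participant that themselves fail the
4-day/weekend rule are dropped from analysis rather than the participant.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import date as Date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .epoch_io import EpochSeries, EpochValidationError

MINUTES_PER_DAY_WINDOW = 1020  # 17 h x 60


class MinuteState(enum.IntEnum):
    WORN = 0
    NONWEAR = 1
    INVALID = 2


class ResolutionError(ValueError):
    """Operation requires a different epoch resolution."""


class AlignmentError(ValueError):
    """Epoch stream is not aligned to the reintegration block grid."""


@dataclass(frozen=True)
class ProcessingConfig:
    """Data-reduction parameters; defaults are the pooled-analysis rules."""

    nonwear_min_minutes: int = 60
    spike_threshold: int = 30000
    window_start: str = "07:00"
    valid_day_minutes: int = 480
    min_valid_days: int = 4
    min_weekend_days: int = 1
    target_epoch: int = 60

    @property
    def window_start_minute(self) -> int:
        h, m = self.window_start.split(":")
        return int(h) * 60 + int(m)

    @property
    def window_minutes(self) -> int:
        return 24 * 60 - self.window_start_minute


DEFAULT_CONFIG = ProcessingConfig()


@dataclass
class DayRecord:
    """One calendar day after preprocessing.

    ``minute_counts``/``minute_state`` cover the full waking window
    (1020 slots from 07:00), with counts NaN wherever the state is not WORN.
    """

    date: Date
    weekend: bool
    wear_minutes: int
    valid: bool
    minute_counts: np.ndarray
    minute_state: np.ndarray

    @property
    def nonwear_minutes(self) -> int:
        return int(np.sum(self.minute_state == MinuteState.NONWEAR))

    @property
    def invalid_minutes(self) -> int:
        return int(np.sum(self.minute_state == MinuteState.INVALID))


class InclusionReason(str, enum.Enum):
    OK = "ok"
    TOO_FEW_DAYS_BASELINE = "too_few_days_baseline"
    NO_WEEKEND_BASELINE = "no_weekend_baseline"
    NO_VALID_FOLLOWUP = "no_valid_followup"
    NO_BASELINE = "no_baseline"


@dataclass
class InclusionDecision:
    participant_id: str
    included: bool
    reason: InclusionReason
    valid_day_counts: dict[int, int]
    eligible_waves: list[int] = field(default_factory=list)


def reintegrate(series: EpochSeries, target_epoch: int = 60) -> EpochSeries:
    """Sum sub-minute epochs into ``target_epoch``-second blocks.

    Blocks are aligned to the clock grid (a 60-s block spans hh:mm:00 to
    hh:mm+1:00). A block containing a missing epoch is missing; a block
    containing an invalid epoch is invalid; a block not fully covered by
    input epochs (possible only at the stream edges, since gaps within a day
    are rejected at read time) is treated as missing.
    """
    if target_epoch % series.epoch_length != 0:
        raise ResolutionError(
            f"target epoch {target_epoch} not a multiple of {series.epoch_length}"
        )
    if series.epoch_length == target_epoch:
        return series.copy()
    if len(series) == 0:
        return replace(series, epoch_length=target_epoch)
    offsets = (
        series.timestamps.asi8 // 10**9
    ) % target_epoch
    if offsets[0] != 0:
        raise AlignmentError(
            f"first timestamp {series.timestamps[0]} not aligned to a "
            f"{target_epoch}-s block boundary"
        )
    factor = target_epoch // series.epoch_length
    block = series.timestamps.floor(f"{target_epoch}s")
    df = pd.DataFrame(
        {"block": block, "counts": series.counts, "invalid": series.invalid}
    )
    agg = df.groupby("block", sort=True).agg(
        counts=("counts", "sum"),
        n=("counts", "size"),
        n_missing=("counts", lambda c: int(c.isna().sum())),
        invalid=("invalid", "any"),
    )
    counts = agg["counts"].to_numpy(dtype=float)
    counts[(agg["n_missing"] > 0) | (agg["n"] < factor)] = np.nan
    return replace(
        series,
        epoch_length=target_epoch,
        timestamps=pd.DatetimeIndex(agg.index),
        counts=counts,
        invalid=agg["invalid"].to_numpy(dtype=bool),
    )


def invalidate_spikes(
    series: EpochSeries, threshold_cpm: int = DEFAULT_CONFIG.spike_threshold
) -> EpochSeries:
    """Mark 60-s epochs with counts strictly above ``threshold_cpm`` invalid."""
    if series.epoch_length != 60:
        raise ResolutionError(
            f"spike rule is defined at 60-s resolution, got {series.epoch_length}-s"
        )
    out = series.copy()
    with np.errstate(invalid="ignore"):
        out.invalid |= np.nan_to_num(out.counts, nan=-1.0) > threshold_cpm
    return out


def crop_waking_window(
    series: EpochSeries, config: ProcessingConfig = DEFAULT_CONFIG
) -> EpochSeries:
    """Discard epochs starting before 07:00; keep [07:00, 24:00)."""
    minute_of_day = series.timestamps.hour * 60 + series.timestamps.minute
    keep = np.asarray(minute_of_day >= config.window_start_minute)
    return replace(
        series,
        timestamps=series.timestamps[keep],
        counts=series.counts[keep],
        invalid=series.invalid[keep],
    )


def detect_nonwear(
    counts: np.ndarray,
    invalid: np.ndarray,
    present: np.ndarray | None = None,
    min_run: int = DEFAULT_CONFIG.nonwear_min_minutes,
) -> np.ndarray:
    """Label one day's waking-window minutes as worn / non-wear / invalid.

    A minute is non-wear when it belongs to a maximal run of consecutive
    zero-count minutes of length >= ``min_run``. Invalid, missing-count and
    unrecorded minutes are INVALID and terminate zero-runs; the array spans a
    single day's window so runs cannot cross 07:00 or midnight by construction.
    """
    counts = np.asarray(counts, dtype=float)
    invalid = np.asarray(invalid, dtype=bool)
    if present is None:
        present = np.ones(len(counts), dtype=bool)
    state = np.full(len(counts), MinuteState.WORN, dtype=np.int8)
    bad = invalid | ~present | np.isnan(counts)
    state[bad] = MinuteState.INVALID
    with np.errstate(invalid="ignore"):
        zero = ~bad & (np.nan_to_num(counts, nan=-1.0) == 0.0)
    # maximal runs of `zero`
    i = 0
    n = len(zero)
    while i < n:
        if zero[i]:
            j = i
            while j < n and zero[j]:
                j += 1
            if j - i >= min_run:
                state[i:j] = MinuteState.NONWEAR
            i = j
        else:
            i += 1
    return state


def build_day_record(
    minute_counts: np.ndarray,
    minute_state: np.ndarray,
    date: Date,
    config: ProcessingConfig = DEFAULT_CONFIG,
) -> DayRecord:
    """Assemble a :class:`DayRecord` from a day's 1020-slot minute stream."""
    minute_counts = np.asarray(minute_counts, dtype=float)
    minute_state = np.asarray(minute_state, dtype=np.int8)
    if len(minute_state) != config.window_minutes or len(minute_counts) != len(minute_state):
        raise EpochValidationError(
            f"minute stream must have length {config.window_minutes}, "
            f"got {len(minute_state)}"
        )
    counts = minute_counts.copy()
    counts[minute_state != MinuteState.WORN] = np.nan
    wear = int(np.sum(minute_state == MinuteState.WORN))
    return DayRecord(
        date=date,
        weekend=date.weekday() >= 5,
        wear_minutes=wear,
        valid=wear >= config.valid_day_minutes,
        minute_counts=counts,
        minute_state=minute_state,
    )


def series_to_day_records(
    series: EpochSeries, config: ProcessingConfig = DEFAULT_CONFIG
) -> list[DayRecord]:
    """Run the full reduction chain on one epoch stream.

    Days with no recorded epochs in the window are absent from the result
    (rather than appearing as all-invalid days).
    """
    s = reintegrate(series, config.target_epoch)
    s = invalidate_spikes(s, config.spike_threshold)
    s = crop_waking_window(s, config)
    records: list[DayRecord] = []
    if len(s) == 0:
        return records
    days = s.timestamps.normalize()
    minute_of_day = (s.timestamps.hour * 60 + s.timestamps.minute).to_numpy()
    start = config.window_start_minute
    for day in days.unique():
        sel = np.asarray(days == day)
        slots = minute_of_day[sel] - start
        counts = np.full(config.window_minutes, np.nan)
        invalid = np.zeros(config.window_minutes, dtype=bool)
        present = np.zeros(config.window_minutes, dtype=bool)
        counts[slots] = s.counts[sel]
        invalid[slots] = s.invalid[sel]
        present[slots] = True
        state = detect_nonwear(counts, invalid, present, config.nonwear_min_minutes)
        records.append(build_day_record(counts, state, day.date(), config))
    return records


def _wave_ok(days: Sequence[DayRecord], config: ProcessingConfig) -> tuple[bool, str | None]:
    n_valid = sum(d.valid for d in days)
    n_valid_weekend = sum(d.valid and d.weekend for d in days)
    if n_valid < config.min_valid_days:
        return False, "too_few_days"
    if n_valid_weekend < config.min_weekend_days:
        return False, "no_weekend"
    return True, None


def decide_inclusion(
    day_records_by_wave: Mapping[int, Sequence[DayRecord]],
    participant_id: str = "",
    config: ProcessingConfig = DEFAULT_CONFIG,
) -> InclusionDecision:
    """Apply the participant-inclusion rule across waves.

    Wave 1 is the baseline; waves >= 2 are follow-ups. The weekend day must
    itself be a valid day. ``eligible_waves`` lists every wave (baseline and
    follow-ups) meeting the 4-day/weekend rule, so that only those waves
    enter the analysis.
    """
    if 1 not in day_records_by_wave:
        raise EpochValidationError(
            f"participant {participant_id!r}: no baseline wave (wave 1) present"
        )
    valid_counts = {
        w: sum(d.valid for d in days) for w, days in day_records_by_wave.items()
    }
    base_ok, base_fail = _wave_ok(day_records_by_wave[1], config)
    eligible = [
        w
        for w in sorted(day_records_by_wave)
        if _wave_ok(day_records_by_wave[w], config)[0]
    ]
    if not base_ok:
        reason = (
            InclusionReason.TOO_FEW_DAYS_BASELINE
            if base_fail == "too_few_days"
            else InclusionReason.NO_WEEKEND_BASELINE
        )
        return InclusionDecision(participant_id, False, reason, valid_counts, [])
    if not any(w >= 2 for w in eligible):
        return InclusionDecision(
            participant_id, False, InclusionReason.NO_VALID_FOLLOWUP, valid_counts, []
        )
    return InclusionDecision(
        participant_id, True, InclusionReason.OK, valid_counts, eligible
    )
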