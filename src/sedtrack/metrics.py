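"""Daily and wave-level sedentary-accumulation outcomes.

Intensity classification of worn minutes uses the uniaxial ActiGraph count
cut-points: sedentary < 100 cpm, MVPA >= 3000 cpm, light in between.
Prolonged sedentary time is time accumulated in uninterrupted runs of >= 10
consecutive sedentary minutes (no tolerance: a single non-sedentary, non-wear
or invalid minute ends a run). Zero-count worn minutes are sedentary; only
runs of >= 60 zeros become non-wear upstream, so 10-59 zero minutes do form
sedentary bouts.

The day-to-day variation of a daily metric x_1..x_N over a wave's valid days
is the mean absolute deviation  sum_i |x_i - mean(x)| / N.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date as Date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .preprocess import DayRecord, MinuteState

SEDENTARY_CPM = 100
MVPA_CPM = 3000
PROLONGED_BOUT_MINUTES = 10

WAVE_SUMMARY_COLUMNS = [
    "participant_id",
    "study_id",
    "country_id",
    "wave",
    "age",
    "gender",
    "n_valid_days",
    "mean_total_sed",
    "mean_prolonged_sed",
    "dtd_total",
    "dtd_prolonged",
    "mean_wear",
    "mean_mvpa",
]


class Intensity(enum.IntEnum):
    SEDENTARY = 0
    LIGHT = 1
    MVPA = 2


@dataclass
class DailyMetrics:
    date: Date
    total_sedentary: int
    prolonged_sedentary: int
    mvpa: int
    wear_minutes: int
    n_prolonged_bouts: int


@dataclass
class WaveSummary:
    participant_id: str
    study_id: str
    country_id: str
    wave: int
    age: float
    gender: str
    n_valid_days: int
    mean_total_sed: float
    mean_prolonged_sed: float
    dtd_total: float
    dtd_prolonged: float
    mean_wear: float
    mean_mvpa: float


def classify_minute(counts: float) -> Intensity:
    """Intensity class of a single worn minute's counts."""
    if counts < SEDENTARY_CPM:
        return Intensity.SEDENTARY
    if counts >= MVPA_CPM:
        return Intensity.MVPA
    return Intensity.LIGHT


def prolonged_sedentary_time(
    minute_counts: np.ndarray,
    minute_state: np.ndarray,
    min_bout: int = PROLONGED_BOUT_MINUTES,
) -> tuple[int, int]:
    """Total minutes and bout count of maximal sedentary runs >= ``min_bout``.

    A run consists of consecutive worn minutes with counts < 100 cpm; any
    non-sedentary, non-wear or invalid minute terminates it. The window ends
    at midnight, so a run truncated there counts only if already >= min_bout.
    """
    counts = np.asarray(minute_counts, dtype=float)
    state = np.asarray(minute_state, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        sed = (state == MinuteState.WORN) & (np.nan_to_num(counts, nan=np.inf) < SEDENTARY_CPM)
    total = 0
    bouts = 0
    run = 0
    for flag in sed:
        if flag:
            run += 1
        else:
            if run >= min_bout:
                total += run
                bouts += 1
            run = 0
    if run >= min_bout:
        total += run
        bouts += 1
    return total, bouts


def daily_metrics(day: DayRecord) -> DailyMetrics:
    """Per-day outcome totals; defined only on valid days."""
    if not day.valid:
        raise ValueError(f"daily metrics are defined on valid days only ({day.date})")
    worn = day.minute_state == MinuteState.WORN
    counts = day.minute_counts
    with np.errstate(invalid="ignore"):
        sed = worn & (np.nan_to_num(counts, nan=np.inf) < SEDENTARY_CPM)
        mvpa = worn & (np.nan_to_num(counts, nan=-1.0) >= MVPA_CPM)
    prolonged, n_bouts = prolonged_sedentary_time(counts, day.minute_state)
    return DailyMetrics(
        date=day.date,
        total_sedentary=int(sed.sum()),
        prolonged_sedentary=prolonged,
        mvpa=int(mvpa.sum()),
        wear_minutes=day.wear_minutes,
        n_prolonged_bouts=n_bouts,
    )


def day_to_day_variation(day_values: Sequence[float]) -> float:
    """Mean absolute deviation of a daily metric across measurement days."""
    values = np.asarray(list(day_values), dtype=float)
    if values.size == 0:
        raise ValueError("day_to_day_variation requires at least one day")
    if np.all(values == values[0]):  # exact zero for identical days
        return 0.0
    return float(np.mean(np.abs(values - values.mean())))


def summarize_wave(
    daily: Sequence[DailyMetrics],
    participant_id: str,
    study_id: str,
    country_id: str,
    wave: int,
    age: float,
    gender: str,
    min_valid_days: int = 4,
) -> WaveSummary:
    """Aggregate one eligible wave's valid days into a :class:`WaveSummary`."""
    if len(daily) < min_valid_days:
        raise ValueError(
            f"wave {wave} of participant {participant_id!r} has {len(daily)} valid "
            f"days; needs >= {min_valid_days} to be eligible"
        )
    totals = [d.total_sedentary for d in daily]
    prolonged = [d.prolonged_sedentary for d in daily]
    return WaveSummary(
        participant_id=participant_id,
        study_id=study_id,
        country_id=country_id,
        wave=wave,
        age=age,
        gender=gender,
        n_valid_days=len(daily),
        mean_total_sed=float(np.mean(totals)),
        mean_prolonged_sed=float(np.mean(prolonged)),
        dtd_total=day_to_day_variation(totals),
        dtd_prolonged=day_to_day_variation(prolonged),
        mean_wear=float(np.mean([d.wear_minutes for d in daily])),
        mean_mvpa=float(np.mean([d.mvpa for d in daily])),
    )


def wave_summaries_to_frame(summaries: Iterable[WaveSummary]) -> pd.DataFrame:
    """Wave summaries as a DataFrame in the wave-summary CSV dialect."""
    rows = [
        {col: getattr(s, col) for col in WAVE_SUMMARY_COLUMNS} for s in summaries
    ]
    return pd.DataFrame(rows, columns=WAVE_SUMMARY_COLUMNS)
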