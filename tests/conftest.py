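"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use a different mechanism (itertools.groupby run
enumeration, plain-Python arithmetic) than the implementation they check.
"""

from __future__ import annotations

import itertools
from datetime import date as Date

import numpy as np
import pandas as pd
import pytest

from sedtrack.epoch_io import EpochSeries
from sedtrack.preprocess import MinuteState, build_day_record, detect_nonwear

WINDOW = 1020


def make_series(
    counts,
    start="2005-01-03 07:00:00",
    epoch_length=60,
    participant_id="p1",
    study_id="s1",
    country_id="c1",
    wave=1,
):
    counts = np.asarray(counts, dtype=float)
    timestamps = pd.date_range(start, periods=len(counts), freq=f"{epoch_length}s")
    return EpochSeries(
        participant_id=participant_id,
        study_id=study_id,
        country_id=country_id,
        wave=wave,
        epoch_length=epoch_length,
        timestamps=timestamps,
        counts=counts,
    )


def day_from_counts(counts, date=Date(2005, 1, 3), invalid=None):
    """DayRecord from a window of minute counts (padded with absent slots)."""
    counts = np.asarray(counts, dtype=float)
    full = np.full(WINDOW, np.nan)
    full[: len(counts)] = counts
    present = np.zeros(WINDOW, dtype=bool)
    present[: len(counts)] = True
    inv = np.zeros(WINDOW, dtype=bool)
    if invalid is not None:
        inv[: len(counts)] = np.asarray(invalid, dtype=bool)
    state = detect_nonwear(full, inv, present)
    return build_day_record(full, state, date)


def oracle_zero_runs(counts, invalid, min_run=60):
    """Brute-force maximal-run enumeration of non-wear labels."""
    n = len(counts)
    ok = [
        (not invalid[i]) and (not np.isnan(counts[i]))
        for i in range(n)
    ]
    key = [
        "zero" if ok[i] and counts[i] == 0 else ("worn" if ok[i] else "invalid")
        for i in range(n)
    ]
    state = np.empty(n, dtype=np.int8)
    pos = 0
    for k, grp in itertools.groupby(key):
        L = len(list(grp))
        if k == "invalid":
            state[pos:pos + L] = MinuteState.INVALID
        elif k == "zero" and L >= min_run:
            state[pos:pos + L] = MinuteState.NONWEAR
        else:
            state[pos:pos + L] = MinuteState.WORN
        pos += L
    return state


def oracle_prolonged(counts, state, min_bout=10):
    """Brute-force maximal sedentary-run enumeration."""
    sed = [
        state[i] == MinuteState.WORN and counts[i] < 100 for i in range(len(counts))
    ]
    total = 0
    bouts = 0
    for k, grp in itertools.groupby(sed):
        L = len(list(grp))
        if k and L >= min_bout:
            total += L
            bouts += 1
    return total, bouts


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_day_counts(rng, n=WINDOW):
    """A structured random day: zero runs of many lengths, spikes, activity."""
    counts = np.empty(n)
    i = 0
    while i < n:
        kind = rng.random()
        L = int(rng.integers(1, 140))
        L = min(L, n - i)
        if kind < 0.35:
            counts[i:i + L] = 0
        elif kind < 0.9:
            counts[i:i + L] = rng.integers(0, 4000, L)
        else:
            counts[i:i + L] = rng.integers(25000, 40000, L)
        i += L
    return counts
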