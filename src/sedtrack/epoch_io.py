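"""Reading and writing epoch-level accelerometer count data.

The on-disk dialect is a plain CSV with columns ``participant_id, study_id,
country_id, wave, timestamp, counts``: one row per epoch, timestamps in
ISO-8601 local clock time (no timezone) marking the epoch *start*, counts as
non-negative integers with missing counts encoded as an empty field.
Participant metadata travels in a second CSV with columns ``participant_id,
study_id, country_id, gender, wave, age_years``.

Structure is validated before any computation: timestamps must be strictly
increasing and, within a calendar day, spaced exactly one epoch length apart
(gaps must be explicit missing rows), so that downstream run-length logic is
unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

EPOCH_COLUMNS = ["participant_id", "study_id", "country_id", "wave", "timestamp", "counts"]
META_COLUMNS = ["participant_id", "study_id", "country_id", "gender", "wave", "age_years"]
VALID_EPOCH_LENGTHS = (1, 5, 10, 15, 30, 60)
GENDERS = ("boy", "girl")
TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"


class EpochCsvError(ValueError):
    """Structural problem with an epoch or metadata CSV (missing columns, unreadable)."""


class EpochValidationError(ValueError):
    """Row- or series-level contract violation; message carries line numbers / group ids."""


@dataclass(frozen=True)
class CsvDialect:
    """Dialect knobs for the epoch CSV; defaults match the formats this package writes."""

    delimiter: str = ","
    missing: str = ""
    timestamp_format: str = TIMESTAMP_FORMAT


DEFAULT_DIALECT = CsvDialect()


@dataclass
class EpochSeries:
    """One participant-wave stream of accelerometer counts at a fixed epoch length.

    ``counts`` is a float array with NaN as the missing marker; ``invalid``
    flags epochs struck out by downstream rules (e.g. intensity spikes) and is
    all-False on freshly read data.
    """

    participant_id: str
    study_id: str
    country_id: str
    wave: int
    epoch_length: int
    timestamps: pd.DatetimeIndex
    counts: np.ndarray
    invalid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.invalid is None:
            self.invalid = np.zeros(len(self.counts), dtype=bool)
        self.invalid = np.asarray(self.invalid, dtype=bool)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def key(self) -> tuple[str, int]:
        return (self.participant_id, self.wave)

    def copy(self) -> "EpochSeries":
        return replace(
            self,
            timestamps=self.timestamps.copy(),
            counts=self.counts.copy(),
            invalid=self.invalid.copy(),
        )

    def validate(self) -> None:
        """Raise :class:`EpochValidationError` on any invariant violation."""
        name = f"participant {self.participant_id!r} wave {self.wave}"
        if self.wave < 1:
            raise EpochValidationError(f"{name}: wave must be >= 1")
        if self.epoch_length not in VALID_EPOCH_LENGTHS:
            raise EpochValidationError(
                f"{name}: epoch_length {self.epoch_length} not in {VALID_EPOCH_LENGTHS}"
            )
        if not (len(self.timestamps) == len(self.counts) == len(self.invalid)):
            raise EpochValidationError(f"{name}: field lengths differ")
        if len(self) == 0:
            return
        with np.errstate(invalid="ignore"):
            if np.any(self.counts[~np.isnan(self.counts)] < 0):
                raise EpochValidationError(f"{name}: negative counts")
        diffs = np.diff(self.timestamps.asi8) / 1e9
        if np.any(diffs <= 0):
            raise EpochValidationError(f"{name}: timestamps not strictly increasing")
        same_day = self.timestamps.normalize()[1:] == self.timestamps.normalize()[:-1]
        if np.any(diffs[same_day] != self.epoch_length):
            raise EpochValidationError(
                f"{name}: epochs within a day must be spaced exactly "
                f"{self.epoch_length} s (gaps must be explicit missing rows)"
            )


def _infer_epoch_length(timestamps: pd.DatetimeIndex, name: str) -> int:
    if len(timestamps) < 2:
        return 60
    diffs = np.diff(timestamps.asi8) / 1e9
    same_day = timestamps.normalize()[1:] == timestamps.normalize()[:-1]
    within = diffs[same_day]
    if len(within) == 0:
        return 60
    step = int(within.min())
    if step not in VALID_EPOCH_LENGTHS:
        raise EpochValidationError(
            f"{name}: inferred epoch length {step} s not in {VALID_EPOCH_LENGTHS}"
        )
    return step


def read_epoch_csv(
    path,
    dialect: CsvDialect = DEFAULT_DIALECT,
    errors: str = "raise",
) -> list[EpochSeries] | tuple[list[EpochSeries], list[tuple[int, str]]]:
    """Read an epoch CSV into one :class:`EpochSeries` per (participant, wave).

    Parameters
    ----------
    path
        CSV file with the columns in :data:`EPOCH_COLUMNS`.
    dialect
        Delimiter / missing-marker / timestamp-format configuration.
    errors
        ``"raise"`` (default) aborts on the first malformed row, naming its
        line number; ``"collect"`` instead returns
        ``(series_list, rejected)`` where ``rejected`` is a list of
        ``(line_number, reason)`` pairs and every accepted row appears in
        exactly one series.
    """
    if errors not in ("raise", "collect"):
        raise ValueError("errors must be 'raise' or 'collect'")
    try:
        raw = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed beyond repair
        raise EpochCsvError(f"cannot parse {path}: {exc}") from exc
    missing_cols = [c for c in EPOCH_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise EpochCsvError(f"{path}: missing required columns {missing_cols}")

    rejected: list[tuple[int, str]] = []

    def _bad(line: int, reason: str) -> None:
        if errors == "raise":
            raise EpochValidationError(f"{path} line {line}: {reason}")
        rejected.append((line, reason))

    # line numbers: header is line 1, first data row line 2
    lines = raw.index.to_numpy() + 2
    ts = pd.to_datetime(raw["timestamp"], format=dialect.timestamp_format, errors="coerce")
    counts = pd.to_numeric(
        raw["counts"].mask(raw["counts"] == dialect.missing), errors="coerce"
    )
    wave = pd.to_numeric(raw["wave"], errors="coerce")

    bad_ts = ts.isna().to_numpy()
    bad_counts = (
        (raw["counts"] != dialect.missing).to_numpy() & counts.isna().to_numpy()
    ) | (counts.fillna(0) < 0).to_numpy()
    bad_wave = (
        wave.isna() | (wave < 1) | (wave != wave.fillna(-1).astype(int))
    ).to_numpy()
    ok = ~(bad_ts | bad_counts | bad_wave)
    for i in np.flatnonzero(~ok):
        if bad_ts[i]:
            _bad(lines[i], f"unparseable timestamp {raw['timestamp'].iloc[i]!r}")
        elif bad_counts[i]:
            _bad(lines[i], f"bad counts {raw['counts'].iloc[i]!r}")
        else:
            _bad(lines[i], f"invalid wave {raw['wave'].iloc[i]!r}")

    df = raw.loc[ok].copy()
    df["_ts"] = ts[ok]
    df["_counts"] = counts[ok]
    df["_wave"] = wave[ok].astype(int)

    series_list: list[EpochSeries] = []
    for (pid, w), grp in df.groupby(["participant_id", "_wave"], sort=True):
        grp = grp  # rows already in file order
        name = f"participant {pid!r} wave {w}"
        study = grp["study_id"].iloc[0]
        country = grp["country_id"].iloc[0]
        if grp["study_id"].nunique() > 1 or grp["country_id"].nunique() > 1:
            raise EpochValidationError(f"{name}: inconsistent study/country ids")
        tsi = pd.DatetimeIndex(grp["_ts"])
        if len(tsi) > 1 and np.any(np.diff(tsi.asi8) <= 0):
            raise EpochValidationError(f"{name}: timestamps not strictly increasing")
        s = EpochSeries(
            participant_id=str(pid),
            study_id=str(study),
            country_id=str(country),
            wave=int(w),
            epoch_length=_infer_epoch_length(tsi, name),
            timestamps=tsi,
            counts=grp["_counts"].to_numpy(dtype=float),
        )
        s.validate()
        series_list.append(s)
    if errors == "collect":
        return series_list, rejected
    return series_list


def write_epoch_csv(
    series_list: Sequence[EpochSeries], path, dialect: CsvDialect = DEFAULT_DIALECT
) -> None:
    """Write series to the epoch CSV dialect; inverse of :func:`read_epoch_csv`."""
    frames = []
    for s in series_list:
        s.validate()
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "study_id": s.study_id,
                    "country_id": s.country_id,
                    "wave": s.wave,
                    "timestamp": s.timestamps.strftime(dialect.timestamp_format),
                    "counts": [
                        dialect.missing if np.isnan(c) else str(int(c)) for c in s.counts
                    ],
                }
            )
        )
    if frames:
        out = pd.concat(frames, ignore_index=True)
        out = out.sort_values(
            ["participant_id", "wave", "timestamp"], kind="stable"
        )
    else:
        out = pd.DataFrame(columns=EPOCH_COLUMNS)
    out.to_csv(path, sep=dialect.delimiter, index=False)


def read_meta_csv(path, dialect: CsvDialect = DEFAULT_DIALECT) -> pd.DataFrame:
    """Read and validate the participant-metadata CSV.

    Returns a DataFrame with one row per (participant, wave); gender must be
    constant within participant and ``age_years`` strictly increasing with wave.
    """
    df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    missing_cols = [c for c in META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise EpochCsvError(f"{path}: missing required columns {missing_cols}")
    if len(df) == 0:
        df["wave"] = df["wave"].astype(int)
        df["age_years"] = df["age_years"].astype(float)
        return df
    df["wave"] = pd.to_numeric(df["wave"], errors="raise").astype(int)
    df["age_years"] = pd.to_numeric(df["age_years"], errors="raise").astype(float)
    bad_gender = ~df["gender"].isin(GENDERS)
    if bad_gender.any():
        raise EpochValidationError(
            f"{path}: gender must be one of {GENDERS}; offending rows "
            f"{(df.index[bad_gender] + 2).tolist()}"
        )
    for pid, grp in df.groupby("participant_id"):
        if grp["gender"].nunique() > 1:
            raise EpochValidationError(f"participant {pid!r}: gender varies across waves")
        g = grp.sort_values("wave")
        if not g["age_years"].is_monotonic_increasing or g["age_years"].duplicated().any():
            raise EpochValidationError(
                f"participant {pid!r}: age_years must increase with wave"
            )
    return df


def write_meta_csv(meta: pd.DataFrame, path, dialect: CsvDialect = DEFAULT_DIALECT) -> None:
    meta.loc[:, META_COLUMNS].to_csv(path, sep=dialect.delimiter, index=False)
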