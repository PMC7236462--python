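"""Synthetic longitudinal accelerometer cohorts with known ground truth.

The generator emulates a pooled multi-country, multi-study children's cohort
measured with uniaxial 60-s count accelerometers over 2-4 waves:

* a **latent layer** draws, per child, per-wave sedentary propensities
  (min/day) from a multivariate normal with an exchangeable cross-wave
  correlation equal to ``true_tracking``, plus random country and study
  offsets and a fixed annual drift;
* a **day layer** scatters each wave's propensity into 7 per-day targets
  (Monday-Sunday) whose mean equals the propensity exactly (day-level noise
  is centred within the wave), so the correlation of measured wave means is
  the configured truth;
* an **epoch layer** realizes each day as 1440 one-minute epochs: alternating
  sedentary bouts (truncated-geometric lengths, counts uniform on [0, 99])
  and active periods (light counts with occasional MVPA bursts), injected
  non-wear blocks of >= 60 zero minutes, optional >30,000 cpm spikes, and
  zeros between midnight and 07:00.

Every realized quantity is recorded in a :class:`TruthLedger`, reproducible
from config + seed, so pipeline outputs can be checked against known truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import date as Date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .epoch_io import EpochSeries, META_COLUMNS

WINDOW_MINUTES = 1020
WINDOW_START_MINUTE = 7 * 60


class SimConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults emulate a pooled youth cohort at desk scale.

    Means, SDs and drifts are in min/day (drifts per year); the default annual
    drifts, baseline levels, between/within-child spreads, follow-up interval
    and wear-time structure mirror typical pooled children's accelerometry.
    """

    n_countries: int = 4
    studies_per_country: int = 2
    children_per_study: int = 125
    waves: int = 2
    followup_years: float = 2.7
    followup_jitter_sd: float = 0.3
    true_tracking: float = 0.48
    true_tracking_by_gender: dict | None = None
    annual_drift_total: float = 21.4
    annual_drift_prolonged: float = 20.9
    mean_total_sed_baseline: float = 340.0
    mean_prolonged_sed_baseline: float = 150.0
    between_child_sd: float = 70.0
    between_child_sd_prolonged: float = 55.0
    within_child_sd: float = 60.0
    within_child_sd_prolonged: float = 50.0
    country_sd: float = 10.0
    study_sd: float = 15.0
    bout_family: str = "truncated_geometric"  # or "fixed"
    mean_bout_length: float = 7.0
    nonwear_blocks_per_day: float = 2.5
    nonwear_block_mean_extra: float = 35.0
    spike_rate: float = 0.0
    mvpa_burst_prob: float = 0.07
    days_per_wave: int = 7
    start_date: str = "2005-01-03"  # a Monday
    age_baseline_low: float = 5.0
    age_baseline_high: float = 11.5
    prop_boys: float = 0.49
    seed: int = 0

    @property
    def n_children(self) -> int:
        return self.n_countries * self.studies_per_country * self.children_per_study

    def validate(self) -> None:
        if not (0.0 <= self.true_tracking <= 1.0):
            raise SimConfigError("true_tracking must be in [0, 1]")
        if self.true_tracking_by_gender is not None:
            for v in self.true_tracking_by_gender.values():
                if not (0.0 <= v <= 1.0):
                    raise SimConfigError("per-gender tracking must be in [0, 1]")
        for name in (
            "between_child_sd", "between_child_sd_prolonged", "within_child_sd",
            "within_child_sd_prolonged", "country_sd", "study_sd",
            "followup_jitter_sd",
        ):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if self.waves < 2:
            raise SimConfigError("waves must be >= 2")
        if self.bout_family not in ("truncated_geometric", "fixed"):
            raise SimConfigError(f"unknown bout_family {self.bout_family!r}")
        horizon = self.followup_years * (self.waves - 1)
        if self.mean_total_sed_baseline + self.annual_drift_total * horizon > WINDOW_MINUTES:
            raise SimConfigError(
                "mean sedentary target exceeds the 1020-min wear window"
            )
        if self.mean_total_sed_baseline < 0:
            raise SimConfigError("mean_total_sed_baseline must be >= 0")


@dataclass
class TruthLedger:
    """Ground truth of one simulated cohort, reproducible from config + seed."""

    seed: int
    config: dict
    children: pd.DataFrame
    waves: pd.DataFrame
    days: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "config": self.config,
            "children": self.children.to_dict(orient="list"),
            "waves": self.waves.to_dict(orient="list"),
            "days": self.days.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        payload = json.loads(Path(path).read_text())
        return cls(
            seed=payload["seed"],
            config=payload["config"],
            children=pd.DataFrame(payload["children"]),
            waves=pd.DataFrame(payload["waves"]),
            days=pd.DataFrame(payload["days"]),
        )


def _exchangeable_cholesky(rho: float, w: int) -> np.ndarray:
    if rho >= 1.0 - 1e-12:  # perfect tracking: one shared draw across waves
        out = np.zeros((w, w))
        out[:, 0] = 1.0
        return out
    corr = np.full((w, w), rho)
    np.fill_diagonal(corr, 1.0)
    return np.linalg.cholesky(corr)


def _simulate_latent(config: SimConfig, rng: np.random.Generator):
    """Children table, per-wave latent propensities and centred day targets."""
    config.validate()
    n = config.n_children
    w = config.waves
    d = config.days_per_wave

    country_ids = [f"country{c + 1}" for c in range(config.n_countries)]
    records = []
    k = 0
    for ci, country in enumerate(country_ids):
        for si in range(config.studies_per_country):
            study = f"study{ci + 1}_{si + 1}"
            for _ in range(config.children_per_study):
                records.append((f"child{k + 1:05d}", study, country))
                k += 1
    children = pd.DataFrame(records, columns=["participant_id", "study_id", "country_id"])
    children["gender"] = np.where(
        rng.random(n) < config.prop_boys, "boy", "girl"
    )
    children["age_baseline"] = rng.uniform(
        config.age_baseline_low, config.age_baseline_high, n
    )
    country_off = dict(
        zip(country_ids, rng.normal(0.0, config.country_sd, len(country_ids)))
    )
    study_ids = children["study_id"].unique()
    study_off = dict(zip(study_ids, rng.normal(0.0, config.study_sd, len(study_ids))))
    cluster = (
        children["country_id"].map(country_off).to_numpy()
        + children["study_id"].map(study_off).to_numpy()
    )

    # follow-up times (years since baseline), jittered but strictly increasing
    times = np.zeros((n, w))
    for j in range(1, w):
        jitter = rng.normal(0.0, config.followup_jitter_sd, n)
        gap = np.clip(config.followup_years + jitter, 0.5, None)
        times[:, j] = times[:, j - 1] + gap

    def correlated(sd: float) -> np.ndarray:
        z = rng.standard_normal((n, w))
        out = np.empty((n, w))
        if config.true_tracking_by_gender is None:
            chol = _exchangeable_cholesky(config.true_tracking, w)
            out[:] = z @ chol.T
        else:
            for g, rho in config.true_tracking_by_gender.items():
                mask = (children["gender"] == g).to_numpy()
                out[mask] = z[mask] @ _exchangeable_cholesky(rho, w).T
        return sd * out

    prop_total = (
        config.mean_total_sed_baseline
        + cluster[:, None]
        + config.annual_drift_total * times
        + correlated(config.between_child_sd)
    )
    prop_prol = (
        config.mean_prolonged_sed_baseline
        + 0.6 * cluster[:, None]
        + config.annual_drift_prolonged * times
        + correlated(config.between_child_sd_prolonged)
    )
    prop_total = np.clip(prop_total, 0.0, WINDOW_MINUTES)
    prop_prol = np.clip(prop_prol, 0.0, prop_total)

    def centred_days(prop: np.ndarray, sd: float) -> np.ndarray:
        dev = rng.normal(0.0, sd, (n, w, d))
        dev -= dev.mean(axis=2, keepdims=True)
        return prop[:, :, None] + dev

    day_total = np.clip(centred_days(prop_total, config.within_child_sd), 0.0, WINDOW_MINUTES)
    day_prol = np.clip(
        centred_days(prop_prol, config.within_child_sd_prolonged), 0.0, day_total
    )
    return children, times, prop_total, prop_prol, day_total, day_prol


def _ledger_frames(config, children, times, prop_total, prop_prol, day_total, day_prol):
    n, w, d = day_total.shape
    waves = pd.DataFrame(
        {
            "participant_id": np.repeat(children["participant_id"].to_numpy(), w),
            "wave": np.tile(np.arange(1, w + 1), n),
            "time_since_baseline": times.ravel(),
            "age": (children["age_baseline"].to_numpy()[:, None] + times).ravel(),
            "propensity_total": prop_total.ravel(),
            "propensity_prolonged": prop_prol.ravel(),
        }
    )
    days = pd.DataFrame(
        {
            "participant_id": np.repeat(children["participant_id"].to_numpy(), w * d),
            "wave": np.tile(np.repeat(np.arange(1, w + 1), d), n),
            "day_index": np.tile(np.arange(d), n * w),
            "target_total": day_total.ravel(),
            "target_prolonged": day_prol.ravel(),
        }
    )
    return waves, days


def simulate_wave_summaries(
    config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, TruthLedger]:
    """Fast path: wave summaries straight from the latent and day layers.

    Produces the wave-summary table the metrics module would emit, without
    realizing epochs: per-wave means equal the latent propensities and the
    day-to-day variation statistics are computed from the per-day targets.
    Wear time and MVPA are drawn from their marginal distributions.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    children, times, prop_total, prop_prol, day_total, day_prol = _simulate_latent(
        config, rng
    )
    n, w, d = day_total.shape
    expected_nonwear = config.nonwear_blocks_per_day * (
        60.0 + config.nonwear_block_mean_extra
    )
    wear = np.clip(
        rng.normal(WINDOW_MINUTES - expected_nonwear, 20.0, (n, w)),
        480.0,
        WINDOW_MINUTES,
    )
    mvpa = rng.lognormal(np.log(25.0), 0.4, (n, w))
    mad = lambda a: np.mean(np.abs(a - a.mean(axis=2, keepdims=True)), axis=2)
    summary = pd.DataFrame(
        {
            "participant_id": np.repeat(children["participant_id"].to_numpy(), w),
            "study_id": np.repeat(children["study_id"].to_numpy(), w),
            "country_id": np.repeat(children["country_id"].to_numpy(), w),
            "wave": np.tile(np.arange(1, w + 1), n),
            "age": (children["age_baseline"].to_numpy()[:, None] + times).ravel(),
            "gender": np.repeat(children["gender"].to_numpy(), w),
            "n_valid_days": d,
            "mean_total_sed": day_total.mean(axis=2).ravel(),
            "mean_prolonged_sed": day_prol.mean(axis=2).ravel(),
            "dtd_total": mad(day_total).ravel(),
            "dtd_prolonged": mad(day_prol).ravel(),
            "mean_wear": wear.ravel(),
            "mean_mvpa": mvpa.ravel(),
        }
    )
    waves, days = _ledger_frames(
        config, children, times, prop_total, prop_prol, day_total, day_prol
    )
    ledger = TruthLedger(
        seed=int(config.seed if seed is None else seed),
        config=dataclasses.asdict(config),
        children=children,
        waves=waves,
        days=days,
    )
    return summary, ledger


# ---------------------------------------------------------------------------
# epoch layer


def _draw_geometric(rng, mean: float, low: int, high: int) -> int:
    """Truncated geometric bout length on [low, high] with pre-truncation mean."""
    p = min(1.0, 1.0 / max(mean, 1.0))
    for _ in range(100):
        k = int(rng.geometric(p))
        if low <= k <= high:
            return k
    return low


def _sed_run_lengths(total: int, prolonged: int, config: SimConfig, rng) -> list[int]:
    """Bout lengths summing to ``total`` with >=10-min bouts summing to ~``prolonged``."""
    if total <= 0:
        return []
    if config.bout_family == "fixed":
        length = max(1, int(round(config.mean_bout_length)))
        n = max(1, int(round(total / length)))
        return [length] * n
    prolonged = min(prolonged, total)
    if 0 < prolonged < 10:  # a prolonged bout needs >= 10 min; round to nearest feasible
        prolonged = 10 if (prolonged >= 5 and total >= 10) else 0
    short_budget = total - prolonged
    runs: list[int] = []
    remaining = prolonged
    while remaining >= 10:
        k = min(10 + _draw_geometric(rng, config.mean_bout_length, 1, 120) - 1, remaining)
        if remaining - k < 10:
            k = remaining  # absorb the tail so the last long bout stays >= 10
        runs.append(int(k))
        remaining -= k
    remaining = short_budget
    while remaining > 0:
        k = min(_draw_geometric(rng, min(config.mean_bout_length, 5.0), 1, 9), remaining)
        runs.append(int(k))
        remaining -= k
    return [int(x) for x in rng.permutation(runs)] if runs else runs


def _place_nonwear_blocks(config: SimConfig, rng) -> list[tuple[int, int]]:
    """Non-overlapping, non-adjacent [start, stop) blocks inside the window."""
    n_blocks = rng.poisson(config.nonwear_blocks_per_day)
    blocks: list[tuple[int, int]] = []
    for _ in range(n_blocks):
        length = 60 + int(rng.exponential(config.nonwear_block_mean_extra))
        length = min(length, WINDOW_MINUTES - 2)
        for _attempt in range(30):
            start = int(rng.integers(0, WINDOW_MINUTES - length + 1))
            stop = start + length
            # keep >= 1 worn minute between blocks so runs stay distinct
            if all(stop < b0 - 1 or start > b1 for b0, b1 in blocks):
                blocks.append((start, stop))
                break
    return sorted(blocks)


def generate_epoch_day(
    day_target_total: float,
    day_target_prolonged: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Realize one day as 1440 one-minute counts (midnight-midnight).

    Minutes before 07:00 are zero; within the 07:00-24:00 window, injected
    non-wear blocks are all-zero, sedentary minutes draw uniform [0, 99],
    active minutes draw light counts in [100, 3000) with MVPA bursts >= 3000
    at ``mvpa_burst_prob``, and spikes > 30,000 cpm are injected at
    ``spike_rate`` per day. Returns the counts and a per-day truth dict with
    injected non-wear minutes and realized metrics (computed by the
    generator's own scan of the finished counts).
    """
    if day_target_total > WINDOW_MINUTES:
        raise SimConfigError("day target exceeds the wear window")
    window = np.zeros(WINDOW_MINUTES, dtype=np.int64)
    blocks = _place_nonwear_blocks(config, rng)
    nonwear_mask = np.zeros(WINDOW_MINUTES, dtype=bool)
    for b0, b1 in blocks:
        nonwear_mask[b0:b1] = True
    worn_slots = np.flatnonzero(~nonwear_mask)
    n_worn = len(worn_slots)

    total = int(np.clip(round(day_target_total), 0, n_worn))
    prolonged = int(np.clip(round(day_target_prolonged), 0, total))

    # allocate targets across contiguous worn segments (largest remainder),
    # so sedentary bouts never straddle an injected non-wear block
    segments: list[np.ndarray] = []
    if n_worn:
        breaks = np.flatnonzero(np.diff(worn_slots) > 1) + 1
        segments = np.split(worn_slots, breaks)
    seg_lens = np.array([len(s) for s in segments], dtype=np.int64)

    def _apportion(amount: int, caps: np.ndarray) -> np.ndarray:
        if amount <= 0 or seg_lens.sum() == 0:
            return np.zeros(len(seg_lens), dtype=np.int64)
        quota = amount * seg_lens / seg_lens.sum()
        alloc = np.minimum(np.floor(quota).astype(np.int64), caps)
        order = np.argsort(-(quota - alloc))
        for idx in np.tile(order, 3):
            if alloc.sum() >= amount:
                break
            if alloc[idx] < caps[idx]:
                alloc[idx] += 1
        return alloc

    total_alloc = _apportion(total, seg_lens)
    prol_alloc = _apportion(prolonged, total_alloc)

    seq = np.zeros(n_worn, dtype=bool)  # True = sedentary, in worn-slot order
    offset = 0
    for L, t_seg, p_seg in zip(seg_lens, total_alloc, prol_alloc):
        sed_runs = _sed_run_lengths(int(t_seg), int(p_seg), config, rng)
        active_total = int(L) - sum(sed_runs)
        k = len(sed_runs)
        gaps = np.zeros(k + 1, dtype=np.int64)
        if k > 1:
            take = min(active_total, k - 1)
            gaps[1:1 + take] = 1
            active_total -= take
        if active_total > 0:
            gaps += rng.multinomial(active_total, np.full(k + 1, 1.0 / (k + 1)))
        pos = offset
        for i, run in enumerate(sed_runs):
            pos += int(gaps[i])
            seq[pos:pos + run] = True
            pos += run
        offset += int(L)

    counts = np.zeros(n_worn, dtype=np.int64)
    sed_idx = np.flatnonzero(seq)
    act_idx = np.flatnonzero(~seq)
    counts[sed_idx] = rng.integers(0, 100, len(sed_idx))
    burst = rng.random(len(act_idx)) < config.mvpa_burst_prob
    light = np.clip(rng.lognormal(np.log(500.0), 0.8, len(act_idx)), 100, 2999)
    vig = np.clip(rng.lognormal(np.log(4000.0), 0.3, len(act_idx)), 3000, 20000)
    counts[act_idx] = np.where(burst, vig, light).astype(np.int64)
    window[worn_slots] = counts

    # spikes (> 30,000 cpm -> invalid downstream)
    n_spikes = rng.poisson(config.spike_rate)
    if n_spikes > 0 and n_worn > 0:
        hit = rng.choice(worn_slots, size=min(n_spikes, n_worn), replace=False)
        window[hit] = 30001 + rng.integers(0, 30000, len(hit))

    # guarantee injected non-wear == detected non-wear: no worn zero minute may
    # extend an injected block, and no incidental worn zero-run may reach 60
    spike_mask = window > 30000
    for b0, b1 in blocks:
        for edge in (b0 - 1, b1):
            if 0 <= edge < WINDOW_MINUTES and not nonwear_mask[edge] and window[edge] == 0:
                window[edge] = int(rng.integers(1, 100))
    zero = (window == 0) & ~nonwear_mask & ~spike_mask
    run_start = None
    for i in range(WINDOW_MINUTES + 1):
        z = zero[i] if i < WINDOW_MINUTES else False
        if z and run_start is None:
            run_start = i
        elif not z and run_start is not None:
            if i - run_start >= 60:
                mid = (run_start + i) // 2
                window[mid] = int(rng.integers(1, 100))
            run_start = None

    truth = _scan_day(window, blocks)
    truth["target_total"] = float(day_target_total)
    truth["target_prolonged"] = float(day_target_prolonged)

    day = np.zeros(1440, dtype=np.int64)
    day[WINDOW_START_MINUTE:] = window
    return day, truth


def _scan_day(window: np.ndarray, blocks) -> dict:
    """Generator's own bookkeeping scan of a finished window (independent of
    the preprocessing/metrics modules): applies the zero-run, spike, cut-point
    and bout rules directly."""
    spike = window > 30000
    zero = (window == 0) & ~spike
    n = len(window)
    nonwear = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if zero[i]:
            j = i
            while j < n and zero[j]:
                j += 1
            if j - i >= 60:
                nonwear[i:j] = True
            i = j
        else:
            i += 1
    worn = ~nonwear & ~spike
    sed = worn & (window < 100)
    realized_prolonged = 0
    run = 0
    for i in range(n + 1):
        if i < n and sed[i]:
            run += 1
        else:
            if run >= 10:
                realized_prolonged += run
            run = 0
    return {
        "injected_nonwear": int(sum(b1 - b0 for b0, b1 in blocks)),
        "detected_nonwear": int(nonwear.sum()),
        "realized_wear": int(worn.sum()),
        "realized_total": int(sed.sum()),
        "realized_prolonged": int(realized_prolonged),
        "realized_mvpa": int((worn & (window >= 3000)).sum()),
        "n_spikes": int(spike.sum()),
    }


def _wave_start_date(config: SimConfig, years_since_baseline: float) -> Date:
    start = datetime.strptime(config.start_date, "%Y-%m-%d").date()
    day = start + timedelta(days=int(round(years_since_baseline * 365.25)))
    return day - timedelta(days=day.weekday())  # snap to Monday


def generate_cohort(
    config: SimConfig, seed: int | None = None
) -> tuple[list[EpochSeries], pd.DataFrame, TruthLedger]:
    """Generate a full epoch-level cohort: one series per child-wave.

    Each wave records ``days_per_wave`` consecutive days starting on a
    Monday (so the inclusion rule's weekend requirement is exercised), as
    1440 one-minute epochs per day. Deterministic given config + seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    children, times, prop_total, prop_prol, day_total, day_prol = _simulate_latent(
        config, rng
    )
    n, w, d = day_total.shape
    series: list[EpochSeries] = []
    meta_rows = []
    day_truths = []
    for i in range(n):
        child = children.iloc[i]
        for j in range(w):
            start = _wave_start_date(config, times[i, j])
            counts_all = np.empty(1440 * d, dtype=np.int64)
            for day_idx in range(d):
                day_counts, truth = generate_epoch_day(
                    day_total[i, j, day_idx], day_prol[i, j, day_idx], config, rng
                )
                counts_all[day_idx * 1440:(day_idx + 1) * 1440] = day_counts
                truth.update(
                    participant_id=child["participant_id"],
                    wave=j + 1,
                    day_index=day_idx,
                    date=str(start + timedelta(days=day_idx)),
                )
                day_truths.append(truth)
            timestamps = pd.date_range(
                datetime.combine(start, datetime.min.time()),
                periods=1440 * d,
                freq="60s",
            )
            series.append(
                EpochSeries(
                    participant_id=child["participant_id"],
                    study_id=child["study_id"],
                    country_id=child["country_id"],
                    wave=j + 1,
                    epoch_length=60,
                    timestamps=timestamps,
                    counts=counts_all.astype(float),
                )
            )
            meta_rows.append(
                {
                    "participant_id": child["participant_id"],
                    "study_id": child["study_id"],
                    "country_id": child["country_id"],
                    "gender": child["gender"],
                    "wave": j + 1,
                    "age_years": round(child["age_baseline"] + times[i, j], 3),
                }
            )
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    waves, days = _ledger_frames(
        config, children, times, prop_total, prop_prol, day_total, day_prol
    )
    if day_truths:
        realized = pd.DataFrame(day_truths)
        days = days.merge(
            realized.drop(columns=["target_total", "target_prolonged"]),
            on=["participant_id", "wave", "day_index"],
            how="left",
        )
    ledger = TruthLedger(
        seed=int(config.seed if seed is None else seed),
        config=dataclasses.asdict(config),
        children=children,
        waves=waves,
        days=days,
    )
    return series, meta, ledger


def generate_cohort_files(config: SimConfig, out_dir, seed: int | None = None) -> dict:
    """Generate a cohort and write epoch.csv, meta.csv and truth.json."""
    from .epoch_io import write_epoch_csv, write_meta_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series, meta, ledger = generate_cohort(config, seed)
    write_epoch_csv(series, out / "epoch.csv")
    write_meta_csv(meta, out / "meta.csv")
    ledger.to_json(out / "truth.json")
    return {
        "epoch_csv": str(out / "epoch.csv"),
        "meta_csv": str(out / "meta.csv"),
        "truth_json": str(out / "truth.json"),
        "n_children": config.n_children,
    }
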