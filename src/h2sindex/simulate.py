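"""Synthetic exposure cohorts and the three observation regimes.

Real personal-detector data from water/wastewater work cannot be shipped
with the package, so this module generates a latent ground-truth cohort
with the field's salient features — sporadic exposure (most workdays have
none), short excursions of 1–15 consecutive 15-s readings, log-normal
excursion peaks whose daily-maximum mode among detected days falls between
5 and 8 ppm, instrument overload above 100 ppm, confirmed real-zero days
and missing days — and then renders what each sampling strategy would
actually observe:

* **A** — expert campaign: a small targeted subset of person-days, with a
  configurable bias toward days the workers expected exposure; LOD 0.1 ppm.
* **B** — self-assessed routine collection: instruments dock about weekly
  and after alarms; the 16-h wraparound memory holds only the last two 8-h
  shifts, so un-docked days lose their readings; LOD 1.6 ppm.
* **C** — daily campaign: every worn day in three two-week campaign periods
  is observed, with logbook metadata attached; LOD 1.6 ppm.

Strategy operators only select, truncate, or censor latent days — they
never alter a concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Iterable, Sequence

import numpy as np

from .cohort import SEGS, StudyDataset, aggregate_person_day, season_of
from .errors import ConfigError
from .gaslog import DATASET_A_CONSTANTS, ExposureConstants, GasLog
from .logbook import REAL_ZERO_REASONS, LogbookDay, TaskRecord, DayClassification

__all__ = [
    "SimParams",
    "LatentDay",
    "StrategyDescriptor",
    "STRATEGY_A",
    "STRATEGY_B",
    "STRATEGY_C",
    "simulate_latent_cohort",
    "apply_strategy",
    "simulate_logbook",
    "write_gas_log_csv",
    "write_logbook_csv",
    "write_roster_csv",
]

# Study-group sizes of the monitored department: wastewater collection
# network (incl. cesspool emptying), treatment plants, pumping stations,
# water distribution network.
DEFAULT_SEG_SIZES = {
    "wastewater_network": 24,
    "treatment_plant": 15,
    "pumping_station": 6,
    "water_network": 15,
}

# Probability that a (non-real-zero) workday carries any H₂S excursion.
DEFAULT_P_EXPOSED = {
    "wastewater_network": 0.65,
    "treatment_plant": 0.60,
    "pumping_station": 0.55,
    "water_network": 0.65,
}

# Manhole-entry rates per worked day; water-network work enters manholes an
# order of magnitude more often than the wastewater collection network.
DEFAULT_MANHOLE_RATE = {
    "wastewater_network": 0.0042,
    "treatment_plant": 0.0,
    "pumping_station": 0.0,
    "water_network": 0.0756,
}

SEG_TASKS = {
    "wastewater_network": ("wastewater_task", "driving", "flushing"),
    "treatment_plant": ("plant_operation", "driving"),
    "pumping_station": ("pumping_station_check", "driving"),
    "water_network": ("driving", "unexposed_water_task", "water_network_task"),
}


@dataclass
class SimParams:
    """Generator settings; defaults are the study conditions being emulated.

    peak_mu/peak_sigma are the log-scale location and spread of excursion
    peak heights (ppm); with the defaults the mode of the daily maximum
    among detected days lands in the 5–8 ppm range and the probability of
    exceeding the 100 ppm instrument ceiling is small but nonzero.
    excursion_length_p is the success probability of a geometric length
    distribution truncated to 1–15 readings (most excursions are a single
    15-s reading; the longest span 4 min).
    """

    n_persons: dict = field(default_factory=lambda: dict(DEFAULT_SEG_SIZES))
    study_start: str = "2019-02-04"  # a Monday
    study_weeks: int = 32
    study_months: float = 7.0
    p_exposed_day: dict = field(default_factory=lambda: dict(DEFAULT_P_EXPOSED))
    excursions_per_exposed_day: float = 1.5
    excursion_length_p: float = 0.65
    max_excursion_readings: int = 15
    peak_mu: float = 2.0
    peak_sigma: float = 0.55
    person_sd_log_peak: float = 0.4
    p_real_zero: float = 0.23
    p_missing: float = 0.11
    p_worn_real_zero: float = 0.10
    reporting_rate: float = 0.81
    manhole_rate: dict = field(default_factory=lambda: dict(DEFAULT_MANHOLE_RATE))
    lod_ppm: float = 1.6
    interval_s: float = 15.0
    shift_readings: int = 1920  # 8-h shift on a 15-s grid
    alarm_ppm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_real_zero", "p_missing", "p_worn_real_zero", "reporting_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.p_real_zero + self.p_missing > 1.0:
            raise ConfigError("p_real_zero + p_missing must not exceed 1")
        for seg, p in self.p_exposed_day.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"p_exposed_day[{seg!r}] must be in [0, 1]")


@dataclass
class LatentDay:
    """Ground truth for one person-day: the uncensored log plus labels."""

    person_id: str
    date: date
    seg: str
    true_log: GasLog
    tasks: LogbookDay | None = None
    is_real_zero: bool = False
    is_missing: bool = False
    is_exposed: bool = False
    worn: bool = True
    real_zero_reason: str = ""


@dataclass(frozen=True)
class StrategyDescriptor:
    """How an observation regime selects and truncates latent days."""

    label: str
    lod_ppm: float = 1.6
    # A: expert campaign
    n_campaign_measurements: int = 93
    targeting_bias: float = 0.5  # probability of drawing from the exposed pool
    # B: routine docking
    docking_weekday: int = 0  # Monday
    retention_shifts: int = 2  # 16-h wraparound / 8-h shift
    # C: campaign periods, as (start_week, n_weeks) offsets from study start
    campaign_weeks: tuple = ((0, 2), (17, 2), (30, 2))
    attach_logbooks: bool = False


STRATEGY_A = StrategyDescriptor(label="A", lod_ppm=0.1)
STRATEGY_B = StrategyDescriptor(label="B", lod_ppm=1.6)
STRATEGY_C = StrategyDescriptor(label="C", lod_ppm=1.6, attach_logbooks=True)


def _workdays(start: date, weeks: int) -> list[date]:
    days = []
    for w in range(weeks):
        for dow in range(5):
            days.append(start + timedelta(days=7 * w + dow))
    return days


def simulate_latent_cohort(params: SimParams) -> list[LatentDay]:
    """Generate the latent cohort: one LatentDay per person and workday.

    Reproducible from ``params.seed``.  Exposed days carry a zero-truncated
    Poisson count of excursions with geometric lengths and log-normal peaks
    scaled by a per-person log-normal effect; real-zero and missing labels
    are drawn independently per day.
    """
    rng = np.random.default_rng(params.seed)
    start = date.fromisoformat(params.study_start)
    dates = _workdays(start, params.study_weeks)
    out: list[LatentDay] = []
    prefixes = {"wastewater_network": "WW", "treatment_plant": "TP",
                "pumping_station": "PS", "water_network": "WN"}
    for seg in SEGS:
        n = params.n_persons.get(seg, 0)
        for k in range(n):
            pid = f"{prefixes.get(seg, 'XX')}{k+1:03d}"
            person_effect = rng.normal(0.0, params.person_sd_log_peak)
            for d in dates:
                out.append(
                    _simulate_day(pid, d, seg, person_effect, params, rng)
                )
    return out


def _simulate_day(pid, d, seg, person_effect, params: SimParams, rng) -> LatentDay:
    u = rng.random()
    is_real_zero = u < params.p_real_zero
    is_missing = (not is_real_zero) and u < params.p_real_zero + params.p_missing
    ppm = np.zeros(params.shift_readings)
    is_exposed = False
    if not is_real_zero and rng.random() < params.p_exposed_day.get(seg, 0.0):
        is_exposed = True
        n_exc = 1 + rng.poisson(max(params.excursions_per_exposed_day - 1.0, 0.0))
        used: list[tuple[int, int]] = []
        for _ in range(n_exc):
            length = _trunc_geometric(rng, params.excursion_length_p, params.max_excursion_readings)
            pos = _place(rng, params.shift_readings, length, used)
            if pos is None:
                continue
            peak = math.exp(rng.normal(params.peak_mu + person_effect, params.peak_sigma))
            vals = peak * rng.uniform(0.3, 1.0, size=length)
            vals[rng.integers(length)] = peak
            vals = np.clip(np.round(vals, 1), 0.1, 100.0)
            ppm[pos : pos + length] = vals
            used.append((pos, pos + length))
    worn = not is_missing and (not is_real_zero or rng.random() < params.p_worn_real_zero)
    log = GasLog.from_ppm(
        ppm,
        person_id=pid,
        device_id=f"dev-{pid}",
        start=np.datetime64(f"{d.isoformat()}T07:00:00"),
        sampling_interval_s=params.interval_s,
    )
    tasks = simulate_logbook(
        LatentDay(pid, d, seg, log, None, is_real_zero, is_missing, is_exposed, worn),
        params.reporting_rate,
        rng,
        manhole_rate=params.manhole_rate,
    )
    reason = ""
    if is_real_zero:
        reason = REAL_ZERO_REASONS[rng.integers(len(REAL_ZERO_REASONS))]
    return LatentDay(pid, d, seg, log, tasks, is_real_zero, is_missing, is_exposed, worn, reason)


def _trunc_geometric(rng, p: float, kmax: int) -> int:
    while True:
        k = int(rng.geometric(p))
        if k <= kmax:
            return k


def _place(rng, n: int, length: int, used: list) -> int | None:
    for _ in range(20):
        pos = int(rng.integers(0, n - length))
        if all(pos + length <= s or pos >= e for s, e in used):
            return pos
    return None


def simulate_logbook(
    day: LatentDay,
    reporting_rate: float,
    rng,
    *,
    manhole_rate: dict | None = None,
) -> LogbookDay | None:
    """Generate the worker's logbook record for a day, or None if unreported.

    A record is present with probability ``reporting_rate``; manhole-entry
    tasks are generated at SEG-specific daily rates (water-distribution
    work enters manholes far more often than the wastewater network).
    """
    if not 0.0 <= reporting_rate <= 1.0:
        raise ConfigError("reporting_rate must be in [0, 1]")
    if rng.random() >= reporting_rate:
        return None
    manhole_rate = manhole_rate or DEFAULT_MANHOLE_RATE
    cats = SEG_TASKS.get(day.seg, ("other",))
    n_tasks = 1 + int(rng.integers(0, 3))
    tasks = []
    start_min = 7 * 60
    for _ in range(n_tasks):
        cat = cats[rng.integers(len(cats))]
        dur = float(rng.integers(15, 180))
        from datetime import time as _time

        tasks.append(
            TaskRecord(
                category=cat,
                start=_time(start_min // 60 % 24, start_min % 60),
                duration_min=dur,
                raw_duration=str(int(dur)),
            )
        )
        start_min += int(dur) + 10
    n_manhole = int(rng.poisson(manhole_rate.get(day.seg, 0.0)))
    for _ in range(n_manhole):
        from datetime import time as _time

        tasks.append(
            TaskRecord(
                category="manhole_entry",
                start=_time(10, 0),
                duration_min=30.0,
                raw_duration="30",
                is_manhole_entry=True,
            )
        )
    return LogbookDay(
        person_id=day.person_id,
        date=day.date,
        workplace=day.seg,
        flushing="some" if any(t.category == "flushing" for t in tasks) else "none",
        manhole_entries=n_manhole,
        tasks=tasks,
        source="electronic_form",
    )


# ---------------------------------------------------------------------------
# Observation regimes


def apply_strategy(
    latent: Sequence[LatentDay],
    strategy: StrategyDescriptor,
    seed: int,
    mode: str = "cumulative",
) -> StudyDataset:
    """Render the StudyDataset one sampling strategy would have collected.

    All observed logs are the latent logs censored at the strategy's LOD
    (readings below the LOD report as 0.0); alarms above 10 ppm always
    leave at least a single stored datapoint.
    """
    rng = np.random.default_rng(seed)
    if strategy.label == "A":
        selected = _select_expert(latent, strategy, rng)
    elif strategy.label == "B":
        selected = _select_routine(latent, strategy)
    elif strategy.label == "C":
        selected = _select_campaign(latent, strategy)
    else:
        raise ConfigError(f"unknown strategy label {strategy.label!r}")

    constants = ExposureConstants(lod_ppm=strategy.lod_ppm)
    days = []
    persons = set()
    for ld, keep_readings in selected:
        persons.add(ld.person_id)
        obs = _observe(ld.true_log, strategy.lod_ppm, keep_readings)
        status = DayClassification("measured")
        if ld.is_real_zero:
            status = DayClassification("real_zero", ld.real_zero_reason or "confirmed real zero")
        meta = ld.tasks if strategy.attach_logbooks else None
        days.append(
            aggregate_person_day(
                [obs], meta=meta, constants=constants, mode=mode, status=status, seg=ld.seg
            )
        )
    dates = [ld.date for ld, _ in selected]
    months = _span_months(dates)
    return StudyDataset(
        label=strategy.label,
        days=days,
        n_persons=max(len(persons), 1),
        months=months,
        lod_ppm=strategy.lod_ppm,
        mode=mode,
    )


def _observe(log: GasLog, lod_ppm: float, keep_readings: bool) -> GasLog:
    """Censor at the LOD and optionally drop the readings (wraparound loss).

    An alarm above 10 ppm stores the excursion maximum as a single
    datapoint in a separate slot, surviving even when the log is lost.
    """
    censored = np.where(log.ppm >= lod_ppm - 0.05, log.ppm, 0.0)
    alarm_times = log.alarm_times
    alarm_ppm = log.alarm_ppm
    peak = float(censored.max()) if len(censored) else 0.0
    if peak >= 10.05 and len(alarm_ppm) == 0:
        i = int(np.argmax(censored))
        alarm_times = np.array([log.times[i]], dtype="datetime64[s]")
        alarm_ppm = np.array([peak])
    if keep_readings:
        return replace(
            log, ppm=censored, overload=censored >= 100.0,
            alarm_times=alarm_times, alarm_ppm=alarm_ppm,
        )
    return GasLog(
        person_id=log.person_id,
        device_id=log.device_id,
        sampling_interval_s=log.sampling_interval_s,
        alarm_times=alarm_times,
        alarm_ppm=alarm_ppm,
        truncated=True,
    )


def _select_expert(latent, strategy, rng):
    """Expert campaign: targeted subset of worn days.

    With probability ``targeting_bias`` a measurement day is drawn from the
    exposed pool with weight proportional to the day's true maximum (workers
    and experts steer measurements toward the tasks they expect to be
    hazardous), otherwise uniformly from all worn days.
    """
    worn = [ld for ld in latent if ld.worn]
    exposed = [ld for ld in worn if ld.is_exposed]
    weights = np.array([ld.true_log.max_ppm for ld in exposed], dtype=float)
    if weights.sum() > 0:
        weights = weights / weights.sum()
    n = min(strategy.n_campaign_measurements, len(worn))
    chosen: list[LatentDay] = []
    seen = set()
    guard = 0
    while len(chosen) < n and guard < 100 * n:
        guard += 1
        if exposed and weights.sum() > 0 and rng.random() < strategy.targeting_bias:
            ld = exposed[int(rng.choice(len(exposed), p=weights))]
        else:
            ld = worn[int(rng.integers(len(worn)))]
        key = (ld.person_id, ld.date)
        if key in seen:
            continue
        seen.add(key)
        chosen.append(ld)
    return [(ld, True) for ld in chosen]


def _select_routine(latent, strategy):
    """Routine docking: a day's readings survive only if the device docks
    before the 16-h wraparound (two worn shifts) overwrites them, or an
    alarm forces a dock; alarm maxima survive regardless."""
    by_person: dict[str, list[LatentDay]] = {}
    for ld in latent:
        if ld.worn:
            by_person.setdefault(ld.person_id, []).append(ld)
    out = []
    for pid, days in by_person.items():
        days.sort(key=lambda ld: ld.date)
        alarm = [ld.true_log.max_ppm >= 10.05 for ld in days]
        dock = [
            ld.date.weekday() == strategy.docking_weekday or alarm[i]
            for i, ld in enumerate(days)
        ]
        # next dock at or after each worn day, in worn-day counts
        next_dock = [None] * len(days)
        last = None
        for i in range(len(days) - 1, -1, -1):
            if dock[i]:
                last = i
            next_dock[i] = last
        for i, ld in enumerate(days):
            if next_dock[i] is None:
                survives = False  # never docked again
            else:
                shifts_until_dock = next_dock[i] - i + 1
                survives = shifts_until_dock <= strategy.retention_shifts
            if survives:
                out.append((ld, True))
            elif alarm[i]:
                out.append((ld, False))  # alarm datapoint only
    return out


def _select_campaign(latent, strategy):
    """Daily campaign: every worn day inside the campaign windows."""
    if not latent:
        return []
    start = min(ld.date for ld in latent)
    windows = []
    for start_week, n_weeks in strategy.campaign_weeks:
        w0 = start + timedelta(weeks=start_week)
        windows.append((w0, w0 + timedelta(weeks=n_weeks)))
    out = []
    for ld in latent:
        if ld.worn and any(a <= ld.date < b for a, b in windows):
            out.append((ld, True))
    return out


def _span_months(dates: list[date]) -> float:
    if not dates:
        return 1.0
    span_days = (max(dates) - min(dates)).days + 1
    return max(span_days / 30.44, 0.25)


# ---------------------------------------------------------------------------
# CSV emission (round-trips through the parsers)


def write_gas_log_csv(latent_days: Iterable[LatentDay], path, lod_ppm: float = 1.6) -> None:
    """Emit worn days' observed readings in the gas-log CSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("person_id,device_id,timestamp,ppm,flag\n")
        for ld in latent_days:
            if not ld.worn:
                continue
            obs = _observe(ld.true_log, lod_ppm, True)
            for t, c, o in zip(obs.times, obs.ppm, obs.overload):
                if c < 0.05:
                    continue  # storage skips all-zero intervals
                flag = "OVERLOAD" if o else ""
                fh.write(f"{ld.person_id},{obs.device_id},{np.datetime64(t, 's')},{c:.1f},{flag}\n")
            for t, c in zip(obs.alarm_times, obs.alarm_ppm):
                fh.write(f"{ld.person_id},{obs.device_id},{np.datetime64(t, 's')},{c:.1f},ALARM\n")


def write_logbook_csv(latent_days: Iterable[LatentDay], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("person_id,date,workplace,category,start,duration_or_end,flushing,manhole_entry,comment\n")
        for ld in latent_days:
            lb = ld.tasks
            if lb is None:
                continue
            for t in lb.tasks:
                start = t.start.strftime("%H:%M") if t.start else ""
                fh.write(
                    f"{lb.person_id},{lb.date.isoformat()},{lb.workplace},{t.category},"
                    f"{start},{t.raw_duration},{lb.flushing},"
                    f"{1 if t.is_manhole_entry else 0},\n"
                )


def write_roster_csv(latent_days: Iterable[LatentDay], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("person_id,date,reason\n")
        for ld in latent_days:
            reason = ld.real_zero_reason if ld.is_real_zero else "normal duty"
            fh.write(f"{ld.person_id},{ld.date.isoformat()},{reason}\n")
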