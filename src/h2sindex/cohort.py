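"""Person-day aggregation and study-level descriptive outputs.

Gas logs are aggregated to one exposure record per person and day; days with
no reading at or above the instrument's limit of detection (LOD) are
censored and later imputed with the lowest-index-at-LOD/√2 constant.  A
collection of person-days plus its design descriptor (sampling strategy,
study months, persons) forms a StudyDataset, from which the study-level
summary table, the maximum-value histograms, and the index-vs-TWA table are
computed.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InvariantError, UndefinedStatisticError
from .gaslog import (
    B10_EDGE,
    DETECT_EDGE,
    BandProfile,
    ExposureConstants,
    GasLog,
    band_profile,
    compute_index,
    compute_twa,
    imputation_constant,
    round_half_away,
)
from .logbook import DayClassification, LogbookDay

__all__ = [
    "SEGS",
    "SEASONS",
    "DailyExposure",
    "StudyDataset",
    "SummaryRow",
    "HistogramSpec",
    "aggregate_person_day",
    "impute_censored",
    "summarize_dataset",
    "histogram_bins",
    "index_twa_table",
    "season_of",
    "dataset_to_frame",
    "write_dataset_csv",
    "read_dataset_csv",
]

SEGS = ("wastewater_network", "treatment_plant", "pumping_station", "water_network")
SEASONS = ("winter", "spring", "summer", "autumn")

# Meteorological season mapping, overridable via the ``mapping`` argument of
# season_of (month -> season).
DEFAULT_SEASON_MAP = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}

WORKDAYS_PER_YEAR = 220  # study convention for scheduled workdays

# Cross-dataset detection floor: the common measurement area of all
# instruments is above 1.6 ppm, even where a dataset's own LOD is 0.1.
COMMON_DETECT_PPM = 1.6


@dataclass
class DailyExposure:
    """Per person-day exposure summary."""

    person_id: str
    date: date
    seg: str = ""
    season: str = ""
    profile: BandProfile = field(default_factory=BandProfile)
    index: float = 0.0
    twa_ppm: float = float("nan")
    cv_exceeded: bool = False
    censored: bool = False
    imputed: bool = False
    status: DayClassification = field(default_factory=lambda: DayClassification("measured"))
    n_positive_readings: int = 0
    mode: str = "cumulative"

    def __post_init__(self) -> None:
        if self.index < 0:
            raise InvariantError("index must be >= 0")
        if self.censored and self.cv_exceeded:
            raise InvariantError("a censored day cannot exceed the ceiling")


@dataclass
class StudyDataset:
    """Person-days plus the design descriptor of the sampling strategy."""

    label: str  # A | B | C
    days: list[DailyExposure] = field(default_factory=list)
    n_persons: int = 1
    months: float = 1.0
    lod_ppm: float = 1.6
    frame_workdays: int | None = None  # scheduled person-days in the study frame
    interval_s: float = 15.0
    mode: str = "cumulative"

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise InvariantError("n_persons must be >= 1")

    @property
    def n_measurement_days(self) -> int:
        return sum(1 for d in self.days if d.status.status == "measured")

    @property
    def constants(self) -> ExposureConstants:
        return ExposureConstants(lod_ppm=self.lod_ppm)

    def model_frame(self) -> pd.DataFrame:
        """Measured days only (real-zero and missing excluded), as a frame."""
        df = dataset_to_frame(self)
        return df[df["status"] == "measured"].reset_index(drop=True)


@dataclass
class SummaryRow:
    """One dataset's row block of the descriptive comparison table."""

    n_measured: int
    n_detect: int
    n_cv: int
    n_over100: int
    pct_detect_of_measured: float
    pct_cv_of_measured: float
    pct_cv_of_detect: float | None
    study_workdays: int
    duration_workdays: int
    pct_measured_of_study_workdays: float
    pct_measured_of_duration_workdays: float

    def __post_init__(self) -> None:
        if not (self.n_cv <= self.n_detect <= self.n_measured):
            raise InvariantError("expected n_cv <= n_detect <= n_measured")


@dataclass(frozen=True)
class HistogramSpec:
    """Daily-maximum histogram over the common detection range (1.6, 100]."""

    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    overload_count: int  # > 100 ppm
    rejected_count: int  # <= 1.6 ppm, not binnable

    @property
    def total(self) -> int:
        return sum(self.counts) + self.overload_count


# ---------------------------------------------------------------------------


def aggregate_person_day(
    logs: Sequence[GasLog],
    meta: LogbookDay | None = None,
    constants: ExposureConstants = ExposureConstants(),
    mode: str = "cumulative",
    status: DayClassification | None = None,
    seg: str = "",
) -> DailyExposure:
    """Merge all of one person's logs for one calendar day into a DailyExposure.

    Readings from multiple logs are concatenated in time order; identical
    timestamps are resolved by taking the maximum.  A day is censored when
    no reading and no alarm datapoint reaches the LOD.
    """
    if not logs:
        raise ConfigError("at least one gas log is required")
    persons = {lg.person_id for lg in logs}
    if len(persons) > 1:
        raise ConfigError(f"logs mix persons: {sorted(persons)}")
    dates = set()
    for lg in logs:
        for arr in (lg.times, lg.alarm_times):
            if len(arr):
                dates.update(np.unique(arr.astype("datetime64[D]")).tolist())
    if len(dates) > 1:
        raise ConfigError(f"logs mix calendar dates: {sorted(dates)}")
    if not dates:
        raise ConfigError("logs contain no readings and no alarm datapoints")
    merged = _merge_logs(logs)
    profile = band_profile(merged, mode=mode)
    index = compute_index(profile)
    try:
        twa = compute_twa(merged, constants)
    except UndefinedStatisticError:
        twa = float("nan")
    lod_edge = constants.lod_ppm - 0.05
    n_pos = int((merged.ppm >= lod_edge).sum() + (merged.alarm_ppm >= lod_edge).sum())
    censored = n_pos == 0
    if censored:
        index = 0.0  # sub-LOD readings are not trusted; imputation fills in later
    day_date = dates.pop()
    return DailyExposure(
        person_id=merged.person_id,
        date=day_date,
        seg=seg or (meta.workplace if meta else ""),
        season=season_of(day_date),
        profile=profile,
        index=index,
        twa_ppm=twa,
        cv_exceeded=profile.max_ppm >= B10_EDGE,
        censored=censored,
        status=status or DayClassification("measured"),
        n_positive_readings=n_pos,
        mode=mode,
    )


def _merge_logs(logs: Sequence[GasLog]) -> GasLog:
    if len(logs) == 1:
        return logs[0]
    times = np.concatenate([lg.times for lg in logs])
    ppm = np.concatenate([lg.ppm for lg in logs])
    over = np.concatenate([lg.overload for lg in logs])
    order = np.argsort(times, kind="stable")
    times, ppm, over = times[order], ppm[order], over[order]
    # resolve duplicate timestamps by the maximum concentration
    keep_t, keep_c, keep_o = [], [], []
    for t, c, o in zip(times, ppm, over):
        if keep_t and t == keep_t[-1]:
            if c > keep_c[-1]:
                keep_c[-1], keep_o[-1] = c, o
        else:
            keep_t.append(t)
            keep_c.append(c)
            keep_o.append(o)
    interval = logs[0].sampling_interval_s
    times_a = np.array(keep_t, dtype="datetime64[s]")
    # long gaps between different logs must not join excursions
    breaks = []
    if len(times_a) > 1:
        diffs = np.diff(times_a).astype("timedelta64[s]").astype(float)
        breaks = [i + 1 for i, g in enumerate(diffs) if g > interval + 1e-9]
    return GasLog(
        person_id=logs[0].person_id,
        device_id=",".join(sorted({lg.device_id for lg in logs if lg.device_id})),
        sampling_interval_s=interval,
        times=times_a,
        ppm=np.array(keep_c, dtype=float),
        overload=np.array(keep_o, dtype=bool),
        alarm_times=np.concatenate([lg.alarm_times for lg in logs]),
        alarm_ppm=np.concatenate([lg.alarm_ppm for lg in logs]),
        segment_breaks=tuple(breaks),
    )


def impute_censored(dataset: StudyDataset, mode: str | None = None) -> StudyDataset:
    """Assign the lowest-index/√2 constant to censored measured days.

    Confirmed real-zero days are never imputed (they stay in descriptives
    but are excluded from the model frame).  Idempotent: the constant is
    assigned, not accumulated.
    """
    mode = mode or dataset.mode
    const = imputation_constant(dataset.constants, dataset.interval_s, mode)
    new_days = []
    for d in dataset.days:
        if d.censored and d.status.status == "measured":
            new_days.append(replace(d, index=const, imputed=True))
        else:
            new_days.append(d)
    return replace(dataset, days=new_days)


def summarize_dataset(
    dataset: StudyDataset,
    *,
    n_measured: int | None = None,
    n_detect: int | None = None,
    n_cv: int | None = None,
    n_over100: int | None = None,
) -> SummaryRow:
    """Descriptive counts and workday arithmetic for one dataset.

    Detection uses the common 1.6 ppm floor for cross-dataset comparability
    regardless of the dataset's own LOD.  ``study_workdays`` is measurement
    days × persons; ``duration_workdays`` comes from the study duration in
    months at 220 workdays/year/person.  Counts can be supplied explicitly
    (e.g. from a printed table) to reproduce published arithmetic.
    """
    if dataset.months <= 0:
        raise ConfigError("study duration in months must be positive")
    measured = [d for d in dataset.days if d.status.status == "measured"]
    if n_measured is None:
        n_measured = len(measured)
    if n_detect is None:
        n_detect = sum(1 for d in measured if d.profile.max_ppm > COMMON_DETECT_PPM + 1e-9)
    if n_cv is None:
        n_cv = sum(1 for d in measured if d.cv_exceeded)
    if n_over100 is None:
        n_over100 = sum(1 for d in measured if d.profile.max_ppm >= 100.0 - 1e-9)
    study_workdays = n_measured * dataset.n_persons
    duration_workdays = int(
        round_half_away(dataset.months * dataset.n_persons * WORKDAYS_PER_YEAR / 12.0)
    )
    frame = dataset.frame_workdays if dataset.frame_workdays is not None else study_workdays
    pct = lambda num, den: round_half_away(100.0 * num / den) if den else float("nan")
    return SummaryRow(
        n_measured=n_measured,
        n_detect=n_detect,
        n_cv=n_cv,
        n_over100=n_over100,
        pct_detect_of_measured=pct(n_detect, n_measured),
        pct_cv_of_measured=pct(n_cv, n_measured),
        pct_cv_of_detect=pct(n_cv, n_detect) if n_detect else None,
        study_workdays=frame,
        duration_workdays=duration_workdays,
        pct_measured_of_study_workdays=pct(n_measured, frame),
        pct_measured_of_duration_workdays=pct(n_measured, duration_workdays),
    )


def histogram_bins(values: Iterable[float]) -> HistogramSpec:
    """Bin daily maxima over (1.6, 100] with bin width 1/10 of the upper decade.

    Bins are (1.6, 2], (2, 3], …, (9, 10], (10, 20], …, (90, 100]; the 10.0
    endpoint is the ceiling value.  Values above 100 ppm (instrument
    overload) fall in one extra bin; values at or below 1.6 ppm are not
    binnable and are counted as rejected.
    """
    edges = [1.6] + list(range(2, 11)) + list(range(20, 101, 10))
    counts = [0] * (len(edges) - 1)
    overload = 0
    rejected = 0
    for v in values:
        if v <= edges[0] + 1e-9:
            rejected += 1
        elif v > 100.0 + 1e-9:
            overload += 1
        else:
            # first edge strictly below v; value belongs to (edges[i], edges[i+1]]
            i = 0
            while v > edges[i + 1] + 1e-9:
                i += 1
            counts[i] += 1
    return HistogramSpec(
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(counts),
        overload_count=overload,
        rejected_count=rejected,
    )


def index_twa_table(days: Sequence[DailyExposure]) -> tuple[pd.DataFrame, dict]:
    """Index-vs-TWA rows and log10–log10 least-squares fits per CV stratum.

    Returns the row table (twa_ppm, index, cv_exceeded) and a dict of fits
    {"all": ..., "cv": ..., "no_cv": ...} with slope, intercept, r2 and n;
    rows with zero/undefined TWA or index are excluded from the fits and
    counted.
    """
    df = pd.DataFrame(
        {
            "person_id": [d.person_id for d in days],
            "date": [d.date for d in days],
            "twa_ppm": [d.twa_ppm for d in days],
            "index": [d.index for d in days],
            "cv_exceeded": [d.cv_exceeded for d in days],
        }
    )
    fits: dict[str, dict] = {}
    usable = df[(df["twa_ppm"] > 0) & (df["index"] > 0)].copy()
    fits["excluded_rows"] = {"n": int(len(df) - len(usable))}
    for name, sub in (
        ("all", usable),
        ("cv", usable[usable["cv_exceeded"]]),
        ("no_cv", usable[~usable["cv_exceeded"]]),
    ):
        if len(sub) < 2:
            fits[name] = {"n": int(len(sub)), "note": "fit skipped: fewer than 2 usable rows"}
            continue
        x = np.log10(sub["twa_ppm"].to_numpy())
        y = np.log10(sub["index"].to_numpy())
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        ss_res = float(((y - yhat) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        fits[name] = {
            "slope": float(slope),
            "intercept": float(intercept),
            "r2": float(r2),
            "n": int(len(sub)),
            "space": "log10-log10",
        }
    return df, fits


def season_of(d: date, mapping: dict[int, str] | None = None) -> str:
    """Meteorological season of a date (Dec–Feb winter, …); configurable."""
    mapping = mapping or DEFAULT_SEASON_MAP
    return mapping[d.month]


# ---------------------------------------------------------------------------
# Export / import

DATASET_COLUMNS = [
    "person_id",
    "date",
    "seg",
    "season",
    "index",
    "twa_ppm",
    "max_ppm",
    "cv_exceeded",
    "censored",
    "imputed",
    "status",
]


def dataset_to_frame(dataset: StudyDataset) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "person_id": [d.person_id for d in dataset.days],
            "date": [d.date for d in dataset.days],
            "seg": [d.seg for d in dataset.days],
            "season": [d.season for d in dataset.days],
            "index": [d.index for d in dataset.days],
            "twa_ppm": [d.twa_ppm for d in dataset.days],
            "max_ppm": [d.profile.max_ppm for d in dataset.days],
            "cv_exceeded": [d.cv_exceeded for d in dataset.days],
            "censored": [d.censored for d in dataset.days],
            "imputed": [d.imputed for d in dataset.days],
            "status": [d.status.status for d in dataset.days],
        }
    )


def write_dataset_csv(dataset: StudyDataset, path, sidecar_path=None) -> None:
    """Write the person-day table as CSV plus a JSON design sidecar."""
    df = dataset_to_frame(dataset)
    df.to_csv(path, index=False)
    meta = {
        "label": dataset.label,
        "n_persons": dataset.n_persons,
        "months": dataset.months,
        "lod_ppm": dataset.lod_ppm,
        "frame_workdays": dataset.frame_workdays,
        "interval_s": dataset.interval_s,
        "mode": dataset.mode,
    }
    if sidecar_path is None:
        sidecar_path = str(path) + ".meta.json"
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)


def read_dataset_csv(path, sidecar_path=None) -> StudyDataset:
    """Read a person-day CSV (+ sidecar) back into a StudyDataset.

    Band profiles are reduced to the maximum; index/TWA/flags round-trip
    exactly, which is all the models and summaries need.
    """
    df = pd.read_csv(path, parse_dates=["date"])
    if sidecar_path is None:
        sidecar_path = str(path) + ".meta.json"
    try:
        with open(sidecar_path, "r", encoding="utf-8") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        meta = {}
    days = []
    for _, row in df.iterrows():
        days.append(
            DailyExposure(
                person_id=str(row["person_id"]),
                date=row["date"].date(),
                seg="" if pd.isna(row["seg"]) else str(row["seg"]),
                season="" if pd.isna(row["season"]) else str(row["season"]),
                profile=BandProfile(max_ppm=float(row["max_ppm"])),
                index=float(row["index"]),
                twa_ppm=float(row["twa_ppm"]),
                cv_exceeded=bool(row["cv_exceeded"]),
                censored=bool(row["censored"]),
                imputed=bool(row.get("imputed", False)),
                status=DayClassification(str(row["status"])),
            )
        )
    return StudyDataset(
        label=meta.get("label", "?"),
        days=days,
        n_persons=meta.get("n_persons", max(1, df["person_id"].nunique())),
        months=meta.get("months", 1.0),
        lod_ppm=meta.get("lod_ppm", 1.6),
        frame_workdays=meta.get("frame_workdays"),
        interval_s=meta.get("interval_s", 15.0),
        mode=meta.get("mode", "cumulative"),
    )
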