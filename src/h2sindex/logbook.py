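"""Worker-logbook parsing, cleaning and person-day classification.

Workers in a daily-measurement campaign keep a logbook of tasks (category,
start, duration, workplace, flushing activity, manhole entries).  Field
entries are messy: durations are often written as end times, one entry may
cover several days, and category vocabulary drifts between workers.  This
module codifies the cleaning rules, classifies person-days into
measured / real-zero / missing against a work-log roster, and computes
activity contrasts such as the manhole-entry ratio between worker groups.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta

import numpy as np

from .errors import ParseError, UndefinedStatisticError
from .gaslog import DETECT_EDGE, GasLog, round_half_away

__all__ = [
    "TaskRecord",
    "LogbookDay",
    "DayClassification",
    "KNOWN_CATEGORIES",
    "FLUSHING_LEVELS",
    "parse_logbook",
    "parse_roster",
    "normalize_durations",
    "split_multiday",
    "drop_weekend_zero_days",
    "classify_day",
    "manhole_entry_ratio",
]

# Controlled vocabulary from the logbook form; editable because workers give
# categories different meanings.
KNOWN_CATEGORIES = (
    "driving",
    "unexposed_water_task",
    "water_network_task",
    "wastewater_task",
    "flushing",
    "manhole_entry",
    "plant_operation",
    "pumping_station_check",
    "office",
    "other",
)

FLUSHING_LEVELS = ("none", "some", "much")  # ordered factor

# A raw "duration" larger than this (minutes) is suspected to be an end time
# written as a clock number; configurable in normalize_durations.
DEFAULT_END_TIME_THRESHOLD_MIN = 720.0

# Reasons in the work-log roster that make a day a confirmed real zero.
REAL_ZERO_REASONS = (
    "sick leave",
    "holiday",
    "education day",
    "union work",
    "compensation day",
)


@dataclass
class TaskRecord:
    """One task entry: category, start time, and a duration or end time."""

    category: str
    start: time | None = None
    duration_min: float | None = None
    end: time | None = None
    raw_duration: str = ""
    is_manhole_entry: bool = False
    flagged: str = ""  # non-empty = cleaning decision or problem note

    @property
    def normalized(self) -> bool:
        return self.duration_min is not None or self.flagged.startswith("ambiguous")


@dataclass
class LogbookDay:
    """Cleaned activity metadata for one person-day."""

    person_id: str
    date: date
    workplace: str = ""
    flushing: str = "none"  # absence of mention = none
    manhole_entries: int = 0
    tasks: list[TaskRecord] = field(default_factory=list)
    source: str = "paper_form"  # paper_form | electronic_form | worklog
    flags: list[str] = field(default_factory=list)

    @property
    def n_exposed_tasks(self) -> int:
        unexposed = {"driving", "unexposed_water_task", "office"}
        return sum(1 for t in self.tasks if t.category not in unexposed)


@dataclass(frozen=True)
class DayClassification:
    """Status of a person-day in the study frame."""

    status: str  # measured | real_zero | missing
    reason: str = ""


# ---------------------------------------------------------------------------
# Parsing

LOGBOOK_HEADER = [
    "person_id",
    "date",
    "workplace",
    "category",
    "start",
    "duration_or_end",
    "flushing",
    "manhole_entry",
    "comment",
]


def parse_logbook(source, *, source_kind: str = "paper_form") -> list[LogbookDay]:
    """Parse logbook CSV (or electronic-form JSON) into LogbookDay records.

    One LogbookDay per person-date; task rows for the same person-date are
    merged.  Unknown categories are preserved verbatim and flagged.  Rows
    missing person or date are rejected with a line-level report collected
    on a ParseError.
    """
    rows, kind = _load_rows(source)
    days: dict[tuple[str, str], LogbookDay] = {}
    rejects: list[str] = []
    for lineno, rec in rows:
        pid = str(rec.get("person_id", "")).strip()
        date_raw = str(rec.get("date", "")).strip()
        if not pid or not date_raw:
            rejects.append(f"line {lineno}: missing person_id or date")
            continue
        key = (pid, date_raw)
        if key not in days:
            days[key] = LogbookDay(
                person_id=pid,
                date=_parse_date_or_range(date_raw)[0],
                workplace=str(rec.get("workplace", "")).strip(),
                source=source_kind if kind == "csv" else "electronic_form",
            )
            if "--" in date_raw or ".." in date_raw:
                days[key].flags.append(f"date_range:{date_raw}")
        day = days[key]
        category = str(rec.get("category", "")).strip() or "other"
        if category not in KNOWN_CATEGORIES:
            day.flags.append(f"unknown_category:{category}")
        flush = str(rec.get("flushing", "")).strip().lower()
        if flush in FLUSHING_LEVELS and flush != "none":
            # keep the highest flushing level mentioned that day
            if FLUSHING_LEVELS.index(flush) > FLUSHING_LEVELS.index(day.flushing):
                day.flushing = flush
        manhole = str(rec.get("manhole_entry", "")).strip().lower() in ("1", "true", "yes", "x")
        if manhole or category == "manhole_entry":
            day.manhole_entries += 1
        task = TaskRecord(
            category=category,
            start=_parse_clock(str(rec.get("start", "")).strip()),
            raw_duration=str(rec.get("duration_or_end", "")).strip(),
            is_manhole_entry=manhole or category == "manhole_entry",
        )
        day.tasks.append(task)
    if rejects:
        raise ParseError("; ".join(rejects))
    return [days[k] for k in sorted(days)]


def parse_roster(source) -> dict[tuple[str, date], str]:
    """Work-log roster CSV ``person_id,date,reason`` -> {(person, date): reason}."""
    text = _read_text(source)
    out: dict[tuple[str, date], str] = {}
    for lineno, row in enumerate(csv.reader(io.StringIO(text)), start=1):
        if not row or not "".join(row).strip():
            continue
        if lineno == 1 and row[0].strip().lower() == "person_id":
            continue
        if len(row) < 3:
            raise ParseError(f"roster line {lineno}: expected 3 fields")
        out[(row[0].strip(), date.fromisoformat(row[1].strip()))] = row[2].strip().lower()
    return out


def _load_rows(source):
    text = _read_text(source)
    stripped = text.lstrip()
    if stripped.startswith("[") or stripped.startswith("{"):
        data = json.loads(text)
        if isinstance(data, dict):
            data = [data]
        return [(i + 1, rec) for i, rec in enumerate(data)], "json"
    rows = []
    reader = csv.DictReader(io.StringIO(text))
    for lineno, rec in enumerate(reader, start=2):
        rows.append((lineno, rec))
    return rows, "csv"


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    text = str(source)
    if "\n" in text or "," in text or text.lstrip().startswith(("[", "{")):
        return text
    with open(text, "r", encoding="utf-8") as fh:
        return fh.read()


def _parse_date_or_range(raw: str) -> tuple[date, date]:
    for sep in ("--", ".."):
        if sep in raw:
            a, b = raw.split(sep, 1)
            return date.fromisoformat(a.strip()), date.fromisoformat(b.strip())
    d = date.fromisoformat(raw)
    return d, d


_CLOCK_RE = re.compile(r"^(\d{1,2}):?(\d{2})$")


def _parse_clock(raw: str) -> time | None:
    m = _CLOCK_RE.match(raw)
    if not m:
        return None
    hh, mm = int(m.group(1)), int(m.group(2))
    if hh > 23 or mm > 59:
        return None
    return time(hh, mm)


# ---------------------------------------------------------------------------
# Cleaning


def normalize_durations(
    day: LogbookDay,
    *,
    end_time_threshold_min: float = DEFAULT_END_TIME_THRESHOLD_MIN,
) -> LogbookDay:
    """Resolve the duration-vs-end-time ambiguity in raw task entries.

    Workers often wrote the task's end time in the duration field.  A raw
    value is reinterpreted as an end time when (a) it parses as a clock time
    later than the start, or (b) read as minutes it would push the task past
    midnight or exceed ``end_time_threshold_min``.  Each reinterpretation is
    recorded on the task; irrecoverable entries keep duration undefined and
    are flagged ambiguous.  Idempotent.
    """
    new_tasks = []
    for task in day.tasks:
        if task.duration_min is not None or task.flagged.startswith("ambiguous"):
            new_tasks.append(task)  # already normalized
            continue
        raw = task.raw_duration
        t = replace(task)
        if not raw:
            t.flagged = "ambiguous: empty duration"
            new_tasks.append(t)
            continue
        clock = _parse_clock(raw)
        minutes = _parse_minutes(raw)
        start = task.start
        if clock is not None and start is not None and clock > start:
            # looks like an end time after start -> reinterpret
            if minutes is not None and minutes <= end_time_threshold_min and ":" not in raw:
                # plausible as plain minutes too; prefer minutes only when the
                # clock reading would be absurdly long
                dur_as_clock = _minutes_between(start, clock)
                if minutes <= dur_as_clock:
                    t.duration_min = minutes
                    new_tasks.append(t)
                    continue
            t.end = clock
            t.duration_min = _minutes_between(start, clock)
            t.flagged = f"reinterpreted: {raw!r} read as end time"
        elif minutes is not None:
            if minutes > end_time_threshold_min or _crosses_midnight(start, minutes):
                t.flagged = f"ambiguous: {raw!r} too long as minutes, not a valid end time"
            else:
                t.duration_min = minutes
        else:
            t.flagged = f"ambiguous: cannot read {raw!r} as minutes or clock time"
        new_tasks.append(t)
    return replace(day, tasks=new_tasks)


def _parse_minutes(raw: str) -> float | None:
    if ":" in raw:
        return None
    try:
        v = float(raw)
    except ValueError:
        return None
    return v if v > 0 else None


def _minutes_between(start: time, end: time) -> float:
    s = start.hour * 60 + start.minute
    e = end.hour * 60 + end.minute
    return float(e - s)


def _crosses_midnight(start: time | None, minutes: float) -> bool:
    if start is None:
        return minutes > 24 * 60
    return (start.hour * 60 + start.minute) + minutes > 24 * 60


def split_multiday(days: list[LogbookDay]) -> list[LogbookDay]:
    """Expand entries covering a date range into one record per date.

    Tasks are duplicated to every date of the range; the total task count is
    conserved times the number of days.  Open-ended or inverted ranges are
    errors.
    """
    out: list[LogbookDay] = []
    for day in days:
        range_flags = [f for f in day.flags if f.startswith("date_range:")]
        if not range_flags:
            out.append(day)
            continue
        raw = range_flags[0].split(":", 1)[1]
        if raw.endswith(("--", "..")) or raw.startswith(("--", "..")):
            raise ParseError(f"open-ended date range {raw!r}")
        start, end = _parse_date_or_range(raw)
        if end < start:
            raise ParseError(f"date range end before start: {raw!r}")
        d = start
        while d <= end:
            clone = replace(
                day,
                date=d,
                tasks=[replace(t) for t in day.tasks],
                flags=[f for f in day.flags if not f.startswith("date_range:")],
            )
            out.append(clone)
            d += timedelta(days=1)
    return out


def drop_weekend_zero_days(
    days: list,
    measurements: dict,
    logbook: dict | None = None,
    *,
    holidays: set | None = None,
    lod_ppm: float = 1.6,
):
    """Remove weekend/holiday measurement days with only below-LOD readings.

    ``days`` is a list of (person_id, date) keys into ``measurements``
    (person-day GasLogs); a day is dropped iff it falls on a weekend or a
    configured holiday, every reading and alarm point is below the LOD, and
    no logbook record exists for that person-date.
    """
    holidays = holidays or set()
    logbook = logbook or {}
    kept = []
    for key in days:
        person, d = key
        is_offday = d.weekday() >= 5 or d in holidays
        log = measurements.get(key)
        all_zero = log is None or log.max_ppm < lod_ppm - 0.05
        if is_offday and all_zero and key not in logbook:
            continue
        kept.append(key)
    return kept


def classify_day(
    person_id: str,
    d: date,
    has_measurement: bool,
    logbook: dict | None,
    roster: dict | None,
) -> DayClassification:
    """Classify a person-day as measured, real-zero, or missing.

    Days with no sensor data are controlled against the work-log roster:
    an absence reason (sick leave, holiday, education, union work,
    compensation day) makes the day a confirmed real zero; otherwise the
    day is missing data.
    """
    if has_measurement:
        return DayClassification("measured")
    roster = roster or {}
    key = (person_id, d)
    if key not in roster:
        return DayClassification("missing", "no roster")
    reason = roster[key]
    if any(rz in reason for rz in REAL_ZERO_REASONS):
        return DayClassification("real_zero", reason)
    return DayClassification("missing", reason)


def manhole_entry_ratio(
    count_a: int,
    n_a: int,
    count_b: int,
    n_b: int,
    corrected: bool = True,
) -> float:
    """How much more often group A enters manholes than group B.

    corrected=True normalizes each count by its group size (entries per
    person); corrected=False is the raw count ratio.  Reported rounded to
    an integer by callers; this returns the unrounded ratio.
    """
    if count_a < 0 or count_b < 0 or n_a <= 0 or n_b <= 0:
        raise UndefinedStatisticError("counts must be >= 0 and group sizes > 0")
    if count_b == 0:
        raise UndefinedStatisticError("ratio undefined: comparison group has no entries")
    if corrected:
        return (count_a / n_a) / (count_b / n_b)
    return count_a / count_b
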