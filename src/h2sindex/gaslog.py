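"""Gas-detector log parsing and per-measurement exposure metrics.

A personal electrochemical H₂S detector logs instantaneous concentration at a
fixed cadence (15 s by default) with 0.1 ppm resolution on a 0.1–100 ppm
measurement range.  This module parses the CSV export of such logs and
computes every per-log exposure metric used downstream:

* excursions (maximal runs of readings at or above the detection floor),
* band-wise peak counts and band durations,
* the daily maximum, the 8-h time-weighted average (TWA), and ceiling-value
  exceedance,
* the unitless H₂S exposure index

      index = 0.1·n01 + 0.1·dur01 + 1·n1 + 5·n5 + 5·dur5 + 10·n10 + max

  where n01/n1/n5/n10 count peaks reaching the 0.1–1.0, 1.1–5.0, 5.1–10.0
  and >10 ppm bands, dur01/dur5 are minutes spent in 0.1–5.0 ppm and above
  5.0 ppm, and max is the highest concentration seen.

Band membership is decided on half-grid edges (0.05, 1.05, 5.05, 10.05 ppm)
so that 0.1-resolution readings never sit on a boundary; reports use the
conventional printed edges.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

from .errors import (
    ConfigError,
    InvariantError,
    OrderingError,
    ParseError,
    UndefinedStatisticError,
)

__all__ = [
    "Reading",
    "GasLog",
    "Excursion",
    "BandProfile",
    "ExposureConstants",
    "DATASET_A_CONSTANTS",
    "DATASET_BC_CONSTANTS",
    "parse_gas_log",
    "read_gas_logs",
    "detect_excursions",
    "band_profile",
    "compute_index",
    "lowest_index_at_lod",
    "imputation_constant",
    "compute_twa",
    "exceeds_ceiling",
    "round_half_away",
]

# Internal half-grid band edges: readings are on a 0.1-ppm grid, so placing
# edges halfway between grid points makes band membership unambiguous.
DETECT_EDGE = 0.05   # >= here means "detected" (0.1 ppm floor)
B1_EDGE = 1.05       # 1.1-5.0 ppm band
B5_EDGE = 5.05       # 5.1-10.0 ppm band
B10_EDGE = 10.05     # > 10 ppm band (ceiling exceedance)

BAND_NAMES = ("B01", "B1", "B5", "B10")

PEAK_MODES = ("cumulative", "max_band")


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention).

    Python's built-in ``round`` is banker's rounding; printed tables in
    occupational-hygiene reports round 0.5 up.
    """
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


class Reading(NamedTuple):
    """One time-stamped concentration sample."""

    timestamp: np.datetime64
    ppm: float
    overload: bool = False


@dataclass(frozen=True)
class ExposureConstants:
    """Instrument and regulatory constants for one dataset.

    lod_ppm
        Limit of detection: 0.1 ppm for the expert-campaign instruments,
        1.6 ppm for the self-assessed-collection alarm detectors.
    cv_ppm
        Ceiling value, 10 ppm; exceedance is strict (> 10).
    oel_ppm
        8-h occupational exposure limit, 5 ppm.
    twa_reference_min
        Fixed TWA denominator in minutes (480 = 8-h shift).
    """

    lod_ppm: float = 1.6
    cv_ppm: float = 10.0
    oel_ppm: float = 5.0
    twa_reference_min: float = 480.0

    def __post_init__(self) -> None:
        if self.lod_ppm <= 0:
            raise InvariantError("lod_ppm must be positive")
        if self.cv_ppm != 10.0:
            raise InvariantError("cv_ppm is fixed at 10.0 ppm")
        if self.oel_ppm != 5.0:
            raise InvariantError("oel_ppm is fixed at 5.0 ppm")


DATASET_A_CONSTANTS = ExposureConstants(lod_ppm=0.1)
DATASET_BC_CONSTANTS = ExposureConstants(lod_ppm=1.6)


@dataclass
class GasLog:
    """One device-person time series of H₂S readings at fixed interval.

    ``times``/``ppm``/``overload`` are parallel numpy arrays for the logged
    readings; ``alarm_times``/``alarm_ppm`` hold isolated single datapoints
    stored by the instrument at alarm time without a surrounding log.
    ``segment_breaks`` marks indices where a gap longer than the zero-refill
    limit was found at parse time; excursion detection never joins readings
    across a break.
    """

    person_id: str
    device_id: str = ""
    sampling_interval_s: float = 15.0
    times: np.ndarray = field(default_factory=lambda: np.array([], dtype="datetime64[s]"))
    ppm: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))
    overload: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    alarm_times: np.ndarray = field(default_factory=lambda: np.array([], dtype="datetime64[s]"))
    alarm_ppm: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))
    truncated: bool = False
    segment_breaks: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.overload is None or len(self.overload) != len(self.ppm):
            self.overload = np.zeros(len(self.ppm), dtype=bool)
        self.alarm_times = np.asarray(self.alarm_times, dtype="datetime64[s]")
        self.alarm_ppm = np.asarray(self.alarm_ppm, dtype=float)
        if len(self.times) != len(self.ppm):
            raise InvariantError("times and ppm must have equal length")
        if np.any(self.ppm < 0) or np.any(self.alarm_ppm < 0):
            raise InvariantError("concentrations must be non-negative")
        if len(self.times) > 1:
            diffs = np.diff(self.times).astype("timedelta64[s]").astype(float)
            if np.any(diffs <= 0):
                raise OrderingError("gas-log timestamps must be strictly increasing")
            rem = np.mod(diffs, self.sampling_interval_s)
            if not np.all((rem < 1e-6) | (self.sampling_interval_s - rem < 1e-6)):
                raise InvariantError(
                    "consecutive timestamps must differ by a multiple of the "
                    f"sampling interval ({self.sampling_interval_s} s)"
                )

    def __len__(self) -> int:
        return len(self.ppm)

    @property
    def max_ppm(self) -> float:
        """Maximum over logged readings and alarm datapoints (0 if empty)."""
        vals = [v for arr in (self.ppm, self.alarm_ppm) if len(arr) for v in (arr.max(),)]
        return float(max(vals)) if vals else 0.0

    def readings(self) -> Iterator[Reading]:
        for t, c, o in zip(self.times, self.ppm, self.overload):
            yield Reading(t, float(c), bool(o))

    @classmethod
    def from_ppm(
        cls,
        values: Sequence[float],
        *,
        person_id: str = "p",
        device_id: str = "d",
        start: str | np.datetime64 = "2019-02-04T08:00:00",
        sampling_interval_s: float = 15.0,
        **kwargs,
    ) -> "GasLog":
        """Convenience constructor from a plain concentration sequence."""
        values = np.asarray(values, dtype=float)
        t0 = np.datetime64(start, "s")
        times = t0 + (np.arange(len(values)) * sampling_interval_s).astype("timedelta64[s]")
        return cls(
            person_id=person_id,
            device_id=device_id,
            sampling_interval_s=sampling_interval_s,
            times=times,
            ppm=values,
            overload=values >= 100.0,
            **kwargs,
        )


@dataclass(frozen=True)
class Excursion:
    """A maximal contiguous run of readings at or above the detection floor."""

    start_index: int
    end_index: int      # inclusive
    peak_ppm: float
    n_readings: int
    bands_crossed: frozenset[str]


@dataclass(frozen=True)
class BandProfile:
    """The seven terms of the H₂S index for one person-day.

    Peak counts per band (h2s01 … h2s10), minutes in the 0.1–5.0 ppm range
    (duration01_min), minutes above 5.0 ppm (duration5_min), and the daily
    maximum.
    """

    h2s01: int = 0
    h2s1: int = 0
    h2s5: int = 0
    h2s10: int = 0
    duration01_min: float = 0.0
    duration5_min: float = 0.0
    max_ppm: float = 0.0

    def __post_init__(self) -> None:
        for name in ("h2s01", "h2s1", "h2s5", "h2s10"):
            if getattr(self, name) < 0:
                raise InvariantError(f"{name} must be >= 0")
        if self.duration01_min < 0 or self.duration5_min < 0:
            raise InvariantError("durations must be >= 0")
        if self.max_ppm < 0:
            raise InvariantError("max_ppm must be >= 0")


def bands_for_peak(peak_ppm: float) -> frozenset[str]:
    """All bands whose lower edge lies at or below ``peak_ppm``."""
    bands = set()
    if peak_ppm >= DETECT_EDGE:
        bands.add("B01")
    if peak_ppm >= B1_EDGE:
        bands.add("B1")
    if peak_ppm >= B5_EDGE:
        bands.add("B5")
    if peak_ppm >= B10_EDGE:
        bands.add("B10")
    return frozenset(bands)


def highest_band(peak_ppm: float) -> str | None:
    for name, edge in (("B10", B10_EDGE), ("B5", B5_EDGE), ("B1", B1_EDGE), ("B01", DETECT_EDGE)):
        if peak_ppm >= edge:
            return name
    return None


# ---------------------------------------------------------------------------
# Parsing

GASLOG_HEADER = ["person_id", "device_id", "timestamp", "ppm", "flag"]

DEFAULT_MAX_GAP_S = 4 * 3600  # zero-skipped gaps up to 4 h are refilled


def parse_gas_log(
    source,
    *,
    sampling_interval_s: float = 15.0,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
) -> GasLog:
    """Parse one gas-detector CSV export into a :class:`GasLog`.

    The dialect is ``person_id,device_id,timestamp,ppm,flag`` with ISO-8601
    timestamps and flag in {"", "ALARM", "OVERLOAD"}.  The instrument's
    storage unit skips all-zero intervals at transfer, so a timestamp gap of
    up to ``max_gap_s`` between consecutive readings is reinstated as
    explicit 0.0 readings; longer gaps split the log into segments, recorded
    in ``segment_breaks``.

    ``source`` may be a path, a CSV string, or a file-like object.
    """
    rows = _read_rows(source)
    person_ids, device_ids = set(), set()
    times: list[np.datetime64] = []
    ppm: list[float] = []
    overload: list[bool] = []
    alarm_times: list[np.datetime64] = []
    alarm_ppm: list[float] = []

    for lineno, row in rows:
        if len(row) < 4:
            raise ParseError(f"line {lineno}: expected at least 4 fields, got {len(row)}")
        pid, did, ts_raw, ppm_raw = row[0].strip(), row[1].strip(), row[2].strip(), row[3].strip()
        flag = row[4].strip().upper() if len(row) > 4 else ""
        if not pid:
            raise ParseError(f"line {lineno}: missing person_id")
        person_ids.add(pid)
        device_ids.add(did)
        try:
            ts = np.datetime64(ts_raw.replace(" ", "T"), "s")
        except ValueError as exc:
            raise ParseError(f"line {lineno}: malformed timestamp {ts_raw!r}") from exc
        try:
            conc = float(ppm_raw)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: malformed concentration {ppm_raw!r}") from exc
        if conc < 0:
            raise ParseError(f"line {lineno}: negative concentration {conc}")
        if flag == "ALARM":
            alarm_times.append(ts)
            alarm_ppm.append(conc)
            continue
        if flag == "OVERLOAD":
            conc = max(conc, 100.0)
        elif flag not in ("", "LOG"):
            raise ParseError(f"line {lineno}: unknown flag {flag!r}")
        if times and ts <= times[-1]:
            raise OrderingError(f"line {lineno}: timestamp {ts} not after {times[-1]}")
        times.append(ts)
        ppm.append(conc)
        overload.append(flag == "OVERLOAD")

    if len(person_ids) > 1 or len(device_ids) > 1:
        raise ParseError(
            f"gas log must cover one person/device, got persons={sorted(person_ids)} "
            f"devices={sorted(device_ids)}"
        )

    times_a = np.array(times, dtype="datetime64[s]")
    ppm_a = np.array(ppm, dtype=float)
    over_a = np.array(overload, dtype=bool)
    times_a, ppm_a, over_a, breaks = _refill_zero_gaps(
        times_a, ppm_a, over_a, sampling_interval_s, max_gap_s
    )
    return GasLog(
        person_id=next(iter(person_ids), ""),
        device_id=next(iter(device_ids), ""),
        sampling_interval_s=sampling_interval_s,
        times=times_a,
        ppm=ppm_a,
        overload=over_a,
        alarm_times=np.array(alarm_times, dtype="datetime64[s]"),
        alarm_ppm=np.array(alarm_ppm, dtype=float),
        segment_breaks=breaks,
    )


def read_gas_logs(source, **kwargs) -> list[GasLog]:
    """Read a CSV that may mix several persons/devices; one GasLog per pair."""
    rows = _read_rows(source)
    by_key: dict[tuple[str, str], list[str]] = {}
    for _, row in rows:
        key = (row[0].strip(), row[1].strip())
        by_key.setdefault(key, []).append(",".join(row))
    logs = []
    for key in sorted(by_key):
        text = "\n".join([",".join(GASLOG_HEADER)] + by_key[key])
        logs.append(parse_gas_log(io.StringIO(text), **kwargs))
    return logs


def _read_rows(source) -> list[tuple[int, list[str]]]:
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text and "," not in text:
            with open(text, "r", encoding="utf-8") as fh:
                text = fh.read()
    reader = csv.reader(io.StringIO(text))
    out = []
    for lineno, row in enumerate(reader, start=1):
        if not row or not "".join(row).strip():
            continue
        if lineno == 1 and row[0].strip().lower() == "person_id":
            continue
        out.append((lineno, row))
    return out


def _refill_zero_gaps(times, ppm, overload, interval_s, max_gap_s):
    """Reinstate zero-skipped gaps as explicit zeros; split on long gaps."""
    if len(times) < 2:
        return times, ppm, overload, ()
    diffs = np.diff(times).astype("timedelta64[s]").astype(float)
    bad = np.mod(diffs, interval_s)
    if not np.all((bad < 1e-6) | (interval_s - bad < 1e-6)):
        raise ParseError("timestamps are not aligned to the sampling interval")
    out_t, out_c, out_o, breaks = [times[0]], [ppm[0]], [overload[0]], []
    step = np.timedelta64(int(interval_s), "s")
    for i in range(1, len(times)):
        gap = diffs[i - 1]
        n_missing = int(round(gap / interval_s)) - 1
        if n_missing > 0 and gap <= max_gap_s:
            for k in range(1, n_missing + 1):
                out_t.append(times[i - 1] + k * step)
                out_c.append(0.0)
                out_o.append(False)
        elif n_missing > 0:
            breaks.append(len(out_t))
        out_t.append(times[i])
        out_c.append(ppm[i])
        out_o.append(overload[i])
    return (
        np.array(out_t, dtype="datetime64[s]"),
        np.array(out_c, dtype=float),
        np.array(out_o, dtype=bool),
        tuple(breaks),
    )


# ---------------------------------------------------------------------------
# Metrics


def detect_excursions(log: GasLog, threshold: float = 0.1) -> list[Excursion]:
    """Maximal runs of consecutive readings at or above ``threshold``.

    A single qualifying reading is one excursion.  Runs never join across a
    segment break (a gap too long to be a zero-skip).  Alarm-only datapoints
    are not excursions; they contribute only to the maximum.
    """
    if threshold <= 0:
        raise ConfigError("threshold must be positive")
    edge = threshold - 0.05  # half-grid: >= threshold on the 0.1 grid
    mask = log.ppm >= edge
    if not mask.any():
        return []
    idx = np.flatnonzero(mask)
    # a run breaks where indices are non-consecutive or cross a segment break
    split_after = np.diff(idx) != 1
    if log.segment_breaks:
        split_after |= np.isin(idx[1:], np.asarray(log.segment_breaks, dtype=int))
    runs = np.split(idx, np.flatnonzero(split_after) + 1)
    starts_ends = [(int(r[0]), int(r[-1])) for r in runs if len(r)]
    out = []
    for s, e in starts_ends:
        peak = float(log.ppm[s : e + 1].max())
        out.append(
            Excursion(
                start_index=s,
                end_index=e,
                peak_ppm=peak,
                n_readings=e - s + 1,
                bands_crossed=bands_for_peak(peak),
            )
        )
    return out


def band_profile(log: GasLog, mode: str = "cumulative") -> BandProfile:
    """Band-wise peak counts, durations and maximum for one log.

    mode="cumulative": an excursion increments the count of every band its
    peak reaches (a 10.1 ppm peak counts in all four bands).
    mode="max_band": an excursion increments only its highest band.
    """
    if mode not in PEAK_MODES:
        raise ConfigError(f"unknown peak-count mode {mode!r}; choose from {PEAK_MODES}")
    counts = {b: 0 for b in BAND_NAMES}
    for exc in detect_excursions(log):
        if mode == "cumulative":
            for b in exc.bands_crossed:
                counts[b] += 1
        else:
            top = highest_band(exc.peak_ppm)
            if top is not None:
                counts[top] += 1
    minutes = log.sampling_interval_s / 60.0
    in01 = (log.ppm >= DETECT_EDGE) & (log.ppm < B5_EDGE)
    in5 = log.ppm >= B5_EDGE
    return BandProfile(
        h2s01=counts["B01"],
        h2s1=counts["B1"],
        h2s5=counts["B5"],
        h2s10=counts["B10"],
        duration01_min=float(in01.sum()) * minutes,
        duration5_min=float(in5.sum()) * minutes,
        max_ppm=log.max_ppm,
    )


def compute_index(profile: BandProfile) -> float:
    """The unitless H₂S exposure index from a band profile.

    Weighted sum of peak counts per band, band durations in minutes, and the
    daily maximum; 0 for an all-censored profile.
    """
    if profile.max_ppm < DETECT_EDGE:
        return 0.0
    return (
        0.1 * profile.h2s01
        + 0.1 * profile.duration01_min
        + 1.0 * profile.h2s1
        + 5.0 * profile.h2s5
        + 5.0 * profile.duration5_min
        + 10.0 * profile.h2s10
        + profile.max_ppm
    )


def lowest_index_at_lod(
    constants: ExposureConstants,
    interval_s: float = 15.0,
    mode: str = "cumulative",
) -> float:
    """Index of a log containing exactly one reading at the LOD.

    This is the lowest index value a detected day can have, and the basis of
    the below-LOD imputation constant.
    """
    log = GasLog.from_ppm([constants.lod_ppm], sampling_interval_s=interval_s)
    return compute_index(band_profile(log, mode=mode))


def imputation_constant(
    constants: ExposureConstants,
    interval_s: float = 15.0,
    mode: str = "cumulative",
) -> float:
    """Below-LOD imputation value: lowest index at the LOD divided by √2."""
    return lowest_index_at_lod(constants, interval_s, mode) / math.sqrt(2.0)


def compute_twa(log: GasLog, constants: ExposureConstants = DATASET_BC_CONSTANTS) -> float:
    """8-h time-weighted average in ppm over a fixed 480-min denominator.

    Each reading represents one sampling interval; alarm-only datapoints
    carry no duration and are excluded.
    """
    if len(log) == 0:
        raise UndefinedStatisticError("TWA is undefined for a log with no readings")
    minutes = log.sampling_interval_s / 60.0
    return float(log.ppm.sum() * minutes / constants.twa_reference_min)


def exceeds_ceiling(log: GasLog, constants: ExposureConstants = DATASET_BC_CONSTANTS) -> bool:
    """True iff any reading or alarm datapoint exceeds the 10 ppm ceiling."""
    return log.max_ppm >= B10_EDGE
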