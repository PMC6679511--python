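"""Parsing and preprocessing of raw home-sensor event streams.

Turns timestamped on/off and detect events from bed, chair, toilet, PIR and
magnetic-contact sensors into the analysis-ready representations used by the
statistical layers: rest intervals (sessionized bed/chair presence), daily
visit counts (toilet usage), binary day traces (per-bin activation vectors)
and transmission-quality summaries.

Conventions
-----------
* Storage timestamps are UTC instants (ISO 8601 with a ``Z`` suffix on disk,
  timezone-aware :class:`datetime.datetime` in memory).
* Calendar days and time bins are defined on the subject's *local* clock; a
  day's trace therefore follows the true length of the local day, which on a
  DST transition is shorter or longer than 24 h.
* Time bins are half-open intervals ``[start, end)``.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta, timezone
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Valid event kinds per sensor type. Presence sensors (bed, chair) and
#: magnetic contacts report state transitions; toilet and PIR sensors report
#: momentary detections.
VALID_EVENTS: dict[str, frozenset[str]] = {
    "bed": frozenset({"on", "off"}),
    "chair": frozenset({"on", "off"}),
    "contact": frozenset({"on", "off"}),
    "toilet": frozenset({"detect"}),
    "pir": frozenset({"detect"}),
}

EVENT_CSV_HEADER = ["timestamp_utc", "sensor_id", "sensor_type", "event", "burst_id"]

UTC = timezone.utc


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class SensorEvent:
    """One timestamped reading from one sensor (the atomic input record)."""

    timestamp_utc: datetime
    sensor_id: str
    sensor_type: str
    event: str
    burst_id: str | None = None

    def __post_init__(self) -> None:
        if self.timestamp_utc.tzinfo is None:
            object.__setattr__(self, "timestamp_utc", self.timestamp_utc.replace(tzinfo=UTC))


@dataclass(frozen=True)
class RestInterval:
    """A contiguous presence interval after gap-merging and duration filtering.

    ``confirmed_end`` is set by :func:`confirm_rest_end` when an independent
    sensor (PIR / contact) fires shortly after the interval ends, confirming
    that the subject actually left.  ``truncated`` marks intervals closed
    artificially because the stream ended while the sensor was still on.
    """

    start: datetime
    end: datetime
    confirmed_end: bool = False
    truncated: bool = False

    @property
    def duration_minutes(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


@dataclass
class DailyCounts:
    """Ordered per-day visit counts, with optional parallel night counts.

    ``counts`` is a float Series indexed by a normalized ``DatetimeIndex``;
    days inside the covered range with no events are explicit zeros, days
    explicitly marked missing are NaN.
    """

    counts: pd.Series
    night_counts: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.sort_index().astype(float)
        if (self.counts.dropna() < 0).any():
            raise ValueError("daily counts must be non-negative")

    @property
    def dates(self) -> list[date]:
        return [ts.date() for ts in self.counts.index]

    def __len__(self) -> int:
        return len(self.counts)

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame({"date": self.counts.index.strftime("%Y-%m-%d"),
                              "count": self.counts.values})
        if self.night_counts is not None:
            frame["night_count"] = self.night_counts.reindex(self.counts.index).values
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DailyCounts":
        frame = pd.read_csv(path, parse_dates=["date"])
        counts = pd.Series(frame["count"].values, index=pd.DatetimeIndex(frame["date"]))
        night = None
        if "night_count" in frame.columns:
            night = pd.Series(frame["night_count"].values, index=counts.index)
        return cls(counts=counts, night_counts=night)


@dataclass(frozen=True)
class DayTrace:
    """Binary activation vector of one local day, one entry per time bin."""

    date: date
    bins: np.ndarray
    bin_width: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.bins, dtype=np.uint8)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("trace entries must be 0 or 1")
        object.__setattr__(self, "bins", arr)

    @property
    def n_bins(self) -> int:
        return int(self.bins.size)

    def __eq__(self, other: object) -> bool:  # ndarray needs explicit comparison
        if not isinstance(other, DayTrace):
            return NotImplemented
        return (self.date == other.date and self.bin_width == other.bin_width
                and np.array_equal(self.bins, other.bins))

    def __hash__(self) -> int:
        return hash((self.date, self.bin_width, self.bins.tobytes()))


@dataclass(frozen=True)
class QualitySummary:
    """Transmission reliability report over a deployment period.

    Percentages use conservative reporting: the ideal-day share is floored at
    one decimal (reliability is never overstated) and the severe-failure share
    is ceiled at two decimals (failures are never understated).
    """

    n_total_days: int
    n_ideal_days: int
    n_severe_days: int
    pct_ideal: float
    pct_severe: float


# ---------------------------------------------------------------------------
# Reading / writing the event CSV dialect
# ---------------------------------------------------------------------------


def _parse_timestamp(raw: str) -> datetime:
    ts = datetime.fromisoformat(raw.replace("Z", "+00:00"))
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=UTC)
    return ts.astimezone(UTC)


def read_events(path: str | Path) -> list[SensorEvent]:
    """Read an event CSV, validate each row, and return events sorted by time.

    Raises :class:`ValueError` naming the offending line for an unknown
    sensor type, an invalid sensor/event combination, or an unparsable
    timestamp.
    """
    path = Path(path)
    events: list[SensorEvent] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        header = next(reader, None)
        if header != EVENT_CSV_HEADER:
            raise ValueError(
                f"{path}: unexpected header {header!r}; expected {EVENT_CSV_HEADER!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell for cell in row):
                continue
            if len(row) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(row)}")
            raw_ts, sensor_id, sensor_type, event, burst_id = row
            try:
                ts = _parse_timestamp(raw_ts)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable timestamp {raw_ts!r}") from exc
            if sensor_type not in VALID_EVENTS:
                raise ValueError(f"{path}:{lineno}: unknown sensor_type {sensor_type!r}")
            if event not in VALID_EVENTS[sensor_type]:
                raise ValueError(
                    f"{path}:{lineno}: event {event!r} invalid for sensor_type {sensor_type!r}")
            events.append(SensorEvent(ts, sensor_id, sensor_type, event, burst_id or None))
    events.sort(key=lambda ev: (ev.timestamp_utc, ev.sensor_id, ev.event))
    return events


def write_events(events: Iterable[SensorEvent], path: str | Path) -> None:
    """Write events in the canonical CSV dialect (UTC timestamps, Z suffix)."""
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(EVENT_CSV_HEADER)
        for ev in events:
            stamp = ev.timestamp_utc.astimezone(UTC).strftime("%Y-%m-%dT%H:%M:%SZ")
            writer.writerow([stamp, ev.sensor_id, ev.sensor_type, ev.event, ev.burst_id or ""])


# ---------------------------------------------------------------------------
# Sessionization and rest intervals
# ---------------------------------------------------------------------------


def sessionize(
    events: Sequence[SensorEvent],
    gap_merge: float = 15.0,
    min_rest_duration: float = 10.0,
) -> list[RestInterval]:
    """Merge raw on/off events of one presence sensor into rest intervals.

    on -> off pairs form raw intervals; consecutive intervals separated by a
    gap shorter than ``gap_merge`` minutes are merged (brief exits do not end
    a rest); merged intervals shorter than ``min_rest_duration`` minutes are
    discarded as incidental presences unrelated to actual rest.

    Robustness to lost packets: a repeated "on" extends the open interval, an
    orphan "off" is dropped with a warning, and a dangling "on" at the end of
    the stream closes at the last observed event time and is flagged
    ``truncated``.
    """
    relevant = sorted(
        (ev for ev in events if ev.event in ("on", "off")),
        key=lambda ev: ev.timestamp_utc,
    )
    if not relevant:
        return []
    sensors = {ev.sensor_id for ev in relevant}
    if len(sensors) > 1:
        raise ValueError(f"sessionize expects events from a single sensor, got {sorted(sensors)}")

    raw: list[tuple[datetime, datetime, bool]] = []
    open_start: datetime | None = None
    for ev in relevant:
        if ev.event == "on":
            if open_start is None:
                open_start = ev.timestamp_utc
            # repeated "on": the interval is already open, keep the earlier start
        else:
            if open_start is None:
                logger.warning("orphan 'off' at %s dropped", ev.timestamp_utc.isoformat())
            elif ev.timestamp_utc > open_start:
                raw.append((open_start, ev.timestamp_utc, False))
                open_start = None
            else:
                open_start = None
    if open_start is not None:
        last_ts = relevant[-1].timestamp_utc
        if last_ts > open_start:
            raw.append((open_start, last_ts, True))
        logger.warning("dangling 'on' at %s closed at end of stream", open_start.isoformat())

    merged: list[tuple[datetime, datetime, bool]] = []
    for start, end, trunc in raw:
        if merged and (start - merged[-1][1]).total_seconds() / 60.0 < gap_merge:
            prev_start, prev_end, prev_trunc = merged[-1]
            merged[-1] = (prev_start, max(prev_end, end), prev_trunc or trunc)
        else:
            merged.append((start, end, trunc))

    return [
        RestInterval(start=start, end=end, truncated=trunc)
        for start, end, trunc in merged
        if (end - start).total_seconds() / 60.0 >= min_rest_duration
    ]


def confirm_rest_end(
    intervals: Sequence[RestInterval],
    other_events: Sequence[SensorEvent],
    confirm_window: float = 10.0,
) -> list[RestInterval]:
    """Fuse PIR/contact activity to confirm that each rest actually ended.

    An interval is confirmed when an independent motion or contact event
    occurs within ``confirm_window`` minutes after the interval end.
    """
    witness_times = sorted(
        ev.timestamp_utc for ev in other_events if ev.sensor_type in ("pir", "contact")
    )
    stamps = np.array([t.timestamp() for t in witness_times])
    out = []
    for iv in intervals:
        lo, hi = iv.end.timestamp(), iv.end.timestamp() + confirm_window * 60.0
        i = np.searchsorted(stamps, lo, side="left")
        confirmed = bool(i < stamps.size and stamps[i] <= hi)
        out.append(replace(iv, confirmed_end=confirmed))
    return out


# ---------------------------------------------------------------------------
# Daily visit counts
# ---------------------------------------------------------------------------


def daily_visit_counts(
    events: Sequence[SensorEvent],
    visit_gap: float = 5.0,
    tz: str = "UTC",
    night_window: tuple[time, time] = (time(0, 0), time(6, 0)),
    start: date | None = None,
    end: date | None = None,
) -> DailyCounts:
    """Cluster momentary detections into visits and count them per local day.

    Consecutive detections separated by less than ``visit_gap`` minutes belong
    to the same visit; a visit's date is the local calendar date of its first
    detection.  Days inside the covered range with no visits count 0.  Night
    counts tally visits whose first detection falls in ``night_window`` (a
    half-open local-time range).
    """
    detections = sorted(
        (ev.timestamp_utc for ev in events if ev.event == "detect"),
    )
    zone = ZoneInfo(tz)
    visit_starts: list[datetime] = []
    prev: datetime | None = None
    for ts in detections:
        if prev is None or (ts - prev).total_seconds() / 60.0 >= visit_gap:
            visit_starts.append(ts)
        prev = ts

    local_starts = [ts.astimezone(zone) for ts in visit_starts]
    if start is None:
        if not local_starts:
            raise ValueError("no detections and no explicit date range")
        start = min(ls.date() for ls in local_starts)
    if end is None:
        end = max(ls.date() for ls in local_starts) if local_starts else start

    index = pd.date_range(start, end, freq="D")
    counts = pd.Series(0.0, index=index)
    nights = pd.Series(0.0, index=index)
    nw_lo, nw_hi = night_window
    for ls in local_starts:
        key = pd.Timestamp(ls.date())
        if key not in counts.index:
            continue
        counts[key] += 1
        if nw_lo <= ls.time() < nw_hi:
            nights[key] += 1
    return DailyCounts(counts=counts, night_counts=nights)


# ---------------------------------------------------------------------------
# Day traces (per-bin activation vectors)
# ---------------------------------------------------------------------------


def _local_day_bounds(day: date, zone: ZoneInfo) -> tuple[datetime, datetime]:
    start = datetime.combine(day, time(0, 0), tzinfo=zone).astimezone(UTC)
    end = datetime.combine(day + timedelta(days=1), time(0, 0), tzinfo=zone).astimezone(UTC)
    return start, end


def bin_day_trace(
    source: Sequence[RestInterval] | Sequence[SensorEvent],
    day: date,
    bin_width: int = 30,
    tmin: float = 5.0,
    tz: str = "UTC",
) -> DayTrace:
    """Discretize presence on one local day into a binary per-bin vector.

    Bin ``j`` is 1 iff the sensor was active for at least ``tmin`` minutes in
    total within bin ``j`` (half-open ``[start, end)`` in local time) on that
    local calendar date.  On DST-transition days the trace keeps the true
    number of bins of the local day rather than forcing ``1440/bin_width``.
    """
    if tmin > bin_width:
        raise ValueError(f"tmin ({tmin}) must not exceed bin_width ({bin_width})")
    if 1440 % bin_width != 0:
        raise ValueError(f"bin_width ({bin_width}) must divide 1440")

    if source and isinstance(source[0], SensorEvent):
        intervals = sessionize(source, gap_merge=0.0, min_rest_duration=0.0)
    else:
        intervals = list(source)  # type: ignore[arg-type]

    zone = ZoneInfo(tz)
    day_start, day_end = _local_day_bounds(day, zone)
    day_seconds = (day_end - day_start).total_seconds()
    n_bins = int(round(day_seconds / (bin_width * 60.0)))

    active = np.zeros(n_bins)
    width_s = bin_width * 60.0
    for iv in intervals:
        lo = max((iv.start - day_start).total_seconds(), 0.0)
        hi = min((iv.end - day_start).total_seconds(), day_seconds)
        if hi <= lo:
            continue
        first = int(lo // width_s)
        last = int(math.ceil(hi / width_s))
        for j in range(first, min(last, n_bins)):
            overlap = min(hi, (j + 1) * width_s) - max(lo, j * width_s)
            if overlap > 0:
                active[j] += overlap

    bins = (active >= tmin * 60.0 - 1e-9).astype(np.uint8)
    return DayTrace(date=day, bins=bins, bin_width=bin_width)


def traces_to_csv(traces: Sequence[DayTrace], path: str | Path) -> None:
    """Serialize day traces: one row per day, bins as a 0/1 string."""
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["date", "bin_width", "bins"])
        for tr in traces:
            writer.writerow([tr.date.isoformat(), tr.bin_width,
                             "".join(str(int(b)) for b in tr.bins)])


def traces_from_csv(path: str | Path) -> list[DayTrace]:
    traces = []
    with Path(path).open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        for row in reader:
            traces.append(DayTrace(
                date=date.fromisoformat(row["date"]),
                bins=np.array([int(c) for c in row["bins"]], dtype=np.uint8),
                bin_width=int(row["bin_width"]),
            ))
    return traces


# ---------------------------------------------------------------------------
# Transmission quality
# ---------------------------------------------------------------------------


def transmission_quality(
    n_total_days: int, n_ideal_days: int, n_severe_days: int
) -> QualitySummary:
    """Summarize deployment reliability from day counts.

    Ideal days completed every scheduled transmission burst; severe days
    exceeded the sensors' local buffering capacity (roughly one day of data),
    so data were actually lost rather than merely delayed.  Percentages are
    reported conservatively: ideal share floored to 1 decimal, severe share
    ceiled to 2 decimals.
    """
    if n_total_days <= 0:
        raise ValueError("n_total_days must be positive")
    if not (0 <= n_ideal_days <= n_total_days and 0 <= n_severe_days <= n_total_days):
        raise ValueError("day counts must lie in [0, n_total_days]")
    pct_ideal = math.floor(Fraction(1000 * n_ideal_days, n_total_days)) / 10
    pct_severe = math.ceil(Fraction(10000 * n_severe_days, n_total_days)) / 100
    return QualitySummary(
        n_total_days=n_total_days,
        n_ideal_days=n_ideal_days,
        n_severe_days=n_severe_days,
        pct_ideal=pct_ideal,
        pct_severe=pct_severe,
    )


def _ceil_to_period(ts: datetime, period_minutes: int) -> datetime:
    period_s = period_minutes * 60
    stamp = ts.timestamp()
    return datetime.fromtimestamp(math.ceil(stamp / period_s) * period_s, UTC)


def assess_transmission(
    events: Sequence[SensorEvent],
    start_date: date,
    n_days: int,
    period_minutes: int = 60,
) -> tuple[QualitySummary, set[date], set[date]]:
    """Classify each UTC day of a covered range from burst annotations.

    A day is *severe* when no events survive for it (local buffering was
    exceeded and data were lost); *missed* when any event was carried by a
    burst later than its nominal schedule (data delayed, then retransmitted);
    *ideal* otherwise.  Returns the summary plus the missed and severe day
    sets.
    """
    days = [start_date + timedelta(days=i) for i in range(n_days)]
    seen: set[date] = set()
    delayed: set[date] = set()
    for ev in events:
        day = ev.timestamp_utc.astimezone(UTC).date()
        seen.add(day)
        if ev.burst_id:
            nominal = _ceil_to_period(ev.timestamp_utc, period_minutes)
            actual = _parse_timestamp(ev.burst_id)
            if actual > nominal:
                delayed.add(day)
    severe = {d for d in days if d not in seen}
    missed = {d for d in days if d in delayed} | severe
    ideal = [d for d in days if d not in missed]
    summary = transmission_quality(len(days), len(ideal), len(severe))
    return summary, missed, severe
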