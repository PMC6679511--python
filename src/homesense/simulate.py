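"""Seeded generators for synthetic home-sensor data with known ground truth.

The generators are the exact inverses of the analysis models so that
parameter recovery is well-posed: day traces are drawn from a mixture of
per-bin Bernoulli "modes" (the quantity the sensor-profile layer estimates),
and daily visit counts are independent Poisson draws with a log-linear mean
combining a baseline, an optional linear drift, an optional abrupt step and
per-day outlier multipliers (the covariate structure the rolling regression
fits).  Every operation takes an explicit seed and is fully reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence
from zoneinfo import ZoneInfo

import numpy as np

from .events import UTC, DailyCounts, DayTrace, SensorEvent

import pandas as pd

__all__ = [
    "ModeSpec",
    "CountScenario",
    "GroundTruth",
    "sample_day_traces",
    "traces_to_events",
    "simulate_daily_counts",
    "counts_to_events",
    "inject_transmission_schedule",
]


@dataclass(frozen=True)
class ModeSpec:
    """One recurrent daily routine: a per-bin presence probability vector.

    ``weight`` is the mixing proportion of the mode within a mode set (a
    subject may alternate between e.g. a night-only routine and a
    night-plus-afternoon-nap routine).
    """

    name: str
    bin_probabilities: tuple[float, ...]
    weight: float = 1.0

    def __post_init__(self) -> None:
        probs = tuple(float(p) for p in self.bin_probabilities)
        if not probs:
            raise ValueError(f"mode {self.name!r}: empty probability vector")
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError(f"mode {self.name!r}: probabilities must lie in [0, 1]")
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"mode {self.name!r}: weight must lie in [0, 1]")
        object.__setattr__(self, "bin_probabilities", probs)

    @property
    def n_bins(self) -> int:
        return len(self.bin_probabilities)


def night_mode(name: str = "night", n_bins: int = 48, p_active: float = 0.95,
               night_bins: Sequence[int] | None = None, p_background: float = 0.02,
               weight: float = 1.0) -> ModeSpec:
    """Convenience constructor: high presence probability overnight only.

    The default night span covers 21:30-07:00 on a 30-min grid (bins 43-47
    and 0-13), mirroring a typical sleep routine.
    """
    if night_bins is None:
        night_bins = list(range(0, 14)) + list(range(43, n_bins))
    probs = [p_background] * n_bins
    for j in night_bins:
        probs[j] = p_active
    return ModeSpec(name=name, bin_probabilities=tuple(probs), weight=weight)


def nap_mode(name: str = "night+nap", n_bins: int = 48, p_active: float = 0.95,
             nap_bins: Sequence[int] | None = None, weight: float = 1.0,
             p_background: float = 0.02) -> ModeSpec:
    """Night routine plus an early-afternoon nap (13:30-15:00 by default)."""
    if nap_bins is None:
        nap_bins = range(27, 30)
    base = night_mode(name=name, n_bins=n_bins, p_active=p_active,
                      p_background=p_background, weight=weight)
    probs = list(base.bin_probabilities)
    for j in nap_bins:
        probs[j] = p_active
    return ModeSpec(name=name, bin_probabilities=tuple(probs), weight=weight)


@dataclass(frozen=True)
class CountScenario:
    """Generative scenario for a daily count series.

    Day ``d`` (1-based) has Poisson mean
    ``baseline_rate * exp(linear_log_slope * (d-1)/(n_days-1))
    * exp(abrupt_log_effect * 1[d >= abrupt_start_day]) * outlier_days.get(d, 1)``.
    ``linear_log_slope`` is the log fold-change over the whole period.
    """

    n_days: int
    baseline_rate: float
    linear_log_slope: float = 0.0
    abrupt_start_day: int | None = None
    abrupt_log_effect: float = 0.0
    outlier_days: Mapping[int, float] = field(default_factory=dict)
    seed: int = 0
    start_date: date = date(2024, 1, 1)

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be positive")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.abrupt_start_day is not None and not (1 <= self.abrupt_start_day <= self.n_days):
            raise ValueError("abrupt_start_day must lie in [1, n_days]")
        for d, mult in self.outlier_days.items():
            if not (1 <= d <= self.n_days):
                raise ValueError(f"outlier day {d} outside [1, n_days]")
            if mult <= 0:
                raise ValueError(f"outlier multiplier for day {d} must be > 0")

    def expected_rates(self) -> np.ndarray:
        d = np.arange(1, self.n_days + 1, dtype=float)
        ramp = (d - 1) / (self.n_days - 1) if self.n_days > 1 else np.zeros(1)
        log_mu = np.log(self.baseline_rate) + self.linear_log_slope * ramp
        if self.abrupt_start_day is not None:
            log_mu = log_mu + self.abrupt_log_effect * (d >= self.abrupt_start_day)
        rates = np.exp(log_mu)
        for day, mult in self.outlier_days.items():
            rates[day - 1] *= mult
        return rates


@dataclass
class GroundTruth:
    """Sidecar record of what the generator actually did, for recovery tests."""

    mode_labels: list[str] | None = None
    deviant_days: set[int] = field(default_factory=set)
    severe_failure_days: set[date] = field(default_factory=set)
    missed_days: set[date] = field(default_factory=set)
    expected_rates: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mode_labels": self.mode_labels,
            "deviant_days": sorted(self.deviant_days),
            "severe_failure_days": sorted(d.isoformat() for d in self.severe_failure_days),
            "missed_days": sorted(d.isoformat() for d in self.missed_days),
            "expected_rates": (None if self.expected_rates is None
                               else [float(r) for r in self.expected_rates]),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                              encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            mode_labels=payload.get("mode_labels"),
            deviant_days=set(payload.get("deviant_days", [])),
            severe_failure_days={date.fromisoformat(d)
                                 for d in payload.get("severe_failure_days", [])},
            missed_days={date.fromisoformat(d) for d in payload.get("missed_days", [])},
            expected_rates=(None if payload.get("expected_rates") is None
                            else np.asarray(payload["expected_rates"], dtype=float)),
        )


# ---------------------------------------------------------------------------
# Day traces
# ---------------------------------------------------------------------------


def sample_day_traces(
    modes: Sequence[ModeSpec],
    n_days: int,
    seed: int,
    *,
    deviant_mode: ModeSpec | None = None,
    n_deviant: int = 0,
    start_date: date = date(2024, 1, 1),
) -> tuple[list[DayTrace], GroundTruth]:
    """Draw one day trace per day from a mixture of Bernoulli modes.

    Each day first picks a mode according to the mode weights, then each bin
    is an independent Bernoulli draw with that mode's bin probability.  When
    ``deviant_mode`` is given, ``n_deviant`` days (chosen uniformly without
    replacement) are drawn from it instead and recorded as deviant.
    """
    if not modes:
        raise ValueError("at least one mode is required")
    n_bins = modes[0].n_bins
    for mode in modes:
        if mode.n_bins != n_bins:
            raise ValueError(
                f"mode {mode.name!r} has {mode.n_bins} bins, expected {n_bins}")
    if 1440 % n_bins != 0:
        raise ValueError(f"number of bins ({n_bins}) must divide 1440")
    weights = np.array([m.weight for m in modes], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"mode weights must sum to 1, got {weights.sum():.6f}")
    if deviant_mode is not None and deviant_mode.n_bins != n_bins:
        raise ValueError(f"mode {deviant_mode.name!r} has {deviant_mode.n_bins} bins, "
                         f"expected {n_bins}")
    if n_deviant < 0 or n_deviant > n_days:
        raise ValueError("n_deviant must lie in [0, n_days]")

    rng = np.random.default_rng(seed)
    mode_idx = rng.choice(len(modes), size=n_days, p=weights)
    deviant_days: set[int] = set()
    if deviant_mode is not None and n_deviant > 0:
        deviant_days = set(int(i) for i in rng.choice(n_days, size=n_deviant, replace=False))

    bin_width = 1440 // n_bins
    traces: list[DayTrace] = []
    labels: list[str] = []
    for i in range(n_days):
        if i in deviant_days:
            probs = np.asarray(deviant_mode.bin_probabilities)  # type: ignore[union-attr]
            labels.append(deviant_mode.name)  # type: ignore[union-attr]
        else:
            probs = np.asarray(modes[mode_idx[i]].bin_probabilities)
            labels.append(modes[mode_idx[i]].name)
        bins = (rng.random(n_bins) < probs).astype(np.uint8)
        traces.append(DayTrace(date=start_date + timedelta(days=i), bins=bins,
                               bin_width=bin_width))
    return traces, GroundTruth(mode_labels=labels, deviant_days=deviant_days)


def traces_to_events(
    traces: Sequence[DayTrace],
    sensor_id: str = "bed-1",
    *,
    sensor_type: str = "bed",
    fill_fraction: float = 1.0,
    tz: str = "UTC",
    seed: int = 0,
) -> list[SensorEvent]:
    """Expand day traces into raw on/off event pairs, one pair per active bin.

    Each active bin emits an interval covering ``fill_fraction`` of the bin;
    the free slack (when ``fill_fraction < 1``) is placed at a seeded uniform
    offset inside the bin.  Round-tripping through ``bin_day_trace`` with the
    same bin width and ``tmin <= fill_fraction * bin_width`` recovers the
    traces exactly.
    """
    if not (0.0 < fill_fraction <= 1.0):
        raise ValueError("fill_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    zone = ZoneInfo(tz)
    events: list[SensorEvent] = []
    for tr in traces:
        day_start = datetime.combine(tr.date, time(0, 0), tzinfo=zone).astimezone(UTC)
        width = timedelta(minutes=tr.bin_width)
        dur = timedelta(minutes=tr.bin_width * fill_fraction)
        for j, bit in enumerate(tr.bins):
            if not bit:
                continue
            slack_min = tr.bin_width * (1.0 - fill_fraction)
            offset = timedelta(minutes=float(rng.uniform(0.0, slack_min))) if slack_min else timedelta()
            on_ts = day_start + j * width + offset
            events.append(SensorEvent(on_ts, sensor_id, sensor_type, "on"))
            events.append(SensorEvent(on_ts + dur, sensor_id, sensor_type, "off"))
    # same tie-break as read_events: at equal instants "off" precedes "on",
    # closing the previous bin's interval before the next one opens
    events.sort(key=lambda ev: (ev.timestamp_utc, ev.sensor_id, ev.event))
    return events


# ---------------------------------------------------------------------------
# Daily counts
# ---------------------------------------------------------------------------


def simulate_daily_counts(scenario: CountScenario) -> tuple[DailyCounts, GroundTruth]:
    """Draw independent Poisson counts with the scenario's per-day means."""
    rates = scenario.expected_rates()
    rng = np.random.default_rng(scenario.seed)
    counts = rng.poisson(rates).astype(float)
    index = pd.date_range(scenario.start_date, periods=scenario.n_days, freq="D")
    series = pd.Series(counts, index=index)
    return DailyCounts(counts=series), GroundTruth(expected_rates=rates)


def counts_to_events(
    counts: DailyCounts,
    sensor_id: str = "toilet-1",
    *,
    seed: int = 0,
    visit_gap: float = 5.0,
    tz: str = "UTC",
) -> list[SensorEvent]:
    """Synthesize toilet detect events realizing the given daily visit counts.

    Visits are spread evenly over the local day (so inter-visit gaps exceed
    ``visit_gap``); each visit emits 1-3 detections one minute apart, which
    re-cluster into a single visit downstream.
    """
    rng = np.random.default_rng(seed)
    zone = ZoneInfo(tz)
    events: list[SensorEvent] = []
    for stamp, value in counts.counts.items():
        if np.isnan(value) or value <= 0:
            continue
        c = int(value)
        if 1440.0 / c - 2.0 < visit_gap:
            raise ValueError(f"{c} visits/day cannot keep {visit_gap}-min separation")
        day_start = datetime.combine(stamp.date(), time(0, 0), tzinfo=zone).astimezone(UTC)
        spacing = 1440.0 / c
        for k in range(c):
            visit_start = day_start + timedelta(minutes=(k + 0.5) * spacing)
            for j in range(int(rng.integers(1, 4))):
                events.append(SensorEvent(visit_start + timedelta(minutes=j),
                                          sensor_id, "toilet", "detect"))
    events.sort(key=lambda ev: ev.timestamp_utc)
    return events


# ---------------------------------------------------------------------------
# Transmission schedule
# ---------------------------------------------------------------------------


def inject_transmission_schedule(
    events: Sequence[SensorEvent],
    period_minutes: int = 60,
    missed_days: set[date] | None = None,
    severe_days: set[date] | None = None,
    seed: int = 0,
) -> tuple[list[SensorEvent], GroundTruth]:
    """Tag events with the burst that carried them; inject transmission faults.

    Sensors buffer readings and transmit them in periodic bursts.  On a
    *missed* day one scheduled burst fails and its payload is carried by the
    next burst instead (data delayed, not lost).  On a *severe* day the
    outage exceeds the local one-day buffer and the day's events are lost
    entirely.  ``severe_days`` must be a subset of ``missed_days``.
    """
    missed_days = set(missed_days or ())
    severe_days = set(severe_days or ())
    if not severe_days <= missed_days:
        raise ValueError("severe_days must be a subset of missed_days")
    rng = np.random.default_rng(seed)

    import math as _math

    def nominal_burst(ts: datetime) -> datetime:
        period_s = period_minutes * 60
        return datetime.fromtimestamp(_math.ceil(ts.timestamp() / period_s) * period_s, UTC)

    # choose, per non-severe missed day, which scheduled burst is delayed
    bursts_by_day: dict[date, set[datetime]] = {}
    for ev in events:
        day = ev.timestamp_utc.astimezone(UTC).date()
        if day in missed_days and day not in severe_days:
            bursts_by_day.setdefault(day, set()).add(nominal_burst(ev.timestamp_utc))
    delayed_burst: dict[date, datetime] = {
        day: sorted(bursts)[int(rng.integers(0, len(bursts)))]
        for day, bursts in sorted(bursts_by_day.items())
    }

    out: list[SensorEvent] = []
    for ev in events:
        day = ev.timestamp_utc.astimezone(UTC).date()
        if day in severe_days:
            continue
        burst = nominal_burst(ev.timestamp_utc)
        if delayed_burst.get(day) == burst:
            burst = burst + timedelta(minutes=period_minutes)
        out.append(SensorEvent(ev.timestamp_utc, ev.sensor_id, ev.sensor_type, ev.event,
                               burst_id=burst.strftime("%Y-%m-%dT%H:%M:%SZ")))
    truth = GroundTruth(severe_failure_days=severe_days, missed_days=missed_days)
    return out, truth
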