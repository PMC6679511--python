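"""End-to-end pipeline: raw event log -> caregiver-facing behavior report.

The report carries only derived summaries (trend alerts, unexplained dates,
cluster prototypes, deviant dates, data-quality figures) and never raw event
payloads, matching the pseudonymized synthesis-only delivery of the
monitoring platform it feeds.
"""

from __future__ import annotations

import json
import logging
import sys
from datetime import date, time
from pathlib import Path
from typing import Any, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from . import events as ev
from . import profiles as pr
from . import trends as tr

logger = logging.getLogger("homesense.pipeline")

REPORT_SCHEMA_VERSION = "1.0"


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and the input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


class PipelineConfig(BaseModel):
    """All stage parameters, validated up front against stage preconditions."""

    events_csv: str
    subject: str = "anonymous"
    timezone: str = "UTC"
    seed: int = 0
    output_dir: str = "."

    # binning / profiles
    bin_width: int = 30
    tmin: float = 5.0
    ci: str = "wilson"
    epsilon: Optional[float] = None

    # sessionization
    gap_merge: float = 15.0
    min_rest_duration: float = 10.0
    confirm_window: float = 10.0

    # counts
    visit_gap: float = 5.0
    night_window: tuple[str, str] = ("00:00", "06:00")

    # rolling regression
    window: int = 30
    abrupt: int = 5
    intermediate: int = 10
    alpha: float = 0.05
    level: float = 0.95
    holdout_last: bool = False

    # clustering / novelty
    n_sam: int = 5
    k_max: int = 8
    linkage: str = "average"

    # transmission
    period_minutes: int = 60

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.tmin > self.bin_width:
            raise ValueError("tmin must not exceed bin_width")
        if 1440 % self.bin_width != 0:
            raise ValueError("bin_width must divide 1440")
        tr.DesignSpec(window=self.window, abrupt=self.abrupt,
                      intermediate=self.intermediate, alpha=self.alpha,
                      level=self.level)
        if self.ci not in ("wilson", "beta"):
            raise ValueError("ci must be 'wilson' or 'beta'")
        if self.linkage not in ("average", "complete"):
            raise ValueError("linkage must be 'average' or 'complete'")
        if self.epsilon is not None and not (0 < self.epsilon < 0.5):
            raise ValueError("epsilon must lie in (0, 0.5)")
        for field_name in ("gap_merge", "min_rest_duration", "confirm_window",
                           "visit_gap"):
            if getattr(self, field_name) < 0:
                raise ValueError(f"{field_name} must be non-negative")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**payload)

    def night_window_times(self) -> tuple[time, time]:
        lo, hi = self.night_window
        return time.fromisoformat(lo), time.fromisoformat(hi)


# --- report schema (pydantic models double as the published JSON schema) ---


class TrendAlert(BaseModel):
    date: str
    abrupt_effect_pct: Optional[float] = None
    linear_effect_pct: Optional[float] = None


class TrendSection(BaseModel):
    n_days_analyzed: int = 0
    alerts: list[TrendAlert] = Field(default_factory=list)
    unexplained_dates: list[str] = Field(default_factory=list)
    skipped_dates: list[str] = Field(default_factory=list)


class ClusterSummary(BaseModel):
    cluster_id: int
    n_days: int
    mean_active_bins: float


class RestSection(BaseModel):
    n_days: int = 0
    n_rest_intervals: int = 0
    pct_confirmed_ends: Optional[float] = None
    n_clusters: Optional[int] = None
    silhouette: Optional[float] = None
    clusters: list[ClusterSummary] = Field(default_factory=list)
    novelty_threshold: Optional[float] = None
    deviant_dates: list[dict[str, Any]] = Field(default_factory=list)


class QualitySection(BaseModel):
    n_total_days: int
    n_ideal_days: int
    n_severe_days: int
    pct_ideal: float
    pct_severe: float


class BehaviorReport(BaseModel):
    """Synthesis report delivered to the caregiver; no raw payloads."""

    schema_version: str = REPORT_SCHEMA_VERSION
    subject: str
    period_start: str
    period_end: str
    parameters: dict[str, Any]
    toilet_trends: Optional[TrendSection] = None
    bed_rests: Optional[RestSection] = None
    quality: Optional[QualitySection] = None

    def to_text(self) -> str:
        lines = [
            f"Behavior report for {self.subject}",
            f"Period: {self.period_start} .. {self.period_end}",
            "",
        ]
        if self.quality:
            q = self.quality
            lines += [
                "Data quality:",
                f"  {q.n_ideal_days}/{q.n_total_days} ideal days ({q.pct_ideal}%), "
                f"{q.n_severe_days} severe transmission failures ({q.pct_severe}%)",
                "",
            ]
        if self.toilet_trends:
            t = self.toilet_trends
            lines.append(f"Toilet usage ({t.n_days_analyzed} analysis days):")
            if t.alerts:
                for a in t.alerts:
                    bits = []
                    if a.abrupt_effect_pct is not None:
                        bits.append(f"abrupt {a.abrupt_effect_pct:+.1f}%")
                    if a.linear_effect_pct is not None:
                        bits.append(f"linear {a.linear_effect_pct:+.1f}%")
                    lines.append(f"  alert {a.date}: " + ", ".join(bits))
            else:
                lines.append("  no trend alerts")
            lines.append(
                "  unexplained days: " + (", ".join(t.unexplained_dates) or "none"))
            lines.append("")
        if self.bed_rests:
            r = self.bed_rests
            lines.append(f"Bed rests ({r.n_days} days, {r.n_rest_intervals} rest intervals):")
            if r.n_clusters:
                lines.append(f"  {r.n_clusters} routine cluster(s), "
                             f"silhouette {r.silhouette if r.silhouette is not None else 'n/a'}")
            if r.novelty_threshold is not None:
                lines.append(f"  novelty threshold {r.novelty_threshold:.2f}; deviant days: "
                             + (", ".join(d["date"] for d in r.deviant_dates) or "none"))
            lines.append("")
        return "\n".join(lines)


def report_json_schema() -> dict:
    """The published JSON schema the report validates against."""
    return BehaviorReport.model_json_schema()


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
    return wrap


def run_pipeline(config: PipelineConfig) -> BehaviorReport:
    """Run every analysis stage and assemble the behavior report.

    Deterministic given the configuration (and its seed); writes
    ``report.json`` and ``report.txt`` into the output directory.  Any stage
    error aborts with a message naming the stage.
    """
    logger.info("[read_events] reading %s", config.events_csv)
    all_events = _stage("read_events")(ev.read_events, config.events_csv)
    if not all_events:
        raise PipelineError("read_events", f"no events in {config.events_csv}")

    by_type: dict[str, list[ev.SensorEvent]] = {}
    for e in all_events:
        by_type.setdefault(e.sensor_type, []).append(e)

    first_day = min(e.timestamp_utc for e in all_events).date()
    last_day = max(e.timestamp_utc for e in all_events).date()
    n_days = (last_day - first_day).days + 1

    # --- transmission quality ---
    quality_section = None
    if any(e.burst_id for e in all_events):
        summary, _, _ = _stage("assess_transmission")(
            ev.assess_transmission, all_events, first_day, n_days,
            config.period_minutes)
        quality_section = QualitySection(**summary.__dict__)

    # --- toilet counts -> rolling regression ---
    trend_section = None
    toilet = by_type.get("toilet", [])
    if toilet:
        logger.info("[daily_visit_counts] %d toilet events", len(toilet))
        counts = _stage("daily_visit_counts")(
            ev.daily_visit_counts, toilet, config.visit_gap, config.timezone,
            config.night_window_times())
        if len(counts) >= config.window:
            spec = tr.DesignSpec(window=config.window, abrupt=config.abrupt,
                                 intermediate=config.intermediate,
                                 alpha=config.alpha, level=config.level)
            logger.info("[rolling_analysis] %d days", len(counts))
            results = _stage("rolling_analysis")(
                tr.rolling_analysis, counts, spec,
                holdout_last=config.holdout_last)
            trend_section = TrendSection(
                n_days_analyzed=sum(1 for r in results if not r.skipped),
                alerts=[TrendAlert(date=r.date.isoformat(),
                                   abrupt_effect_pct=r.abrupt_effect_pct,
                                   linear_effect_pct=r.linear_effect_pct)
                        for r in results if r.alert],
                unexplained_dates=[r.date.isoformat()
                                   for r in results if r.unexplained],
                skipped_dates=[r.date.isoformat() for r in results if r.skipped],
            )
        else:
            trend_section = TrendSection(n_days_analyzed=0)

    # --- bed rests -> profiles, clustering, novelty ---
    rest_section = None
    bed = by_type.get("bed", [])
    if bed:
        by_sensor: dict[str, list[ev.SensorEvent]] = {}
        for e in bed:
            by_sensor.setdefault(e.sensor_id, []).append(e)
        intervals: list[ev.RestInterval] = []
        for sensor_events in by_sensor.values():
            intervals.extend(_stage("sessionize")(
                ev.sessionize, sensor_events, config.gap_merge,
                config.min_rest_duration))
        intervals.sort(key=lambda iv: iv.start)
        witnesses = by_type.get("pir", []) + by_type.get("contact", [])
        intervals = _stage("confirm_rest_end")(
            ev.confirm_rest_end, intervals, witnesses, config.confirm_window)

        from datetime import timedelta
        from zoneinfo import ZoneInfo

        from .events import _local_day_bounds
        # score only fully observed local days: a day whose midnight-to-
        # midnight span sticks out of the observation window is censored and
        # would yield a spuriously deviant partial trace
        zone = ZoneInfo(config.timezone)
        min_ts = min(e.timestamp_utc for e in all_events)
        max_ts = max(e.timestamp_utc for e in all_events)
        days = [
            d for d in (first_day + timedelta(days=i) for i in range(n_days))
            if _local_day_bounds(d, zone)[0] >= min_ts
            and _local_day_bounds(d, zone)[1] <= max_ts
        ] or [first_day]
        traces = [
            _stage("bin_day_trace")(ev.bin_day_trace, intervals, day,
                                    config.bin_width, config.tmin, config.timezone)
            for day in days
        ]
        rest_section = RestSection(
            n_days=len(traces),
            n_rest_intervals=len(intervals),
            pct_confirmed_ends=(round(100.0 * sum(iv.confirmed_end for iv in intervals)
                                      / len(intervals), 1) if intervals else None),
        )
        if len(traces) >= 2 * config.n_sam:
            clustering = _stage("cluster_day_traces")(
                pr.cluster_day_traces, traces, config.n_sam, config.k_max,
                config.linkage)
            rest_section.n_clusters = clustering.n_clus
            rest_section.silhouette = (None if clustering.silhouette is None
                                       else round(clustering.silhouette, 4))
            rest_section.clusters = [
                ClusterSummary(cluster_id=i,
                               n_days=int((clustering.labels == i).sum()),
                               mean_active_bins=round(float(p.p_hat.sum()), 2))
                for i, p in enumerate(clustering.prototypes)
            ]
            prototype = clustering.prototypes[0]
            scores = _stage("novelty_score")(
                pr.novelty_scores, traces, prototype, config.epsilon)
            novelty = _stage("iqr_outlier_threshold")(
                pr.iqr_outlier_threshold, scores,
                [t.date for t in traces])
            rest_section.novelty_threshold = round(novelty.threshold, 4)
            rest_section.deviant_dates = [
                {"date": d.isoformat(), "ns": round(float(s), 4)}
                for d, s, flag in zip(novelty.dates, novelty.scores, novelty.outlier)
                if flag
            ]

    report = BehaviorReport(
        subject=config.subject,
        period_start=first_day.isoformat(),
        period_end=last_day.isoformat(),
        parameters=config.model_dump(),
        toilet_trends=trend_section,
        bed_rests=rest_section,
        quality=quality_section,
    )

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(report.model_dump(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    (outdir / "report.txt").write_text(report.to_text(), encoding="utf-8")
    logger.info("[report] wrote %s", outdir / "report.json")
    return report


def configure_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )
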