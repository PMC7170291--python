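"""Validation statistics: sensitivity against a service log, CV trending.

Detection performance is judged at *instance* granularity: a service event
(an engineering intervention for image quality) is a true positive if any
of that station's records inside the event's date span exceeds the alert
threshold, and a false positive is a maximal run of consecutive alerting
days that overlaps no event — multi-day repairs produce several poor floods
for one issue, so a run counts once.  Day-to-day consistency is tracked
with the coefficient of variation of a station's scores and its fleet-wide
aggregate (mean per-station SD over mean per-station mean).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ServiceEvent",
    "SensitivityReport",
    "read_service_log",
    "match_alerts_to_events",
    "system_cv",
    "fleet_cv",
    "trend_table",
]


@dataclass(frozen=True)
class ServiceEvent:
    """One service/intervention entry from the engineering log."""

    station: str
    start_date: date
    end_date: date
    image_quality_related: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError("event start must not follow its end")

    def covers(self, day: date) -> bool:
        return self.start_date <= day <= self.end_date


@dataclass
class SensitivityReport:
    """Instance-level detection summary for one metric over one period."""

    true_positives: int
    false_negatives: int
    false_positives: int
    sensitivity: float  # NaN when undefined (no events)
    defined: bool
    period: tuple[date, date] | None = None
    metric: str = "sni"
    threshold: float = 0.60


def read_service_log(path: str | Path) -> list[ServiceEvent]:
    """Service log CSV: station, start_date, end_date, image_quality_related, note."""
    frame = pd.read_csv(path, dtype={"station": str})
    events = []
    for row in frame.itertuples(index=False):
        events.append(
            ServiceEvent(
                station=str(row.station),
                start_date=pd.Timestamp(row.start_date).date(),
                end_date=pd.Timestamp(row.end_date).date(),
                image_quality_related=bool(row.image_quality_related),
                note=str(getattr(row, "note", "")),
            )
        )
    return events


def _records_frame(records) -> pd.DataFrame:
    """Normalize records (QCRecord list or DataFrame) to station/date/value columns."""
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
        frame["acquired_at"] = pd.to_datetime(frame["acquired_at"])
        return frame
    rows = []
    for rec in records:
        if getattr(rec, "status", "analyzed") != "analyzed":
            continue
        rows.append(
            {
                "station": rec.station,
                "acquired_at": pd.Timestamp(rec.acquired_at),
                "sni": rec.sni,
                "iu_ufov": getattr(rec, "iu_ufov", None),
                "iu_cfov": getattr(rec, "iu_cfov", None),
                "alert_level": getattr(rec, "alert_level", ""),
            }
        )
    return pd.DataFrame(
        rows, columns=["station", "acquired_at", "sni", "iu_ufov", "iu_cfov", "alert_level"]
    )


def _metric_column(metric: str) -> str:
    if metric == "sni":
        return "sni"
    if metric == "iu":
        return "iu_ufov"
    raise ValueError("metric must be 'sni' or 'iu'")


def _alert_day_runs(days: list[date]) -> list[list[date]]:
    """Group sorted alert days into maximal runs of consecutive calendar days."""
    runs: list[list[date]] = []
    for day in sorted(set(days)):
        if runs and (day - runs[-1][-1]) == timedelta(days=1):
            runs[-1].append(day)
        else:
            runs.append([day])
    return runs


def match_alerts_to_events(
    records,
    events: list[ServiceEvent],
    metric: str = "sni",
    threshold: float = 0.60,
) -> SensitivityReport:
    """Score alerting records against the service log at instance granularity.

    Only image-quality-related events are eligible targets.  An event is a
    true positive when any record for its station dated within
    [start_date, end_date] exceeds ``threshold`` (strictly); otherwise a
    false negative.  False positives are maximal consecutive-day alert runs
    per station overlapping no event.  With no eligible events sensitivity
    is NaN and ``defined`` is False — never reported as zero.
    """
    frame = _records_frame(records)
    column = _metric_column(metric)
    eligible = [e for e in events if e.image_quality_related]

    if frame.empty:
        alerting = frame
    else:
        values = pd.to_numeric(frame[column], errors="coerce")
        alerting = frame[values > threshold]

    tp = fn = 0
    for event in eligible:
        hit = False
        if not alerting.empty:
            sub = alerting[alerting["station"] == event.station]
            hit = any(event.covers(ts.date()) for ts in sub["acquired_at"])
        if hit:
            tp += 1
        else:
            fn += 1

    fp = 0
    if not alerting.empty:
        for station, sub in alerting.groupby("station"):
            station_events = [e for e in events if e.station == station]
            days = [ts.date() for ts in sub["acquired_at"]]
            for run in _alert_day_runs(days):
                overlapped = any(
                    e.covers(day) for e in station_events for day in run
                )
                if not overlapped:
                    fp += 1

    defined = tp + fn > 0
    sensitivity = tp / (tp + fn) if defined else float("nan")
    period = None
    if not frame.empty:
        period = (frame["acquired_at"].min().date(), frame["acquired_at"].max().date())
    return SensitivityReport(
        true_positives=tp,
        false_negatives=fn,
        false_positives=fp,
        sensitivity=sensitivity,
        defined=defined,
        period=period,
        metric=metric,
        threshold=threshold,
    )


def _in_period(frame: pd.DataFrame, period: tuple[date, date] | None) -> pd.DataFrame:
    if period is None or frame.empty:
        return frame
    start, end = period
    dates = frame["acquired_at"].dt.date
    return frame[(dates >= start) & (dates <= end)]


def system_cv(records, station: str, period: tuple[date, date] | None = None) -> float:
    """Coefficient of variation (sample SD / mean) of one station's SNI values.

    Returns NaN when fewer than two records fall in the period.
    """
    frame = _in_period(_records_frame(records), period)
    values = pd.to_numeric(
        frame.loc[frame["station"] == station, "sni"], errors="coerce"
    ).dropna()
    if len(values) < 2 or values.mean() == 0:
        return float("nan")
    return float(values.std(ddof=1) / values.mean())


def fleet_cv(records, period: tuple[date, date] | None = None) -> float:
    """Fleet-wide CV: mean per-station SD divided by mean per-station mean."""
    frame = _in_period(_records_frame(records), period)
    sds, means = [], []
    for _, sub in frame.groupby("station"):
        values = pd.to_numeric(sub["sni"], errors="coerce").dropna()
        if len(values) >= 2:
            sds.append(values.std(ddof=1))
            means.append(values.mean())
    if not sds or np.mean(means) == 0:
        return float("nan")
    return float(np.mean(sds) / np.mean(means))


def trend_table(
    records,
    station: str,
    sni_threshold: float = 0.50,
    iu_threshold: float = 5.0,
) -> pd.DataFrame:
    """Chronological per-acquisition trend export for one station.

    Columns: acquired_at, sni, iu_ufov, iu_cfov, alert_level, plus constant
    threshold columns and an ``sni_exceeds`` flag, ready for plotting the
    SNI-vs-IU trend chart of a detector over time.
    """
    frame = _records_frame(records)
    sub = frame[frame["station"] == station].sort_values("acquired_at").reset_index(drop=True)
    sub = sub[["acquired_at", "sni", "iu_ufov", "iu_cfov", "alert_level"]].copy()
    sub["sni_threshold"] = sni_threshold
    sub["iu_threshold"] = iu_threshold
    sub["sni_exceeds"] = pd.to_numeric(sub["sni"], errors="coerce") > sni_threshold
    return sub
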