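"""Daily QC orchestration: ingest → sort → analyze → record → alert → archive.

Every ingested file yields exactly one :class:`QCRecord` — analyzed,
skipped (failed the sorting gate) or errored — so inputs are conserved and
nothing is dropped silently.  Alerts fire at two SNI levels (0.50 physics
only, 0.60 physics + clinical + engineering) through a pluggable notifier;
the default writes a JSON message per alert into a file outbox, which keeps
the pipeline testable without mail infrastructure.  Records accumulate in
an append-only CSV store keyed by (station, acquired_at, analysis_version),
so re-analysis with a newer code version coexists with history.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import date, datetime, time
from pathlib import Path

import pandas as pd

from .config import AlertConfig, QCConfig
from .dicomio import FloodReadError, archive_flood, is_qc_flood, read_flood_dicom
from .roi import image_sni
from .uniformity import fov_mask, integral_uniformity

__all__ = [
    "QCRecord",
    "RecordStore",
    "DuplicateRecordError",
    "FileOutboxNotifier",
    "classify_alert",
    "process_image",
    "notify",
    "detect_missing",
]

logger = logging.getLogger("floodqc")

ALERT_LEVELS = ("none", "lower", "upper")


def classify_alert(sni: float, config: AlertConfig) -> str:
    """Map an SNI value to "none", "lower" or "upper".

    "Exceeds" is strict by default: a value exactly at a threshold does not
    alert (configurable to >=).
    """
    exceeds = (lambda v, t: v >= t) if config.comparison == "ge" else (lambda v, t: v > t)
    if exceeds(sni, config.upper_threshold):
        return "upper"
    if exceeds(sni, config.lower_threshold):
        return "lower"
    return "none"


@dataclass
class QCRecord:
    """One pipeline outcome for one ingested file."""

    source: str
    station: str = ""
    acquired_at: datetime | None = None
    isotope: str = ""
    total_counts: int | None = None
    sni: float | None = None
    best_roi: tuple[int, int, int] | None = None  # (row, col, size)
    iu_ufov: float | None = None
    iu_cfov: float | None = None
    alert_level: str = "none"
    status: str = "analyzed"  # analyzed | skipped | error
    reason: str = ""
    archive_dicom: str = ""
    archive_figure: str = ""
    analysis_version: str = "1"

    def key(self) -> tuple[str, str, str]:
        stamp = self.acquired_at.isoformat() if self.acquired_at else ""
        return (self.station, stamp, self.analysis_version)


class DuplicateRecordError(ValueError):
    """A record with the same (station, acquired_at, analysis_version) exists."""


_FIELDS = [
    "source",
    "station",
    "acquired_at",
    "isotope",
    "total_counts",
    "sni",
    "best_roi",
    "iu_ufov",
    "iu_cfov",
    "alert_level",
    "status",
    "reason",
    "archive_dicom",
    "archive_figure",
    "analysis_version",
]


class RecordStore:
    """Append-only CSV store of :class:`QCRecord` rows."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._keys: set[tuple[str, str, str]] = set()
        if self.path.exists():
            for rec in self.load_records():
                self._keys.add(rec.key())

    def append(self, record: QCRecord) -> None:
        """Append one record; duplicates of analyzed records are rejected."""
        key = record.key()
        if record.status == "analyzed":
            if key in self._keys:
                raise DuplicateRecordError(f"duplicate record {key}")
            self._keys.add(key)
        new_file = not self.path.exists()
        with open(self.path, "a", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_FIELDS)
            if new_file:
                writer.writeheader()
            row = asdict(record)
            row["acquired_at"] = (
                record.acquired_at.isoformat() if record.acquired_at else ""
            )
            row["best_roi"] = (
                "|".join(map(str, record.best_roi)) if record.best_roi else ""
            )
            writer.writerow(row)

    def load_records(self) -> list[QCRecord]:
        if not self.path.exists():
            return []
        out: list[QCRecord] = []
        with open(self.path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                out.append(
                    QCRecord(
                        source=row["source"],
                        station=row["station"],
                        acquired_at=(
                            datetime.fromisoformat(row["acquired_at"])
                            if row["acquired_at"]
                            else None
                        ),
                        isotope=row["isotope"],
                        total_counts=int(row["total_counts"])
                        if row["total_counts"]
                        else None,
                        sni=float(row["sni"]) if row["sni"] else None,
                        best_roi=tuple(map(int, row["best_roi"].split("|")))
                        if row["best_roi"]
                        else None,
                        iu_ufov=float(row["iu_ufov"]) if row["iu_ufov"] else None,
                        iu_cfov=float(row["iu_cfov"]) if row["iu_cfov"] else None,
                        alert_level=row["alert_level"],
                        status=row["status"],
                        reason=row["reason"],
                        archive_dicom=row["archive_dicom"],
                        archive_figure=row["archive_figure"],
                        analysis_version=row["analysis_version"],
                    )
                )
        return out

    def to_frame(self) -> pd.DataFrame:
        """Records as a DataFrame (datetimes parsed), for the statistics layer."""
        if not self.path.exists():
            return pd.DataFrame(columns=_FIELDS)
        frame = pd.read_csv(self.path, dtype={"station": str})
        frame["acquired_at"] = pd.to_datetime(frame["acquired_at"])
        return frame

    def query(
        self, station: str | None = None, day: date | None = None
    ) -> list[QCRecord]:
        records = self.load_records()
        if station is not None:
            records = [r for r in records if r.station == station]
        if day is not None:
            records = [
                r for r in records if r.acquired_at and r.acquired_at.date() == day
            ]
        return records


class FileOutboxNotifier:
    """Default notification channel: one JSON message file per alert."""

    def __init__(self, outbox_dir: str | Path):
        self.outbox_dir = Path(outbox_dir)
        self.outbox_dir.mkdir(parents=True, exist_ok=True)

    def send(
        self,
        recipients: list[str],
        subject: str,
        body: str,
        attachment: str | None = None,
    ) -> Path:
        stamp = datetime.now().strftime("%Y%m%d%H%M%S%f")
        path = self.outbox_dir / f"alert_{stamp}.json"
        path.write_text(
            json.dumps(
                {
                    "recipients": recipients,
                    "subject": subject,
                    "body": body,
                    "attachment": attachment,
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        return path


def notify(
    record: QCRecord,
    figure_path: str | None,
    config: AlertConfig,
    notifier: FileOutboxNotifier,
) -> dict | None:
    """Dispatch an alert for a record; returns a delivery-log entry.

    Recipients follow the alert level (lower → physics only; upper adds
    clinical and engineering).  Channel failures are logged and never block
    the pipeline.
    """
    if record.alert_level == "none":
        return None
    recipients = (
        config.recipients_upper
        if record.alert_level == "upper"
        else config.recipients_lower
    )
    subject = (
        f"[floodqc {record.alert_level.upper()} alert] {record.station} "
        f"SNI={record.sni:.3f}"
    )
    body = (
        f"Station: {record.station}\n"
        f"Acquired: {record.acquired_at}\n"
        f"SNI: {record.sni:.4f}\n"
        f"IU UFOV/CFOV: {record.iu_ufov}/{record.iu_cfov}\n"
        f"Alert level: {record.alert_level}"
    )
    try:
        delivered = notifier.send(recipients, subject, body, attachment=figure_path)
    except Exception as exc:  # notification must never take down the pipeline
        logger.error("notification failed for %s: %s", record.station, exc)
        return {"delivered": False, "error": str(exc), "recipients": recipients}
    logger.info("alert %s -> %s", record.alert_level, ",".join(recipients))
    return {
        "delivered": True,
        "recipients": recipients,
        "message": str(delivered),
        "attachment": figure_path,
    }


def process_image(
    path: str | Path,
    config: QCConfig,
    *,
    store: RecordStore | None = None,
    notifier: FileOutboxNotifier | None = None,
) -> QCRecord:
    """Run the full pipeline on one DICOM file and return its record.

    Stages: read → sort → SNI sweep (incl. artifact) → IU (UFOV, CFOV) →
    alert classification → notification → archive → store.  A failure at
    any stage yields an ``error`` record naming the stage; rejected non-QC
    files yield a ``skipped`` record with the sorting reason.
    """
    path = str(path)
    record = QCRecord(source=path, analysis_version=config.analysis_version)
    try:
        flood = read_flood_dicom(path)
    except FloodReadError as exc:
        record.status, record.reason = "error", f"read: {exc}"
        _finish(record, store)
        return record

    record.station = flood.station
    record.acquired_at = flood.acquired_at
    record.isotope = flood.isotope
    record.total_counts = flood.total_counts

    accepted, reason = is_qc_flood(flood, config.sort_rule)
    if not accepted:
        record.status, record.reason = "skipped", reason
        _finish(record, store)
        return record

    try:
        result = image_sni(flood, config.geometry, config.roi)
        record.sni = result.image_sni
        r0, c0 = result.best_roi.origin
        record.best_roi = (r0, c0, result.best_roi.size)
        rows, cols = flood.shape
        record.iu_ufov = integral_uniformity(flood.pixels, fov_mask(rows, cols, "ufov"))
        record.iu_cfov = integral_uniformity(flood.pixels, fov_mask(rows, cols, "cfov"))
    except Exception as exc:
        record.status, record.reason = "error", f"analysis: {exc}"
        _finish(record, store)
        return record

    record.alert_level = classify_alert(record.sni, config.alert)

    try:
        dicom_path, figure_path = archive_flood(flood, result, config.archive_root)
        record.archive_dicom = str(dicom_path)
        record.archive_figure = str(figure_path)
    except Exception as exc:
        record.status, record.reason = "error", f"archive: {exc}"
        _finish(record, store)
        return record

    if record.alert_level != "none":
        notify(
            record,
            record.archive_figure or None,
            config.alert,
            notifier or FileOutboxNotifier(config.outbox_dir),
        )

    _finish(record, store)
    return record


def _finish(record: QCRecord, store: RecordStore | None) -> None:
    if store is not None:
        try:
            store.append(record)
        except DuplicateRecordError:
            record.status, record.reason = "error", "duplicate record"


def detect_missing(
    expected_stations: list[str],
    records_for_date: list[QCRecord],
    cutoff_time: time | datetime,
) -> list[str]:
    """Stations with no accepted QC record timestamped before the cutoff.

    ``cutoff_time`` may be a time-of-day (compared against each record's
    time) or a full datetime.  Returns stations in the order given.
    """
    seen: set[str] = set()
    for rec in records_for_date:
        if rec.status != "analyzed" or rec.acquired_at is None:
            continue
        stamp = rec.acquired_at if isinstance(cutoff_time, datetime) else rec.acquired_at.time()
        if stamp < cutoff_time:
            seen.add(rec.station)
    return [s for s in expected_stations if s not in seen]
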