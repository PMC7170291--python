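"""Alert classification, the end-to-end pipeline, the record store and missing-QC detection."""

import json
from datetime import date, datetime, time

import numpy as np
import pytest

from floodqc.config import AlertConfig, QCConfig, load_config, save_config
from floodqc.dicomio import SortRule
from floodqc.service import (
    DuplicateRecordError,
    FileOutboxNotifier,
    QCRecord,
    RecordStore,
    classify_alert,
    detect_missing,
    notify,
    process_image,
)
from floodqc.synthetic import write_synthetic_dicom


class TestClassifyAlert:
    @pytest.mark.parametrize(
        "sni,expected",
        [(0.0, "none"), (0.50, "none"), (0.55, "lower"), (0.60, "lower"), (0.65, "upper")],
    )
    def test_levels_with_strict_comparison(self, sni, expected):
        assert classify_alert(sni, AlertConfig()) == expected

    def test_ge_comparison_alerts_on_boundary(self):
        cfg = AlertConfig(comparison="ge")
        assert classify_alert(0.50, cfg) == "lower"
        assert classify_alert(0.60, cfg) == "upper"

    def test_monotone_in_sni(self):
        cfg = AlertConfig()
        order = {"none": 0, "lower": 1, "upper": 2}
        levels = [order[classify_alert(v, cfg)] for v in np.linspace(0, 0.99, 50)]
        assert levels == sorted(levels)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            AlertConfig(lower_threshold=0.7, upper_threshold=0.6)


@pytest.fixture
def pipeline_config(tmp_path):
    return QCConfig(
        sort_rule=SortRule(
            allowed_stations=["NM01", "NM02"],
            min_counts=500_000,
            matrix_sizes=[(128, 128), (256, 256)],
        ),
        archive_root=str(tmp_path / "archive"),
        store_path=str(tmp_path / "records.csv"),
        outbox_dir=str(tmp_path / "outbox"),
    )


class TestProcessImage:
    def test_clean_flood_analyzed_and_archived(self, flood_factory, pipeline_config, tmp_path):
        flood = flood_factory(shape=(128, 128), seed=0, station="NM01")
        path = write_synthetic_dicom(flood, tmp_path / "clean.dcm")
        store = RecordStore(pipeline_config.store_path)
        record = process_image(path, pipeline_config, store=store)
        assert record.status == "analyzed"
        assert record.alert_level == "none"
        assert record.sni is not None and record.iu_ufov is not None
        assert "NM01" in record.archive_dicom
        assert len(store.load_records()) == 1

    def test_defect_flood_alerts_and_notifies(
        self, flood_factory, dropout, pipeline_config, tmp_path
    ):
        flood = flood_factory(
            shape=(256, 256), defects=[dropout(center=(96.0, 128.0))],
            total_counts=5_000_000, seed=1, station="NM01",
        )
        path = write_synthetic_dicom(flood, tmp_path / "defect.dcm")
        notifier = FileOutboxNotifier(pipeline_config.outbox_dir)
        record = process_image(path, pipeline_config, notifier=notifier)
        assert record.status == "analyzed"
        assert record.alert_level == "upper"
        messages = list(notifier.outbox_dir.glob("alert_*.json"))
        assert len(messages) == 1
        payload = json.loads(messages[0].read_text())
        assert payload["recipients"] == ["physics", "clinical", "engineering"]
        assert payload["attachment"].endswith(".png")

    def test_non_qc_file_skipped_without_analysis(
        self, flood_factory, pipeline_config, tmp_path
    ):
        outsider = flood_factory(shape=(128, 128), seed=2, station="CT99")
        path = write_synthetic_dicom(outsider, tmp_path / "other.dcm")
        record = process_image(path, pipeline_config)
        assert record.status == "skipped"
        assert record.reason == "station"
        assert record.sni is None

    def test_unreadable_file_yields_error_record(self, pipeline_config, tmp_path):
        junk = tmp_path / "junk.dcm"
        junk.write_text("nope")
        record = process_image(junk, pipeline_config)
        assert record.status == "error"
        assert record.reason.startswith("read:")


class TestNotify:
    def test_lower_alert_goes_to_physics_only(self, tmp_path):
        notifier = FileOutboxNotifier(tmp_path / "outbox")
        record = QCRecord(
            source="x", station="NM01", acquired_at=datetime(2024, 1, 2, 7),
            sni=0.55, alert_level="lower",
        )
        log = notify(record, None, AlertConfig(), notifier)
        assert log["delivered"] and log["recipients"] == ["physics"]

    def test_no_alert_no_dispatch(self, tmp_path):
        notifier = FileOutboxNotifier(tmp_path / "outbox")
        record = QCRecord(source="x", station="NM01", sni=0.2, alert_level="none")
        assert notify(record, None, AlertConfig(), notifier) is None
        assert list(notifier.outbox_dir.glob("*.json")) == []


class TestRecordStore:
    def make_record(self, i, station="NM01"):
        return QCRecord(
            source=f"f{i}.dcm", station=station,
            acquired_at=datetime(2024, 1, 1 + i % 27, 7, 0, 0),
            sni=0.3, alert_level="none",
        )

    def test_append_query_roundtrip(self, tmp_path):
        store = RecordStore(tmp_path / "store.csv")
        store.append(self.make_record(0))
        got = store.query(station="NM01", day=date(2024, 1, 1))
        assert len(got) == 1 and got[0].sni == 0.3

    def test_duplicate_rejected_even_after_reload(self, tmp_path):
        store = RecordStore(tmp_path / "store.csv")
        store.append(self.make_record(0))
        with pytest.raises(DuplicateRecordError):
            store.append(self.make_record(0))
        fresh = RecordStore(tmp_path / "store.csv")
        with pytest.raises(DuplicateRecordError):
            fresh.append(self.make_record(0))

    def test_bulk_appends_preserve_order(self, tmp_path):
        store = RecordStore(tmp_path / "store.csv")
        for i in range(100):
            store.append(self.make_record(i, station=f"NM{i:03d}"))
        records = store.load_records()
        assert len(records) == 100
        assert [r.station for r in records] == [f"NM{i:03d}" for i in range(100)]


class TestDetectMissing:
    def rec(self, station, hour, status="analyzed"):
        return QCRecord(
            source="x", station=station, status=status,
            acquired_at=datetime(2024, 3, 1, hour, 0, 0),
        )

    def test_missing_stations_listed(self):
        records = [self.rec("A", 6)]
        assert detect_missing(["A", "B", "C"], records, time(9, 0)) == ["B", "C"]

    def test_all_received_empty(self):
        records = [self.rec(s, 6) for s in "ABC"]
        assert detect_missing(["A", "B", "C"], records, time(9, 0)) == []

    def test_cutoff_semantics(self):
        records = [self.rec("A", 11)]  # after the morning cutoff
        assert detect_missing(["A"], records, time(9, 0)) == ["A"]
        assert detect_missing(["A"], records, time(23, 59)) == []

    def test_skipped_records_do_not_count(self):
        records = [self.rec("A", 6, status="skipped")]
        assert detect_missing(["A"], records, time(9, 0)) == ["A"]


class TestConfigYaml:
    def test_roundtrip(self, tmp_path):
        cfg = QCConfig(
            sort_rule=SortRule(allowed_stations=["NM01"], min_counts=123),
            alert=AlertConfig(lower_threshold=0.4, upper_threshold=0.7),
        )
        path = save_config(cfg, tmp_path / "cfg.yaml")
        back = load_config(path)
        assert back.sort_rule.allowed_stations == ["NM01"]
        assert back.sort_rule.min_counts == 123
        assert back.alert.upper_threshold == 0.7
        assert back.roi.size == 64
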