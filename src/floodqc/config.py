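"""YAML-backed configuration for the QC pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import ViewingGeometry
from .dicomio import SortRule
from .roi import ROIConfig

__all__ = ["AlertConfig", "QCConfig", "load_config", "save_config"]


@dataclass
class AlertConfig:
    """Two-level SNI alert thresholds and their recipient lists.

    The lower threshold (0.50) notifies physics staff only; the upper
    threshold (0.60) additionally notifies clinical and clinical-engineering
    staff.  "Exceeds" is strict inequality by default (``comparison`` =
    ``"gt"``); set ``"ge"`` to alert on boundary values.
    """

    lower_threshold: float = 0.50
    upper_threshold: float = 0.60
    recipients_lower: list[str] = field(default_factory=lambda: ["physics"])
    recipients_upper: list[str] = field(
        default_factory=lambda: ["physics", "clinical", "engineering"]
    )
    comparison: str = "gt"

    def __post_init__(self) -> None:
        if not 0.0 < self.lower_threshold <= self.upper_threshold < 1.0:
            raise ValueError("thresholds must satisfy 0 < lower <= upper < 1")
        if self.comparison not in ("gt", "ge"):
            raise ValueError("comparison must be 'gt' or 'ge'")


@dataclass
class QCConfig:
    """Everything the daily pipeline needs: sorting, scoring, alerting, storage."""

    sort_rule: SortRule = field(default_factory=SortRule)
    alert: AlertConfig = field(default_factory=AlertConfig)
    roi: ROIConfig = field(default_factory=ROIConfig)
    geometry: ViewingGeometry = field(default_factory=ViewingGeometry)
    archive_root: str = "archive"
    store_path: str = "qc_records.csv"
    outbox_dir: str = "outbox"
    analysis_version: str = "1"


def load_config(path: str | Path) -> QCConfig:
    """Load a :class:`QCConfig` from YAML; absent sections keep their defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = QCConfig()
    if "sort_rule" in raw:
        sr = dict(raw["sort_rule"])
        if "matrix_sizes" in sr:
            sr["matrix_sizes"] = [tuple(m) for m in sr["matrix_sizes"]]
        cfg.sort_rule = SortRule(**sr)
    if "alert" in raw:
        cfg.alert = AlertConfig(**raw["alert"])
    if "roi" in raw:
        cfg.roi = ROIConfig(**raw["roi"])
    if "geometry" in raw:
        cfg.geometry = ViewingGeometry(**raw["geometry"])
    for key in ("archive_root", "store_path", "outbox_dir", "analysis_version"):
        if key in raw:
            setattr(cfg, key, str(raw[key]))
    return cfg


def save_config(cfg: QCConfig, path: str | Path) -> Path:
    path = Path(path)
    data = {
        "sort_rule": {
            "allowed_stations": list(cfg.sort_rule.allowed_stations),
            "series_tokens": list(cfg.sort_rule.series_tokens),
            "min_counts": cfg.sort_rule.min_counts,
            "matrix_sizes": [list(m) for m in cfg.sort_rule.matrix_sizes],
        },
        "alert": asdict(cfg.alert),
        "roi": asdict(cfg.roi),
        "geometry": asdict(cfg.geometry),
        "archive_root": cfg.archive_root,
        "store_path": cfg.store_path,
        "outbox_dir": cfg.outbox_dir,
        "analysis_version": cfg.analysis_version,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path
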