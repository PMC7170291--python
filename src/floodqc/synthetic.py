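"""Synthetic flood-field images with known injected nonuniformities.

Real daily QC floods are Poisson count maps of a uniform source modulated by
the detector's spatially varying sensitivity.  The simulator reproduces
exactly that: a multiplicative sensitivity map (unit mean) built from
parameterized defects, then independent Poisson draws per pixel.  Defect
profiles emulate the common failure classes:

``pmt_dropout``
    Gaussian-profile sensitivity dip (depth = amplitude, FWHM = width) — a
    weak or failing photomultiplier tube.
``gradient``
    Unit-mean linear ramp with peak-to-peak swing 2·amplitude along
    ``orientation`` — electronic drift / tuning imbalance.
``sinusoid``
    1 + amplitude·sin(2π·f·(row·cosθ + col·sinθ)) with f = width in
    cycles/pixel — periodic interference patterns.
``edge_band``
    A border strip of ``width`` pixels lowered by ``amplitude`` on the side
    selected by ``orientation`` (0°=top, 90°=left, 180°=bottom, 270°=right)
    — edge packing / masking faults.

These are simulator conventions, not measurements of any particular camera.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FloodImage

__all__ = [
    "DefectSpec",
    "SensitivityMap",
    "DefectError",
    "make_sensitivity_map",
    "simulate_flood",
    "write_synthetic_dicom",
    "simulate_campaign",
    "write_campaign_manifest",
    "SERVICE_WORTHY_AMPLITUDE",
]

DEFECT_KINDS = ("pmt_dropout", "gradient", "sinusoid", "edge_band")

#: Default truth threshold: defects at or above this amplitude are labelled
#: "service-worthy" in simulated campaigns (a 10% local sensitivity loss is
#: plainly visible and would trigger an engineering call).
SERVICE_WORTHY_AMPLITUDE = 0.10


class DefectError(ValueError):
    """A defect specification is invalid or drives the sensitivity non-positive."""


@dataclass(frozen=True)
class DefectSpec:
    """One multiplicative nonuniformity.

    amplitude is a dimensionless fraction of mean sensitivity in [0, 1);
    ``width`` is the FWHM in pixels (pmt_dropout), the spatial frequency in
    cycles/pixel (sinusoid), or the band width in pixels (edge_band);
    ``orientation`` is in degrees (gradient/sinusoid/edge_band).
    """

    kind: str
    amplitude: float
    center: tuple[float, float] | None = None
    width: float = 1.0
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in DEFECT_KINDS:
            raise DefectError(f"unknown defect kind: {self.kind!r}")
        if not 0.0 <= self.amplitude < 1.0:
            raise DefectError(f"{self.kind}: amplitude must lie in [0, 1)")
        if self.width <= 0:
            raise DefectError(f"{self.kind}: width must be positive")


@dataclass
class SensitivityMap:
    """Relative detector sensitivity, normalized to unit mean over the field."""

    values: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def _defect_field(shape: tuple[int, int], spec: DefectSpec) -> np.ndarray:
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)
    if spec.kind == "pmt_dropout":
        cr, ccol = spec.center if spec.center else ((rows - 1) / 2, (cols - 1) / 2)
        d2 = (rr - cr) ** 2 + (cc - ccol) ** 2
        # Gaussian dip of depth `amplitude` and FWHM `width`
        return 1.0 - spec.amplitude * np.exp(-4.0 * np.log(2.0) * d2 / spec.width**2)
    if spec.kind == "gradient":
        theta = np.deg2rad(spec.orientation)
        proj = rr * np.cos(theta) + cc * np.sin(theta)
        span = proj.max() - proj.min()
        t = np.zeros_like(proj) if span == 0 else 2.0 * (proj - proj.min()) / span - 1.0
        return 1.0 + spec.amplitude * t
    if spec.kind == "sinusoid":
        theta = np.deg2rad(spec.orientation)
        phase = 2.0 * np.pi * spec.width * (rr * np.cos(theta) + cc * np.sin(theta))
        return 1.0 + spec.amplitude * np.sin(phase)
    # edge_band
    w = int(round(spec.width))
    band = np.ones(shape)
    side = int(round(spec.orientation / 90.0)) % 4
    if side == 0:
        band[:w, :] = 1.0 - spec.amplitude
    elif side == 1:
        band[:, :w] = 1.0 - spec.amplitude
    elif side == 2:
        band[-w:, :] = 1.0 - spec.amplitude
    else:
        band[:, -w:] = 1.0 - spec.amplitude
    return band


def make_sensitivity_map(
    shape: tuple[int, int], defects: list[DefectSpec] | tuple[DefectSpec, ...] = ()
) -> SensitivityMap:
    """Product of all defect fields, renormalized to unit mean.

    Raises :class:`DefectError`, naming the offending defect, if the
    combined map is not strictly positive.
    """
    rows, cols = shape
    if min(rows, cols) < 64:
        raise ValueError("sensitivity map must be at least 64x64")
    values = np.ones(shape, dtype=np.float64)
    for i, spec in enumerate(defects):
        values *= _defect_field(shape, spec)
        if values.min() <= 0:
            raise DefectError(
                f"defect {i} ({spec.kind}, amplitude {spec.amplitude}) "
                "drives the sensitivity non-positive"
            )
    values /= values.mean()
    return SensitivityMap(values=values)


def simulate_flood(
    smap: SensitivityMap,
    total_counts: int,
    seed: int | np.random.Generator,
    *,
    station: str = "SIM01",
    acquired_at: datetime | None = None,
    isotope: str = "Co-57",
    spacing: tuple[float, float] = (2.2, 2.2),
) -> FloodImage:
    """Draw one Poisson flood from a sensitivity map.

    Per-pixel counts are independent Poisson with mean
    total_counts · map / sum(map), so the expected total equals
    ``total_counts`` regardless of the defects present.  Reproducible for a
    given seed.
    """
    if total_counts < 10_000:
        raise ValueError("total_counts must be at least 1e4")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = total_counts * smap.values / smap.values.sum()
    pixels = rng.poisson(lam).astype(np.int64)
    return FloodImage(
        pixels=pixels,
        spacing=spacing,
        station=station,
        acquired_at=acquired_at or datetime(2024, 1, 1, 7, 0, 0),
        isotope=isotope,
        series_description="DAILY QC FLOOD",
    )


def write_synthetic_dicom(flood: FloodImage, path: str | Path) -> Path:
    """Serialize a simulated flood as a DICOM file (16-bit unsigned pixels)."""
    from .dicomio import write_flood_dicom

    return write_flood_dicom(flood, path)


def _station_rng(seed: int, day: int, station: str) -> np.random.Generator:
    # stable per-(seed, day, station) stream: crc32 keeps the key platform-independent
    return np.random.default_rng([seed, day, zlib.crc32(station.encode("utf-8"))])


def simulate_campaign(
    n_days: int,
    stations: list[str],
    defect_schedule: dict | None,
    seed: int,
    *,
    shape: tuple[int, int] = (256, 256),
    total_counts: int = 5_000_000,
    service_amplitude: float = SERVICE_WORTHY_AMPLITUDE,
    start_date: datetime | None = None,
) -> list[tuple[FloodImage, bool]]:
    """One flood per station per day, with ground-truth defect labels.

    ``defect_schedule`` maps day index (0-based) to either a list of
    :class:`DefectSpec` applied to every station that day, or a dict
    ``station -> list of DefectSpec``.  The truth label of an image is True
    when any defect applied to it has amplitude ≥ ``service_amplitude``
    (the simulated analog of "service was required").  Per-image randomness
    is derived from (seed, day, station) so the campaign is reproducible and
    insensitive to iteration order.
    """
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    schedule = defect_schedule or {}
    t0 = start_date or datetime(2024, 1, 1, 7, 0, 0)
    out: list[tuple[FloodImage, bool]] = []
    for day in range(n_days):
        day_entry = schedule.get(day, [])
        for station in stations:
            if isinstance(day_entry, dict):
                defects = list(day_entry.get(station, []))
            else:
                defects = list(day_entry)
            smap = make_sensitivity_map(shape, defects)
            flood = simulate_flood(
                smap,
                total_counts,
                _station_rng(seed, day, station),
                station=station,
                acquired_at=t0 + timedelta(days=day),
            )
            label = any(d.amplitude >= service_amplitude for d in defects)
            out.append((flood, label))
    return out


def write_campaign_manifest(
    campaign: list[tuple[FloodImage, bool]], path: str | Path
) -> Path:
    """CSV manifest of a simulated campaign: day, station, timestamp, truth label."""
    path = Path(path)
    dates = [f.acquired_at for f, _ in campaign if f.acquired_at is not None]
    t0 = min(dates) if dates else None
    rows = [
        {
            "day": (flood.acquired_at - t0).days if t0 and flood.acquired_at else "",
            "station": flood.station,
            "acquired_at": flood.acquired_at.isoformat() if flood.acquired_at else "",
            "total_counts": flood.total_counts,
            "defect_present": label,
        }
        for flood, label in campaign
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
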