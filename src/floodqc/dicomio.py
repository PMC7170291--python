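"""Flood DICOM reading/writing, QC sorting, archiving and the quadrant figure.

Cameras push every study to the physics share, so the first pipeline stage
sorts genuine daily-QC floods from whatever else arrives (patient studies,
bar phantoms, service acquisitions) using header attributes only: station
allow-list, a token match against the series/study description, a minimum
count sum and the expected matrix sizes.  Accepted floods are archived per
station together with a four-quadrant diagnostic figure: input image (upper
left), artifact image (upper right), winning ROI (lower left) and its 2D
NPS (lower right).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .core import FloodImage
from .roi import SNIResult

__all__ = [
    "FloodReadError",
    "SortRule",
    "read_flood_dicom",
    "write_flood_dicom",
    "is_qc_flood",
    "archive_flood",
    "render_quadrant_figure",
]

_NM_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.20"


class FloodReadError(ValueError):
    """The file is not a readable single-frame image DICOM."""


@dataclass
class SortRule:
    """Header-based acceptance rule for daily-QC floods."""

    allowed_stations: list[str] = field(default_factory=list)
    series_tokens: list[str] = field(default_factory=lambda: ["FLOOD", "UNIFORMITY", "QC"])
    min_counts: int = 1_000_000
    matrix_sizes: list[tuple[int, int]] = field(default_factory=lambda: [(256, 256)])

    def __post_init__(self) -> None:
        if self.min_counts < 0:
            raise ValueError("min_counts must be non-negative")


def _parse_dt(date: str | None, time: str | None) -> datetime | None:
    if not date:
        return None
    time = (time or "000000").split(".")[0].ljust(6, "0")
    try:
        return datetime.strptime(date + time, "%Y%m%d%H%M%S")
    except ValueError:
        return None


def read_flood_dicom(path: str | Path) -> FloodImage:
    """Read a flood DICOM into a :class:`FloodImage`.

    Pixel spacing defaults to (1.0, 1.0) mm — with ``spacing_assumed`` set —
    when the tag is absent.  Total counts come from the pixel sum; a header
    count value, when present, is kept separately for audit.
    """
    path = Path(path)
    try:
        ds = pydicom.dcmread(path, force=False)
    except Exception as exc:  # invalid preamble, truncated file, not DICOM
        raise FloodReadError(f"{path} is not a readable DICOM file: {exc}") from exc
    if "PixelData" not in ds:
        raise FloodReadError(f"{path} contains no pixel data")
    try:
        pixels = np.asarray(ds.pixel_array)
    except Exception as exc:
        raise FloodReadError(f"{path}: cannot decode pixel data: {exc}") from exc
    if pixels.ndim != 2:
        raise FloodReadError(f"{path}: expected a single-frame 2D image")

    spacing_assumed = False
    ps = getattr(ds, "PixelSpacing", None)
    if ps is not None and len(ps) == 2:
        spacing = (float(ps[1]), float(ps[0]))  # DICOM order is (row, col)
    else:
        spacing, spacing_assumed = (1.0, 1.0), True

    header_counts = None
    if "CountsAccumulated" in ds:
        try:
            header_counts = int(ds.CountsAccumulated)
        except (TypeError, ValueError):
            header_counts = None

    return FloodImage(
        pixels=pixels.astype(np.int64),
        spacing=spacing,
        station=str(getattr(ds, "StationName", "")),
        acquired_at=_parse_dt(
            getattr(ds, "AcquisitionDate", None) or getattr(ds, "StudyDate", None),
            getattr(ds, "AcquisitionTime", None) or getattr(ds, "StudyTime", None),
        ),
        isotope=str(getattr(ds, "Radiopharmaceutical", "")),
        series_description=str(
            getattr(ds, "SeriesDescription", "")
            or getattr(ds, "StudyDescription", "")
        ),
        spacing_assumed=spacing_assumed,
        header_counts=header_counts,
        source_path=str(path),
    )


def write_flood_dicom(
    flood: FloodImage, path: str | Path, *, include_spacing: bool = True
) -> Path:
    """Write a flood as an explicit-VR little-endian NM image DICOM.

    Counts are stored as 16-bit unsigned integers; values beyond that range
    are rejected rather than truncated.
    """
    path = Path(path)
    pixels = np.asarray(flood.pixels)
    if pixels.max(initial=0) > 0xFFFF:
        raise ValueError("counts exceed the 16-bit stored pixel range")

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _NM_IMAGE_STORAGE
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = _NM_IMAGE_STORAGE
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "NM"
    ds.StationName = flood.station
    ds.SeriesDescription = flood.series_description or "DAILY QC FLOOD"
    ds.Radiopharmaceutical = flood.isotope
    if flood.acquired_at is not None:
        ds.AcquisitionDate = flood.acquired_at.strftime("%Y%m%d")
        ds.AcquisitionTime = flood.acquired_at.strftime("%H%M%S")
        ds.StudyDate = ds.AcquisitionDate
        ds.StudyTime = ds.AcquisitionTime
    ds.Rows, ds.Columns = pixels.shape
    if include_spacing:
        dx, dy = flood.spacing
        ds.PixelSpacing = [f"{dy:g}", f"{dx:g}"]  # DICOM order is (row, col)
    ds.CountsAccumulated = int(pixels.sum())
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = pixels.astype("<u2").tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def is_qc_flood(flood: FloodImage, rule: SortRule) -> tuple[bool, str]:
    """Header-only sorting decision: (accepted, reason of first failure or "ok")."""
    if rule.allowed_stations and flood.station not in rule.allowed_stations:
        return False, "station"
    desc = flood.series_description.upper()
    if rule.series_tokens and not any(tok.upper() in desc for tok in rule.series_tokens):
        return False, "series"
    if (flood.total_counts or 0) < rule.min_counts:
        return False, "low_counts"
    if rule.matrix_sizes and tuple(flood.shape) not in [
        tuple(m) for m in rule.matrix_sizes
    ]:
        return False, "matrix"
    return True, "ok"


def _unique_path(candidate: Path) -> Path:
    if not candidate.exists():
        return candidate
    stem, suffix = candidate.stem, candidate.suffix
    i = 1
    while True:
        alt = candidate.with_name(f"{stem}_{i}{suffix}")
        if not alt.exists():
            return alt
        i += 1


def archive_flood(
    flood: FloodImage,
    result: SNIResult,
    root: str | Path,
    *,
    figure_format: str = "png",
) -> tuple[Path, Path]:
    """Archive one analyzed flood under per-station folders.

    The DICOM goes to ``root/<station>/images/`` and the quadrant figure to
    ``root/<station>/figures/``; filenames embed station and timestamp and
    are suffixed on collision, so re-running never overwrites history.
    """
    root = Path(root)
    station = flood.station or "UNKNOWN"
    stamp = (
        flood.acquired_at.strftime("%Y%m%d_%H%M%S")
        if flood.acquired_at
        else "undated"
    )
    img_dir = root / station / "images"
    fig_dir = root / station / "figures"
    img_dir.mkdir(parents=True, exist_ok=True)
    fig_dir.mkdir(parents=True, exist_ok=True)

    dicom_path = _unique_path(img_dir / f"{station}_{stamp}.dcm")
    if flood.source_path and Path(flood.source_path).is_file():
        dicom_path.write_bytes(Path(flood.source_path).read_bytes())
    else:
        write_flood_dicom(flood, dicom_path)
    figure_path = _unique_path(fig_dir / f"{station}_{stamp}.{figure_format}")
    render_quadrant_figure(flood, result, figure_path)
    return dicom_path, figure_path


def render_quadrant_figure(
    flood: FloodImage, result: SNIResult, path: str | Path
) -> Path:
    """Render the four-quadrant diagnostic figure.

    Upper left: input flood; upper right: artifact image; lower left: the
    ROI with the highest SNI; lower right: that ROI's 2D NPS (log display,
    zero-frequency centered).  Output format follows the file extension
    (PNG default; JPEG selectable for mail payloads).
    """
    path = Path(path)
    fig, axes = plt.subplots(2, 2, figsize=(8, 8))
    ul, ur = axes[0]
    ll, lr = axes[1]

    ul.imshow(flood.pixels, cmap="gray", interpolation="nearest")
    ul.set_title("Input flood")
    if result.artifact is not None:
        ur.imshow(result.artifact.values, cmap="gray", interpolation="nearest")
    ur.set_title("Artifact image")
    ll.imshow(
        result.best_roi.extract(np.asarray(flood.pixels)),
        cmap="gray",
        interpolation="nearest",
    )
    r0, c0 = result.best_roi.origin
    ll.set_title(f"Best ROI @ ({r0},{c0}) size {result.best_roi.size}")
    nps_disp = np.fft.fftshift(result.best_nps.values)
    lr.imshow(np.log10(nps_disp + 1e-12), cmap="viridis", interpolation="nearest")
    lr.set_title("2D NPS of best ROI")
    for ax in axes.ravel():
        ax.set_xticks([])
        ax.set_yticks([])
    when = flood.acquired_at.isoformat(sep=" ") if flood.acquired_at else "undated"
    fig.suptitle(f"{flood.station}  {when}  SNI = {result.image_sni:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata=_figure_metadata(path))
    plt.close(fig)
    return path


def _figure_metadata(path: Path) -> dict | None:
    # strip the creation-date comment PNG would otherwise embed, so renders
    # of identical inputs are byte-identical
    if path.suffix.lower() == ".png":
        return {"Software": "floodqc"}
    return None
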