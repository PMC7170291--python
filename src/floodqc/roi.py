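"""ROI enumeration and the per-image SNI sweep.

The image-level SNI is the maximum patch SNI over a fixed ROI set: two
large equally sized overlapping squares spanning the central 90% of the
field (which coincide, and are deduplicated, on a square matrix) plus a
small roving 64×64 window stepped in 16-pixel increments over the entire
image (169 positions on a 256×256 matrix).  The roving window targets
local defects — a failing photomultiplier tube occupies only a few percent
of the field and barely moves a full-field statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .artifact import ArtifactImage, artifact_image
from .core import FloodImage, NPS2D, SNIScore, ViewingGeometry, compute_nps_2d, sni_for_patch

__all__ = ["ROI", "ROIConfig", "SNIResult", "large_rois", "roving_rois", "image_sni"]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True, order=True)
class ROI:
    """A square region of interest: 0-based origin (row, col) and side length."""

    origin: tuple[int, int]
    size: int

    def slices(self) -> tuple[slice, slice]:
        r, c = self.origin
        return slice(r, r + self.size), slice(c, c + self.size)

    def contains(self, row: int, col: int) -> bool:
        r, c = self.origin
        return r <= row < r + self.size and c <= col < c + self.size

    def extract(self, image: np.ndarray) -> np.ndarray:
        sr, sc = self.slices()
        return image[sr, sc]


@dataclass(frozen=True)
class ROIConfig:
    """Sweep parameters: central fraction for the large squares, roving size/step."""

    fraction: float = 0.9
    size: int = 64
    step: int = 16


@dataclass
class SNIResult:
    """Outcome of the per-image sweep: the winning ROI and everything scored."""

    image_sni: float
    best_roi: ROI
    per_roi_scores: list[tuple[ROI, SNIScore]]
    best_nps: NPS2D
    artifact: ArtifactImage | None = None


def large_rois(rows: int, cols: int, fraction: float = 0.9) -> list[ROI]:
    """Two equal overlapping squares spanning the central ``fraction`` region.

    The square side is round(fraction·min(rows, cols)); the central region
    is the centered fraction·rows × fraction·cols rectangle (odd margins
    biased so the region sits one pixel toward the top/left).  One square is
    anchored at the region's top-left corner, the other at its bottom-right;
    on a square image they coincide and a single ROI is returned.
    """
    if min(rows, cols) * fraction < 64:
        raise ValueError("image too small for the large-ROI scheme")
    side = _round_half_up(fraction * min(rows, cols))
    region_h = _round_half_up(fraction * rows)
    region_w = _round_half_up(fraction * cols)
    top = (rows - region_h) // 2
    left = (cols - region_w) // 2
    first = ROI(origin=(top, left), size=side)
    second = ROI(origin=(top + region_h - side, left + region_w - side), size=side)
    return [first] if second == first else [first, second]


def roving_rois(rows: int, cols: int, size: int = 64, step: int = 16) -> list[ROI]:
    """All roving-window positions, stepped by ``step`` with an edge clamp.

    Origins run over multiples of ``step``; when (dim − size) is not
    step-aligned a final origin flush with the image edge is appended so the
    sweep covers the entire image.  Positions are in raster order.
    """
    if rows < size or cols < size:
        raise ValueError("image smaller than the roving window")

    def axis_origins(dim: int) -> list[int]:
        origins = list(range(0, dim - size + 1, step))
        if origins[-1] != dim - size:
            origins.append(dim - size)
        return origins

    return [
        ROI(origin=(r, c), size=size)
        for r in axis_origins(rows)
        for c in axis_origins(cols)
    ]


def image_sni(
    flood: FloodImage,
    geometry: ViewingGeometry | None = None,
    roi_config: ROIConfig | None = None,
    *,
    compute_artifact: bool = True,
) -> SNIResult:
    """Score every ROI and assign the maximum as the image SNI.

    Large ROIs are scored first, then the roving sweep in raster order; ties
    are broken in favour of the earliest ROI, so the sweep is deterministic.
    The artifact image is computed on the full field (for the diagnostic
    quadrant figure) unless ``compute_artifact`` is False.
    """
    cfg = roi_config or ROIConfig()
    rows, cols = flood.shape
    geo = (geometry or ViewingGeometry()).for_image(cols)
    rois = large_rois(rows, cols, cfg.fraction) + roving_rois(
        rows, cols, cfg.size, cfg.step
    )
    pixels = flood.pixels
    scores: list[tuple[ROI, SNIScore]] = []
    best_roi: ROI | None = None
    best_score: SNIScore | None = None
    for roi in rois:
        score = sni_for_patch(roi.extract(pixels), flood.spacing, geo)
        scores.append((roi, score))
        if best_score is None or score.value > best_score.value:
            best_roi, best_score = roi, score
    assert best_roi is not None and best_score is not None
    best_nps = compute_nps_2d(
        best_roi.extract(pixels).astype(np.float64), flood.spacing
    )
    art = artifact_image(pixels) if compute_artifact else None
    return SNIResult(
        image_sni=best_score.value,
        best_roi=best_roi,
        per_roi_scores=scores,
        best_nps=best_nps,
        artifact=art,
    )
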