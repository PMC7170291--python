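"""Pixel-value integral uniformity (IU) over UFOV/CFOV — the traditional metric.

IU = 100·(max − min)/(max + min) of the smoothed counts inside a field of
view: the useful field of view (UFOV, central 90% of the matrix per axis)
or the central field of view (CFOV, central 75% of the UFOV linear
dimensions).  Smoothing uses the standard 9-point kernel
[[1,2,1],[2,4,2],[1,2,1]]/16 with edge taps renormalized over the in-bounds
support.  This serves as the comparison arm for the structured noise index;
it reacts to pixel-value extremes, not to spatial texture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["FOVMask", "nema_smooth", "fov_mask", "integral_uniformity"]

_KERNEL = np.array([[1.0, 2.0, 1.0], [2.0, 4.0, 2.0], [1.0, 2.0, 1.0]]) / 16.0

UFOV_FRACTION = 0.9
CFOV_FRACTION = 0.75


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class FOVMask:
    """Rectangular field-of-view: half-open pixel bounds (row0, col0, rows, cols)."""

    kind: str  # "ufov" | "cfov"
    rect: tuple[int, int, int, int]

    def slices(self) -> tuple[slice, slice]:
        r0, c0, h, w = self.rect
        return slice(r0, r0 + h), slice(c0, c0 + w)


def nema_smooth(image: np.ndarray) -> np.ndarray:
    """9-point weighted smoothing with edge renormalization.

    Edge and corner pixels use the kernel renormalized over in-bounds taps,
    so a constant image is exactly preserved everywhere.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or min(arr.shape) < 3:
        raise ValueError("image must be 2D and at least 3x3")
    num = ndimage.convolve(arr, _KERNEL, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(arr), _KERNEL, mode="constant", cval=0.0)
    return num / den


def fov_mask(rows: int, cols: int, kind: str) -> FOVMask:
    """Centered UFOV or CFOV rectangle for an image of the given shape.

    UFOV spans round(0.9·dim) pixels per axis; CFOV spans round(0.75·UFOV)
    per axis.  Rounding is half-up; on odd margins the region sits one pixel
    toward the top/left.
    """
    if rows < 16 or cols < 16:
        raise ValueError("image must be at least 16x16")
    if kind not in ("ufov", "cfov"):
        raise ValueError(f"unknown FOV kind: {kind!r}")
    u_h = _round_half_up(UFOV_FRACTION * rows)
    u_w = _round_half_up(UFOV_FRACTION * cols)
    if kind == "ufov":
        h, w = u_h, u_w
    else:
        h, w = _round_half_up(CFOV_FRACTION * u_h), _round_half_up(CFOV_FRACTION * u_w)
    r0 = (rows - h) // 2
    c0 = (cols - w) // 2
    return FOVMask(kind=kind, rect=(r0, c0, h, w))


def integral_uniformity(image: np.ndarray, mask: FOVMask) -> float:
    """IU in percent: 100·(max − min)/(max + min) of smoothed counts in the FOV."""
    arr = np.asarray(image, dtype=np.float64)
    r0, c0, h, w = mask.rect
    if r0 < 0 or c0 < 0 or r0 + h > arr.shape[0] or c0 + w > arr.shape[1]:
        raise ValueError("FOV mask does not fit inside the image")
    region = nema_smooth(arr)[mask.slices()]
    hi, lo = float(region.max()), float(region.min())
    if hi + lo == 0:
        raise ValueError("integral uniformity undefined for an all-zero region")
    return 100.0 * (hi - lo) / (hi + lo)
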