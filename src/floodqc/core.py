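"""Noise-power-spectrum and structured-noise-index computation for flood images.

A gamma-camera flood-field image of a uniform source contains two noise
components: *quantum* noise from Poisson counting statistics, whose 2D noise
power spectrum (NPS) is flat ("white") at a level equal to the mean count
times the pixel area, and *structured* noise — spatially correlated patterns
produced by detector defects (failing photomultiplier tubes, drift,
correction-map mismatch).  The structured noise index (SNI) isolates the
structured component by subtracting the expected quantum level from the 2D
NPS, weights both spectra by a band-pass human visual response function
peaked at 4 cycles/degree, and reports the ratio

    SNI = sum(filtered structured NPS) / sum(filtered input NPS)

which is 0 for a purely quantum-limited flood and approaches 1 when
structure dominates the visually relevant frequency band.

Conventions: arrays are row-major with origin top-left; ``x`` is the column
index (spacing ``dx``), ``y`` the row index (spacing ``dy``).  The NPS is a
single-realization periodogram (no ensemble averaging, no windowing); mean
subtraction removes the DC term exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from functools import lru_cache

import numpy as np

__all__ = [
    "FloodImage",
    "NPS2D",
    "ViewingGeometry",
    "SNIScore",
    "compute_nps_2d",
    "quantum_nps_level",
    "structured_nps",
    "visual_filter_scale",
    "visual_response",
    "frequency_to_degrees",
    "apply_visual_filter",
    "sni_for_patch",
]


@dataclass
class FloodImage:
    """One flood-field acquisition: a 2D count map plus acquisition metadata.

    Parameters
    ----------
    pixels : ndarray of int
        Non-negative per-pixel counts, shape (rows, cols).
    spacing : (float, float)
        Pixel spacing ``(dx, dy)`` in mm/pixel (x = column direction).
    station : str
        Acquisition station name (camera identifier).
    acquired_at : datetime, optional
        Acquisition timestamp.
    isotope : str
        Source isotope, e.g. ``"Co-57"`` or ``"Tc-99m"``.
    total_counts : int, optional
        Total counts; computed from the pixel sum when omitted.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    station: str = ""
    acquired_at: datetime | None = None
    isotope: str = ""
    total_counts: int | None = None
    series_description: str = ""
    spacing_assumed: bool = False
    header_counts: int | None = None
    source_path: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("flood pixels must be a 2D array")
        if np.any(self.pixels < 0):
            raise ValueError("flood pixels must be non-negative counts")
        dx, dy = self.spacing
        if dx <= 0 or dy <= 0:
            raise ValueError("pixel spacing must be positive")
        if self.total_counts is None:
            self.total_counts = int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class NPS2D:
    """A 2D noise power spectrum on its frequency grid.

    ``values`` has units counts²·mm²; ``freq_u``/``freq_v`` are the spatial
    frequencies (cycles/mm) conjugate to x (columns) and y (rows), in
    standard DFT order (``numpy.fft.fftfreq``).  ``mean_intensity`` is the
    patch mean subtracted before the transform and ``ensemble_size`` the
    number of realizations averaged (1 for a single periodogram).
    """

    values: np.ndarray
    freq_u: np.ndarray
    freq_v: np.ndarray
    mean_intensity: float
    ensemble_size: int = 1
    spacing: tuple[float, float] = (1.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def total(self) -> float:
        """Discrete integral of the spectrum (sum over all bins)."""
        return float(self.values.sum())


@dataclass(frozen=True)
class ViewingGeometry:
    """Display geometry defining the visual response weighting.

    The radial frequency of each NPS bin is converted to cycles/degree
    assuming the *full* image width is rendered at ``display_cm`` and viewed
    from ``distance_cm``; ROIs inherit the full-image mapping, so a 64-pixel
    window occupies 64/W of the display.  ``filter_exponent`` is the power
    applied to the visual response V(r) when weighting the NPS (2 by
    default: a power spectrum is weighted by the squared transfer function).
    """

    distance_cm: float = 150.0
    display_cm: float = 6.5
    peak_cyc_per_deg: float = 4.0
    full_image_width_px: int = 256
    filter_exponent: int = 2

    def __post_init__(self) -> None:
        if min(self.distance_cm, self.display_cm, self.peak_cyc_per_deg) <= 0:
            raise ValueError("viewing geometry parameters must be positive")
        if self.full_image_width_px <= 0:
            raise ValueError("full_image_width_px must be positive")
        if self.filter_exponent not in (1, 2):
            raise ValueError("filter_exponent must be 1 or 2")

    def for_image(self, width_px: int) -> "ViewingGeometry":
        """Geometry with the display size anchored to an image of ``width_px``."""
        return ViewingGeometry(
            distance_cm=self.distance_cm,
            display_cm=self.display_cm,
            peak_cyc_per_deg=self.peak_cyc_per_deg,
            full_image_width_px=width_px,
            filter_exponent=self.filter_exponent,
        )


@dataclass
class SNIScore:
    """SNI for one patch, with the integrals behind the ratio."""

    value: float
    numerator: float
    denominator: float
    quantum_level: float


def compute_nps_2d(patch: np.ndarray, spacing: tuple[float, float]) -> NPS2D:
    """Single-realization 2D noise power spectrum of a patch.

    NPS(u, v) = (dx·dy)/(Nx·Ny) · |DFT(patch − mean)|², with the DC bin
    exactly zero by construction.  A constant patch yields an all-zero
    spectrum.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2 or min(patch.shape) < 8:
        raise ValueError("patch must be 2D and at least 8x8")
    dx, dy = spacing
    ny, nx = patch.shape
    mean = float(patch.mean())
    spectrum = np.fft.fft2(patch - mean)
    values = (dx * dy) / (nx * ny) * np.abs(spectrum) ** 2
    values[0, 0] = 0.0
    return NPS2D(
        values=values,
        freq_u=np.fft.fftfreq(nx, d=dx),
        freq_v=np.fft.fftfreq(ny, d=dy),
        mean_intensity=mean,
        ensemble_size=1,
        spacing=(dx, dy),
    )


def quantum_nps_level(patch: np.ndarray, spacing: tuple[float, float]) -> float:
    """Expected white-noise NPS level of Poisson counting noise.

    For Poisson counts the variance equals the mean, and white noise of
    variance σ² has a flat NPS at σ²·dx·dy, so the quantum floor is the
    patch mean times the pixel area (counts²·mm²).
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.size == 0:
        raise ValueError("patch must be nonempty")
    dx, dy = spacing
    return float(patch.mean()) * dx * dy


def structured_nps(
    input_nps: NPS2D, quantum_level: float, *, clamp: bool = True
) -> NPS2D:
    """Subtract the flat quantum floor from every non-DC bin.

    With ``clamp`` (default) residuals below the floor are set to 0, giving
    a non-negative spectrum suitable for display.  The SNI integral itself
    uses the unclamped residual (``clamp=False``): a single-realization
    periodogram bin is exponentially distributed about the quantum level,
    so zeroing the negative half of the fluctuations would bias the
    structured-noise integral upward by a factor 1/e of the total quantum
    power and saturate the index on structure-free floods.
    """
    if quantum_level < 0:
        raise ValueError("quantum level must be non-negative")
    values = input_nps.values - quantum_level
    if clamp:
        values = np.maximum(values, 0.0)
    values[0, 0] = 0.0
    return NPS2D(
        values=values,
        freq_u=input_nps.freq_u,
        freq_v=input_nps.freq_v,
        mean_intensity=input_nps.mean_intensity,
        ensemble_size=input_nps.ensemble_size,
        spacing=input_nps.spacing,
    )


def visual_filter_scale(geometry: ViewingGeometry) -> float:
    """Scale factor c placing the peak of V(r) = r^1.3·exp(−c·r²) at the target.

    Setting dV/dr = 0 gives r* = sqrt(1.3 / (2c)), hence c = 1.3 / (2·r*²).
    With the default 4 cycles/degree peak, c = 0.040625 (cyc/deg)⁻².
    """
    return 1.3 / (2.0 * geometry.peak_cyc_per_deg**2)


def visual_response(r: np.ndarray | float, c: float) -> np.ndarray:
    """Band-pass visual response V(r) = r^1.3 · exp(−c·r²); V(0) = 0."""
    r = np.asarray(r, dtype=np.float64)
    positive = r > 0
    safe = np.where(positive, r, 1.0)
    return np.where(positive, safe**1.3 * np.exp(-c * safe**2), 0.0)


def frequency_to_degrees(
    f_cyc_per_px: np.ndarray | float, geometry: ViewingGeometry
) -> np.ndarray | float:
    """Convert spatial frequency in cycles/pixel to cycles/degree of visual angle.

    The full image width maps onto ``display_cm`` on screen, so one pixel
    subtends display_cm / W centimetres; at viewing distance D a centimetre
    subtends (180/π)/D degrees (small-angle).  The same mapping applies to
    every ROI regardless of its size.
    """
    scale = (
        geometry.full_image_width_px / geometry.display_cm
    ) * geometry.distance_cm * np.pi / 180.0
    return f_cyc_per_px * scale


@lru_cache(maxsize=64)
def _filter_weights(
    shape: tuple[int, int],
    geometry: ViewingGeometry,
) -> np.ndarray:
    """Visual weights V(r)^exponent on the DFT grid of ``shape`` (cycles/pixel).

    Frequencies are taken in cycles/pixel so the weighting — and therefore
    the SNI — is independent of the physical pixel spacing.
    """
    ny, nx = shape
    fx = np.fft.fftfreq(nx)  # cycles/pixel
    fy = np.fft.fftfreq(ny)
    r_px = np.hypot(fy[:, None], fx[None, :])
    r_deg = frequency_to_degrees(r_px, geometry)
    c = visual_filter_scale(geometry)
    weights = visual_response(r_deg, c) ** geometry.filter_exponent
    weights[0, 0] = 0.0
    return weights


def apply_visual_filter(nps: NPS2D, geometry: ViewingGeometry) -> NPS2D:
    """Weight an NPS by the human visual response on its frequency grid."""
    weights = _filter_weights(nps.shape, geometry)
    return NPS2D(
        values=nps.values * weights,
        freq_u=nps.freq_u,
        freq_v=nps.freq_v,
        mean_intensity=nps.mean_intensity,
        ensemble_size=nps.ensemble_size,
        spacing=nps.spacing,
    )


def _detrend_plane(patch: np.ndarray) -> np.ndarray:
    """Remove the least-squares plane a + b·row + c·col (optional hook)."""
    ny, nx = patch.shape
    rows, cols = np.mgrid[0:ny, 0:nx]
    design = np.column_stack(
        [np.ones(patch.size), rows.ravel(), cols.ravel()]
    )
    coef, *_ = np.linalg.lstsq(design, patch.ravel(), rcond=None)
    return patch - (design @ coef).reshape(patch.shape)


def sni_for_patch(
    patch: np.ndarray,
    spacing: tuple[float, float],
    geometry: ViewingGeometry,
    *,
    quantum_mean: float | None = None,
    detrend: bool = False,
) -> SNIScore:
    """Structured noise index of a single patch.

    Computes the periodogram NPS, subtracts the quantum floor from every
    non-DC bin (unclamped — see :func:`structured_nps`), applies the visual
    filter to both the structured and the input spectrum, and returns the
    ratio of their discrete integrals, clamped to [0, 1].

    Parameters
    ----------
    quantum_mean : float, optional
        Mean count used for the quantum floor.  Defaults to the patch mean
        (local floor); pass the global image mean to use a global floor.
    detrend : bool
        Remove a least-squares plane before the transform (off by default).
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2 or min(patch.shape) < 16:
        raise ValueError("patch must be 2D and at least 16x16")
    dx, dy = spacing
    level = (patch.mean() if quantum_mean is None else quantum_mean) * dx * dy
    if np.ptp(patch) == 0:
        # constant patch: no noise of either kind
        return SNIScore(value=0.0, numerator=0.0, denominator=0.0, quantum_level=level)
    work = _detrend_plane(patch) if detrend else patch
    nps = compute_nps_2d(work, spacing)
    struct = structured_nps(nps, level, clamp=False)
    weights = _filter_weights(nps.shape, geometry)
    denominator = float((nps.values * weights).sum())
    numerator = float((struct.values * weights).sum())
    if denominator <= 0:
        return SNIScore(value=0.0, numerator=numerator, denominator=denominator, quantum_level=level)
    value = min(max(numerator / denominator, 0.0), 1.0)
    return SNIScore(
        value=value, numerator=numerator, denominator=denominator, quantum_level=level
    )
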