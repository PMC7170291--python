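"""Artifact image: Fourier-domain thresholding that isolates nonuniform structure.

Under a pure counting-noise null the mean-subtracted flood is (approximately)
iid Gaussian with per-pixel variance equal to the mean count, so each non-DC
coefficient of its unnormalized 2D DFT is complex Gaussian and its magnitude
is Rayleigh with scale sqrt(Nx·Ny·mean/2).  Coefficients whose magnitude
stays within a high quantile of that null are zeroed; the inverse transform
of the survivors renders only the structure a uniform flood should not
contain.  The default quantile, 1 − 1/N_bins, admits about one false
coefficient per image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ArtifactImage", "artifact_image"]


@dataclass
class ArtifactImage:
    """Thresholded-spectrum reconstruction of the nonuniform structure."""

    values: np.ndarray
    retained_bins: int
    threshold: float


def artifact_image(
    flood_or_patch: np.ndarray, quantile: float | None = None
) -> ArtifactImage:
    """Build the artifact image of a count map.

    Parameters
    ----------
    flood_or_patch : ndarray
        2D count map, at least 16×16.
    quantile : float, optional
        Probability level of the Rayleigh null used as the magnitude cutoff;
        defaults to 1 − 1/N_bins ("expect one false coefficient").

    Returns
    -------
    ArtifactImage
        Real-valued map of the retained structure (same shape as the input),
        the number of retained coefficients, and the threshold applied.
        Retained coefficients keep their full complex value; the DC bin is
        always removed, so a structure-free input yields an all-zero map.
    """
    arr = np.asarray(flood_or_patch, dtype=np.float64)
    if arr.ndim != 2 or min(arr.shape) < 16:
        raise ValueError("input must be 2D and at least 16x16")
    n_bins = arr.size
    if quantile is None:
        quantile = 1.0 - 1.0 / n_bins
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie strictly between 0 and 1")
    mean = float(arr.mean())
    if mean <= 0 or np.ptp(arr) == 0:
        return ArtifactImage(values=np.zeros_like(arr), retained_bins=0, threshold=0.0)
    spectrum = np.fft.fft2(arr - mean)
    # Rayleigh null: per-pixel Poisson variance ≈ mean, unnormalized DFT
    sigma = np.sqrt(n_bins * mean / 2.0)
    threshold = float(sigma * np.sqrt(-2.0 * np.log1p(-quantile)))
    keep = np.abs(spectrum) > threshold
    keep[0, 0] = False
    retained = int(keep.sum())
    values = np.fft.ifft2(np.where(keep, spectrum, 0.0)).real
    return ArtifactImage(values=values, retained_bins=retained, threshold=threshold)
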