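import numpy as np
import pytest

from floodqc.core import ViewingGeometry
from floodqc.synthetic import DefectSpec, make_sensitivity_map, simulate_flood


@pytest.fixture
def geometry():
    return ViewingGeometry()


@pytest.fixture
def flood_factory():
    """Factory for small synthetic floods: (shape, defects, counts, seed) -> FloodImage."""

    def make(shape=(128, 128), defects=(), total_counts=2_000_000, seed=0, **kwargs):
        smap = make_sensitivity_map(shape, list(defects))
        return simulate_flood(smap, total_counts, seed, **kwargs)

    return make


@pytest.fixture
def dropout():
    """A clearly service-worthy local defect: 20% PMT dropout, FWHM 40 px."""

    def make(amplitude=0.2, center=(96.0, 128.0), width=40.0):
        return DefectSpec(
            kind="pmt_dropout", amplitude=amplitude, center=center, width=width
        )

    return make


def nps_direct(patch, dx, dy):
    """Brute-force double-sum NPS evaluation, independent of the FFT path."""
    patch = np.asarray(patch, dtype=np.float64)
    ny, nx = patch.shape
    centered = patch - patch.mean()
    xs = np.arange(nx)
    ys = np.arange(ny)
    out = np.empty((ny, nx))
    for kv in range(ny):
        for ku in range(nx):
            phase = np.exp(
                -2j * np.pi * (ku * xs[None, :] / nx + kv * ys[:, None] / ny)
            )
            out[kv, ku] = (dx * dy) / (nx * ny) * abs((centered * phase).sum()) ** 2
    out[0, 0] = 0.0
    return out
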