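"""NPS, quantum subtraction, visual filter and patch-level SNI."""

import numpy as np
import pytest

from floodqc.core import (
    ViewingGeometry,
    apply_visual_filter,
    compute_nps_2d,
    frequency_to_degrees,
    quantum_nps_level,
    sni_for_patch,
    structured_nps,
    visual_filter_scale,
    visual_response,
)

from conftest import nps_direct


class TestComputeNPS:
    def test_constant_patch_gives_zero_spectrum(self):
        nps = compute_nps_2d(np.full((8, 8), 42.0), (1.0, 1.0))
        assert np.all(nps.values == 0.0)

    @pytest.mark.parametrize("shape,spacing", [((8, 8), (1.0, 1.0)), ((8, 12), (0.5, 2.0))])
    def test_matches_direct_double_sum(self, shape, spacing):
        rng = np.random.default_rng(3)
        patch = rng.integers(0, 100, shape).astype(float)
        nps = compute_nps_2d(patch, spacing)
        expected = nps_direct(patch, *spacing)
        assert np.allclose(nps.values, expected, rtol=1e-10, atol=1e-12)

    def test_white_noise_level_matches_variance(self):
        rng = np.random.default_rng(1)
        patch = rng.normal(0.0, 2.0, (64, 64))
        nps = compute_nps_2d(patch, (1.0, 1.0))
        mean_level = nps.values.sum() / (patch.size - 1)
        assert mean_level == pytest.approx(4.0, rel=0.10)

    def test_dc_bin_exactly_zero_and_axes_match(self):
        rng = np.random.default_rng(2)
        nps = compute_nps_2d(rng.poisson(50, (16, 24)), (2.0, 3.0))
        assert nps.values[0, 0] == 0.0
        assert len(nps.freq_v) == 16 and len(nps.freq_u) == 24
        # conjugate axes carry the pixel spacing
        assert nps.freq_u[1] == pytest.approx(1 / (24 * 2.0))
        assert nps.freq_v[1] == pytest.approx(1 / (16 * 3.0))

    def test_rejects_tiny_patch(self):
        with pytest.raises(ValueError):
            compute_nps_2d(np.ones((4, 4)), (1.0, 1.0))


class TestQuantumLevel:
    @pytest.mark.parametrize(
        "mean,spacing,expected",
        [(100.0, (1.0, 1.0), 100.0), (250.0, (0.5, 0.5), 62.5)],
    )
    def test_definition(self, mean, spacing, expected):
        patch = np.full((8, 8), mean)
        assert quantum_nps_level(patch, spacing) == pytest.approx(expected)

    def test_poisson_flat_spectrum_matches_level(self):
        lam = 500.0
        rng = np.random.default_rng(7)
        patch = rng.poisson(lam, (64, 64))
        level = quantum_nps_level(patch, (1.0, 1.0))
        nps = compute_nps_2d(patch, (1.0, 1.0))
        measured = nps.values.sum() / (patch.size - 1)
        assert measured == pytest.approx(level, rel=0.05)


class TestStructuredNPS:
    def test_subtraction_and_clamp_rules(self):
        nps = compute_nps_2d(np.random.default_rng(0).poisson(100, (8, 8)), (1, 1))
        nps.values[:] = 120.0
        nps.values[0, 0] = 0.0
        out = structured_nps(nps, 100.0)
        assert out.values[1, 1] == pytest.approx(20.0)
        out_zero = structured_nps(nps, 120.0)
        assert np.all(out_zero.values == 0.0)
        out_clamped = structured_nps(nps, 200.0)
        assert np.all(out_clamped.values == 0.0)  # never negative when clamped

    def test_unclamped_residual_keeps_sign(self):
        nps = compute_nps_2d(np.random.default_rng(0).poisson(100, (8, 8)), (1, 1))
        nps.values[:] = 80.0
        nps.values[0, 0] = 0.0
        out = structured_nps(nps, 100.0, clamp=False)
        assert out.values[1, 1] == pytest.approx(-20.0)
        assert out.values[0, 0] == 0.0


class TestVisualFilter:
    def test_scale_closed_form(self, geometry):
        assert visual_filter_scale(geometry) == pytest.approx(1.3 / 32.0)

    def test_response_peaks_at_four_cycles_per_degree(self, geometry):
        c = visual_filter_scale(geometry)
        r = np.linspace(0.001, 20.0, 200001)
        assert r[np.argmax(visual_response(r, c))] == pytest.approx(4.0, abs=1e-3)

    def test_doubling_peak_quarters_scale(self, geometry):
        doubled = ViewingGeometry(peak_cyc_per_deg=8.0)
        assert visual_filter_scale(doubled) == pytest.approx(
            visual_filter_scale(geometry) / 4.0
        )

    def test_frequency_mapping(self, geometry):
        assert frequency_to_degrees(0.0, geometry) == 0.0
        r = frequency_to_degrees(1.0 / 256.0, geometry)
        assert r == pytest.approx((1 / 6.5) * 150.0 * np.pi / 180.0, rel=1e-12)
        far = ViewingGeometry(distance_cm=300.0)
        assert frequency_to_degrees(0.01, far) == pytest.approx(
            2.0 * frequency_to_degrees(0.01, geometry)
        )

    def test_filter_zeroes_dc_and_preserves_proportionality(self, geometry):
        rng = np.random.default_rng(5)
        nps = compute_nps_2d(rng.poisson(200, (32, 32)), (1.0, 1.0))
        filtered = apply_visual_filter(nps, geometry)
        assert filtered.values[0, 0] == 0.0
        # doubling the spectrum doubles the filtered integral (linear weighting)
        nps2 = compute_nps_2d(rng.poisson(200, (32, 32)), (1.0, 1.0))
        nps2.values = 2.0 * nps.values
        assert apply_visual_filter(nps2, geometry).total() == pytest.approx(
            2.0 * filtered.total(), rel=1e-12
        )


class TestPatchSNI:
    def test_constant_patch_scores_zero(self, geometry):
        score = sni_for_patch(np.full((32, 32), 500.0), (1.0, 1.0), geometry)
        assert score.value == 0.0

    def test_bounded_and_spacing_invariant(self, geometry):
        rng = np.random.default_rng(9)
        patch = rng.poisson(800, (64, 64))
        fine = sni_for_patch(patch, (0.5, 0.5), geometry)
        coarse = sni_for_patch(patch, (2.0, 2.0), geometry)
        assert 0.0 <= fine.value <= 1.0
        assert fine.value == pytest.approx(coarse.value, abs=1e-12)

    def test_structure_dominated_limit(self, geometry):
        # huge counts + fixed 5% sinusoid: quantum floor negligible, SNI -> 1
        rows, cols = np.mgrid[0:64, 0:64]
        pattern = 1e6 * (1.0 + 0.05 * np.sin(2 * np.pi * 0.05 * rows))
        score = sni_for_patch(pattern, (1.0, 1.0), geometry)
        assert score.value > 0.95

    def test_expectation_increases_with_sinusoid_amplitude(self, geometry):
        means = []
        for amp in (0.0, 0.01, 0.03, 0.05):
            vals = []
            for seed in range(20):
                rng = np.random.default_rng(1000 + seed)
                rows = np.arange(64)[:, None]
                lam = 1000.0 * (1.0 + amp * np.sin(2 * np.pi * 0.05 * rows))
                patch = rng.poisson(np.broadcast_to(lam, (64, 64)))
                vals.append(sni_for_patch(patch, (1.0, 1.0), geometry).value)
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_quantum_mean_override_and_detrend_hook(self, geometry):
        rng = np.random.default_rng(4)
        patch = rng.poisson(500, (32, 32)).astype(float)
        local = sni_for_patch(patch, (1.0, 1.0), geometry)
        global_floor = sni_for_patch(patch, (1.0, 1.0), geometry, quantum_mean=480.0)
        assert local.quantum_level != global_floor.quantum_level
        ramp = patch + np.linspace(0, 50, 32)[None, :]
        with_trend = sni_for_patch(ramp, (1.0, 1.0), geometry)
        detrended = sni_for_patch(ramp, (1.0, 1.0), geometry, detrend=True)
        assert detrended.value < with_trend.value
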