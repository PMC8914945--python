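"""Processing-chain tests: truncation, baselining, zapping, SG derivative."""

from __future__ import annotations

import numpy as np
import pytest

import lsratio as lr
from lsratio.errors import EmptyRangeError, InvalidGridError, InvalidParameterError
from lsratio.preprocess import zap_regions


def _flat(nu, value=0.0, **meta):
    return lr.Spectrum(wavenumbers=nu, absorbances=np.full_like(nu, value), **meta)


class TestTruncate:
    def test_default_window_keeps_1336_points(self, full_grid):
        sp = _flat(full_grid)
        out = lr.truncate(sp, 830.0, 3500.0)
        assert out.wavenumbers.size == 1336
        assert out.wavenumbers[0] == 830.0 and out.wavenumbers[-1] == 3500.0

    def test_full_range_is_identity(self, full_grid):
        sp = _flat(full_grid, 0.01)
        out = lr.truncate(sp, full_grid[0], full_grid[-1])
        assert np.array_equal(out.wavenumbers, sp.wavenumbers)
        assert np.array_equal(out.absorbances, sp.absorbances)

    def test_disjoint_window_raises(self, full_grid):
        with pytest.raises(EmptyRangeError):
            lr.truncate(_flat(full_grid), 5000.0, 6000.0)

    def test_metadata_preserved(self, full_grid):
        sp = _flat(full_grid, session_id="s1", sample_id="a", replicate=3)
        out = lr.truncate(sp, 1000.0, 2000.0)
        assert (out.session_id, out.sample_id, out.replicate) == ("s1", "a", 3)


class TestBaselineOffset:
    def test_constant_spectrum_becomes_zero(self, full_grid):
        out = lr.baseline_offset(_flat(full_grid, 0.01), 2500.0)
        assert np.array_equal(out.absorbances, np.zeros_like(full_grid))

    def test_idempotent(self, full_grid, rng):
        sp = lr.Spectrum(full_grid, rng.normal(0, 1e-3, full_grid.size))
        once = lr.baseline_offset(sp, 2500.0)
        twice = lr.baseline_offset(once, 2500.0)
        assert np.array_equal(once.absorbances, twice.absorbances)

    def test_subtracts_anchor_value_everywhere(self, full_grid):
        sp = _flat(full_grid, 0.0)
        idx = int(np.argmin(np.abs(full_grid - 2500.0)))
        sp.absorbances[idx] = 3.7e-4
        out = lr.baseline_offset(sp, 2500.0)
        assert out.absorbances[idx] == 0.0
        assert out.absorbances[0] == pytest.approx(-3.7e-4)

    def test_pairwise_differences_unchanged(self, full_grid, rng):
        sp = lr.Spectrum(full_grid, rng.normal(0, 1e-3, full_grid.size))
        out = lr.baseline_offset(sp, 2500.0)
        np.testing.assert_allclose(
            np.diff(out.absorbances), np.diff(sp.absorbances), atol=1e-18
        )

    def test_anchor_outside_grid_raises(self, full_grid):
        with pytest.raises(InvalidParameterError):
            lr.baseline_offset(_flat(full_grid), 9000.0)


class TestNoiseEstimate:
    def test_recovers_gaussian_noise_level(self, full_grid, rng):
        sp = lr.Spectrum(full_grid, rng.normal(0.0, 4e-5, full_grid.size))
        est = lr.estimate_noise_sd(sp, (2450.0, 2640.0))
        assert est == pytest.approx(4e-5, rel=0.15)

    def test_linear_segment_estimates_zero(self, full_grid):
        sp = lr.Spectrum(full_grid, 1e-6 * full_grid + 0.01)
        assert lr.estimate_noise_sd(sp, (2450.0, 2640.0)) == pytest.approx(0.0, abs=1e-15)

    def test_constant_segment_estimates_zero(self, full_grid):
        assert lr.estimate_noise_sd(_flat(full_grid, 0.02)) == pytest.approx(0.0, abs=1e-18)

    def test_too_few_points_rejected(self, full_grid):
        with pytest.raises(InvalidParameterError):
            lr.estimate_noise_sd(_flat(full_grid), (2450.0, 2455.0))


class TestZapRegions:
    REGIONS = ((2150.0, 2430.0), (1190.0, 1310.0))

    def test_zero_noise_fills_with_zeros(self, full_grid):
        sp = _flat(full_grid, 0.01)
        out = zap_regions(sp, self.REGIONS, 0.0, seed=0)
        for lo, hi in self.REGIONS:
            mask = (full_grid >= lo) & (full_grid <= hi)
            assert np.all(out.absorbances[mask] == 0.0)

    def test_points_outside_regions_unchanged_bitwise(self, full_grid, rng):
        sp = lr.Spectrum(full_grid, rng.normal(0, 1e-3, full_grid.size))
        out = zap_regions(sp, self.REGIONS, 4e-5, seed=0)
        outside = np.ones(full_grid.size, dtype=bool)
        for lo, hi in self.REGIONS:
            outside &= ~((full_grid >= lo) & (full_grid <= hi))
        assert np.array_equal(out.absorbances[outside], sp.absorbances[outside])

    def test_fill_noise_matches_requested_level(self, full_grid):
        """Pooled over many spectra, the fill sd reproduces noise_sd."""
        values = []
        stream = np.random.default_rng(99)
        sp = _flat(full_grid, 0.005)
        for _ in range(50):
            out = zap_regions(sp, self.REGIONS, 4e-5, seed=stream)
            for lo, hi in self.REGIONS:
                mask = (full_grid >= lo) & (full_grid <= hi)
                values.append(out.absorbances[mask])
        sd = float(np.std(np.concatenate(values), ddof=1))
        assert sd == pytest.approx(4e-5, rel=0.05)

    def test_seeded_reproducibility(self, full_grid):
        sp = _flat(full_grid, 0.01)
        a = zap_regions(sp, self.REGIONS, 4e-5, seed=7)
        b = zap_regions(sp, self.REGIONS, 4e-5, seed=7)
        assert np.array_equal(a.absorbances, b.absorbances)

    def test_negative_noise_sd_rejected(self, full_grid):
        with pytest.raises(InvalidParameterError):
            zap_regions(_flat(full_grid), self.REGIONS, -1.0)


class TestSecondDerivative:
    def test_quadratic_gives_constant_curvature(self):
        nu = 1000.0 + 2.0 * np.arange(200)
        a, b, c = 3e-7, -1e-4, 0.5
        sp = lr.Spectrum(nu, a * nu**2 + b * nu + c)
        out = lr.second_derivative(sp, 15, 3)
        np.testing.assert_allclose(out.absorbances, 2 * a, rtol=1e-6)

    def test_cubic_matches_analytic_second_derivative(self):
        """SG order-3 filters reproduce cubics exactly (polyder oracle)."""
        nu = 800.0 + 2.0 * np.arange(300)
        coeffs = np.array([2e-10, -4e-7, 1e-4, -0.02])
        sp = lr.Spectrum(nu, np.polyval(coeffs, nu))
        expected = np.polyval(np.polyder(coeffs, 2), nu)
        out = lr.second_derivative(sp, 15, 3)
        interior = slice(7, -7)
        np.testing.assert_allclose(out.absorbances[interior], expected[interior], rtol=1e-6)

    def test_constant_maps_to_zero(self, full_grid):
        out = lr.second_derivative(_flat(full_grid, 0.3))
        np.testing.assert_allclose(out.absorbances, 0.0, atol=1e-12)

    def test_nonuniform_grid_rejected(self):
        nu = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 17.0, 18.0, 19.0, 20.0] + list(range(21, 31)))
        sp = lr.Spectrum(np.asarray(nu, float), np.zeros(len(nu)))
        with pytest.raises(InvalidGridError):
            lr.second_derivative(sp, 5, 3)

    def test_window_shorter_than_spectrum_required(self):
        nu = 1000.0 + 2.0 * np.arange(10)
        with pytest.raises(InvalidParameterError):
            lr.second_derivative(lr.Spectrum(nu, np.zeros(10)), 15, 3)


class TestPipeline:
    def test_identity_case(self, clean_preprocess):
        nu = 830.0 + 2.0 * np.arange(1336)
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1e-3, nu.size)
        anchor = int(np.argmin(np.abs(nu - 2500.0)))
        values -= values[anchor]
        sp = lr.Spectrum(nu, values)
        from dataclasses import replace

        cfg = replace(clean_preprocess, zap_regions=(), derivative_order=0)
        out = lr.preprocess_pipeline(sp, cfg)
        assert np.array_equal(out.absorbances, sp.absorbances)

    def test_derivative_invariant_to_additive_linear_baseline(self):
        """pipeline(x + a + b*nu) with derivative == pipeline(x) with derivative."""
        from dataclasses import replace

        cfg = replace(lr.PreprocessConfig(derivative_order=2), zap_regions=())
        nu = lr.GeneratorConfig().wavenumbers()
        rng = np.random.default_rng(8)
        smooth = np.convolve(rng.normal(0, 1e-3, nu.size), np.ones(25) / 25, mode="same")
        sp = lr.Spectrum(nu, smooth)
        shifted = lr.Spectrum(nu, smooth + 0.02 + 1e-5 * nu)
        a = lr.preprocess_pipeline(sp, cfg)
        b = lr.preprocess_pipeline(shifted, cfg)
        np.testing.assert_allclose(a.absorbances, b.absorbances, atol=1e-10)

    def test_point_count_fixed_after_truncation(self, default_dataset):
        for cfg in (
            lr.PreprocessConfig(derivative_order=0),
            lr.PreprocessConfig(derivative_order=2),
        ):
            out = lr.preprocess_pipeline(default_dataset[0], cfg)
            assert out.wavenumbers.size == 1336

    def test_zapped_region_bounded_by_noise(self, default_dataset):
        """After zapping, the solvent region carries only fill noise."""
        cfg = lr.PreprocessConfig(derivative_order=0)
        out = lr.preprocess_dataset(default_dataset[:40], cfg)
        for sp in out:
            mask = (sp.wavenumbers > 1190) & (sp.wavenumbers < 1310)
            assert np.all(np.abs(sp.absorbances[mask]) <= 6 * cfg.zap_noise_sd)

    def test_determinism(self, default_dataset):
        cfg = lr.PreprocessConfig(derivative_order=2, zap_seed=21)
        a = lr.preprocess_pipeline(default_dataset[0], cfg)
        b = lr.preprocess_pipeline(default_dataset[0], cfg)
        assert np.array_equal(a.absorbances, b.absorbances)
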