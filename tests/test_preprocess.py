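"""Quality control, baseline, smoothing, differentiation, ROI extraction."""

import numpy as np
import pytest

import cartspec as cs
from cartspec import mapping
from cartspec.preprocess import (
    average_roi,
    baseline_correct,
    crop,
    cube_quality,
    extract_rois,
    minmax_normalize,
    preprocess_cube,
    quality_test,
    second_derivative,
    smooth,
)
from cartspec.spectra import Spectrum, build_grid

GRID = build_grid(1800.0, 900.0, 3.93)


def _spec(values):
    return Spectrum(GRID, values)


class TestQuality:
    def test_zero_spectrum_fails_thickness(self):
        rep = quality_test(_spec(np.zeros_like(GRID)))
        assert not rep.passed
        assert any("thickness" in r for r in rep.reasons)

    def test_clean_synthetic_spectrum_passes(self, sz_control_cube):
        rep = quality_test(sz_control_cube.mean_spectrum())
        assert rep.passed, rep.reasons
        assert rep.snr > 10

    def test_saturated_spectrum_fails(self):
        rep = quality_test(_spec(10.0 * np.exp(-0.5 * ((GRID - 1660) / 30) ** 2)))
        assert not rep.passed
        assert any("too high" in r for r in rep.reasons)

    def test_window_coverage_required(self):
        g = build_grid(1500.0, 900.0, 3.93)
        with pytest.raises(ValueError):
            quality_test(Spectrum(g, np.ones_like(g)))

    def test_cube_quality_matches_per_pixel_test(self, sz_control_cube):
        mask, summary = cube_quality(sz_control_cube)
        singles = np.array(
            [
                quality_test(sz_control_cube.pixel(iy, ix)).passed
                for iy in range(sz_control_cube.ny)
                for ix in range(sz_control_cube.nx)
            ]
        )
        assert np.array_equal(mask.ravel(), singles)
        assert summary["n_passed"] == int(singles.sum())


class TestBaseline:
    def test_pure_quadratic_removed(self):
        s = _spec(0.3 + 0.001 * (GRID - 1300) + 2e-7 * (GRID - 1300) ** 2)
        out = baseline_correct(s, order=2)
        assert np.max(np.abs(out.absorbance)) < 1e-8

    def test_order_zero_on_constant(self):
        s = _spec(np.full_like(GRID, 0.7))
        out = baseline_correct(s, order=0)
        assert np.max(np.abs(out.absorbance)) < 1e-10

    def test_band_integral_preserved_over_quadratic(self):
        band = 0.5 * np.exp(-0.5 * ((GRID - 1340) / 9.0) ** 2)
        base = 0.1 + 2e-4 * (GRID - 1300) + 1e-7 * (GRID - 1300) ** 2
        corrected = baseline_correct(_spec(band + base), order=2)
        truth = mapping.integrate_band(_spec(band), (1380.0, 1300.0))
        got = mapping.integrate_band(corrected, (1380.0, 1300.0))
        assert got == pytest.approx(truth, rel=0.03)

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValueError):
            baseline_correct(Spectrum(GRID[:2], np.ones(2)), order=2)


class TestNormalize:
    def test_global_mode_is_affine_invariant(self):
        s = _spec(np.exp(-0.5 * ((GRID - 1660) / 20.0) ** 2))
        t = Spectrum(GRID, 3.0 * s.absorbance + 0.2)
        assert np.allclose(
            minmax_normalize(s).absorbance, minmax_normalize(t).absorbance, atol=1e-12
        )
        out = minmax_normalize(s).absorbance
        assert out.min() == 0.0 and out.max() == 1.0

    def test_amide_i_mode_scales_band_maximum_to_one(self):
        s = _spec(2.0 * np.exp(-0.5 * ((GRID - 1650) / 15.0) ** 2))
        out = minmax_normalize(s, mode="amideI")
        assert out.max_in(1700.0, 1600.0) == pytest.approx(1.0)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize(_spec(np.ones_like(GRID)))


class TestSavitzkyGolay:
    def test_linear_spectrum_unchanged_by_smoothing(self):
        s = _spec(0.001 * GRID + 0.1)
        assert np.allclose(smooth(s, 9, 2).absorbance, s.absorbance, atol=1e-10)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        s = _spec(rng.normal(size=GRID.size))
        assert smooth(s, 9, 2).absorbance.var() < s.absorbance.var()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth(_spec(GRID * 0.001), window=8)

    def test_second_derivative_of_quadratic_is_two(self):
        s = _spec(GRID.astype(float) ** 2)
        d2 = second_derivative(s)
        assert np.allclose(d2.absorbance, 2.0, rtol=1e-6)

    def test_second_derivative_of_linear_is_zero(self):
        d2 = second_derivative(_spec(0.01 * GRID + 3.0))
        assert np.max(np.abs(d2.absorbance)) < 1e-8

    def test_gaussian_band_minimum_at_center(self):
        """A band at 1635 cm^-1 appears as the global 2nd-derivative minimum."""
        s = _spec(np.exp(-0.5 * ((GRID - 1635.0) / 11.0) ** 2))
        d2 = second_derivative(s)
        k_min = d2.wavenumbers[np.argmin(d2.absorbance)]
        nearest = GRID[np.argmin(np.abs(GRID - 1635.0))]
        assert k_min == nearest

    def test_second_derivative_is_linear(self):
        a = np.exp(-0.5 * ((GRID - 1550) / 14.0) ** 2)
        b = 0.5 * np.exp(-0.5 * ((GRID - 1080) / 10.0) ** 2)
        lhs = second_derivative(_spec(a + b)).absorbance
        rhs = second_derivative(_spec(a)).absorbance + second_derivative(_spec(b)).absorbance
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestROIs:
    def test_default_rois_disjoint_and_in_bounds(self):
        cube = cs.generate_cube(
            cs.GeneratorConfig(pixels_x=64, pixels_y=64, seed=5),
            cs.default_profiles()[("SZ", "C")],
            cs.default_bands("SZ"),
        )
        rois = extract_rois(cube, n=5, size=(10, 10), seed=3)
        assert len(rois) == 5
        seen = set()
        for x0, y0, w, h in rois:
            assert 0 <= x0 <= 54 and 0 <= y0 <= 54
            pix = {(x, y) for x in range(x0, x0 + w) for y in range(y0, y0 + h)}
            assert not (pix & seen)
            seen |= pix

    def test_roi_extraction_deterministic(self, sz_control_cube):
        a = extract_rois(sz_control_cube, n=1, size=(10, 10), seed=9)
        b = extract_rois(sz_control_cube, n=1, size=(10, 10), seed=9)
        assert a.rois == b.rois

    def test_exact_fit_returns_full_cube(self):
        cube = cs.generate_cube(
            cs.GeneratorConfig(pixels_x=10, pixels_y=10, seed=1),
            cs.default_profiles()[("MZ", "C")],
            cs.default_bands("MZ"),
        )
        rois = extract_rois(cube, n=1, size=(10, 10), seed=0)
        assert rois.rois == [(0, 0, 10, 10)]
        with pytest.raises(ValueError):
            extract_rois(cube, n=2, size=(10, 10), seed=0)

    def test_average_roi_of_two_pixels(self):
        g = build_grid(1800.0, 900.0, 3.93)
        data = np.zeros((1, 2, g.size))
        data[0, 0] = 1.0
        data[0, 1] = 3.0
        cube = cs.SpectralCube(grid=g, data=data)
        avg = average_roi(cube, (0, 0, 2, 1))
        assert np.allclose(avg.absorbance, 2.0)

    def test_roi_mean_noise_attenuation(self):
        """Averaging n iid-noise pixels shrinks the residual SD by sqrt(n)."""
        cfg = cs.GeneratorConfig(
            pixels_x=10, pixels_y=10, noise_sd=0.05, heterogeneity_sd=0.0,
            baseline_coeffs_sd=0.0, seed=12,
        )
        cube = cs.generate_cube(cfg, cs.default_profiles()[("DZ", "C")], cs.default_bands("DZ"))
        clean = cs.generate_cube(
            cs.GeneratorConfig(**{**cfg.__dict__, "noise_sd": 0.0}),
            cs.default_profiles()[("DZ", "C")],
            cs.default_bands("DZ"),
        )
        resid = average_roi(cube, (0, 0, 10, 10)).absorbance - clean.pixel(0, 0).absorbance
        assert resid.std() == pytest.approx(0.05 / 10.0, rel=0.35)


class TestPipelineComposition:
    def test_pipeline_idempotent_on_own_output(self, sz_control_cube):
        once = preprocess_cube(sz_control_cube, normalize="global")
        twice = preprocess_cube(once, normalize="global", crop_bounds=None)
        # a second pass only re-touches the noise floor (few % of full scale)
        assert np.allclose(once.data, twice.data, atol=0.05)
        assert np.corrcoef(once.data.ravel(), twice.data.ravel())[0, 1] > 0.999

    def test_preprocess_crops_to_fingerprint(self, sz_control_cube):
        out = preprocess_cube(sz_control_cube)
        assert out.grid.size == 212
        assert out.grid[0] <= 1730.0 and out.grid[-1] >= 900.0
        assert "preprocess" in out.meta
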