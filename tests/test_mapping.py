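"""Band integration, chemical maps and the group-statistics cascade."""

import numpy as np
import pandas as pd
import pytest

import cartspec as cs
from cartspec import mapping
from cartspec.mapping import compare_groups, compute_maps, fit_random_intercept, integrate_band
from cartspec.preprocess import ROISet, extract_rois
from cartspec.spectra import Spectrum, SpectralCube, build_grid

GRID = build_grid(1800.0, 900.0, 3.93)


class TestIntegrateBand:
    def test_zero_spectrum(self):
        s = Spectrum(GRID, np.zeros_like(GRID))
        assert integrate_band(s, (1750.0, 1590.0)) == 0.0

    def test_gaussian_area_matches_closed_form(self):
        """A unit-amplitude sigma=10 Gaussian integrates to sigma*sqrt(2 pi)."""
        s = Spectrum(GRID, np.exp(-0.5 * ((GRID - 1400.0) / 10.0) ** 2))
        assert integrate_band(s, (1500.0, 1300.0)) == pytest.approx(
            10.0 * np.sqrt(2.0 * np.pi), rel=1e-4
        )

    def test_constant_over_aligned_window(self):
        g = np.linspace(1140.0, 965.0, 176)  # endpoints exactly at the window
        s = Spectrum(g, np.ones_like(g))
        assert integrate_band(s, (1140.0, 965.0)) == pytest.approx(175.0)

    def test_window_outside_grid_rejected(self):
        s = Spectrum(GRID, np.ones_like(GRID))
        with pytest.raises(ValueError):
            integrate_band(s, (4000.0, 3500.0))


def _constant_cube(value=1.0, n=6):
    data = np.full((n, n, GRID.size), value)
    # add the three mapping bands so CI is finite
    bands = (
        0.5 * np.exp(-0.5 * ((GRID - 1660) / 12.0) ** 2)
        + 0.4 * np.exp(-0.5 * ((GRID - 1550) / 14.0) ** 2)
        + 0.2 * np.exp(-0.5 * ((GRID - 1340) / 9.0) ** 2)
    )
    data = data * bands[None, None, :]
    return SpectralCube(grid=GRID, data=data, zone="SZ", group="C", animal_id="C01")


class TestComputeMaps:
    def test_identical_pixels_give_constant_maps(self):
        cmap = compute_maps(_constant_cube())
        for arr in (cmap.cc, cmap.ci, cmap.pg):
            assert np.allclose(arr, arr.flat[0])

    def test_doubling_absorbance_doubles_cc_pg_not_ci(self):
        cube = _constant_cube()
        double = SpectralCube(grid=GRID, data=2.0 * cube.data, zone="SZ", group="C")
        a, b = compute_maps(cube), compute_maps(double)
        assert np.allclose(b.cc, 2.0 * a.cc)
        assert np.allclose(b.pg, 2.0 * a.pg)
        assert np.allclose(b.ci, a.ci)

    @pytest.mark.parametrize("scale", [0.1, 0.5, 2.0, 10.0])
    def test_ci_scale_invariance(self, scale):
        cube = _constant_cube()
        scaled = SpectralCube(grid=GRID, data=scale * cube.data, zone="SZ", group="C")
        assert np.allclose(compute_maps(scaled).ci, compute_maps(cube).ci, rtol=1e-12)

    def test_nonpositive_amide_ii_marks_ci_missing(self):
        cube = _constant_cube()
        data = cube.data.copy()
        m = mapping.window_mask(GRID, *mapping.AMIDE_II_WINDOW)
        data[0, 0, m] = -1.0
        cmap = compute_maps(SpectralCube(grid=GRID, data=data, zone="SZ", group="C"))
        assert np.isnan(cmap.ci[0, 0])
        assert np.isfinite(cmap.ci[1:]).all()

    def test_integrate_then_average_equals_average_then_integrate(self, sz_control_cube):
        from cartspec.preprocess import average_roi

        roi = (0, 0, 6, 6)
        cmap = compute_maps(sz_control_cube)
        x0, y0, w, h = roi
        mean_of_integrals = cmap.cc[y0 : y0 + h, x0 : x0 + w].mean()
        integral_of_mean = integrate_band(average_roi(sz_control_cube, roi), mapping.CC_WINDOW)
        assert mean_of_integrals == pytest.approx(integral_of_mean, rel=1e-12)


class TestZoneStatistics:
    def test_constant_map_statistics(self):
        cmap = compute_maps(_constant_cube(n=12))
        stats = mapping.zone_statistics(cmap, ROISet([(0, 0, 5, 5), (6, 6, 5, 5)], zone="SZ"))
        assert len(stats) == 2
        assert stats["cc_mean"].nunique() == 1
        assert np.allclose(stats["cc_sd"], 0.0)

    def test_two_roi_zone_mean(self):
        cmap = mapping.ChemicalMap(
            cc=np.block([[np.ones((4, 4)), 3.0 * np.ones((4, 4))]]),
            ci=np.ones((4, 8)),
            pg=np.ones((4, 8)),
            zone="MZ",
            group="C",
            animal_id="C01",
        )
        stats = mapping.zone_statistics(cmap, ROISet([(0, 0, 4, 4), (4, 0, 4, 4)], zone="MZ"))
        per_animal = mapping.per_animal_means(stats)
        assert per_animal["CC"].iloc[0] == pytest.approx(2.0)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        vals = [1.0, 1.1, 0.9, 1.05, 0.95]
        comp = compare_groups(vals, vals)
        assert comp.percent_difference == 0.0
        assert not comp.significant

    def test_clear_shift_selects_student_t(self):
        rng = np.random.default_rng(4)
        a = rng.normal(10.0, 0.1, size=10)
        b = rng.normal(20.0, 0.1, size=10)
        comp = compare_groups(a, b)
        assert comp.test_used == "student_t"
        assert comp.significant
        assert comp.percent_difference == pytest.approx(100.0, abs=5.0)

    def test_heavy_tailed_group_selects_mann_whitney(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.0, 1.0, size=30)
        b = rng.standard_cauchy(size=30)  # Shapiro-Wilk rejects with high probability
        comp = compare_groups(a, b)
        assert comp.test_used == "mann_whitney"

    def test_unequal_variances_select_welch(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10.0, 0.05, size=25)
        b = rng.normal(10.5, 2.0, size=25)
        comp = compare_groups(a, b)
        assert comp.test_used == "welch_t"

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_null_zones_rarely_significant(self):
        """Groups drawn from one distribution stay non-significant ~95% of runs."""
        rng = np.random.default_rng(99)
        hits = sum(
            compare_groups(rng.normal(1, 0.03, 5), rng.normal(1, 0.03, 5)).significant
            for _ in range(40)
        )
        assert hits <= 6


class TestRandomIntercept:
    def _data(self, effect=0.0, animal_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, off in (("C", 0.0), ("HMB", effect)):
            for a in range(4):
                shift = rng.normal(0, animal_sd)
                for _ in range(5):
                    rows.append((f"{g}{a}", g, 10.0 + off + shift + rng.normal(0, 0.1)))
        return pd.DataFrame(rows, columns=["animal", "trt", "y"])

    def test_balanced_no_animal_variance_equals_mean_difference(self):
        df = self._data(effect=2.0, animal_sd=0.0, seed=1)
        fit = fit_random_intercept(df["y"], df["animal"], df["trt"])
        mean_diff = df.loc[df.trt == "HMB", "y"].mean() - df.loc[df.trt == "C", "y"].mean()
        assert fit.effect == pytest.approx(mean_diff, abs=1e-6)

    def test_null_effect_estimate_within_three_se(self):
        df = self._data(effect=0.0, animal_sd=0.3, seed=2)
        fit = fit_random_intercept(df["y"], df["animal"], df["trt"])
        assert abs(fit.effect) < 3.0 * fit.se

    def test_duplicating_observations_leaves_estimate_unchanged(self):
        df = self._data(effect=1.0, animal_sd=0.2, seed=3)
        fit1 = fit_random_intercept(df["y"], df["animal"], df["trt"])
        dup = pd.concat([df, df], ignore_index=True)
        fit2 = fit_random_intercept(dup["y"], dup["animal"], dup["trt"])
        assert fit2.effect == pytest.approx(fit1.effect, rel=1e-3)

    def test_single_animal_group_rejected(self):
        df = self._data(seed=4)
        df.loc[df.trt == "HMB", "animal"] = "HMB0"
        with pytest.raises(ValueError):
            fit_random_intercept(df["y"], df["animal"], df["trt"])
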