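import numpy as np
import pytest
from hypothesis import given, strategies as st

from addftir import (
    AcquisitionMethod,
    PreprocessConfig,
    Spectrum,
    SpectrumMetadata,
    WavenumberGrid,
    clip_negatives,
    database_preprocess,
    estimate_snr,
    first_derivative,
    percent_normalize,
    replace_region_with_line,
    rubberband_baseline,
    vector_normalize,
)
from addftir.preprocess import lower_convex_hull_baseline


def _spec(grid, y, method=AcquisitionMethod.ATR):
    return Spectrum(grid, y, SpectrumMetadata("s", method=method))


class TestRubberband:
    def test_straight_line_maps_to_zero(self, atr_grid):
        y = 2.0 + 0.001 * atr_grid.values
        out = rubberband_baseline(_spec(atr_grid, y))
        assert np.abs(out.intensities).max() < 1e-9

    def test_convex_bowl_with_dense_anchors_maps_to_zero(self, atr_grid):
        x = atr_grid.values
        y = 1e-6 * (x - 2200.0) ** 2  # smooth concave-up baseline, no peaks
        cfg = PreprocessConfig(rubberband_points=len(atr_grid))
        out = rubberband_baseline(_spec(atr_grid, y), cfg)
        assert np.abs(out.intensities).max() < 1e-6 * y.max()

    def test_gaussian_on_linear_baseline_recovered(self, atr_grid):
        x = atr_grid.values
        peak = 1.5 * np.exp(-0.5 * ((x - 2000.0) / 30.0) ** 2)
        y = peak + (0.5 + 2e-4 * x)
        out = rubberband_baseline(_spec(atr_grid, y))  # default 64 pts, 10 iter
        assert np.abs(out.intensities - peak).max() < 0.02 * 1.5

    def test_single_iteration_dense_anchors_equals_hull_oracle(self, atr_grid):
        rng = np.random.default_rng(0)
        n = len(atr_grid)
        y = np.abs(rng.normal(0, 1, n)).cumsum() / n + rng.normal(0, 0.05, n)
        cfg = PreprocessConfig(rubberband_iterations=1, rubberband_points=n)
        out = rubberband_baseline(_spec(atr_grid, y), cfg)
        oracle = y[::-1] - lower_convex_hull_baseline(atr_grid.ascending, y[::-1])
        assert np.abs(out.intensities[::-1] - oracle).max() < 1e-9

    def test_too_few_points_rejected(self):
        g = WavenumberGrid(np.arange(2000.0, 1900.0, -10.0))
        with pytest.raises(ValueError, match="rubberband_points"):
            rubberband_baseline(_spec(g, np.ones(len(g))))


class TestReplaceRegion:
    def test_equal_anchors_give_constant_interior(self, atr_grid):
        y = np.full(len(atr_grid), 0.3)
        y[(atr_grid.values <= 2475) & (atr_grid.values >= 1970)] = 9.0
        out = replace_region_with_line(_spec(atr_grid, y), (1970, 2475))
        assert np.allclose(out.intensities, 0.3)

    def test_interior_is_linear_between_anchors(self, atr_grid):
        wn = atr_grid.values
        y = np.where(wn > 2475, 0.4, 0.2)  # anchors differ across the region
        out = replace_region_with_line(_spec(atr_grid, y), (1970, 2475))
        inside = (wn >= 1970) & (wn <= 2475)
        seg = out.intensities[inside]
        assert np.all(np.diff(seg) <= 1e-12)  # monotone along descending wn
        assert seg.min() >= 0.2 - 1e-12 and seg.max() <= 0.4 + 1e-12

    def test_idempotent(self, atr_grid):
        rng = np.random.default_rng(1)
        s = _spec(atr_grid, rng.normal(0.5, 0.1, len(atr_grid)))
        once = replace_region_with_line(s, (2200, 2420))
        twice = replace_region_with_line(once, (2200, 2420))
        np.testing.assert_array_equal(once.intensities, twice.intensities)

    def test_region_touching_boundary_rejected(self, atr_grid):
        with pytest.raises(ValueError, match="boundary"):
            replace_region_with_line(
                _spec(atr_grid, np.ones(len(atr_grid))), (3500, 4000)
            )


class TestPointwiseOps:
    def test_clip_negatives(self, imaging_grid):
        y = np.linspace(-1, 1, len(imaging_grid))
        out = clip_negatives(_spec(imaging_grid, y))
        assert out.intensities.min() == 0.0
        np.testing.assert_array_equal(
            clip_negatives(out).intensities, out.intensities
        )

    def test_percent_normalize_known_values(self):
        g = WavenumberGrid(np.array([3000.0, 2000.0, 1000.0]))
        out = percent_normalize(_spec(g, np.array([2.0, 3.0, 5.0])))
        np.testing.assert_allclose(out.intensities, [20.0, 30.0, 50.0])

    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_percent_normalize_scale_invariant(self, c):
        g = WavenumberGrid(np.array([3000.0, 2000.0, 1000.0]))
        y = np.array([1.0, 4.0, 7.0])
        a = percent_normalize(_spec(g, y)).intensities
        b = percent_normalize(_spec(g, c * y)).intensities
        np.testing.assert_allclose(a, b, rtol=1e-9)
        assert a.sum() == pytest.approx(100.0, abs=1e-9)

    def test_percent_normalize_zero_spectrum_rejected(self, imaging_grid):
        with pytest.raises(ValueError):
            percent_normalize(_spec(imaging_grid, np.zeros(len(imaging_grid))))

    def test_vector_normalize(self):
        g = WavenumberGrid(np.array([2000.0, 1000.0]))
        out = vector_normalize(_spec(g, np.array([3.0, 4.0])))
        np.testing.assert_allclose(out.intensities, [0.6, 0.8])
        with pytest.raises(ValueError):
            vector_normalize(_spec(g, np.zeros(2)))


class TestFirstDerivative:
    def test_constant_gives_zero(self, atr_grid):
        out = first_derivative(_spec(atr_grid, np.full(len(atr_grid), 3.0)))
        assert np.abs(out.intensities).max() < 1e-12

    def test_linear_gives_constant_slope(self, atr_grid):
        out = first_derivative(_spec(atr_grid, 0.25 * atr_grid.values))
        interior = out.intensities[10:-10]
        np.testing.assert_allclose(interior, 0.25, atol=1e-9)

    def test_sine_matches_analytic_derivative(self, atr_grid):
        x = atr_grid.values
        out = first_derivative(_spec(atr_grid, np.sin(0.01 * x)))
        exact = 0.01 * np.cos(0.01 * x)
        err = np.abs(out.intensities - exact)[20:-20].max()
        assert err < 0.01 * 0.01  # within 1% of the derivative amplitude

    def test_window_longer_than_spectrum_rejected(self):
        g = WavenumberGrid(np.arange(2000.0, 1980.0, -4.0))
        with pytest.raises(ValueError):
            first_derivative(_spec(g, np.ones(len(g))))


class TestSnr:
    def test_injected_peak_height_recovered(self, atr_grid):
        x = atr_grid.values
        peak = 50.0 * np.exp(-0.5 * ((x - 2900.0) / 20.0) ** 2)
        ratios = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = peak + rng.normal(0, 1.0, len(x))
            ratios.append(estimate_snr(_spec(atr_grid, y), (3600, 1250), (2100, 1900)))
        assert abs(np.mean(ratios) - 50.0) < 0.2 * 50.0

    def test_flat_zero_spectrum_gives_infinity(self, atr_grid):
        r = estimate_snr(
            _spec(atr_grid, np.zeros(len(atr_grid))), (3600, 1250), (2100, 1900)
        )
        assert r == float("inf")

    def test_no_peak_gives_small_ratio(self, atr_grid):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1.0, len(atr_grid))
        r = estimate_snr(_spec(atr_grid, y), (3600, 1250), (2100, 1900))
        assert r < 10.0


class TestDatabaseChain:
    def test_atr_artifact_bump_removed(self, atr_grid):
        x = atr_grid.values
        bump = 2.0 * np.exp(-0.5 * ((x - 2200.0) / 40.0) ** 2)  # inside 2475-1970
        band = 1.0 * np.exp(-0.5 * ((x - 2900.0) / 25.0) ** 2)
        out = database_preprocess(_spec(atr_grid, band + bump))
        inside = (out.grid.values >= 2000) & (out.grid.values <= 2400)
        # interior of the replaced region carries no residual bump curvature
        assert np.ptp(out.intensities[inside]) < 1e-2

    def test_transmission_co2_doublet_removed(self, atr_grid):
        x = atr_grid.values
        co2 = 1.5 * np.exp(-0.5 * ((x - 2350.0) / 15.0) ** 2)
        band = np.exp(-0.5 * ((x - 1700.0) / 25.0) ** 2)
        s = _spec(atr_grid, band + co2, method=AcquisitionMethod.TRANSMISSION)
        out = database_preprocess(s)
        at_2350 = np.argmin(np.abs(out.grid.values - 2350.0))
        assert out.intensities[at_2350] < 0.05 * out.intensities.max()

    def test_scale_invariance(self, atr_grid):
        rng = np.random.default_rng(2)
        x = atr_grid.values
        y = (
            np.exp(-0.5 * ((x - 2900.0) / 30.0) ** 2)
            + 0.5 * np.exp(-0.5 * ((x - 1450.0) / 20.0) ** 2)
            + np.abs(rng.normal(0, 0.01, len(x)))
        )
        a = database_preprocess(_spec(atr_grid, y)).intensities
        b = database_preprocess(_spec(atr_grid, 7.3 * y)).intensities
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_output_is_percent_normalized_and_cropped(self, atr_grid):
        x = atr_grid.values
        y = np.exp(-0.5 * ((x - 2900.0) / 30.0) ** 2)
        out = database_preprocess(_spec(atr_grid, y))
        assert out.intensities.sum() == pytest.approx(100.0, abs=1e-9)
        assert out.grid.extent[0] >= 1250.0 and out.grid.extent[1] <= 3600.0
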