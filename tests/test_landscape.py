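import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stratispread.landscape import (
    SuitabilityClass,
    classify_suitability,
    generate_fractal_surface,
    generate_survival_map,
    threshold_to_binary,
)
from stratispread.metrics import np_metric, pland
from stratispread.raster import RasterGrid


class TestFractalSurface:
    def test_deterministic_under_fixed_seed(self):
        a = generate_fractal_surface(65, 65, 0.5, 42)
        b = generate_fractal_surface(65, 65, 0.5, 42)
        np.testing.assert_array_equal(a.grid.values, b.grid.values)

    def test_different_seeds_differ(self):
        a = generate_fractal_surface(33, 33, 0.5, 1)
        b = generate_fractal_surface(33, 33, 0.5, 2)
        assert not np.array_equal(a.grid.values, b.grid.values)

    def test_minimal_size_and_rescaling(self):
        s = generate_fractal_surface(2, 2, 0.5, 0)
        v = s.grid.values
        assert v.shape == (2, 2)
        assert np.all(np.isfinite(v))
        assert v.min() == 0.0 and v.max() == 1.0

    def test_non_square_crop(self):
        s = generate_fractal_surface(10, 40, 0.5, 3)
        assert s.grid.shape == (10, 40)

    @pytest.mark.parametrize(
        "rows,cols,hurst",
        [(1, 5, 0.5), (5, 1, 0.5), (5, 5, -0.1), (5, 5, 1.5), (5, 5, float("nan"))],
    )
    def test_invalid_arguments_rejected(self, rows, cols, hurst):
        with pytest.raises((ValueError, TypeError)):
            generate_fractal_surface(rows, cols, hurst, 0)

    def test_higher_autocorrelation_gives_fewer_patches(self):
        """Smoother surfaces (high H) threshold into fewer, larger patches."""
        mean_np = {}
        for hurst in (0.3, 0.5, 0.7):
            counts = [
                np_metric(
                    threshold_to_binary(
                        generate_fractal_surface(65, 65, hurst, seed), 0.5
                    ).grid.values,
                    1.0,
                )
                for seed in range(100)
            ]
            mean_np[hurst] = np.mean(counts)
        assert mean_np[0.7] < mean_np[0.5] < mean_np[0.3]


class TestThresholdToBinary:
    def test_extreme_proportions(self):
        s = generate_fractal_surface(16, 16, 0.5, 1)
        assert threshold_to_binary(s, 0.0).grid.values.sum() == 0
        assert threshold_to_binary(s, 1.0).grid.values.sum() == 256

    def test_exact_cell_count_at_case_study_proportion(self):
        s = generate_fractal_surface(128, 128, 0.5, 7)
        b = threshold_to_binary(s, 0.35)
        assert int(b.grid.values.sum()) == round(0.35 * 128 * 128) == 5734

    def test_ties_resolved_to_exact_count(self):
        # constant surface: every cell ties at the threshold
        s = generate_fractal_surface(8, 8, 0.5, 1)
        s.grid.values[:] = 0.5
        b = threshold_to_binary(s, 0.4)
        assert int(b.grid.values.sum()) == round(0.4 * 64)

    def test_invalid_proportion_rejected(self):
        s = generate_fractal_surface(4, 4, 0.5, 1)
        with pytest.raises(ValueError):
            threshold_to_binary(s, 1.2)

    @given(
        rows=st.integers(2, 12),
        cols=st.integers(2, 12),
        proportion=st.floats(0.0, 1.0),
        seed=st.integers(0, 10_000),
    )
    def test_proportion_recovery_property(self, rows, cols, proportion, seed):
        """|PLAND/100 - P| <= 1/ncells for any surface and proportion."""
        s = generate_fractal_surface(rows, cols, 0.5, seed)
        b = threshold_to_binary(s, proportion)
        n = rows * cols
        assert int(b.grid.values.sum()) == round(proportion * n)
        assert abs(pland(b.grid, 1.0) / 100.0 - proportion) <= 1.0 / n


class TestClassifySuitability:
    def test_boundary_convention(self):
        m = RasterGrid(np.array([[0.05, 0.1, 0.5, 0.51]]))
        out = classify_suitability(m).grid.values
        assert list(out[0]) == [
            SuitabilityClass.MARGINAL,
            SuitabilityClass.LESS_SUITABLE,
            SuitabilityClass.LESS_SUITABLE,
            SuitabilityClass.SUITABLE,
        ]

    @pytest.mark.parametrize(
        "value,expected",
        [(0.6, SuitabilityClass.SUITABLE), (0.0, SuitabilityClass.MARGINAL)],
    )
    def test_uniform_maps(self, value, expected):
        m = RasterGrid(np.full((3, 3), value))
        assert np.all(classify_suitability(m).grid.values == expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_suitability(RasterGrid(np.array([[0.5, 1.2]])))


class TestGenerateSurvivalMap:
    def test_single_band_constant_map(self):
        s = generate_fractal_surface(6, 6, 0.5, 1)
        m = generate_survival_map(s, [(1.0, 1.0)])
        assert np.all(m.values == 1.0)

    def test_two_band_masses(self):
        s = generate_fractal_surface(10, 10, 0.5, 2)
        m = generate_survival_map(s, [(0.5, 0.05), (0.5, 0.9)])
        classes = classify_suitability(m).grid.values
        assert (classes == SuitabilityClass.MARGINAL).sum() == 50
        assert (classes == SuitabilityClass.SUITABLE).sum() == 50

    def test_three_band_masses(self):
        s = generate_fractal_surface(10, 10, 0.5, 3)
        m = generate_survival_map(s, [(0.25, 0.05), (0.35, 0.3), (0.40, 0.8)])
        classes = classify_suitability(m).grid.values
        assert (classes == SuitabilityClass.MARGINAL).sum() == 25
        assert (classes == SuitabilityClass.LESS_SUITABLE).sum() == 35
        assert (classes == SuitabilityClass.SUITABLE).sum() == 40

    @pytest.mark.parametrize(
        "levels",
        [[], [(0.5, 0.5)], [(0.7, 0.5), (0.7, 0.9)], [(0.5, 1.5), (0.5, 0.5)]],
    )
    def test_bad_bands_rejected(self, levels):
        s = generate_fractal_surface(4, 4, 0.5, 1)
        with pytest.raises(ValueError):
            generate_survival_map(s, levels)
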