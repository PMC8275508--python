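"""Probability grids, cutoff calibration and pseudo-contour banding."""

import numpy as np
import pytest

from ashazard import (
    crossover_cutoff,
    cutoff_curves,
    exceedance_grid,
    probability_grid,
    pseudo_contour,
)
from ashazard.ensemble import FinalModel
from ashazard.grids import GeometryError, GridGeometry
from ashazard.hazard import CutoffAnalysis, band_labels
from ashazard.preprocess import NormalizationStats
from ashazard.synthetic import PredictorStack
from scipy import special


def make_final(variables, intercept, coefs, threshold=10.0):
    k = len(variables)
    return FinalModel(threshold, tuple(variables), intercept,
                      np.asarray(coefs, float), 0.0, np.zeros(k),
                      0.8, 0.8, 1)


def uniform_stack(value=0.0, n=8):
    geom = GridGeometry(0.0, 0.0, 1.0, n, n)
    layers = {"a": np.full((n, n), value)}
    return PredictorStack(layers, {"a": "continuous"}, geom,
                          np.zeros((n, n), dtype=bool))


class TestProbabilityGrid:
    def test_stack_at_training_means_gives_intercept_probability(self):
        stats = NormalizationStats(("a",), np.array([2.0]), np.array([1.5]))
        stack = uniform_stack(2.0)
        fm = make_final(["a"], -1.75, [3.47])
        grid = probability_grid(fm, stack, stats)
        np.testing.assert_allclose(grid, special.expit(-1.75), atol=1e-12)

    def test_monotone_in_positive_coefficient_layer(self):
        geom = GridGeometry(0, 0, 1.0, 8, 8)
        ramp = np.tile(np.linspace(-2, 2, 8), (8, 1))
        stack = PredictorStack({"a": ramp}, {"a": "continuous"}, geom,
                               np.zeros((8, 8), bool))
        stats = NormalizationStats(("a",), np.zeros(1), np.ones(1))
        grid = probability_grid(make_final(["a"], 0.0, [1.0]), stack, stats)
        assert np.all(np.diff(grid, axis=1) >= 0)

    def test_missing_layer_named(self):
        stack = uniform_stack()
        stats = NormalizationStats(("b",), np.zeros(1), np.ones(1))
        with pytest.raises(KeyError, match="b"):
            probability_grid(make_final(["b"], 0.0, [1.0]), stack, stats)

    def test_nodata_propagates(self):
        stack = uniform_stack()
        mask = stack.nodata_mask.copy()
        mask[0, 0] = True
        stack = PredictorStack(stack.layers, stack.layer_kind, stack.geometry, mask)
        stats = NormalizationStats(("a",), np.zeros(1), np.ones(1))
        grid = probability_grid(make_final(["a"], 0.0, [1.0]), stack, stats)
        assert np.isnan(grid[0, 0]) and not np.isnan(grid[1, 1])

    def test_recovers_true_probability_field(self, stack, truth, dataset):
        """Fitted hazard surface tracks the generator truth closely."""
        from ashazard import run_ensemble, screen, select_final

        scr = screen(dataset, 10.0, n_repeats=20, base_seed=0)
        summ = run_ensemble(dataset, 10.0, scr.retained, n_runs=30, base_seed=0)
        fm = select_final(summ)
        fitted = probability_grid(fm, stack, dataset.norm_stats)
        true_grid = truth.probability(stack, 10.0)
        assert np.nanmean(np.abs(fitted - true_grid)) < 0.05


class TestCutoffCurves:
    def test_boundary_cutoffs(self, rng):
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        probs = rng.random(100)
        an = cutoff_curves(probs, y, grid_step=0.01)
        assert an.sensitivity[0] == 1.0 and an.specificity[0] == 0.0
        # at cutoff 1.0 only probabilities exactly 1 classify positive
        assert an.sensitivity[-1] == (probs[y == 1] >= 1.0).mean()

    def test_monotone_over_grid(self, rng):
        y = rng.integers(0, 2, 500)
        y[:2] = [0, 1]
        an = cutoff_curves(rng.random(500), y)
        assert np.all(np.diff(an.sensitivity) <= 0)
        assert np.all(np.diff(an.specificity) >= 0)
        assert np.all((an.accuracy >= 0) & (an.accuracy <= 1))


class TestCrossoverCutoff:
    def test_analytic_crossover(self):
        c = np.linspace(0, 1, 1001)
        an = CutoffAnalysis(c, 1 - c, c, np.ones_like(c))
        assert crossover_cutoff(an) == pytest.approx(0.5, abs=1e-12)

    def test_exact_grid_point_returned(self):
        c = np.array([0.0, 0.5, 1.0])
        an = CutoffAnalysis(c, np.array([1.0, 0.7, 0.0]),
                            np.array([0.0, 0.7, 1.0]), np.ones(3))
        assert crossover_cutoff(an) == 0.5

    def test_interpolates_between_grid_points(self):
        c = np.array([0.0, 0.4, 0.8])
        sens = np.array([1.0, 0.6, 0.2])
        spec = np.array([0.0, 0.5, 0.9])
        # d = 1.0, 0.1, −0.7 → zero at 0.4 + (0.1/0.8)·0.4 = 0.45
        an = CutoffAnalysis(c, sens, spec, np.ones(3))
        assert crossover_cutoff(an) == pytest.approx(0.45)

    def test_no_sign_change_warns(self):
        c = np.array([0.0, 0.5, 1.0])
        an = CutoffAnalysis(c, np.array([1.0, 0.9, 0.8]),
                            np.array([0.0, 0.1, 0.2]), np.ones(3))
        with pytest.warns(UserWarning):
            assert crossover_cutoff(an) == 1.0

    def test_balanced_symmetric_scores_cross_at_half(self, rng):
        """Symmetric score distributions around 0.5 cross at 0.5."""
        pos = 0.5 + 0.3 * rng.random(500)
        neg = 0.5 - 0.3 * rng.random(500)
        probs = np.r_[pos, neg]
        y = np.r_[np.ones(500), np.zeros(500)].astype(int)
        an = cutoff_curves(probs, y, grid_step=0.001)
        assert crossover_cutoff(an) == pytest.approx(0.5, abs=0.02)


class TestExceedanceGrid:
    def test_extremes_and_idempotence(self):
        probs = np.array([[0.2, 0.8], [np.nan, 0.5]])
        assert np.nansum(exceedance_grid(probs, 0.0)) == 3  # all valid cells 1
        assert np.nansum(exceedance_grid(probs, 0.9)) == 0
        once = exceedance_grid(probs, 0.5)
        np.testing.assert_array_equal(exceedance_grid(once, 0.5), once)
        assert np.isnan(once[1, 0])

    def test_cutoff_validated(self):
        with pytest.raises(ValueError):
            exceedance_grid(np.zeros((2, 2)), 1.5)


class TestPseudoContour:
    GEOM = GridGeometry(0, 0, 1.0, 8, 8)

    def grids(self, patterns):
        """Build exceedance grids from a per-cell pattern dict."""
        out = {}
        for t, val in patterns.items():
            out[t] = np.full(self.GEOM.shape, float(val))
        return out

    def test_band_rule_example(self):
        """Exceeds 2 and 3 but not 4, 5, 10 → band 3-4."""
        ex = self.grids({2: 1, 3: 1, 4: 0, 5: 0, 10: 0})
        bm = pseudo_contour(ex, self.GEOM)
        assert bm.labels[bm.bands[0, 0]] == "3-4"
        assert not bm.inconsistency_mask.any()

    def test_all_zero_lowest_band(self):
        bm = pseudo_contour(self.grids({2: 0, 3: 0, 4: 0, 5: 0, 10: 0}), self.GEOM)
        assert np.all(bm.bands == 0)
        assert bm.labels[0] == "<2"

    def test_nested_probability_construction_consistent(self, rng):
        """Thresholding one monotone field at five cutoffs nests perfectly."""
        field = rng.random(self.GEOM.shape)
        cutoffs = {2.0: 0.5, 3.0: 0.57, 4.0: 0.61, 5.0: 0.66, 10.0: 0.69}
        ex = {t: exceedance_grid(field, c) for t, c in cutoffs.items()}
        bm = pseudo_contour(ex, self.GEOM, cutoffs)
        assert bm.inconsistency_mask.sum() == 0

    def test_partition_of_valid_cells(self, rng):
        ex = {t: (rng.random(self.GEOM.shape) > 0.5).astype(float)
              for t in (2.0, 3.0, 4.0, 5.0, 10.0)}
        bm = pseudo_contour(ex, self.GEOM)
        assert np.all((bm.bands >= 0) & (bm.bands < len(bm.labels)))
        # non-nested random patterns are flagged, still resolved
        violated = bm.inconsistency_mask
        assert violated.shape == self.GEOM.shape

    def test_inconsistent_cell_flagged_and_resolved_high(self):
        ex = self.grids({2: 0, 3: 0, 4: 0, 5: 0, 10: 1})
        bm = pseudo_contour(ex, self.GEOM)
        assert bm.inconsistency_mask.all()
        assert bm.labels[bm.bands[0, 0]] == ">10"

    def test_geometry_mismatch_rejected(self):
        ex = self.grids({2: 1, 3: 0})
        ex[3.0] = np.zeros((4, 4))
        with pytest.raises(GeometryError):
            pseudo_contour(ex, self.GEOM)


def test_band_labels():
    assert band_labels([2, 3, 4, 5, 10]) == ("<2", "2-3", "3-4", "4-5", "5-10", ">10")
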