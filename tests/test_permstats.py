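"""Permutation inference: decision rule, exchangeability, determinism."""

import numpy as np
import pytest
from scipy import stats

from mtlatlas.geometry import center_of_mass, fit_odr_line
from mtlatlas.permstats import (
    PermutationResult,
    centroid_permutation_test,
    compare_directions,
    extrema_permutation_test,
    group_blob,
)
from mtlatlas.synth import sample_structure_masks

from conftest import make_volume


def null_with_bounds(lo, hi, n=1000):
    """A null sample whose 2.5th/97.5th centiles are exactly (lo, hi)."""
    return np.array([lo] * (n // 2) + [hi] * (n // 2), dtype=float)


class TestDecisionRule:
    def test_observed_outside_interval_is_significant(self):
        """The reported case: observed -5 mm against a (-2, 3) mm null
        interval is flagged."""
        res = PermutationResult.from_null(
            "x_max_diff", -5.0, null_with_bounds(-2.0, 3.0), seed=0, group_sizes=(29, 47)
        )
        assert res.interval == (-2.0, 3.0)
        assert res.significant

    @pytest.mark.parametrize("obs", [-2.0, 0.0, 1.5, 3.0])
    def test_observed_inside_interval_is_not_significant(self, obs):
        res = PermutationResult.from_null(
            "x_max_diff", obs, null_with_bounds(-2.0, 3.0), seed=0, group_sizes=(29, 47)
        )
        assert not res.significant

    def test_one_sided_upper_variant(self):
        null = np.arange(100, dtype=float)  # 95th centile at 94.05
        res = PermutationResult.from_null(
            "s", 97.0, null, seed=0, group_sizes=(5, 5), alternative="greater"
        )
        assert res.significant
        assert not PermutationResult.from_null(
            "s", -50.0, null, seed=0, group_sizes=(5, 5), alternative="greater"
        ).significant


class TestGroupBlob:
    def test_singleton_group_blob_is_the_mask(self):
        m = make_volume([(3, 3, 3), (3, 3, 4)])
        blob = group_blob([m], fraction=0.05)
        assert {tuple(i) for i in blob.voxel_indices} == {(3, 3, 3), (3, 3, 4)}

    def test_two_disjoint_masks_union(self):
        a, b = make_volume([(2, 2, 2)]), make_volume([(9, 9, 9)])
        blob = group_blob([a, b], fraction=0.05)
        assert {tuple(i) for i in blob.voxel_indices} == {(2, 2, 2), (9, 9, 9)}

    def test_identical_masks_any_fraction(self):
        m = make_volume([(5, 5, 5)])
        for f in (0.05, 0.5, 1.0):
            blob = group_blob([m] * 4, fraction=f)
            assert {tuple(i) for i in blob.voxel_indices} == {(5, 5, 5)}


class TestExtremaPermutationTest:
    def test_identical_group_multisets_give_zero_observed(self):
        base = sample_structure_masks(6, rng=1)
        masks = base + base  # group 1 and group 2 identical multisets
        labels = np.array([1] * 6 + [2] * 6)
        res = extrema_permutation_test(
            masks, fractions=0.25, n_perm=100, seed=5, labels=labels
        )
        assert len(res) == 6
        for r in res:
            assert r.observed == pytest.approx(0.0)
            assert not r.significant

    def test_default_thresholds_give_twelve_results(self):
        masks = sample_structure_masks(10, rng=2)
        labels = np.array([1] * 5 + [2] * 5)
        res = extrema_permutation_test(masks, n_perm=100, seed=1, labels=labels)
        assert len(res) == 12
        assert {r.threshold for r in res} == {0.05, 0.25}

    def test_exchangeability_of_input_order(self):
        """Permuting mask order (with labels) changes neither observed
        statistics nor, at fixed seed, any null value."""
        masks = sample_structure_masks(10, rng=3)
        labels = np.array([1] * 5 + [2] * 5)
        res_a = extrema_permutation_test(
            masks, fractions=0.05, n_perm=100, seed=9, labels=labels
        )
        order = np.random.default_rng(0).permutation(10)
        res_b = extrema_permutation_test(
            [masks[i] for i in order],
            fractions=0.05,
            n_perm=100,
            seed=9,
            labels=labels[order],
        )
        for a, b in zip(res_a, res_b):
            assert a.observed == b.observed
            assert np.array_equal(a.null_values, b.null_values)

    def test_determinism(self):
        masks = sample_structure_masks(8, rng=4)
        labels = np.array([1] * 4 + [2] * 4)
        r1 = extrema_permutation_test(masks, fractions=0.05, n_perm=100, seed=2, labels=labels)
        r2 = extrema_permutation_test(masks, fractions=0.05, n_perm=100, seed=2, labels=labels)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.null_values, b.null_values)
            assert a.significant == b.significant

    def test_smoothing_cached_equals_uncached_semantics(self):
        """Observed statistics with smoothing equal direct group-blob extrema
        computed the slow way (smooth each mask, average, threshold)."""
        from mtlatlas.geometry import bounding_box
        from mtlatlas.probmap import build_probability_map, threshold_map

        masks = sample_structure_masks(8, rng=6)
        labels = np.array([1] * 4 + [2] * 4)
        res = extrema_permutation_test(
            masks, fractions=0.05, smoothing_fwhm=3.0, n_perm=100, seed=3, labels=labels
        )
        b1 = bounding_box(
            threshold_map(build_probability_map(masks[:4], smoothing_fwhm=3.0), 0.05)
        )
        b2 = bounding_box(
            threshold_map(build_probability_map(masks[4:], smoothing_fwhm=3.0), 0.05)
        )
        expected = {
            ("x", "min"): b1.min_mm[0] - b2.min_mm[0],
            ("y", "min"): b1.min_mm[1] - b2.min_mm[1],
            ("z", "min"): b1.min_mm[2] - b2.min_mm[2],
            ("x", "max"): b1.max_mm[0] - b2.max_mm[0],
            ("y", "max"): b1.max_mm[1] - b2.max_mm[1],
            ("z", "max"): b1.max_mm[2] - b2.max_mm[2],
        }
        for r in res:
            ax, kind = r.statistic_name.split("_")[:2]
            assert r.observed == pytest.approx(expected[(ax, kind)])


class TestCentroidPermutationTest:
    def test_identical_groups(self):
        pts = np.tile(np.arange(30).reshape(10, 3), (2, 1)).astype(float)
        labels = np.array([1] * 10 + [2] * 10)
        res = centroid_permutation_test(pts, labels, axis="y", n_perm=200, seed=1)
        assert res.observed == pytest.approx(0.0)
        assert not res.significant

    def test_large_deterministic_shift_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.5, (10, 3))
        b = a + np.array([0.0, 10.0, 0.0])
        pts = np.vstack([a, b])
        labels = np.array([1] * 10 + [2] * 10)
        res = centroid_permutation_test(pts, labels, axis="y", n_perm=500, seed=2)
        assert res.observed == pytest.approx(-10.0, abs=1e-9)
        assert res.significant

    def test_axis_selection_and_group_order(self):
        pts = np.array([[0, 0, 0], [0, 0, 0], [1, 2, 3], [1, 2, 3]], dtype=float)
        labels = np.array([1, 1, 2, 2])
        for ax, expected in (("x", -1.0), ("y", -2.0), ("z", -3.0)):
            res = centroid_permutation_test(pts, labels, axis=ax, n_perm=100, seed=0)
            assert res.observed == pytest.approx(expected)


class TestCompareDirections:
    def _fit(self, d):
        d = np.asarray(d, float)
        d = d / np.linalg.norm(d)
        pts = np.outer(np.linspace(-5, 5, 7), d)
        return fit_odr_line(pts)

    def test_identical_fits(self):
        f = self._fit([1, 0.2, 0.1])
        res = compare_directions(f, f)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.extra["differences"] == [0.0, 0.0, 0.0]

    def test_axis_swap_is_invisible_to_paired_t(self):
        """d1=(1,0,0) vs d2=(0,1,0): paired differences (1,-1,0) have mean 0,
        so t=0, p=1 — the test cannot see symmetric swaps."""
        res = compare_directions(self._fit([1, 0, 0]), self._fit([0, 1, 0]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_paired_t(self):
        res = compare_directions(self._fit([1, 0, 0]), self._fit([0.8, 0.6, 0]))
        diffs = np.array([0.2, -0.6, 0.0])
        t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(3))
        assert res.statistic == pytest.approx(t, rel=1e-9)
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), df=2), rel=1e-9)
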