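"""Contact scoring: coverage fractions, interaction runs, offset null."""

import numpy as np
import pytest

from spineglia import contact
from spineglia.contact import (
    AllFramesInvalidError,
    ContactSeries,
    SpineROI,
    coverage_fraction,
    detect_interactions,
    generate_offsets,
    permutation_test_one_tailed,
    summarize_dendrite,
)

from conftest import point_in_polygon, star_polygon


def square_roi(r0, c0, size, spine_id="s", cls="mushroom"):
    # offset by 0.5 so no pixel center lies exactly on an edge
    return SpineROI(
        spine_id=spine_id,
        spine_class=cls,
        polygon=np.array(
            [
                [r0 - 0.5, c0 - 0.5],
                [r0 - 0.5, c0 + size - 0.5],
                [r0 + size - 0.5, c0 + size - 0.5],
                [r0 + size - 0.5, c0 - 0.5],
            ]
        ),
    )


class TestCoverageFraction:
    def test_partial_overlap_counts_pixels(self):
        # 5x4 = 20-pixel spine head with exactly 3 mask-positive pixels
        roi = square_roi(2, 2, 4)
        assert roi.area_px == 16
        roi = SpineROI(
            "s", "mushroom",
            np.array([[1.5, 1.5], [1.5, 5.5], [6.5, 5.5], [6.5, 1.5]]),
        )
        assert roi.area_px == 20
        mask = np.zeros((12, 12), dtype=bool)
        mask[2, 2] = mask[3, 3] = mask[4, 4] = True
        assert coverage_fraction(roi, mask) == pytest.approx(3 / 20)

    def test_empty_and_full_masks(self):
        roi = square_roi(2, 2, 4)
        assert coverage_fraction(roi, np.zeros((10, 10), bool)) == 0.0
        assert coverage_fraction(roi, np.ones((10, 10), bool)) == 1.0

    def test_polygon_outside_image_errors(self):
        roi = square_roi(8, 8, 4)
        with pytest.raises(ValueError, match="bounds"):
            coverage_fraction(roi, np.zeros((10, 10), bool))

    def test_matches_bruteforce_pixel_oracle(self, rng):
        """Rasterized coverage equals per-pixel crossing-number counting."""
        for _ in range(100):
            poly = star_polygon(rng, rng.uniform(9, 22, 2))
            roi = SpineROI("s", "mushroom", poly)
            mask = rng.random((32, 32)) < 0.3
            inside = [
                (r, c)
                for r in range(32)
                for c in range(32)
                if point_in_polygon(r, c, poly)
            ]
            if not inside:
                # degenerate sliver covering no pixel center
                with pytest.raises(ValueError):
                    coverage_fraction(roi, mask)
                continue
            expected = sum(mask[r, c] for r, c in inside) / len(inside)
            assert coverage_fraction(roi, mask) == pytest.approx(expected, abs=0)


class TestDetectInteractions:
    def series(self, c, valid=None, interval=3.0):
        return ContactSeries("s", np.asarray(c, float), interval, valid)

    def test_single_run_with_length_and_peak(self):
        ints = detect_interactions(self.series([0, 0.06, 0.07, 0.02]))
        assert len(ints) == 1
        (i,) = ints
        assert (i.start_frame, i.end_frame) == (1, 2)
        assert i.length_min == pytest.approx(6.0)
        assert i.max_coverage == pytest.approx(0.07)

    def test_all_zero_coverage_gives_no_interactions(self):
        assert detect_interactions(self.series([0.0, 0.0, 0.0])) == []

    def test_criterion_is_inclusive_by_default(self):
        ints = detect_interactions(self.series([0.05, 0.04]))
        assert len(ints) == 1
        assert ints[0].length_min == pytest.approx(3.0)
        assert detect_interactions(self.series([0.05, 0.04]), strict=True) == []

    def test_invalid_frames_break_runs(self):
        valid = np.array([True, True, False, True])
        ints = detect_interactions(self.series([0.1, 0.1, 0.1, 0.1], valid))
        assert [(i.start_frame, i.end_frame) for i in ints] == [(0, 1), (3, 3)]

    def test_all_invalid_is_distinct_error(self):
        with pytest.raises(AllFramesInvalidError):
            detect_interactions(self.series([0.1], np.array([False])))

    def test_appending_zero_frames_leaves_interactions_unchanged(self, rng):
        c = rng.uniform(0, 0.2, 10)
        a = detect_interactions(self.series(c))
        b = detect_interactions(self.series(np.concatenate([c, np.zeros(5)])))
        assert a == b


class TestSummarizeDendrite:
    def test_rate_is_proportional_to_count_over_time(self):
        ints = [contact.Interaction(0, 0, 3.0, 0.1)] * 3
        s = summarize_dendrite({"a": ints}, total_valid_minutes=30.0)
        assert s.rate_per_10min == pytest.approx(1.0)

    def test_rate_arithmetic(self):
        ints = [contact.Interaction(0, 0, 3.0, 0.1)] * 2
        s = summarize_dendrite({"a": ints}, total_valid_minutes=48.0)
        assert s.rate_per_10min == pytest.approx(0.41667, abs=1e-4)

    def test_no_interactions_reports_missing_means(self):
        s = summarize_dendrite({"a": [], "b": []}, total_valid_minutes=30.0)
        assert s.prop_with_interaction == 0.0
        assert np.isnan(s.mean_length_min) and np.isnan(s.mean_max_coverage)

    def test_length_stats_only_over_interacting_spines(self):
        ints = [contact.Interaction(0, 1, 6.0, 0.5)]
        s = summarize_dendrite({"a": ints, "b": []}, total_valid_minutes=30.0)
        assert s.prop_with_interaction == pytest.approx(0.5)
        assert s.mean_length_min == pytest.approx(6.0)
        assert s.mean_max_coverage == pytest.approx(0.5)


class TestGenerateOffsets:
    @pytest.mark.parametrize(
        "size,expected",
        [(800, 231), (50, 6), (100, 21)],
    )
    def test_offset_counts(self, size, expected):
        grid = generate_offsets(size, 32, 10)
        assert len(grid) == expected

    def test_magnitudes_for_small_image(self):
        grid = generate_offsets(50, 32, 10)
        mags = sorted({max(abs(r), abs(c)) for r, c in grid.offsets})
        assert mags == [32, 42]

    def test_offsets_distinct_and_nonzero(self):
        grid = generate_offsets(200, 32, 10)
        assert (0, 0) not in grid.offsets
        assert len(set(grid.offsets)) == len(grid.offsets)

    def test_start_beyond_image_errors(self):
        with pytest.raises(ValueError):
            generate_offsets(30, 32, 10)


class TestOffsetStatistics:
    def _movie(self, rng, S=64, T=4, n=6):
        mask = rng.random((T, S, S)) < 0.05
        spines = [
            square_roi(int(r), int(c), 4, spine_id=f"s{i}")
            for i, (r, c) in enumerate(rng.integers(6, S - 8, size=(n, 2)))
        ]
        return mask, spines

    def test_empty_mask_null_identically_zero(self, rng):
        _, spines = self._movie(rng)
        mask = np.zeros((4, 64, 64), bool)
        grid = generate_offsets(64, 32, 10)
        null = contact.offset_statistics(mask, spines, grid)
        assert np.all(null == 0.0)

    def test_full_period_shift_is_identity(self, rng):
        mask, spines = self._movie(rng)
        real = contact.movie_statistic(mask, spines)
        shifted = contact.movie_statistic(mask, spines, offset=(64, 64))
        assert shifted == pytest.approx(real, abs=0)

    def test_periodic_mask_symmetry_offset_equals_real(self, rng):
        # mask periodic with period 16 along columns: a shift by 16 is a symmetry
        S = 64
        tile = rng.random((4, S, 16)) < 0.1
        mask = np.tile(tile, (1, 1, 4))
        _, spines = self._movie(rng)
        real = contact.movie_statistic(mask, spines)
        assert contact.movie_statistic(mask, spines, offset=(0, 16)) == pytest.approx(
            real, abs=0
        )


class TestPermutationTest:
    def test_observed_above_all_null(self):
        null = np.arange(231, dtype=float)
        assert permutation_test_one_tailed(1000.0, null) == pytest.approx(1 / 232)

    def test_observed_below_all_null(self):
        assert permutation_test_one_tailed(-1.0, np.arange(231.0)) == 1.0

    def test_ten_null_values_at_or_above(self):
        null = np.arange(231, dtype=float)
        # observed 221: null values 221..230 are >= it -> 10 of 231
        p = permutation_test_one_tailed(221.0, null)
        assert p == pytest.approx(11 / 232)
        assert round(p, 3) == 0.047  # the granularity at which 0.048 is reported

    def test_missing_null_entries_warn_and_shrink(self):
        null = np.array([1.0, np.nan, 2.0, 3.0])
        with pytest.warns(UserWarning, match="missing"):
            p = permutation_test_one_tailed(10.0, null)
        assert p == pytest.approx(1 / 4)

    def test_empty_null_errors(self):
        with pytest.raises(ValueError):
            permutation_test_one_tailed(1.0, np.array([]))
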