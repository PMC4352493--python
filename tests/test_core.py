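"""The random-patch density search: index, boxes, classification, full runs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rppd import (
    CandidateBox,
    EmptyTissueIndexError,
    PlantedRegion,
    RppdConfig,
    build_tissue_index,
    classify_candidate,
    generate_binary_fixture,
    make_candidate_box,
    map_regions_to_slide,
    remove_box_pixels,
    run_rppd,
    sample_seed,
)
from rppd.preprocess import Partition

from conftest import overlaps


def brute_force_density(mask, center, box_size):
    """Direct pixel counting over the clipped box."""
    h, w = mask.shape
    r, c = center
    lo, hi = (box_size - 1) // 2, box_size // 2
    top, left = max(0, r - lo), max(0, c - lo)
    bottom, right = min(h, r + hi + 1), min(w, c + hi + 1)
    tissue = sum(
        bool(mask[i, j]) for i in range(top, bottom) for j in range(left, right)
    )
    area = (bottom - top) * (right - left)
    return tissue, area - tissue


class TestTissueIndex:
    def test_empty_mask_gives_empty_index(self):
        idx = build_tissue_index(np.zeros((5, 5), dtype=bool))
        assert len(idx) == 0 and idx.initial_count == 0

    def test_full_mask_counts_every_pixel(self):
        idx = build_tissue_index(np.ones((10, 10), dtype=bool))
        assert len(idx) == 100

    def test_index_contains_exactly_the_tissue_pixels(self):
        mask = np.zeros((6, 7), dtype=bool)
        coords = [(0, 0), (3, 4), (5, 6)]
        for r, c in coords:
            mask[r, c] = True
        idx = build_tissue_index(mask)
        assert sorted(map(tuple, idx.coordinates())) == coords

    def test_sampling_empty_index_raises(self, rng):
        idx = build_tissue_index(np.zeros((3, 3), dtype=bool))
        with pytest.raises(EmptyTissueIndexError):
            sample_seed(idx, rng)

    def test_single_pixel_index_returns_it(self, rng):
        mask = np.zeros((4, 4), dtype=bool)
        mask[2, 1] = True
        assert sample_seed(build_tissue_index(mask), rng) == (2, 1)

    def test_fixed_seed_gives_identical_draw_sequence(self):
        mask = np.random.default_rng(0).random((20, 20)) < 0.3
        draws = []
        for _ in range(2):
            idx = build_tissue_index(mask)
            r = np.random.default_rng(99)
            draws.append([sample_seed(idx, r) for _ in range(50)])
        assert draws[0] == draws[1]

    def test_draws_are_uniform(self):
        # 10,000 draws from a 4-pixel index: each frequency within 5 sigma of 1/4
        mask = np.zeros((2, 2), dtype=bool)
        mask[:] = True
        idx = build_tissue_index(mask)
        r = np.random.default_rng(3)
        counts = {}
        n = 10_000
        for _ in range(n):
            draw = sample_seed(idx, r)
            counts[draw] = counts.get(draw, 0) + 1
        sigma = (n * 0.25 * 0.75) ** 0.5
        for coord in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            assert abs(counts.get(coord, 0) - n * 0.25) < 5 * sigma

    def test_sampling_skips_removed_members(self):
        mask = np.ones((30, 30), dtype=bool)
        idx = build_tissue_index(mask)
        idx.remove_box(0, 30, 0, 15)
        r = np.random.default_rng(1)
        for _ in range(200):
            row, col = sample_seed(idx, r)
            assert col >= 15


class TestCandidateBox:
    def test_interior_all_tissue_box_has_density_one(self):
        mask = np.ones((400, 400), dtype=bool)
        box = make_candidate_box((200, 200), RppdConfig(), mask)
        assert box.density == 1.0
        assert box.area == 150 * 150

    def test_half_tissue_half_background(self):
        # left half tissue, box straddling the boundary: 11250 / 11250
        # the even-sized box spans 74 columns left and 75 right of the center
        mask = np.zeros((400, 400), dtype=bool)
        mask[:, :200] = True
        box = make_candidate_box((200, 199), RppdConfig(), mask)
        assert (box.tissue_count, box.background_count) == (11250, 11250)
        assert box.density == 0.5

    def test_corner_box_is_clipped_to_76x76(self):
        mask = np.ones((300, 300), dtype=bool)
        box = make_candidate_box((0, 0), RppdConfig(), mask)
        assert (box.bottom - box.top, box.right - box.left) == (76, 76)
        assert box.tissue_count + box.background_count == 76 * 76

    def test_out_of_bounds_counted_as_background_when_not_clipping(self):
        mask = np.ones((300, 300), dtype=bool)
        cfg = RppdConfig(clip_boxes=False)
        box = make_candidate_box((0, 0), cfg, mask)
        assert box.tissue_count + box.background_count == 150 * 150
        assert box.density == pytest.approx(76 * 76 / 22500)

    def test_center_outside_mask_rejected(self):
        with pytest.raises(ValueError):
            make_candidate_box((500, 0), RppdConfig(), np.ones((300, 300), dtype=bool))

    @pytest.mark.parametrize("seed", range(5))
    def test_density_matches_brute_force_counting(self, seed):
        r = np.random.default_rng(seed)
        mask = r.random((60, 80)) < 0.4
        cfg = RppdConfig(box_size=21)
        for _ in range(10):
            center = (int(r.integers(60)), int(r.integers(80)))
            box = make_candidate_box(center, cfg, mask)
            tissue, background = brute_force_density(mask, center, 21)
            assert (box.tissue_count, box.background_count) == (tissue, background)


class TestClassifyCandidate:
    @pytest.mark.parametrize(
        "density,tier",
        [(0.75, "red"), (0.50, "blue"), (0.30, "green"), (0.15, "black"),
         (0.90, "red"), (0.749, "blue"), (0.499, "green"), (0.299, "black")],
    )
    def test_tier_boundaries_closed_at_lower_end(self, density, tier):
        decision = classify_candidate(density, RppdConfig())
        assert (decision.action, decision.tier) == ("accept", tier)

    def test_low_density_is_discarded(self):
        assert classify_candidate(0.05, RppdConfig()).action == "discard"

    def test_between_discard_and_accept_is_plain_reject(self):
        assert classify_candidate(0.12, RppdConfig()).action == "reject"

    def test_bounding_mode_accepts_untiered_from_ten_percent(self):
        cfg = RppdConfig.for_tissue_bounding()
        decision = classify_candidate(0.10, cfg)
        assert (decision.action, decision.tier) == ("accept", "accepted")
        assert classify_candidate(0.09, cfg).action == "discard"

    def test_out_of_range_density_rejected(self):
        with pytest.raises(ValueError):
            classify_candidate(1.5, RppdConfig())

    @settings(derandomize=True, database=None, max_examples=200)
    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_decision_total_and_unique_on_unit_interval(self, density):
        decision = classify_candidate(density, RppdConfig())
        assert decision.action in ("accept", "reject", "discard")
        if decision.action == "accept":
            assert decision.tier in ("black", "green", "blue", "red")
            assert density >= 0.15
        elif decision.action == "discard":
            assert density < 0.10
        else:
            assert 0.10 <= density < 0.15


class TestRemoveBoxPixels:
    def test_box_covering_partition_empties_index(self):
        mask = np.ones((50, 50), dtype=bool)
        idx = build_tissue_index(mask)
        box = make_candidate_box((25, 25), RppdConfig(box_size=101), mask)
        removed = remove_box_pixels(idx, box)
        assert removed == 2500 and len(idx) == 0

    def test_background_box_removes_nothing(self):
        mask = np.zeros((200, 200), dtype=bool)
        mask[:10, :10] = True
        idx = build_tissue_index(mask)
        box = make_candidate_box((150, 150), RppdConfig(box_size=21), mask)
        assert remove_box_pixels(idx, box) == 0
        assert len(idx) == 100

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_against_set_difference(self, seed):
        r = np.random.default_rng(seed)
        mask = r.random((80, 80)) < 0.5
        idx = build_tissue_index(mask)
        before = {tuple(c) for c in idx.coordinates()}
        center = (int(r.integers(80)), int(r.integers(80)))
        box = make_candidate_box(center, RppdConfig(box_size=31), mask)
        removed = remove_box_pixels(idx, box)
        after = {tuple(c) for c in idx.coordinates()}
        gone = {
            (i, j)
            for (i, j) in before
            if box.top <= i < box.bottom and box.left <= j < box.right
        }
        assert before - after == gone
        assert removed == len(gone) == box.tissue_count


class TestRunRppd:
    def test_empty_mask_yields_empty_result(self, rng):
        result = run_rppd(np.zeros((200, 200), dtype=bool), RppdConfig(), rng)
        assert result.regions == []
        assert result.termination_reason == "pixel_exhaustion"

    @pytest.mark.parametrize("seed", range(20))
    def test_single_solid_box_found_as_one_red_region(self, seed):
        mask = np.zeros((150, 150), dtype=bool)
        mask[:] = True  # exactly one possible (clipped-to-bounds) solid box
        result = run_rppd(mask, RppdConfig(), np.random.default_rng(seed))
        assert result.n_accepted >= 1
        assert result.regions[0].tier == "red"

    def test_sub_tmin_tissue_terminates_immediately(self, rng):
        # fewer than 0.15 * 150^2 = 3375 tissue pixels: nothing to find
        mask = np.zeros((300, 300), dtype=bool)
        mask[:58, :58] = True  # 3364 < 3375
        result = run_rppd(mask, RppdConfig(), rng)
        assert result.regions == [] and result.iterations == 0
        assert result.termination_reason == "pixel_exhaustion"

    def test_pixel_conservation_over_full_run(self):
        mask = np.random.default_rng(11).random((500, 500)) < 0.3
        result = run_rppd(mask, RppdConfig(), np.random.default_rng(0))
        assert result.initial_tissue == result.final_tissue + result.removed_total

    def test_deterministic_under_seed(self, three_region_mask):
        mask, _ = three_region_mask
        a = run_rppd(mask, RppdConfig(), np.random.default_rng(5))
        b = run_rppd(mask, RppdConfig(), np.random.default_rng(5))
        assert a == b

    def test_accepted_regions_never_share_tissue_pixels(self, three_region_mask):
        # each tissue pixel is consumed at most once, so the accepted boxes'
        # tissue counts never exceed the pixels removed, nor the initial supply
        mask, _ = three_region_mask
        result = run_rppd(mask, RppdConfig(), np.random.default_rng(2))
        accepted_tissue = sum(r.box.tissue_count for r in result.regions)
        assert accepted_tissue <= result.removed_total <= result.initial_tissue

    def test_recovery_on_planted_regions(self):
        """Solid, well-separated planted squares are each found at high
        priority and no accepted box lies off the planted set (50 seeds)."""
        from rppd import PlantedRegion, generate_binary_fixture

        regions = [
            PlantedRegion(40, 40, 300, 300, 1.0),
            PlantedRegion(40, 460, 300, 300, 1.0),
            PlantedRegion(440, 150, 300, 300, 1.0),
        ]
        seeds_ok = 0
        for seed in range(50):
            mask, truth = generate_binary_fixture(
                (800, 820), regions, scatter_fraction=0.002,
                rng=np.random.default_rng(500 + seed),
            )
            result = run_rppd(mask, RppdConfig(), np.random.default_rng(seed))
            high = [r for r in result.regions if r.tier in ("red", "blue")]
            found_all = all(
                any(overlaps(r.slide_extent, p) for r in high)
                for p in truth.planted_regions
            )
            on_tissue = all(
                any(overlaps(r.slide_extent, p) for p in truth.planted_regions)
                for r in result.regions
            )
            seeds_ok += found_all and on_tissue
        assert seeds_ok >= 48  # >= 95% of 50 seeds


class TestMapRegionsToSlide:
    def _region(self, top, left):
        box = CandidateBox((top + 5, left + 5), top, left, top + 10, left + 10, 50, 50)
        from rppd import FocusPointRegion

        return FocusPointRegion(box, "red", 1, top, left, top + 10, left + 10)

    def test_origin_offset_added(self):
        part = Partition(np.zeros((100, 100)), 2070, 1032, 1)
        region = self._region(10, 20)
        (mapped,) = map_regions_to_slide({1: [region]}, [part])
        assert (mapped.slide_top, mapped.slide_left) == (2080, 1052)

    def test_zero_origin_is_identity(self):
        part = Partition(np.zeros((100, 100)), 0, 0, 1)
        (mapped,) = map_regions_to_slide({1: [self._region(3, 4)]}, [part])
        assert mapped.slide_extent == (3, 4, 13, 14)

    def test_merged_count_is_sum_of_partitions(self):
        parts = [Partition(np.zeros((10, 10)), 0, 0, 1), Partition(np.zeros((10, 10)), 10, 0, 2)]
        regions = {1: [self._region(0, 0)], 2: [self._region(0, 0), self._region(2, 2)]}
        regions[2] = [
            r.__class__(r.box, r.tier, 2, r.slide_top, r.slide_left, r.slide_bottom, r.slide_right)
            for r in regions[2]
        ]
        assert len(map_regions_to_slide(regions, parts)) == 3

    def test_unknown_partition_index_rejected(self):
        part = Partition(np.zeros((10, 10)), 0, 0, 1)
        with pytest.raises(ValueError):
            map_regions_to_slide({2: [self._region(0, 0)]}, [part])
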