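"""Tiling geometry, OR-merge stitching, and minimum-area noise filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eosmap.segmentation import (
    ClassMaskPair,
    ReferenceColorSegmenter,
    SegmenterError,
    filter_small_regions,
    merge_tiles,
    plan_tiling,
    segment_subpatch,
    split_tiles,
)
from eosmap.seg_metrics import tally
from eosmap.synthetic import SynthImageSpec, generate_wsi


class TestPlanTiling:
    @pytest.mark.parametrize(
        "patch,tile,n_axis,overlap,n_tiles",
        [
            (2144, 448, 5, 24, 25),  # one HPF: 5x5 sub-patches, 24-px overlap
            (1200, 448, 3, 72, 9),   # training patch: 72-px overlap
            (448, 448, 1, 0, 1),     # single-tile identity
            (64, 32, 2, 0, 4),       # desk-scale grid used across the suite
        ],
    )
    def test_uniform_grids(self, patch, tile, n_axis, overlap, n_tiles):
        grid = plan_tiling(patch, tile)
        assert grid.n_tiles_per_axis == n_axis
        assert grid.overlap_px == overlap
        assert grid.n_tiles == n_tiles

    def test_no_uniform_overlap_is_an_error_naming_both_sides(self):
        with pytest.raises(ValueError, match="1001.*448|448.*1001"):
            plan_tiling(1001, 448)

    def test_tile_larger_than_patch_rejected(self):
        with pytest.raises(ValueError):
            plan_tiling(100, 200)

    @given(
        tile=st.integers(min_value=2, max_value=40),
        extra=st.integers(min_value=0, max_value=120),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_coverage_invariant(self, tile, extra):
        """Valid grids cover every pixel at least once and never overrun."""
        patch = tile + extra
        try:
            grid = plan_tiling(patch, tile)
        except ValueError:
            return  # no uniform-overlap grid exists for this pair
        counts = np.zeros(patch, dtype=int)
        for r, _ in grid.tile_origins[:: grid.n_tiles_per_axis]:
            assert 0 <= r and r + tile <= patch
            counts[r : r + tile] += 1
        assert (counts >= 1).all()


class TestMergeTiles:
    def _random_pair(self, rng, side):
        return ClassMaskPair(
            eos_mask=rng.random((side, side)) < 0.3,
            bz_mask=rng.random((side, side)) < 0.3,
        )

    def test_all_empty_tiles_merge_empty(self):
        grid = plan_tiling(64, 32)
        empty = ClassMaskPair(np.zeros((32, 32), bool), np.zeros((32, 32), bool))
        merged = merge_tiles([empty] * grid.n_tiles, grid)
        assert not merged.eos_mask.any() and not merged.bz_mask.any()

    def test_overlap_pixel_positive_in_one_tile_wins(self):
        # 56-px patch of 32-px tiles -> 8-px overlap band between tiles
        grid = plan_tiling(56, 32)
        assert grid.overlap_px == 8
        tiles = []
        for r, c in grid.tile_origins:
            eos = np.zeros((32, 32), bool)
            if (r, c) == (0, 0):
                eos[28, 28] = True  # inside every overlap band
            tiles.append(ClassMaskPair(eos, np.zeros((32, 32), bool)))
        merged = merge_tiles(tiles, grid)
        assert merged.eos_mask[28, 28]

    def test_split_merge_round_trip(self, rng):
        grid = plan_tiling(56, 32)
        full = self._random_pair(rng, 56)
        tiles = [
            ClassMaskPair(e, b)
            for e, b in zip(split_tiles(full.eos_mask, grid), split_tiles(full.bz_mask, grid))
        ]
        merged = merge_tiles(tiles, grid)
        assert np.array_equal(merged.eos_mask, full.eos_mask)
        assert np.array_equal(merged.bz_mask, full.bz_mask)

    def test_merge_idempotent_on_duplicates(self, rng):
        grid = plan_tiling(32, 32)
        pair = self._random_pair(rng, 32)
        once = merge_tiles([pair], grid)
        assert np.array_equal(once.eos_mask, pair.eos_mask)

    def test_tile_count_mismatch(self):
        grid = plan_tiling(64, 32)
        pair = ClassMaskPair(np.zeros((32, 32), bool), np.zeros((32, 32), bool))
        with pytest.raises(ValueError, match="expected 4 tiles"):
            merge_tiles([pair] * 3, grid)


class TestFilterSmallRegions:
    def _blob(self, area, shape=(80, 80)):
        """A single 8-connected component of exactly `area` pixels."""
        mask = np.zeros(shape, bool)
        side = int(np.ceil(np.sqrt(area)))
        flat = np.zeros(side * side, bool)
        flat[:area] = True
        mask[:side, :side] = flat.reshape(side, side)
        return mask

    @pytest.mark.parametrize(
        "area,min_area,kept",
        [
            (1799, 1800, False),  # just under the eosinophil floor
            (1800, 1800, True),   # exactly at the floor is kept
            (2006, 2007, False),  # just under the 1%-of-sub-patch BZ floor
            (2007, 2007, True),
        ],
    )
    def test_area_threshold_boundaries(self, area, min_area, kept):
        mask = self._blob(area, shape=(60, 60))
        out = filter_small_regions(mask, min_area)
        assert out.any() == kept
        if kept:
            assert np.array_equal(out, mask)

    def test_empty_mask_passes_through(self):
        mask = np.zeros((16, 16), bool)
        assert not filter_small_regions(mask, 100).any()

    def test_diagonal_pixels_form_one_component_under_8_connectivity(self):
        mask = np.zeros((10, 10), bool)
        mask[[0, 1, 2], [0, 1, 2]] = True  # diagonal chain, area 3
        assert filter_small_regions(mask, 3).sum() == 3
        assert not filter_small_regions(mask, 3, connectivity=1).any()

    @given(st.integers(min_value=0, max_value=8), st.integers(min_value=0, max_value=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotent_and_antimonotone(self, t1, t2):
        gen = np.random.default_rng(t1 * 97 + t2)
        mask = gen.random((24, 24)) < 0.35
        lo, hi = sorted((t1, t2))
        once = filter_small_regions(mask, hi)
        assert np.array_equal(filter_small_regions(once, hi), once)
        # larger threshold keeps a subset of the positives
        assert not (once & ~filter_small_regions(mask, lo)).any()


class TestSegmentSubpatch:
    def test_background_tile_yields_empty_masks(self):
        tile = np.full((32, 32, 3), 255, np.uint8)
        pair = segment_subpatch(tile, ReferenceColorSegmenter())
        assert not pair.eos_mask.any() and not pair.bz_mask.any()

    def test_reference_segmenter_recovers_rendered_disk(self):
        spec = SynthImageSpec(
            width_px=64, height_px=64, tissue_fraction=1.0, n_eos=1,
            eos_radius_px=8, bz_band_fraction=0.4, seed=3,
        )
        image, truth = generate_wsi(spec)
        pair = segment_subpatch(image, ReferenceColorSegmenter())
        t = tally(pair.eos_mask, truth.eos_mask)
        iou = t.tp / (t.tp + t.fp + t.fn)
        assert iou >= 0.99
        tb = tally(pair.bz_mask, truth.bz_mask)
        assert tb.tp / (tb.tp + tb.fp + tb.fn) >= 0.99

    def test_probability_exactly_half_is_positive(self):
        half = lambda tile: (np.full(tile.shape[:2], 0.5), np.full(tile.shape[:2], 0.5))
        pair = segment_subpatch(np.zeros((8, 8, 3), np.uint8), half)
        assert pair.eos_mask.all() and pair.bz_mask.all()

    def test_failure_carries_tile_origin(self):
        def broken(tile):
            raise RuntimeError("boom")

        with pytest.raises(SegmenterError, match=r"\(96, 448\)"):
            segment_subpatch(np.zeros((8, 8, 3), np.uint8), broken, tile_origin=(96, 448))
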