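"""Tile planning, extraction and stitching invariants."""

import numpy as np
import pytest

from tubuleseg import AnnotatedPatch, TilePlan, extract_tiles, plan_tiles, stitch


def make_parent(h, w, seed=0):
    g = np.random.default_rng(seed)
    return AnnotatedPatch(
        image=g.integers(0, 256, (h, w, 3), dtype=np.uint8),
        mask=g.integers(0, 2, (h, w), dtype=np.uint8),
    )


class TestPlanTiles:
    def test_quarter_overlap_of_900_core_gives_1350_tiles(self):
        plan = plan_tiles(2000, 2000)
        assert plan.core == 900
        assert plan.overlap == 225
        assert plan.tile == 1350

    def test_zero_overlap_tiles_abut(self):
        plan = plan_tiles(128, 128, core=64, overlap_fraction=0.0)
        assert plan.tile == plan.core
        assert plan.origins == ((0, 0), (0, 64), (64, 0), (64, 64))

    def test_exact_grid_of_four_cores(self):
        plan = plan_tiles(1800, 1800, core=900)
        assert plan.n_tiles == 4
        assert [plan.core_box(i) for i in range(4)] == [
            (0, 0, 900, 900),
            (0, 900, 900, 1800),
            (900, 0, 1800, 900),
            (900, 900, 1800, 1800),
        ]

    def test_cores_partition_the_parent(self):
        plan = plan_tiles(250, 410, core=96, overlap_fraction=0.25)
        covered = np.zeros((250, 410), dtype=int)
        for i in range(plan.n_tiles):
            r0, c0, r1, c1 = plan.core_box(i)
            covered[r0 : min(r1, 250), c0 : min(c1, 410)] += 1
        assert np.all(covered == 1)

    def test_non_integral_overlap_rejected(self):
        with pytest.raises(ValueError):
            plan_tiles(100, 100, core=90, overlap_fraction=0.22)

    def test_json_round_trip(self):
        plan = plan_tiles(300, 300, core=128, overlap_fraction=0.25)
        assert TilePlan.from_json(plan.to_json()) == plan


class TestExtractTiles:
    def test_constant_parent_gives_constant_tiles(self):
        parent = AnnotatedPatch(
            image=np.full((200, 200, 3), 9, dtype=np.uint8),
            mask=np.zeros((200, 200), dtype=np.uint8),
        )
        plan = plan_tiles(200, 200, core=96, overlap_fraction=0.25)
        for tile in extract_tiles(parent, plan):
            assert np.all(tile.image == 9)

    def test_zero_overlap_tiles_reassemble_parent(self):
        parent = make_parent(128, 192, seed=2)
        plan = plan_tiles(128, 192, core=64, overlap_fraction=0.0)
        tiles = extract_tiles(parent, plan)
        rows = [
            np.concatenate([tiles[i * plan.n_cols + j].image for j in range(plan.n_cols)], axis=1)
            for i in range(plan.n_rows)
        ]
        np.testing.assert_array_equal(np.concatenate(rows, axis=0), parent.image)

    def test_interior_tile_matches_parent_window(self):
        parent = make_parent(384, 384, seed=3)
        plan = plan_tiles(384, 384, core=128, overlap_fraction=0.25)
        ov = plan.overlap
        # centre tile (1,1): fully interior, no reflection fill involved
        idx = 1 * plan.n_cols + 1
        tile = extract_tiles(parent, plan)[idx]
        r0, c0, _, _ = plan.core_box(idx)
        window = parent.image[r0 - ov : r0 + plan.core + ov, c0 - ov : c0 + plan.core + ov]
        np.testing.assert_array_equal(tile.image, window)

    def test_plan_parent_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_tiles(make_parent(64, 64), plan_tiles(128, 128, core=64))


class TestStitch:
    @pytest.mark.parametrize("blend", ["core_crop", "mean"])
    def test_constant_tiles_stitch_to_constant(self, blend):
        plan = plan_tiles(200, 260, core=64, overlap_fraction=0.25)
        tiles = [np.full((plan.tile, plan.tile), 0.7, dtype=np.float32)] * plan.n_tiles
        out = stitch(tiles, plan, blend=blend)
        assert out.shape == (200, 260)
        np.testing.assert_allclose(out, 0.7, rtol=1e-6)

    def test_single_tile_plan_returns_core(self):
        plan = plan_tiles(64, 64, core=64, overlap_fraction=0.25)
        g = np.random.default_rng(0)
        tile = g.random((plan.tile, plan.tile)).astype(np.float32)
        out = stitch([tile], plan, blend="core_crop")
        ov = plan.overlap
        np.testing.assert_array_equal(out, tile[ov : ov + 64, ov : ov + 64])

    def test_mean_blend_averages_overlap(self):
        """Two horizontally adjacent tiles valued 0.2 / 0.4 average to 0.3 in the band."""
        plan = plan_tiles(64, 128, core=64, overlap_fraction=0.25)
        assert plan.n_tiles == 2
        tiles = [
            np.full((plan.tile, plan.tile), 0.2, dtype=np.float32),
            np.full((plan.tile, plan.tile), 0.4, dtype=np.float32),
        ]
        out = stitch(tiles, plan, blend="mean")
        ov = plan.overlap
        # the shared region spans the 2*ov columns around the core boundary
        shared = out[:, 64 - ov : 64 + ov]
        np.testing.assert_allclose(shared, 0.3, atol=1e-6)
        np.testing.assert_allclose(out[:, : 64 - ov], 0.2, atol=1e-6)
        np.testing.assert_allclose(out[:, 64 + ov :], 0.4, atol=1e-6)

    @pytest.mark.parametrize("overlap_fraction", [0.0, 0.125, 0.25, 0.5])
    def test_stitch_of_extracted_parent_is_identity(self, overlap_fraction):
        parent = make_parent(160, 224, seed=4)
        prob_parent = AnnotatedPatch(
            image=parent.image, mask=np.zeros(parent.shape, dtype=np.uint8)
        )
        plan = plan_tiles(160, 224, core=64, overlap_fraction=overlap_fraction)
        tiles = extract_tiles(parent, plan)
        maps = [t.mask.astype(np.float32) for t in tiles]
        out = stitch(maps, plan, blend="core_crop")
        np.testing.assert_array_equal(out, parent.mask.astype(np.float32))

    def test_output_range_never_exceeds_input_range(self):
        plan = plan_tiles(100, 100, core=64, overlap_fraction=0.25)
        g = np.random.default_rng(5)
        tiles = [g.random((plan.tile, plan.tile)).astype(np.float32) for _ in range(plan.n_tiles)]
        lo = min(t.min() for t in tiles)
        hi = max(t.max() for t in tiles)
        for blend in ("core_crop", "mean"):
            out = stitch(tiles, plan, blend=blend)
            assert out.min() >= lo - 1e-6 and out.max() <= hi + 1e-6

    def test_wrong_tile_count_rejected(self):
        plan = plan_tiles(128, 128, core=64, overlap_fraction=0.25)
        with pytest.raises(ValueError):
            stitch([np.zeros((plan.tile, plan.tile))], plan)
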