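"""Synthetic phantom generator: determinism, geometry oracles, labelling."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage as ndi

from tubuleseg import PhantomParams, generate_dataset, generate_large_image, generate_patch


def support_oracle(instances, shape):
    """Per-pixel point-in-ellipse re-rasterisation, independent of the renderer."""
    out = np.zeros(shape, dtype=bool)
    for inst in instances:
        a, b = inst.outer_axes
        for r in range(shape[0]):
            for c in range(shape[1]):
                dr, dc = r - inst.center[0], c - inst.center[1]
                u = dc * np.cos(inst.angle) + dr * np.sin(inst.angle)
                v = -dc * np.sin(inst.angle) + dr * np.cos(inst.angle)
                if (u / a) ** 2 + (v / b) ** 2 <= 1.0:
                    out[r, c] = True
    return out


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"patch_size": 32},
            {"n_tubules_range": (3, 1)},
            {"incomplete_fraction": 1.5},
            {"noise_sd": -1.0},
            {"distractor_count_range": (-1, 2)},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_patch(PhantomParams(**kwargs))


class TestGeneratePatch:
    def test_empty_scene_has_zero_mask(self):
        params = PhantomParams(
            patch_size=64, n_tubules_range=(0, 0), distractor_count_range=(0, 0), seed=1
        )
        patch = generate_patch(params)
        assert patch.mask.sum() == 0
        assert patch.tubule_count == 0

    def test_determinism_bit_identical(self, small_params):
        params = dataclasses.replace(small_params, seed=7)
        a, b = generate_patch(params), generate_patch(params)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_three_separated_tubules_give_three_components(self):
        params = PhantomParams(
            patch_size=256,
            n_tubules_range=(3, 3),
            lumen_radius_range=(10.0, 16.0),
            ring_thickness_range=(4.0, 6.0),
            incomplete_fraction=0.0,
            distractor_count_range=(0, 0),
            empty_fraction=0.0,
            seed=5,
        )
        patch = generate_patch(params)
        assert patch.tubule_count == 3
        _, n_components = ndi.label(patch.mask)
        assert n_components == 3

    def test_mask_equals_instance_footprints(self):
        """Rendered mask matches an independent point-in-ellipse oracle."""
        params = PhantomParams(
            patch_size=96,
            n_tubules_range=(2, 2),
            lumen_radius_range=(8.0, 14.0),
            ring_thickness_range=(3.0, 5.0),
            incomplete_fraction=0.5,
            distractor_count_range=(0, 2),
            empty_fraction=0.0,
            seed=3,
        )
        patch = generate_patch(params)
        oracle = support_oracle(patch.instances, patch.shape)
        np.testing.assert_array_equal(patch.mask.astype(bool), oracle)

    def test_distractors_never_enter_the_mask(self):
        params = PhantomParams(
            patch_size=128,
            n_tubules_range=(0, 0),
            empty_fraction=1.0,
            distractor_count_range=(3, 5),
            seed=2,
        )
        patch = generate_patch(params)
        assert len(patch.distractors) > 0
        # distractors are visible in the image but absent from the mask
        assert patch.mask.sum() == 0
        background = np.asarray(params.stain_palette["background"])
        assert np.abs(patch.image.astype(int) - background).max() > 30

    def test_incomplete_tubules_touch_the_border(self):
        params = PhantomParams(
            patch_size=128,
            n_tubules_range=(2, 3),
            lumen_radius_range=(8.0, 16.0),
            ring_thickness_range=(4.0, 6.0),
            incomplete_fraction=1.0,
            distractor_count_range=(0, 0),
            empty_fraction=0.0,
            seed=9,
        )
        patch = generate_patch(params)
        border = np.zeros(patch.shape, dtype=bool)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        assert np.any(patch.mask.astype(bool) & border)


class TestGenerateDataset:
    def test_zero_sizes_give_empty_lists(self, small_params):
        train, val = generate_dataset(small_params, 0, 0, seed=0)
        assert train == [] and val == []

    def test_requested_lengths(self, small_params):
        params = dataclasses.replace(small_params, patch_size=64)
        train, val = generate_dataset(params, 41, 10, seed=0)
        assert len(train) == 41 and len(val) == 10

    def test_same_seed_reproduces_elementwise(self, small_params):
        t1, v1 = generate_dataset(small_params, 3, 2, seed=4)
        t2, v2 = generate_dataset(small_params, 3, 2, seed=4)
        for a, b in zip(t1 + v1, t2 + v2):
            np.testing.assert_array_equal(a.image, b.image)
            np.testing.assert_array_equal(a.mask, b.mask)

    def test_train_and_val_streams_differ(self, small_params):
        train, val = generate_dataset(small_params, 1, 1, seed=4)
        assert not np.array_equal(train[0].image, val[0].image)


class TestGenerateLargeImage:
    def test_shape_contract(self):
        params = PhantomParams(patch_size=128, seed=1)
        big = generate_large_image(params, 300, 260)
        assert big.image.shape == (300, 260, 3)
        assert big.mask.shape == (300, 260)

    def test_empty_range_gives_zero_mask(self):
        params = PhantomParams(
            patch_size=128, n_tubules_range=(0, 0), distractor_count_range=(0, 0), seed=1
        )
        assert generate_large_image(params, 256, 256).mask.sum() == 0

    def test_reproducible_layout(self):
        params = PhantomParams(patch_size=128, seed=6)
        a = generate_large_image(params, 256, 256)
        b = generate_large_image(params, 256, 256)
        np.testing.assert_array_equal(a.image, b.image)

    def test_rejects_dimensions_below_patch_size(self):
        with pytest.raises(ValueError):
            generate_large_image(PhantomParams(patch_size=128), 100, 300)
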