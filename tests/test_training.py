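"""Augmentation contracts, LR schedule, early stopping and learning."""

import dataclasses

import numpy as np
import pytest
from skimage.draw import disk

from tubuleseg import AnnotatedPatch, PhantomParams, build_model, fit, generate_dataset
from tubuleseg.model import SegModelSpec
from tubuleseg.training import AUGMENTATIONS, GEOMETRIC, TrainConfig, augment


def disc_patch(side=64, radius=16):
    mask = np.zeros((side, side), dtype=np.uint8)
    rr, cc = disk((side / 2, side / 2), radius, shape=(side, side))
    mask[rr, cc] = 1
    image = np.stack([mask * 200 + 30] * 3, axis=-1).astype(np.uint8)
    return AnnotatedPatch(image=image, mask=mask)


class TestAugment:
    def test_empty_menu_is_identity(self):
        p = disc_patch()
        out = augment(p, [], seed=0)
        np.testing.assert_array_equal(out.image, p.image)
        np.testing.assert_array_equal(out.mask, p.mask)

    def test_unknown_transform_rejected(self):
        with pytest.raises(KeyError):
            augment(disc_patch(), ["solarize"], seed=0)

    @pytest.mark.parametrize("name", sorted(set(AUGMENTATIONS) - GEOMETRIC))
    def test_photometric_transforms_leave_mask_untouched(self, name, rng):
        p = disc_patch()
        img, msk = AUGMENTATIONS[name](p.image, p.mask, rng)
        np.testing.assert_array_equal(msk, p.mask)
        assert img.dtype == np.uint8

    def test_rotation_preserves_disc_area_within_5_percent(self, rng):
        """A centred disc keeps its pixel count within 5% under pure rotation."""
        from tubuleseg.training import _shift_scale_rotate

        p = disc_patch()
        area = int(p.mask.sum())
        for _ in range(5):
            _, msk = _shift_scale_rotate(
                p.image, p.mask, rng, shift_limit=0.0, scale_limit=0.0, rotate_limit=45.0
            )
            assert set(np.unique(msk)).issubset({0, 1})
            assert abs(int(msk.sum()) - area) <= 0.05 * area

    @pytest.mark.parametrize("name", sorted(GEOMETRIC))
    def test_geometric_transforms_keep_mask_binary_and_plausible(self, name, rng):
        p = disc_patch()
        area = int(p.mask.sum())
        _, msk = AUGMENTATIONS[name](p.image, p.mask, rng)
        assert set(np.unique(msk)).issubset({0, 1})
        # warps jitter the boundary but must not destroy or invert the disc
        assert abs(int(msk.sum()) - area) <= 0.3 * area

    def test_mask_stays_binary_through_full_menu(self, rng):
        p = disc_patch()
        out = augment(p, sorted(AUGMENTATIONS), seed=3)
        assert set(np.unique(out.mask)).issubset({0, 1})


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lr": 0.0},
            {"lr_factor": 0.0},
            {"patience": 100, "epochs": 50},
            {"batch_size": 0},
            {"pad_mode": "zero"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises((ValueError, KeyError)):
            TrainConfig(**kwargs).validate()


def tiny_setup(n_train=4, n_val=2, patch=64, seed=0):
    params = PhantomParams(
        patch_size=patch,
        n_tubules_range=(1, 2),
        lumen_radius_range=(6.0, 12.0),
        ring_thickness_range=(3.0, 5.0),
        distractor_count_range=(0, 1),
        empty_fraction=0.0,
        seed=seed,
    )
    train, val = generate_dataset(params, n_train, n_val, seed=seed)
    model = build_model(SegModelSpec(backbone="tiny", input_size=patch), seed=seed)
    return model, train, val


class TestFit:
    def test_empty_train_set_rejected(self):
        model, _, val = tiny_setup()
        with pytest.raises(ValueError):
            fit(model, [], val, TrainConfig(epochs=1, batch_size=1))

    def test_patience_one_constant_loss_stops_after_two_epochs(self):
        model, train, val = tiny_setup(n_train=2, n_val=0)
        cfg = TrainConfig(epochs=10, patience=1, batch_size=2, seed=0)
        _, log = fit(model, train, [], cfg, val_loss_fn=lambda epoch: 1.0)
        assert len(log.epochs) == 2
        assert log.stop_reason == "early_stop"

    @pytest.mark.parametrize("patience", [2, 4])
    def test_constant_loss_stops_after_patience_plus_one(self, patience):
        model, train, _ = tiny_setup(n_train=2, n_val=0)
        cfg = TrainConfig(epochs=12, patience=patience, batch_size=2, seed=0)
        _, log = fit(model, train, [], cfg, val_loss_fn=lambda epoch: 0.5)
        assert len(log.epochs) == patience + 1
        assert log.stop_reason == "early_stop"

    def test_lr_drops_by_factor_ten_after_step_epoch(self):
        """Default schedule: LR at epoch 31 is 0.1x the LR at epoch 29."""
        model, train, _ = tiny_setup(n_train=2, n_val=0, patch=32 * 2)
        cfg = TrainConfig(epochs=32, lr=1e-4, lr_step_epoch=30, patience=32, batch_size=2, seed=0)
        _, log = fit(model, train, [], cfg, val_loss_fn=lambda e: 1.0 / e)
        lrs = {r.epoch: r.lr for r in log.epochs}
        assert lrs[31] == pytest.approx(0.1 * lrs[29])
        assert lrs[30] == pytest.approx(cfg.lr)

    def test_loss_decreases_on_phantoms(self):
        model, train, val = tiny_setup(n_train=16, n_val=0)
        cfg = TrainConfig(epochs=5, lr=1e-3, batch_size=4, patience=5, seed=0)
        _, log = fit(model, train, [], cfg)
        assert log.epochs[-1].train_loss < log.epochs[0].train_loss
        assert all(np.isfinite(r.train_loss) for r in log.epochs)

    def test_fixed_seed_reproduces_the_log(self):
        cfg = TrainConfig(epochs=2, lr=1e-3, batch_size=2, patience=2, seed=9)
        logs = []
        for _ in range(2):
            model, train, val = tiny_setup(n_train=4, n_val=2, seed=1)
            _, log = fit(model, train, val, cfg)
            logs.append([(r.train_loss, r.val_loss, r.val_dsc) for r in log.epochs])
        assert logs[0] == logs[1]

    def test_best_epoch_tracks_minimal_validation_loss(self):
        model, train, _ = tiny_setup(n_train=2, n_val=0)
        losses = {1: 0.9, 2: 0.4, 3: 0.6, 4: 0.6, 5: 0.6}
        cfg = TrainConfig(epochs=5, patience=3, batch_size=2, seed=0)
        _, log = fit(model, train, [], cfg, val_loss_fn=lambda e: losses[e])
        assert log.best_epoch == 2

    def test_log_csv_round_trip(self, tmp_path):
        model, train, val = tiny_setup(n_train=2, n_val=1)
        cfg = TrainConfig(epochs=2, batch_size=2, patience=2, seed=0)
        _, log = fit(model, train, val, cfg)
        out = tmp_path / "log.csv"
        log.to_csv(out)
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "epoch,train_loss,val_loss,val_dsc,lr"
        assert len(lines) == 1 + len(log.epochs)
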