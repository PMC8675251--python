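"""Splitting, augmentation, the training loop and fine-tuning."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from meniscus3d.augment import AugmentationSpec, augment, flip_label_order
from meniscus3d.phantom import generate_cohort, generate_phantom, PhantomSpec
from meniscus3d.preprocess import box_from_mask
from meniscus3d.train import (TrainConfig, finetune, load_checkpoint,
                              save_checkpoint, split_cohort, train_model)

QUICK = dict(width_multiplier=0.125, input_shape=(16, 32, 32),
             hidden_units=64, batch_size=4)


def _quick_cfg(**kw):
    base = dict(QUICK)
    base.update(kw)
    return TrainConfig(**base)


class TestSplitCohort:
    def _manifest(self, n):
        return pd.DataFrame({"id": [f"s{i:03d}" for i in range(n)]})

    def test_rounding_convention_on_20_samples(self):
        tr, va, te = split_cohort(self._manifest(20), (0.5, 0.15, 0.35), seed=0)
        assert (len(tr), len(va), len(te)) == (10, 3, 7)

    def test_same_seed_reproduces_split(self):
        m = self._manifest(31)
        assert split_cohort(m, (0.5, 0.15, 0.35), 7) == \
            split_cohort(m, (0.5, 0.15, 0.35), 7)

    def test_partition_is_disjoint_and_exhaustive(self):
        m = self._manifest(27)
        tr, va, te = split_cohort(m, (0.5, 0.15, 0.35), seed=3)
        assert set(tr) | set(va) | set(te) == set(m["id"])
        assert not (set(tr) & set(va)) and not (set(tr) & set(te)) \
            and not (set(va) & set(te))

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(self._manifest(0), (0.5, 0.15, 0.35), 0)


class TestAugment:
    def _sample(self, seed=0, flags=(1, 0, 0, 0, 0, 1)):
        return generate_phantom(PhantomSpec(grid_shape=(16, 32, 32),
                                            tear_flags=flags, seed=seed))

    def test_all_probabilities_zero_is_identity(self):
        s = self._sample()
        spec = AugmentationSpec(flip_prob=0.0, apply_prob=0.0, noise_sd=0.0)
        img, mask, labels = augment(s.image, s.mask, s.labels, spec,
                                    "full_scale", np.random.default_rng(0))
        assert np.array_equal(img, s.image.astype(np.float32))
        assert np.array_equal(mask, s.mask)
        assert np.array_equal(labels, s.labels)

    def test_flip_twice_recovers_original_labels_and_image(self):
        s = self._sample()
        spec = AugmentationSpec(flip_prob=1.0, apply_prob=0.0, noise_sd=0.0)
        img1, mask1, lab1 = augment(s.image, s.mask, s.labels, spec,
                                    "full_scale", np.random.default_rng(1))
        img2, mask2, lab2 = augment(img1, mask1, lab1, spec,
                                    "full_scale", np.random.default_rng(2))
        assert np.array_equal(img2, s.image.astype(np.float32))
        assert np.array_equal(lab2, s.labels)

    def test_flip_swaps_anterior_and_posterior_labels(self):
        assert list(flip_label_order([1, 0, 0, 0, 0, 1])) == [0, 0, 1, 1, 0, 0]

    def test_boxes_recomputed_after_rotation_contain_structures(self):
        # with rotation and noise on, the box recomputed from the transformed
        # mask must cover (nearly) all transformed structure voxels
        spec = AugmentationSpec(flip_prob=0.0, apply_prob=1.0,
                                crop_fractions=(0, 0, 0))
        for seed in range(50):
            s = self._sample(seed=seed)
            img, mask, labels = augment(s.image, s.mask, s.labels, spec,
                                        "full_scale",
                                        np.random.default_rng(seed))
            for structure in (1, 2):
                box = box_from_mask(mask, structure)
                lo, hi = box.voxel_bounds(mask.shape)
                coords = np.stack(np.nonzero(mask == structure), axis=1)
                inside = ((coords >= np.floor(lo)) &
                          (coords <= np.ceil(hi))).all(axis=1)
                assert inside.mean() >= 0.99

    def test_crop_never_cuts_structures(self):
        spec = AugmentationSpec(flip_prob=0.0, apply_prob=1.0,
                                rotation_range=0.0, noise_sd=0.0)
        for seed in range(10):
            s = self._sample(seed=100 + seed)
            n_before = (s.mask > 0).sum()
            _, mask, _ = augment(s.image, s.mask, s.labels, spec,
                                 "full_scale", np.random.default_rng(seed))
            assert (mask > 0).sum() == n_before


class TestTrainModel:
    def test_smoke_one_epoch_writes_checkpoint(self, tmp_path):
        samples, manifest = generate_cohort(6, 0.5, seed=8,
                                            grid_shape=(16, 32, 32))
        cfg = _quick_cfg(approach="bb_loss", max_epochs=1, seed=0,
                         split_fractions=(0.67, 0.17, 0.16))
        ckpt = train_model(cfg, samples, manifest)
        path = save_checkpoint(ckpt, tmp_path / "model.npz")
        back = load_checkpoint(path)
        assert back["config"].approach == "bb_loss"
        assert set(back["state"]) == set(ckpt["state"])
        for key in ckpt["state"]:
            assert np.array_equal(back["state"][key], ckpt["state"][key])
        assert len(ckpt["log"]) == 1

    def test_training_reduces_loss_on_easy_phantoms(self):
        samples, manifest = generate_cohort(32, 0.4, seed=9,
                                            grid_shape=(16, 32, 32))
        cfg = _quick_cfg(approach="full_scale", max_epochs=12, seed=1,
                         augmentation=None)
        ckpt = train_model(cfg, samples, manifest)
        log = ckpt["log"]
        assert log["train_loss"].iloc[-1] < log["train_loss"].iloc[0]
        assert ckpt["best_epoch"] == int(log["val_loss"].idxmin())

    def test_lr_schedule_halves_at_epoch_51(self):
        cfg = TrainConfig(lr_decay=0.5, lr_decay_every=50)
        assert cfg.lr_decay ** (50 // cfg.lr_decay_every) == 0.5
        assert cfg.lr_decay ** (49 // cfg.lr_decay_every) == 1.0

    def test_fixed_seed_reproduces_training_log(self):
        samples, manifest = generate_cohort(8, 0.5, seed=10,
                                            grid_shape=(16, 32, 32))
        cfg = _quick_cfg(approach="bb_loss", max_epochs=2, seed=5,
                         split_fractions=(0.5, 0.25, 0.25))
        a = train_model(cfg, samples, manifest)
        b = train_model(cfg, samples, manifest)
        pd.testing.assert_frame_equal(a["log"], b["log"])
        for key in a["state"]:
            assert np.array_equal(a["state"][key], b["state"][key])

    def test_bb_crop_trains_on_fixed_crop_shape(self):
        samples, manifest = generate_cohort(8, 0.5, seed=12,
                                            grid_shape=(16, 32, 32))
        cfg = _quick_cfg(approach="bb_crop", max_epochs=1, seed=0,
                         split_fractions=(0.5, 0.25, 0.25))
        ckpt = train_model(cfg, samples, manifest)
        assert ckpt["crop_shape"] is not None
        assert all(c % 16 == 0 for c in ckpt["crop_shape"])


class TestFinetune:
    def _base(self):
        samples, manifest = generate_cohort(8, 0.5, seed=13,
                                            grid_shape=(16, 32, 32))
        cfg = _quick_cfg(approach="full_scale", max_epochs=2, seed=2,
                         split_fractions=(0.5, 0.25, 0.25))
        return train_model(cfg, samples, manifest), samples, manifest

    def test_zero_epochs_leaves_weights_unchanged(self):
        ckpt, samples, manifest = self._base()
        cfg = dataclasses.replace(ckpt["config"], max_epochs=0)
        out = finetune(ckpt, samples, manifest, cfg)
        for key in ckpt["state"]:
            assert np.array_equal(out["state"][key], ckpt["state"][key])

    def test_architecture_mismatch_rejected(self):
        ckpt, samples, manifest = self._base()
        cfg = dataclasses.replace(ckpt["config"], width_multiplier=0.5)
        with pytest.raises(ValueError):
            finetune(ckpt, samples, manifest, cfg)

    def test_transfer_to_anisotropic_cohort_beats_unadapted(self):
        # emulate sequence transfer: thick-slice anisotropic phantoms
        from meniscus3d.train import (_evaluate_loss, model_from_checkpoint,
                                      prepare_sample, preprocess_cohort)

        base_samples, base_manifest = generate_cohort(
            16, 0.5, seed=13, grid_shape=(16, 32, 32))
        base_cfg = _quick_cfg(approach="full_scale", max_epochs=10, seed=2,
                              split_fractions=(0.5, 0.25, 0.25),
                              augmentation=None)
        ckpt = train_model(base_cfg, base_samples, base_manifest)
        aniso, manifest2 = generate_cohort(16, 0.5, seed=14,
                                           grid_shape=(16, 48, 48))
        cfg = dataclasses.replace(ckpt["config"], max_epochs=10,
                                  input_shape=(16, 32, 32))
        # unadapted baseline: the loaded model's loss on the new validation split
        split = split_cohort(manifest2, cfg.split_fractions, cfg.seed)
        by_id = {s.sample_id: s for s in aniso}
        standardized, stats, _ = preprocess_cohort(aniso, cfg, split[0])
        val_prepared = [prepare_sample(standardized[sid], by_id[sid].mask,
                                       by_id[sid].labels, cfg)
                        for sid in split[1]]
        base_model = model_from_checkpoint(ckpt)
        w0 = ckpt["class_weights"]
        base_loss, _ = _evaluate_loss(base_model, val_prepared, cfg, w0)
        tuned = finetune(ckpt, aniso, manifest2, cfg)
        tuned_model = model_from_checkpoint(tuned)
        tuned_loss, _ = _evaluate_loss(tuned_model, val_prepared, cfg, w0)
        assert tuned_loss < base_loss
        assert len(tuned["log"]) == 10
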