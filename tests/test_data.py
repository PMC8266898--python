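"""Data pipeline: I/O, preprocessing, patching, splitting, augmentation."""

import numpy as np
import pytest

from mildnet import (
    AugmentationConfig,
    DataError,
    ImageSample,
    SplitPlan,
    build_augmenter,
    extract_patches,
    load_manifest,
    load_sample,
    make_split_plan,
    preprocess,
)
from mildnet.data import save_sample
from mildnet.synthetic import SyntheticProfile, generate_dataset, generate_sample


def make_sample(h, w, channels=1, seed=0, sid="s"):
    rng = np.random.default_rng(seed)
    img = rng.random((h, w, channels))
    mask = (rng.random((h, w)) > 0.7).astype(np.uint8)
    return ImageSample(sid, img, mask, (h, w))


class TestLoadSample:
    def test_round_trip_preserves_mask(self, tmp_path):
        sample = generate_sample(SyntheticProfile(seed=1), 0)
        save_sample(sample, tmp_path / "img.png", tmp_path / "msk.png")
        loaded = load_sample(tmp_path / "img.png", tmp_path / "msk.png")
        np.testing.assert_array_equal(loaded.mask, sample.mask)
        assert loaded.original_size == (64, 64)

    def test_constant_image_maps_to_zero(self, tmp_path):
        import imageio.v3 as iio

        iio.imwrite(tmp_path / "c.png", np.full((10, 10), 77, dtype=np.uint8))
        iio.imwrite(tmp_path / "m.png", np.zeros((10, 10), dtype=np.uint8))
        s = load_sample(tmp_path / "c.png", tmp_path / "m.png")
        assert s.image.max() == 0.0

    def test_rgb_image_and_original_size(self, tmp_path):
        import imageio.v3 as iio

        rng = np.random.default_rng(0)
        iio.imwrite(tmp_path / "rgb.png",
                    rng.integers(0, 255, (100, 80, 3), dtype=np.uint8))
        iio.imwrite(tmp_path / "m.png",
                    (rng.random((100, 80)) > 0.5).astype(np.uint8) * 255)
        s = load_sample(tmp_path / "rgb.png", tmp_path / "m.png")
        assert s.image.shape == (100, 80, 3)
        assert s.original_size == (100, 80)
        assert set(np.unique(s.mask)) <= {0, 1}

    def test_shape_mismatch_raises(self, tmp_path):
        import imageio.v3 as iio

        iio.imwrite(tmp_path / "i.png", np.zeros((10, 10), dtype=np.uint8))
        iio.imwrite(tmp_path / "m.png", np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(DataError, match="different spatial dims"):
            load_sample(tmp_path / "i.png", tmp_path / "m.png")

    def test_unreadable_file_mentions_path(self, tmp_path):
        with pytest.raises((DataError, FileNotFoundError)):
            load_sample(tmp_path / "nope.png", tmp_path / "nope_mask.png")


class TestPreprocess:
    def test_resizes_to_target(self):
        s = preprocess(make_sample(512, 512), (256, 256))
        assert s.image.shape == (256, 256, 1)
        assert s.mask.shape == (256, 256)
        assert set(np.unique(s.mask)) <= {0, 1}

    def test_already_at_target_unchanged(self):
        s0 = make_sample(256, 256)
        s = preprocess(s0, (256, 256))
        np.testing.assert_allclose(s.image, s0.image)

    def test_constant_image_stays_constant(self):
        s0 = ImageSample("c", np.full((100, 100, 1), 0.4),
                         np.zeros((100, 100), dtype=np.uint8), (100, 100))
        s = preprocess(s0, (256, 256))
        np.testing.assert_allclose(s.image, 0.4)

    def test_invalid_target(self):
        with pytest.raises(DataError):
            preprocess(make_sample(64, 64), (0, 256))


class TestExtractPatches:
    @pytest.mark.parametrize("size,expected", [(512, 4), (256, 1), (768, 9)])
    def test_patch_counts(self, size, expected):
        patches = extract_patches(make_sample(size, size), patch=256, padding=16)
        assert len(patches) == expected
        assert all(p.image.shape[:2] == (256, 256) for p in patches)
        assert all(p.mask.shape == (256, 256) for p in patches)

    def test_thirty_512_images_give_120_patches(self):
        total = sum(len(extract_patches(make_sample(512, 512, seed=i, sid=f"s{i}")))
                    for i in range(30))
        assert total == 120

    def test_patches_reassemble_padded_mask(self):
        s = make_sample(512, 512, seed=3)
        patches = extract_patches(s, patch=256, padding=16)
        padded = np.pad(s.mask, 16, mode="reflect")
        for idx, p in enumerate(patches):
            iy, ix = divmod(idx, 2)
            np.testing.assert_array_equal(
                p.mask, padded[iy * 256:(iy + 1) * 256, ix * 256:(ix + 1) * 256])

    def test_small_image_single_patch_with_warning(self):
        with pytest.warns(UserWarning, match="smaller than patch"):
            patches = extract_patches(make_sample(100, 100), patch=256, padding=16)
        assert len(patches) == 1
        assert patches[0].mask.shape == (256, 256)

    def test_unique_patch_ids(self):
        patches = extract_patches(make_sample(512, 512, sid="img7"))
        assert len({p.id for p in patches}) == 4
        assert all(p.id.startswith("img7_p") for p in patches)


class TestSplitPlan:
    @pytest.mark.parametrize("n,n_test", [(2594, 778), (120, 36), (1144, 343),
                                          (165, 50), (670, 201), (10, 3)])
    def test_test_set_sizes(self, n, n_test):
        plan = make_split_plan([f"id{i}" for i in range(n)], seed=0)
        assert len(plan.test_ids) == n_test
        assert len(plan.train_ids()) + len(plan.validation_ids()) == n - n_test

    def test_partition_and_fold_balance(self):
        ids = [f"id{i}" for i in range(97)]
        plan = make_split_plan(ids, seed=5)
        groups = [plan.test_ids] + [plan.fold_ids(k) for k in range(1, 6)]
        flat = [i for g in groups for i in g]
        assert sorted(flat) == sorted(ids)  # disjoint and exhaustive
        sizes = [len(plan.fold_ids(k)) for k in range(1, 6)]
        assert max(sizes) - min(sizes) <= 1

    def test_deterministic_and_serializable(self, tmp_path):
        ids = [f"id{i}" for i in range(40)]
        a = make_split_plan(ids, seed=9)
        b = make_split_plan(ids, seed=9)
        assert a.to_json() == b.to_json()  # byte-identical plans
        a.save(tmp_path / "plan.json")
        loaded = SplitPlan.load(tmp_path / "plan.json")
        assert loaded.assignments == a.assignments

    def test_image_level_split_then_patch_order(self):
        """165 whole images split first, then 11 patches per test image: the
        test patch count is 11 * round(0.3 * 165) = 550, which patch-level
        splitting (30% of 1815 = 544.5) could not produce."""
        plan = make_split_plan([f"g{i}" for i in range(165)], seed=1)
        patches_per_image = 11
        assert len(plan.test_ids) * patches_per_image == 550

    def test_duplicate_and_small_inputs_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            make_split_plan(["a"] * 12, seed=0)
        with pytest.raises(DataError, match="at least 10"):
            make_split_plan(["a", "b"], seed=0)


class TestAugmentation:
    def test_identity_config_is_noop(self):
        aug = build_augmenter(AugmentationConfig.identity(), seed=0)
        s = make_sample(32, 32, seed=1)
        out = aug(s)
        np.testing.assert_allclose(out.image, s.image)
        np.testing.assert_array_equal(out.mask, s.mask)

    def test_rotation_180_twice_restores(self):
        cfg = AugmentationConfig(rotations=(180,), horizontal_flip=False,
                                 vertical_flip=False, scale_limit=0.0,
                                 shear_limit=(0.0, 0.0), elastic=False,
                                 color_jitter=(0, 0, 0, 0), probability=0.0)
        aug = build_augmenter(cfg, seed=0)
        s = make_sample(32, 32, seed=2)
        out = aug(aug(s))
        np.testing.assert_allclose(out.image, s.image)
        np.testing.assert_array_equal(out.mask, s.mask)

    def test_flips_preserve_foreground_count(self):
        cfg = AugmentationConfig(rotations=(0,), scale_limit=0.0,
                                 shear_limit=(0.0, 0.0), elastic=False,
                                 color_jitter=(0, 0, 0, 0), probability=0.0)
        aug = build_augmenter(cfg, seed=3)
        s = make_sample(32, 32, seed=4)
        for _ in range(10):
            assert aug(s).mask.sum() == s.mask.sum()

    def test_full_config_preserves_binarity_and_range(self):
        aug = build_augmenter(AugmentationConfig(probability=1.0), seed=5)
        s = make_sample(48, 48, channels=3, seed=6)
        for _ in range(5):
            out = aug(s)
            assert set(np.unique(out.mask)) <= {0, 1}
            assert out.image.min() >= 0.0 and out.image.max() <= 1.0

    def test_deterministic_under_seed(self):
        s = make_sample(32, 32, seed=7)
        outs = []
        for _ in range(2):
            aug = build_augmenter(AugmentationConfig(probability=1.0), seed=11)
            outs.append(aug(s))
        np.testing.assert_array_equal(outs[0].image, outs[1].image)
        np.testing.assert_array_equal(outs[0].mask, outs[1].mask)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(DataError):
            AugmentationConfig(probability=1.5)
        with pytest.raises(DataError):
            AugmentationConfig(scale_limit=-0.1)
        with pytest.raises(DataError):
            AugmentationConfig(shear_limit=(50.0, -50.0))


def test_manifest_round_trip(tmp_path):
    profile = SyntheticProfile(seed=2, image_size=(32, 32))
    manifest = generate_dataset(profile, 5, tmp_path)
    samples = load_manifest(manifest)
    assert len(samples) == 5
    originals = [generate_sample(profile, i) for i in range(5)]
    for loaded, orig in zip(sorted(samples, key=lambda s: s.id),
                            sorted(originals, key=lambda s: s.id)):
        np.testing.assert_array_equal(loaded.mask, orig.mask)
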