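"""Split apportionment, fold assignment, augmentation and preprocessing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from icsms.datapipe import (AugmentConfig, DatasetManifest, augment,
                            make_folds, resize_normalize, split_counts,
                            stratified_split)
from icsms.synth import PAPER_CLASS_COUNTS


def _manifest(per_class: dict[int, int]) -> DatasetManifest:
    rows = []
    for label, n in per_class.items():
        for i in range(n):
            rows.append({"path": f"c{label}/{i}.png", "label": label,
                         "class_name": f"c{label}", "split": "", "fold": -1,
                         "occlusion_band": "none", "occlusion_frac": 0.0})
    return DatasetManifest(pd.DataFrame(rows))


class TestSplitCounts:
    def test_two_balanced_classes_example(self):
        assert split_counts(10, (0.8, 0.1, 0.1)) == (8, 1, 1)

    def test_study_class_counts_reproduce_published_totals(self):
        totals = np.array([split_counts(n, (0.8, 0.1, 0.1))
                           for n in PAPER_CLASS_COUNTS.values()]).sum(axis=0)
        assert tuple(totals) == (4839, 606, 606)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_counts(100, (0.8, 0.1, 0.2))

    @given(n=st.integers(10, 5000))
    @settings(max_examples=50, deadline=None)
    def test_partition_is_exhaustive_and_near_proportional(self, n):
        tr, va, te = split_counts(n, (0.8, 0.1, 0.1))
        assert tr + va + te == n
        assert abs(va - 0.1 * n) <= 0.5 and abs(te - 0.1 * n) <= 0.5
        assert abs(tr - 0.8 * n) <= 1.0


class TestStratifiedSplit:
    def test_deterministic_for_fixed_seed(self):
        m = _manifest({0: 37, 1: 61})
        a = stratified_split(m, seed=5).df
        b = stratified_split(m, seed=5).df
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_changes_assignment(self):
        m = _manifest({0: 37, 1: 61})
        a = stratified_split(m, seed=5).df["split"]
        b = stratified_split(m, seed=6).df["split"]
        assert not a.equals(b)

    def test_per_class_proportions_within_one_image(self):
        m = stratified_split(_manifest({0: 123, 1: 77, 2: 200}), seed=0)
        for label, n in {0: 123, 1: 77, 2: 200}.items():
            sub = m.df[m.df["label"] == label]
            counts = sub["split"].value_counts()
            assert abs(counts.get("val", 0) - 0.1 * n) <= 0.5
            assert abs(counts.get("test", 0) - 0.1 * n) <= 0.5
            assert abs(counts.get("train", 0) - 0.8 * n) <= 1.0

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 10"):
            stratified_split(_manifest({0: 5, 1: 50}))

    def test_manifest_round_trips_through_csv(self, tmp_path):
        m = stratified_split(_manifest({0: 20, 1: 15}), seed=1)
        path = tmp_path / "manifest.csv"
        m.save(path)
        loaded = DatasetManifest.load(path)
        pd.testing.assert_frame_equal(
            loaded.df, m.df, check_dtype=False)


class TestMakeFolds:
    def test_folds_partition_dataset_evenly_per_class(self):
        m = make_folds(_manifest({0: 53, 1: 101}), k=5, seed=2)
        for label in (0, 1):
            sizes = m.df[m.df["label"] == label]["fold"].value_counts()
            assert set(sizes.index) == set(range(5))
            assert sizes.max() - sizes.min() <= 1

    def test_every_sample_in_exactly_one_fold(self):
        m = make_folds(_manifest({0: 53, 1: 101}), k=5, seed=2)
        assert (m.df["fold"] >= 0).all()
        covered = sum(len(m.fold_subset(f, "test")) for f in range(5))
        assert covered == len(m)

    def test_same_seed_identical_folds(self):
        a = make_folds(_manifest({0: 40}), k=4, seed=9).df["fold"]
        b = make_folds(_manifest({0: 40}), k=4, seed=9).df["fold"]
        assert a.equals(b)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="smaller than k"):
            make_folds(_manifest({0: 3, 1: 50}), k=5)


class TestAugment:
    def test_identity_when_no_transform_drawn(self, rng):
        """Zero rotation bound, unit factor ranges, zero probabilities."""
        cfg = AugmentConfig(hflip_p=0.0, rotation_deg=0.0,
                            brightness_range=(1.0, 1.0),
                            contrast_range=(1.0, 1.0), blur_p=0.0)
        img = rng.random((32, 32, 3), dtype=np.float32)
        np.testing.assert_allclose(augment(img, cfg, rng), img, atol=1e-6)

    def test_horizontal_flip_is_involution(self, rng):
        cfg = AugmentConfig(hflip_p=1.0, rotation_deg=0.0,
                            brightness_range=(1.0, 1.0),
                            contrast_range=(1.0, 1.0), blur_p=0.0)
        img = rng.random((16, 16, 3), dtype=np.float32)
        twice = augment(augment(img, cfg, rng), cfg, rng)
        np.testing.assert_allclose(twice, img, atol=1e-6)

    def test_blur_preserves_constant_images(self, rng):
        cfg = AugmentConfig(hflip_p=0.0, rotation_deg=0.0,
                            brightness_range=(1.0, 1.0),
                            contrast_range=(1.0, 1.0), blur_p=1.0)
        img = np.full((24, 24, 3), 0.37, dtype=np.float32)
        out = augment(img, cfg, rng)
        np.testing.assert_allclose(out, img, atol=1e-5)

    def test_output_size_and_range_preserved(self, rng):
        img = rng.random((48, 48, 3), dtype=np.float32)
        out = augment(img, AugmentConfig(), rng)
        assert out.shape == img.shape
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestResizeNormalize:
    def test_downsamples_to_224(self, rng):
        img = rng.random((448, 448, 3), dtype=np.float32)
        out = resize_normalize(img)
        assert out.shape == (3, 224, 224)

    def test_already_sized_input_only_normalized(self):
        img = np.full((224, 224, 3), 0.75, dtype=np.float32)
        out = resize_normalize(img)
        np.testing.assert_allclose(out, (0.75 - 0.5) / 0.5, atol=1e-6)

    def test_all_white_maps_to_max_normalized_value(self):
        img = np.ones((10, 10, 3), dtype=np.float32)
        out = resize_normalize(img, size=8)
        np.testing.assert_allclose(out, 1.0, atol=1e-2)

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError, match="RGB"):
            resize_normalize(np.zeros((10, 10), dtype=np.float32))
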