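"""Synthetic stimulus generation: determinism, averaging rule, suites."""

import numpy as np
import pytest

from gainsweep.images import (
    DifficultyLevel,
    LabeledDataset,
    StyleParams,
    build_difficulty_suite,
    generate_category_dataset,
    generate_real_images,
    load_dataset,
    make_average_image,
    save_dataset,
    split_dataset,
)


class TestRealImages:
    def test_deterministic_given_seed(self, tiny_style):
        a = generate_real_images(10, seed=1, style_params=tiny_style)
        b = generate_real_images(10, seed=1, style_params=tiny_style)
        assert np.array_equal(a.images, b.images)

    def test_seed_sensitivity(self, tiny_style):
        a = generate_real_images(10, seed=1, style_params=tiny_style)
        b = generate_real_images(10, seed=2, style_params=tiny_style)
        assert not np.array_equal(a.images, b.images)

    def test_every_image_has_positive_variance(self, tiny_style):
        ds = generate_real_images(1000, seed=3, style_params=tiny_style)
        per_image_var = ds.images.reshape(len(ds), -1).var(axis=1)
        assert np.all(per_image_var > 0)

    def test_pixel_range_and_shape(self, tiny_style):
        ds = generate_real_images(5, seed=0, style_params=tiny_style)
        assert ds.images.shape == (5, 16, 16, 3)
        assert ds.images.min() >= 0.0 and ds.images.max() <= 1.0

    def test_invalid_args_rejected(self, tiny_style):
        with pytest.raises(ValueError):
            generate_real_images(0, seed=1, style_params=tiny_style)
        with pytest.raises(ValueError):
            StyleParams(image_size=4)
        with pytest.raises(ValueError):
            StyleParams(freq_range=(0.3, 0.1))


class TestAverageImage:
    def test_integer_k_is_plain_mean(self):
        a = np.full((8, 8, 3), 0.4, np.float32)
        b = np.full((8, 8, 3), 0.8, np.float32)
        out = make_average_image([a, b], 2)
        np.testing.assert_allclose(out, 0.6, atol=1e-7)

    def test_fractional_k_weight_rule(self):
        """k = 1.25 blends the base image at full weight plus a second at
        alpha = 0.25, normalised by k."""
        a = np.full((8, 8, 3), 0.4, np.float32)
        b = np.full((8, 8, 3), 0.8, np.float32)
        out = make_average_image([a, b], 1.25)
        np.testing.assert_allclose(out, (0.4 + 0.25 * 0.8) / 1.25, atol=1e-7)

    def test_k_one_is_identity(self, tiny_style):
        img = generate_real_images(1, seed=5, style_params=tiny_style).images[0]
        np.testing.assert_array_equal(make_average_image([img], 1), img)

    def test_source_count_mismatch_rejected(self):
        a = np.zeros((4, 4, 3), np.float32)
        with pytest.raises(ValueError):
            make_average_image([a], 2)
        with pytest.raises(ValueError):
            make_average_image([a, a, a], 1.25)

    def test_permutation_invariant_for_equal_weights(self, tiny_style):
        imgs = list(generate_real_images(3, seed=9, style_params=tiny_style).images)
        out1 = make_average_image(imgs, 3)
        out2 = make_average_image(imgs[::-1], 3)
        np.testing.assert_allclose(out1, out2, atol=1e-6)

    def test_output_within_pixelwise_envelope(self, tiny_style):
        imgs = list(generate_real_images(4, seed=11, style_params=tiny_style).images)
        out = make_average_image(imgs, 4)
        stack = np.stack(imgs)
        assert np.all(out >= stack.min(axis=0) - 1e-6)
        assert np.all(out <= stack.max(axis=0) + 1e-6)


class TestDifficultySuite:
    @pytest.fixture(scope="class")
    def suite(self, tiny_style):
        return build_difficulty_suite(
            [1.25, 3.0, 20.0], n_per_split=(40, 20, 20), seed=7,
            style_params=tiny_style,
        )

    def test_structure_and_balance(self, suite):
        assert set(suite) == {1.25, 3.0, 20.0}
        for level, splits in suite.items():
            for split, ds in splits.items():
                assert ds.labels.mean() == 0.5  # exact 50/50

    def test_split_disjointness_by_hash(self, suite):
        for level, splits in suite.items():
            hashes = {
                split: {arr.tobytes() for arr in splits[split].images}
                for split in splits
            }
            assert not (hashes["train"] & hashes["test"])
            assert not (hashes["train"] & hashes["val"])

    def test_real_images_shared_across_levels(self, suite):
        h1 = {a.tobytes() for a, l in zip(suite[1.25]["train"].images,
                                          suite[1.25]["train"].labels) if l == 1}
        h2 = {a.tobytes() for a, l in zip(suite[20.0]["train"].images,
                                          suite[20.0]["train"].labels) if l == 1}
        assert h1 == h2

    def test_class_separation_grows_with_k(self, tiny_style):
        """Pixel-space distance between class centroids is larger for the
        easy level (k = 40) than for the hard level (k = 1.25)."""
        suite = build_difficulty_suite(
            [1.25, 40.0], n_per_split=(60, 20, 20), seed=3,
            style_params=tiny_style,
        )
        def centroid_distance(ds):
            real = ds.images[ds.labels == 1].mean(axis=0)
            avg = ds.images[ds.labels == 0].mean(axis=0)
            return float(np.linalg.norm(real - avg))
        assert centroid_distance(suite[40.0]["train"]) > centroid_distance(
            suite[1.25]["train"]
        )

    def test_average_class_diverges_from_real_statistics_with_k(self, tiny_style):
        """Blending attenuates contrast ~1/sqrt(k): the average class
        drifts monotonically away from the real-image contrast
        distribution as k grows, which is what makes large-k averages
        look unlike any single scene."""
        suite = build_difficulty_suite(
            [1.25, 6.0, 40.0], n_per_split=(40, 20, 20), seed=13,
            style_params=tiny_style,
        )
        def class_contrast(ds, label):
            imgs = ds.images[ds.labels == label]
            return imgs.reshape(len(imgs), -1).std(axis=1).mean()
        real_c = class_contrast(suite[1.25]["train"], 1)
        avg_c = [class_contrast(suite[k]["train"], 0) for k in (1.25, 6.0, 40.0)]
        assert avg_c[0] > avg_c[1] > avg_c[2]
        gaps = [abs(real_c - c) for c in avg_c]
        assert gaps[0] < gaps[1] < gaps[2]

    def test_odd_split_size_rejected(self, tiny_style):
        with pytest.raises(ValueError):
            build_difficulty_suite([2.0], n_per_split=(11, 4, 4), seed=0,
                                   style_params=tiny_style)


class TestCategoryDataset:
    def test_construction_and_determinism(self, tiny_style):
        ds = generate_category_dataset(8, 5, seed=1, style_params=tiny_style)
        assert len(ds) == 40
        assert np.all(np.bincount(ds.labels) == 5)
        ds2 = generate_category_dataset(8, 5, seed=1, style_params=tiny_style)
        assert np.array_equal(ds.images, ds2.images)
        assert np.array_equal(ds.labels, ds2.labels)

    def test_linear_probe_learns_categories_from_pixels(self, tiny_style):
        """Categories are learnable by design: a pixel-space linear probe
        must beat chance by more than 3 binomial SEs."""
        from sklearn.linear_model import LogisticRegression

        ds = generate_category_dataset(8, 40, seed=2, style_params=tiny_style)
        splits = split_dataset(ds, seed=0)
        clf = LogisticRegression(max_iter=2000)
        clf.fit(splits["train"].images.reshape(len(splits["train"]), -1),
                splits["train"].labels)
        x_test = splits["test"].images.reshape(len(splits["test"]), -1)
        acc = clf.score(x_test, splits["test"].labels)
        n = len(splits["test"])
        chance = 1 / 8
        assert acc > chance + 3 * np.sqrt(chance * (1 - chance) / n)

    def test_too_few_categories_rejected(self, tiny_style):
        with pytest.raises(ValueError):
            generate_category_dataset(1, 5, seed=0, style_params=tiny_style)


def test_png_csv_roundtrip(tmp_path, tiny_style):
    ds = generate_real_images(4, seed=21, style_params=tiny_style)
    manifest = save_dataset(ds, tmp_path, prefix="t", level=2.0, seed=21)
    back = load_dataset(manifest)
    assert len(back) == 4
    assert np.array_equal(back.labels, ds.labels)
    # 8-bit quantisation bounds the roundtrip error
    assert np.max(np.abs(back.images - ds.images)) <= 1.0 / 255.0 + 1e-6
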