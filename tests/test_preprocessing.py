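import numpy as np
import pandas as pd
import pytest
from sonosiam.phantom import PhantomImage, TabularDataset, generate_image_dataset, images_to_manifest
from sonosiam.preprocessing import (AugmentationConfig, augment_abnormal,
                                    folds_to_frame, preprocess_image,
                                    smote_oversample, SMOTEOversampler,
                                    stratified_kfold_split)


class TestPreprocessImage:
    def test_center_maps_to_zero(self):
        out = preprocess_image(np.full((224, 224), 0.5))
        assert out.shape == (224, 224)
        np.testing.assert_allclose(out, 0.0)

    def test_no_resampling_at_target_size(self):
        rng = np.random.default_rng(0)
        raw = rng.random((224, 224))
        out = preprocess_image(raw)
        np.testing.assert_allclose(out, (raw - 0.5) / 0.5)

    def test_downsampling_preserves_centroid(self):
        yy, xx = np.meshgrid(np.arange(448), np.arange(448), indexing="ij")
        disc = ((yy - 224.0) ** 2 + (xx - 224.0) ** 2 <= 60**2).astype(float)
        out = preprocess_image(disc, side=224)
        raw = (out + 1) / 2
        cy = (raw * yy[:224, :224]).sum() / raw.sum()
        cx = (raw * xx[:224, :224]).sum() / raw.sum()
        assert abs(cy - 112.0) < 1.0 and abs(cx - 112.0) < 1.0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            preprocess_image(np.zeros((4, 4, 4)))
        bad = np.zeros((32, 32))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            preprocess_image(bad)


class TestAugmentation:
    def _abnormal(self, pixels):
        return PhantomImage(pixels, "brain", "abnormal", "SRC_B", "a")

    @pytest.mark.parametrize("seed", [0, 1, 2, 99])
    def test_identity_on_normal(self, seed):
        img = generate_image_dataset(1, 0, seed=3, side=32)[0]
        out = augment_abnormal(img, AugmentationConfig(seed=seed))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_zero_config_is_identity(self):
        img = generate_image_dataset(0, 1, seed=3, side=32)[0]
        cfg = AugmentationConfig(flip_probability=0, max_rotation_deg=0,
                                 max_translation_frac=0, seed=0)
        out = augment_abnormal(img, cfg)
        np.testing.assert_allclose(out.pixels, img.pixels)

    def test_rotation_conserves_mass_of_centered_content(self):
        # centered blob on a zero background: rotation with zero-fill keeps
        # the pixel sum within 1%
        yy, xx = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        blob = np.exp(-(((yy - 31.5) ** 2 + (xx - 31.5) ** 2) / (2 * 8.0**2)))
        img = self._abnormal(blob / blob.max())
        cfg = AugmentationConfig(flip_probability=0, max_rotation_deg=10,
                                 max_translation_frac=0, seed=11)
        out = augment_abnormal(img, cfg)
        rel = abs(out.pixels.sum() - img.pixels.sum()) / img.pixels.sum()
        assert rel < 0.01

    def test_labels_and_shape_unchanged(self):
        img = generate_image_dataset(0, 1, seed=5, side=32)[0]
        out = augment_abnormal(img, AugmentationConfig(seed=2))
        assert out.pixels.shape == img.pixels.shape
        assert (out.condition, out.body_part, out.source_tag, out.id) == (
            img.condition, img.body_part, img.source_tag, img.id)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AugmentationConfig(flip_probability=1.5)
        with pytest.raises(ValueError):
            AugmentationConfig(max_translation_frac=1.0)


class TestSmote:
    def _data(self, sizes, p=4, seed=0, sep=1.0, n_cat=0):
        from sonosiam.phantom import generate_tabular_dataset

        return generate_tabular_dataset(list(sizes), p=p, n_categorical=n_cat,
                                        class_separation=sep, seed=seed)

    def test_balances_to_majority(self):
        out = smote_oversample(self._data([100, 20, 10]), k_neighbors=5, seed=0)
        _, counts = np.unique(out.labels, return_counts=True)
        assert counts.tolist() == [100, 100, 100]

    def test_originals_preserved_verbatim(self):
        data = self._data([50, 10])
        out = smote_oversample(data, seed=1)
        np.testing.assert_array_equal(out.features[: len(data.labels)],
                                      data.features)

    def test_balanced_input_is_identity(self):
        data = self._data([30, 30])
        out = smote_oversample(data, seed=0)
        np.testing.assert_array_equal(out.features, data.features)
        np.testing.assert_array_equal(out.labels, data.labels)

    def test_synthetic_rows_are_convex_combinations(self):
        # minority of {0, 1} in 1-D with k=1: every synthetic value in [0, 1]
        X = np.concatenate([np.linspace(5, 6, 30), [0.0, 1.0]])[:, None]
        y = np.array([0] * 30 + [1] * 2)
        data = TabularDataset(X, np.zeros(1, dtype=bool), y)
        out = smote_oversample(data, k_neighbors=1, seed=3)
        synth = out.features[len(y):, 0]
        assert len(synth) == 28
        assert ((synth >= 0) & (synth <= 1)).all()

    def test_deterministic(self):
        data = self._data([40, 12])
        a = smote_oversample(data, seed=9)
        b = smote_oversample(data, seed=9)
        np.testing.assert_array_equal(a.features, b.features)

    def test_error_names_small_class(self):
        data = self._data([30, 4])
        with pytest.raises(ValueError, match="1"):
            smote_oversample(data, k_neighbors=5, seed=0)

    def test_smote_nc_categorical_mode(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(size=40), np.zeros(40)])
        X[:30, 1] = 2.0  # majority level of the categorical column
        y = np.array([0] * 30 + [1] * 10)
        X[y == 1, 1] = 1.0  # minority class all level 1
        data = TabularDataset(X, np.array([False, True]), y)
        out = smote_oversample(data, k_neighbors=3, seed=0)
        synth = out.features[40:]
        # neighbours are same-class, all level 1 -> mode is 1
        assert (synth[:, 1] == 1.0).all()
        # and categorical values are never interpolated off-grid
        assert set(np.unique(out.features[:, 1])) <= {1.0, 2.0}

    def test_estimator_wrapper(self):
        data = self._data([50, 15])
        res = SMOTEOversampler(k_neighbors=5, random_state=0)
        Xr, yr = res.fit_resample(data.features, data.labels)
        _, counts = np.unique(yr, return_counts=True)
        assert counts.tolist() == [50, 50]
        assert res.get_params()["k_neighbors"] == 5


class TestStratifiedKFold:
    def test_exact_fold_counts_940_60(self):
        imgs = generate_image_dataset(940, 60, seed=7, side=32)
        manifest = images_to_manifest(imgs)
        splits = stratified_kfold_split(manifest, k=5, seed=0)
        cond = dict(zip(manifest["id"], manifest["condition"]))
        for s in splits:
            test_conds = pd.Series([cond[i] for i in s.test_ids]).value_counts()
            assert test_conds["normal"] == 188
            assert test_conds["abnormal"] == 12

    def test_partition_properties(self):
        imgs = generate_image_dataset(33, 17, seed=1, side=32, source_mixing=0.3)
        manifest = images_to_manifest(imgs)
        splits = stratified_kfold_split(manifest, k=5, seed=4)
        all_ids = set(manifest["id"])
        seen = []
        for s in splits:
            assert set(s.train_ids).isdisjoint(s.test_ids)
            assert set(s.train_ids) | set(s.test_ids) == all_ids
            seen.extend(s.test_ids)
        assert sorted(seen) == sorted(all_ids)  # test sets partition the data

    def test_both_source_tags_in_every_partition(self):
        imgs = generate_image_dataset(40, 20, seed=2, side=32)
        manifest = images_to_manifest(imgs)
        tag = dict(zip(manifest["id"], manifest["source_tag"]))
        for s in stratified_kfold_split(manifest, k=4, seed=0):
            assert {tag[i] for i in s.train_ids} == {"SRC_A", "SRC_B"}
            assert {tag[i] for i in s.test_ids} == {"SRC_A", "SRC_B"}

    def test_minimal_two_fold(self):
        manifest = pd.DataFrame(
            {"id": list("abcd"), "condition": ["normal", "normal", "abnormal",
                                               "abnormal"]}
        )
        splits = stratified_kfold_split(manifest, k=2, seed=0)
        cond = dict(zip(manifest["id"], manifest["condition"]))
        for s in splits:
            assert sorted(cond[i] for i in s.test_ids) == ["abnormal", "normal"]

    def test_deterministic(self):
        imgs = generate_image_dataset(30, 10, seed=5, side=32)
        manifest = images_to_manifest(imgs)
        a = stratified_kfold_split(manifest, k=5, seed=11)
        b = stratified_kfold_split(manifest, k=5, seed=11)
        assert [s.test_ids for s in a] == [s.test_ids for s in b]

    def test_small_class_error(self):
        manifest = pd.DataFrame(
            {"id": list("abcde"),
             "condition": ["normal"] * 4 + ["abnormal"]}
        )
        with pytest.raises(ValueError, match="abnormal"):
            stratified_kfold_split(manifest, k=2, seed=0)

    def test_export_frame(self):
        imgs = generate_image_dataset(10, 10, seed=0, side=32)
        splits = stratified_kfold_split(images_to_manifest(imgs), k=2, seed=0)
        df = folds_to_frame(splits)
        assert set(df.columns) == {"id", "fold", "partition"}
        assert len(df) == 2 * 20
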