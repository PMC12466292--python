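import numpy as np
import pytest

from sonosiam.model import BackboneSpec
from sonosiam.phantom import generate_image_dataset, images_to_manifest
from sonosiam.pipeline import train_siamese
from sonosiam.preprocessing import preprocess_image, stratified_kfold_split


@pytest.fixture(scope="session")
def phantom_split():
    """940 normal / 60 abnormal phantoms (64 px, confounded sources) split
    80:20 by the stratified k-fold's first fold."""
    images = generate_image_dataset(940, 60, seed=7, side=64)
    manifest = images_to_manifest(images)
    splits = stratified_kfold_split(manifest, k=5, seed=1)
    by_id = {im.id: im for im in images}
    train = [by_id[i] for i in splits[0].train_ids]
    test = [by_id[i] for i in splits[0].test_ids]
    return train, test


@pytest.fixture(scope="session")
def trained_model(phantom_split):
    """Small Siamese network trained on the 800-image partition (15 epochs,
    curriculum + abnormal-only augmentation)."""
    train, _ = phantom_split
    model, log = train_siamese(
        train, spec=BackboneSpec.small(32), epochs=15, pairs_per_epoch=200,
        seed=0,
    )
    return model, log


@pytest.fixture(scope="session")
def calibration_batches(phantom_split):
    train, _ = phantom_split
    rng = np.random.default_rng(0)
    pick = rng.choice(len(train), size=8 * 32, replace=False)
    return [
        np.stack(
            [preprocess_image(train[i].pixels, side=32)
             for i in pick[b * 32 : (b + 1) * 32]]
        )
        for b in range(8)
    ]
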