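"""Image standardisation, abnormal-only augmentation, minority oversampling
and stratified mixed-source cross-validation splits.

Augmentation is deliberately restricted to the abnormal class: the abnormal
corpus is small and source-confounded, so widening its intra-class variability
(flip, ±10° rotation, ≤10% translation — the plausible range of freehand probe
motion) discourages the encoder from keying on source artifacts. Normal images
pass through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .phantom import PhantomImage, TabularDataset

__all__ = [
    "AugmentationConfig",
    "FoldSplit",
    "preprocess_image",
    "augment_abnormal",
    "smote_oversample",
    "SMOTEOversampler",
    "stratified_kfold_split",
    "folds_to_frame",
]


@dataclass
class AugmentationConfig:
    flip_probability: float = 0.5
    max_rotation_deg: float = 10.0
    max_translation_frac: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValueError("flip_probability must be in [0, 1]")
        if self.max_rotation_deg < 0:
            raise ValueError("max_rotation_deg must be >= 0")
        if not 0.0 <= self.max_translation_frac < 1.0:
            raise ValueError("max_translation_frac must be in [0, 1)")


@dataclass
class FoldSplit:
    fold_index: int
    train_ids: list
    test_ids: list
    k: int = 5


def preprocess_image(raw: np.ndarray, side: int = 224) -> np.ndarray:
    """Resize to ``side`` x ``side`` (bilinear) and map intensities
    (v - 0.5) / 0.5 so [0, 1] becomes [-1, 1].

    An input already at the target size is not resampled — only the affine
    intensity map is applied.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2:
        raise ValueError("input must be a 2-D pixel array")
    if not np.isfinite(raw).all():
        raise ValueError("input contains non-finite values")
    if raw.shape != (side, side):
        factors = (side / raw.shape[0], side / raw.shape[1])
        raw = ndimage.zoom(raw, factors, order=1)
        raw = raw[:side, :side]
    return (raw - 0.5) / 0.5


def _augment_pixels(px: np.ndarray, cfg: AugmentationConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Flip -> rotate -> translate with bilinear resampling, zero fill."""
    out = px
    if rng.random() < cfg.flip_probability:
        out = out[:, ::-1]
    angle = rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)
    if angle != 0.0:
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="constant", cval=0.0)
    h, w = out.shape
    dy = rng.uniform(-cfg.max_translation_frac, cfg.max_translation_frac) * h
    dx = rng.uniform(-cfg.max_translation_frac, cfg.max_translation_frac) * w
    if dy != 0.0 or dx != 0.0:
        out = ndimage.shift(out, (dy, dx), order=1, mode="constant", cval=0.0)
    return np.clip(out, 0.0, 1.0)


def augment_abnormal(img: PhantomImage, cfg: AugmentationConfig,
                     rng: np.random.Generator | None = None) -> PhantomImage:
    """Apply flip/rotation/translation to abnormal images only.

    Normal-condition inputs are returned unchanged for any seed. Labels and id
    are never touched.
    """
    if img.condition == "normal":
        return img
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    return replace(img, pixels=_augment_pixels(img.pixels, cfg, rng))


# ---------------------------------------------------------------------------
# SMOTE / SMOTE-NC


def _nc_encode(X: np.ndarray, cat_mask: np.ndarray) -> np.ndarray:
    """Embed mixed columns so Euclidean distance matches the SMOTE-NC metric:
    numeric columns as-is; each categorical column one-hot scaled so a level
    mismatch contributes med^2 (med = median of numeric-column stds)."""
    num = X[:, ~cat_mask]
    stds = num.std(axis=0)
    med = np.median(stds) if stds.size else 1.0
    if med == 0:
        med = 1.0
    blocks = [num]
    for j in np.where(cat_mask)[0]:
        codes = X[:, j].astype(int)
        levels = np.unique(codes)
        onehot = (codes[:, None] == levels[None, :]).astype(float)
        blocks.append(onehot * (med / np.sqrt(2.0)))
    return np.hstack(blocks)


def smote_oversample(data: TabularDataset, k_neighbors: int | None = None,
                     seed: int = 0) -> TabularDataset:
    """Oversample every minority class up to the majority count.

    Synthetic numeric values are x + u (x_nn - x) with u ~ Uniform(0,1) and
    x_nn one of the k nearest same-class neighbours; with categorical columns
    present (SMOTE-NC) the categorical entries are the mode over the k
    neighbours and the distance adds the standard categorical-mismatch
    penalty. Original rows are preserved verbatim; defaults k=5
    (continuous-only) and k=3 (any categorical column).
    """
    X, y, cat = data.features, data.labels, data.categorical_mask
    has_cat = bool(cat.any())
    if k_neighbors is None:
        k_neighbors = 3 if has_cat else 5
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c, n in zip(classes, counts):
        if n <= k_neighbors:
            raise ValueError(
                f"class {c!r} has {n} samples; needs more than k_neighbors={k_neighbors}"
            )
    n_max = counts.max()
    rng = np.random.default_rng(seed)
    new_rows, new_labels = [], []
    for c, n in zip(classes, counts):
        deficit = n_max - n
        if deficit == 0:
            continue
        Xc = X[y == c]
        enc = _nc_encode(Xc, cat) if has_cat else Xc
        nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(enc)
        # drop self-neighbour in column 0
        nbrs = nn.kneighbors(enc, return_distance=False)[:, 1:]
        base = rng.integers(0, n, size=deficit)
        pick = rng.integers(0, k_neighbors, size=deficit)
        u = rng.uniform(0.0, 1.0, size=deficit)
        for b, p, uu in zip(base, pick, u):
            x = Xc[b]
            x_nn = Xc[nbrs[b, p]]
            row = x + uu * (x_nn - x)
            if has_cat:
                neigh_vals = Xc[nbrs[b]][:, cat]
                modes = []
                for col in neigh_vals.T:
                    vals, cnts = np.unique(col, return_counts=True)
                    modes.append(vals[np.argmax(cnts)])
                row[cat] = modes
            new_rows.append(row)
            new_labels.append(c)
    if not new_rows:
        return TabularDataset(X.copy(), cat.copy(), y.copy())
    return TabularDataset(
        np.vstack([X, np.array(new_rows)]),
        cat.copy(),
        np.concatenate([y, np.array(new_labels)]),
    )


class SMOTEOversampler(BaseEstimator):
    """Estimator-style wrapper around :func:`smote_oversample`.

    Parameters
    ----------
    k_neighbors : int or None
        Neighbours used for interpolation; None picks 5 (continuous-only)
        or 3 (mixed-type).
    categorical_mask : array-like of bool or None
        Marks categorical columns (SMOTE-NC); None means all-continuous.
    random_state : int
    """

    def __init__(self, k_neighbors: int | None = None,
                 categorical_mask=None, random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.categorical_mask = categorical_mask
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        mask = (
            np.zeros(X.shape[1], dtype=bool)
            if self.categorical_mask is None
            else np.asarray(self.categorical_mask, dtype=bool)
        )
        out = smote_oversample(
            TabularDataset(X, mask, y), self.k_neighbors, self.random_state
        )
        self.sampling_counts_ = dict(zip(*np.unique(out.labels, return_counts=True)))
        return out.features, out.labels


# ---------------------------------------------------------------------------
# Stratified mixed-source k-fold


def stratified_kfold_split(manifest: pd.DataFrame, k: int = 5,
                           seed: int = 0) -> list[FoldSplit]:
    """Deterministic stratified k-fold over a manifest with columns
    ``id``, ``condition`` and (optionally) ``source_tag``.

    Within each condition class, ids are grouped by source tag, shuffled
    within group, concatenated and dealt round-robin to folds, so per-fold
    class counts deviate from n_class/k by at most one sample and — whenever a
    (class, source) stratum has at least k members — every train and test
    partition contains both source tags.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = manifest["id"].to_numpy()
    labels = manifest["condition"].to_numpy()
    sources = (
        manifest["source_tag"].to_numpy()
        if "source_tag" in manifest.columns
        else np.full(len(ids), "SRC_A")
    )
    rng = np.random.default_rng(seed)
    fold_test: list[list] = [[] for _ in range(k)]
    for c in np.unique(labels):
        c_idx = np.where(labels == c)[0]
        if len(c_idx) < k:
            raise ValueError(f"class {c!r} has {len(c_idx)} members, fewer than k={k}")
        ordered = []
        for s in np.unique(sources[c_idx]):
            grp = c_idx[sources[c_idx] == s]
            ordered.extend(rng.permutation(grp).tolist())
        start = int(rng.integers(0, k))
        for pos, i in enumerate(ordered):
            fold_test[(start + pos) % k].append(ids[i])
    all_ids = set(ids.tolist())
    splits = []
    for f in range(k):
        test = sorted(fold_test[f])
        train = sorted(all_ids.difference(test))
        splits.append(FoldSplit(fold_index=f, train_ids=train, test_ids=test, k=k))
    return splits


def folds_to_frame(splits: list[FoldSplit]) -> pd.DataFrame:
    """Long-form fold assignment table (id, fold, partition) for CSV export."""
    rows = []
    for s in splits:
        rows += [(i, s.fold_index, "train") for i in s.train_ids]
        rows += [(i, s.fold_index, "test") for i in s.test_ids]
    return pd.DataFrame(rows, columns=["id", "fold", "partition"])
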