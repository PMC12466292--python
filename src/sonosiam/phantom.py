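"""Synthetic ultrasound-like phantom images and tabular health records.

Real fetal-ultrasound collections pair a large normal corpus from one
repository with a small abnormal corpus scraped from another, so condition and
acquisition source are confounded and the two sources carry different nuisance
artifacts (video compression, background texture). The phantom generator
reproduces that statistical structure with controllable knobs:

* three anatomical templates (concentric ellipses for brain, rib-like arcs for
  thorax, a large oval for abdomen) under multiplicative speckle;
* abnormal images carry a bright elliptical lesion (semi-axes 5-10% of the
  side, +0.3 contrast) so the classes are genuinely separable from pixels;
* each source tag stamps its own nuisance texture (SRC_A: fine speckle and a
  smooth vignette; SRC_B: horizontal banding, blocky compression-like noise
  and a small brightness offset), so source leakage is detectable and
  embeddings can be tested for source invariance;
* by default normal images carry SRC_A and abnormal SRC_B (the confounded
  regime); ``source_mixing`` swaps a fraction of tags and ``swap_sources``
  reverses the mapping outright for tag-swapped test sets.

Nothing here simulates wave propagation; the templates are statistical
stand-ins whose only job is to give downstream training something learnable
with a controlled confound.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

BODY_PARTS = ("brain", "thorax", "abdomen")
CONDITIONS = ("normal", "abnormal")
SOURCE_TAGS = ("SRC_A", "SRC_B")

__all__ = [
    "PhantomImage",
    "TabularDataset",
    "generate_image_dataset",
    "generate_tabular_dataset",
    "render_phantom",
    "images_to_manifest",
    "write_image_dataset",
    "write_tabular_dataset",
]


@dataclass
class PhantomImage:
    """A single labelled grayscale phantom frame, pixels in [0, 1]."""

    pixels: np.ndarray
    body_part: str
    condition: str
    source_tag: str
    id: str

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError("pixels must be a square 2-D array")
        if px.shape[0] < 32:
            raise ValueError("image side must be >= 32")
        if not np.isfinite(px).all() or px.min() < 0 or px.max() > 1:
            raise ValueError("pixel values must be finite and within [0, 1]")
        if self.body_part not in BODY_PARTS:
            raise ValueError(f"unknown body_part {self.body_part!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.source_tag not in SOURCE_TAGS:
            raise ValueError(f"unknown source_tag {self.source_tag!r}")


@dataclass
class TabularDataset:
    """Numeric/categorical feature table with class labels.

    Categorical columns are stored as integer level codes inside ``features``;
    ``categorical_mask`` marks which columns they are.
    """

    features: np.ndarray
    categorical_mask: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.categorical_mask = np.asarray(self.categorical_mask, dtype=bool)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        if self.categorical_mask.shape != (self.features.shape[1],):
            raise ValueError("categorical_mask length must equal feature count")
        if not np.isfinite(self.features).all():
            raise ValueError("features contain non-finite values")


def _coord_grid(side: int):
    c = (np.arange(side) - (side - 1) / 2.0) / (side / 2.0)
    return np.meshgrid(c, c, indexing="ij")  # yy, xx in [-1, 1]


def _ellipse_mask(yy, xx, cy, cx, ry, rx, theta=0.0):
    ys, xs = yy - cy, xx - cx
    yr = ys * np.cos(theta) - xs * np.sin(theta)
    xr = ys * np.sin(theta) + xs * np.cos(theta)
    return (yr / ry) ** 2 + (xr / rx) ** 2 <= 1.0


def _render_anatomy(body_part: str, side: int, rng: np.random.Generator):
    yy, xx = _coord_grid(side)
    # near-black background, as outside the B-mode fan; keeps zero-filled
    # augmentation borders statistically indistinguishable from background
    img = np.full((side, side), 0.03)
    jit = lambda s: rng.uniform(-s, s)  # noqa: E731  (small geometry jitter)
    if body_part == "brain":
        # bright skull ring with a dimmer interior and a midline
        outer = _ellipse_mask(yy, xx, jit(0.05), jit(0.05), 0.72, 0.58, jit(0.2))
        inner = _ellipse_mask(yy, xx, jit(0.05), jit(0.05), 0.58, 0.45, jit(0.2))
        img[outer] = 0.85
        img[inner] = 0.35
        img[np.abs(xx) < 0.02] = np.maximum(img[np.abs(xx) < 0.02], 0.55)
    elif body_part == "thorax":
        # circular section with rib-like bright arcs
        body = _ellipse_mask(yy, xx, 0.0, 0.0, 0.8, 0.8)
        img[body] = 0.35
        r = np.sqrt(yy**2 + xx**2)
        ang = np.arctan2(yy, xx)
        for k in range(6):
            a0 = -np.pi + k * np.pi / 3 + jit(0.1)
            arc = (np.abs(r - 0.65) < 0.05) & (np.abs(np.angle(np.exp(1j * (ang - a0)))) < 0.35)
            img[arc] = 0.9
        heart = _ellipse_mask(yy, xx, 0.1 + jit(0.05), -0.1 + jit(0.05), 0.25, 0.2)
        img[heart] = 0.55
    else:  # abdomen
        body = _ellipse_mask(yy, xx, jit(0.05), jit(0.05), 0.75, 0.65, jit(0.3))
        img[body] = 0.45
        stomach = _ellipse_mask(yy, xx, 0.15 + jit(0.05), 0.2 + jit(0.05), 0.18, 0.14)
        img[stomach] = 0.2
        cord = _ellipse_mask(yy, xx, -0.2 + jit(0.05), -0.15 + jit(0.05), 0.1, 0.1)
        img[cord] = 0.75
    return img


def _add_lesion(img: np.ndarray, rng: np.random.Generator):
    """Bright elliptical lesion: semi-axes 10-20% of the side, contrast +0.3,
    placed inside the central anatomy."""
    side = img.shape[0]
    yy, xx = _coord_grid(side)
    ry = rng.uniform(0.20, 0.40)
    rx = rng.uniform(0.20, 0.40)
    cy = rng.uniform(-0.35, 0.35)
    cx = rng.uniform(-0.35, 0.35)
    mask = _ellipse_mask(yy, xx, cy, cx, ry, rx, rng.uniform(0, np.pi))
    out = img.copy()
    out[mask] += 0.3
    return out


def _speckle(img: np.ndarray, rng: np.random.Generator, strength: float = 0.10):
    # multiplicative speckle, the dominant noise of B-mode imaging; smoothed
    # slightly so the grain spans more than one pixel, as physical speckle does
    from scipy import ndimage as _ndi

    field = rng.rayleigh(scale=1.0, size=img.shape) - np.sqrt(np.pi / 2)
    field = _ndi.gaussian_filter(field, sigma=0.8)
    mult = 1.0 + strength * field / max(field.std(), 1e-9) * np.sqrt(np.pi / 2 - 1)
    return img * np.clip(mult, 0.2, 2.0)


def _apply_source_texture(img: np.ndarray, source_tag: str, rng: np.random.Generator):
    side = img.shape[0]
    out = img.copy()
    if source_tag == "SRC_A":
        # clean-repository look: fine additive speckle + smooth vignette
        out += 0.03 * rng.standard_normal(img.shape)
        yy, xx = _coord_grid(side)
        out *= 1.0 - 0.08 * (yy**2 + xx**2)
    else:
        # video-scrape look: banding, blocky compression noise, brightness lift
        rows = np.arange(side)
        out += 0.06 * np.sin(2 * np.pi * rows / 4.0 + rng.uniform(0, 2 * np.pi))[:, None]
        nb = max(side // 8, 1)
        blocks = rng.uniform(-0.04, 0.04, size=(nb + 1, nb + 1))
        out += np.kron(blocks, np.ones((8, 8)))[:side, :side]
        out += 0.04
    return np.clip(out, 0.0, 1.0)


def render_phantom(body_part: str, condition: str, source_tag: str, side: int = 224,
                   seed: int = 0, texture_seed: int | None = None) -> np.ndarray:
    """Render one phantom. ``seed`` fixes the geometry and speckle;
    ``texture_seed`` (default: derived from seed) fixes the source texture, so
    the same geometry can be rendered under either tag."""
    if side < 32:
        raise ValueError("side must be >= 32")
    rng = np.random.default_rng(seed)
    img = _render_anatomy(body_part, side, rng)
    if condition == "abnormal":
        img = _add_lesion(img, rng)
    img = _speckle(img, rng)
    trng = np.random.default_rng(seed + 1 if texture_seed is None else texture_seed)
    return _apply_source_texture(np.clip(img, 0, 1), source_tag, trng)


def generate_image_dataset(n_normal: int, n_abnormal: int, seed: int = 0,
                           side: int = 224, source_mixing: float = 0.0,
                           swap_sources: bool = False) -> list[PhantomImage]:
    """Generate ``n_normal + n_abnormal`` labelled phantoms.

    Body parts cycle uniformly over brain/thorax/abdomen. By default normal
    images are tagged SRC_A and abnormal SRC_B (the confounded regime);
    ``source_mixing`` gives the fraction of images per condition whose tag is
    flipped, and ``swap_sources`` reverses the base mapping (for building
    tag-swapped evaluation sets). Deterministic under ``seed``.
    """
    if n_normal < 0 or n_abnormal < 0:
        raise ValueError("counts must be non-negative")
    if side < 32:
        raise ValueError("side must be >= 32")
    if not 0.0 <= source_mixing <= 1.0:
        raise ValueError("source_mixing must be in [0, 1]")
    rng = np.random.default_rng(seed)
    images = []
    idx = 0
    for condition, n in (("normal", n_normal), ("abnormal", n_abnormal)):
        base = "SRC_A" if condition == "normal" else "SRC_B"
        if swap_sources:
            base = "SRC_B" if base == "SRC_A" else "SRC_A"
        other = "SRC_B" if base == "SRC_A" else "SRC_A"
        n_flip = int(round(source_mixing * n))
        flip = np.zeros(n, dtype=bool)
        if n_flip:
            flip[rng.choice(n, size=n_flip, replace=False)] = True
        parts = np.array([BODY_PARTS[i % 3] for i in range(n)])
        rng.shuffle(parts)
        for j in range(n):
            tag = other if flip[j] else base
            img_seed = int(rng.integers(0, 2**31 - 1))
            px = render_phantom(parts[j], condition, tag, side=side, seed=img_seed)
            images.append(PhantomImage(px, parts[j], condition, tag, f"ph{idx:05d}"))
            idx += 1
    return images


def images_to_manifest(images: list[PhantomImage]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [im.id for im in images],
            "body_part": [im.body_part for im in images],
            "condition": [im.condition for im in images],
            "source_tag": [im.source_tag for im in images],
        }
    )


def write_image_dataset(images: list[PhantomImage], out_dir: str) -> str:
    """Write 8-bit grayscale PNGs plus a manifest CSV; returns manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for im in images:
        path = os.path.join(out_dir, f"{im.id}.png")
        Image.fromarray((im.pixels * 255).round().astype(np.uint8), mode="L").save(path)
        rows.append((im.id, path, im.body_part, im.condition, im.source_tag))
    manifest = pd.DataFrame(rows, columns=["id", "path", "body_part", "condition", "source_tag"])
    mpath = os.path.join(out_dir, "manifest.csv")
    manifest.to_csv(mpath, index=False)
    return mpath


def generate_tabular_dataset(n_per_class: list[int], p: int = 6, n_categorical: int = 0,
                             class_separation: float = 1.0, seed: int = 0,
                             n_levels: int = 3) -> TabularDataset:
    """Gaussian class-conditional numeric features plus class-dependent
    multinomial categorical columns.

    Numeric column means are offset by ``class_separation`` per class step
    (unit within-class standard deviation), so separation 0 gives chance-level
    classes. Categorical level probabilities tilt toward a class-specific
    level with the same strength.
    """
    n_per_class = list(n_per_class)
    if len(n_per_class) not in (2, 3):
        raise ValueError("need 2 or 3 classes")
    if any(n < 2 for n in n_per_class):
        raise ValueError("every class needs at least 2 samples")
    if not 0 <= n_categorical <= p:
        raise ValueError("need p >= n_categorical >= 0")
    rng = np.random.default_rng(seed)
    p_num = p - n_categorical
    feats, labels = [], []
    for c, n in enumerate(n_per_class):
        x_num = rng.standard_normal((n, p_num)) + class_separation * c
        cols = [x_num]
        if n_categorical:
            probs = np.ones(n_levels) + class_separation * np.eye(n_levels)[c % n_levels]
            probs /= probs.sum()
            x_cat = rng.choice(n_levels, size=(n, n_categorical), p=probs)
            cols.append(x_cat.astype(float))
        feats.append(np.hstack(cols))
        labels.append(np.full(n, c))
    mask = np.zeros(p, dtype=bool)
    mask[p_num:] = True
    return TabularDataset(np.vstack(feats), mask, np.concatenate(labels))


def write_tabular_dataset(data: TabularDataset, path: str) -> None:
    """CSV with header; categorical columns emitted as level strings."""
    cols = {}
    for j in range(data.features.shape[1]):
        if data.categorical_mask[j]:
            cols[f"cat{j}"] = [f"L{int(v)}" for v in data.features[:, j]]
        else:
            cols[f"num{j}"] = data.features[:, j]
    cols["label"] = data.labels
    pd.DataFrame(cols).to_csv(path, index=False)
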