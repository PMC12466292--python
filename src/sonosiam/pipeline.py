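"""Training/evaluation driver: phantoms -> preprocessing -> curriculum pairs
-> shared-weight Siamese training with the hybrid loss -> metrics -> PTQ.

The training loop is pair-based: each step pushes both members of a batch of
pairs through the *same* encoder object, applies the contrastive loss to the
embedding distances and the two cross-entropy heads to every image of the
pair, combines them with the multi-task weights, and takes one Adam step on
the summed gradients of both branches (the weight-sharing contract).
Augmentation touches abnormal images only and only inside the training
partition; evaluation always uses the classification heads, not distance
thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .curriculum import (CurriculumStage, sample_pairs, sample_random_pairs,
                         stage_schedule)
from .losses import (LossWeights, contrastive_loss, contrastive_loss_grad,
                     cross_entropy, multitask_loss)
from .model import BackboneSpec, SiameseNetwork
from .phantom import BODY_PARTS, CONDITIONS, PhantomImage, generate_image_dataset, images_to_manifest
from .preprocessing import AugmentationConfig, _augment_pixels, preprocess_image

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "train_siamese",
    "evaluate_model",
    "metrics_from_confusion",
    "SiameseNetworkClassifier",
    "anti_leakage_experiment",
]


@dataclass
class ConfusionMatrix:
    """Rows = actual, columns = predicted."""

    counts: np.ndarray
    labels: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.labels)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be C x C for C labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels) -> "ConfusionMatrix":
        idx = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[idx[t], idx[p]] += 1
        return cls(counts, list(labels))


@dataclass
class MetricsReport:
    accuracy: float
    precision: dict
    recall: dict
    f1: dict
    macro_precision: float
    macro_recall: float
    macro_f1: float
    fold_index: int | None = None
    model_precision: str = "fp32"

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "fold_index": self.fold_index,
            "model_precision": self.model_precision,
        }


def metrics_from_confusion(cm: ConfusionMatrix, fold_index: int | None = None,
                           model_precision: str = "fp32") -> MetricsReport:
    """Accuracy = trace/total; per-class precision/recall/F1 plus macro means."""
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(counts) / total)
    precision, recall, f1 = {}, {}, {}
    for i, lab in enumerate(cm.labels):
        tp = counts[i, i]
        p = tp / counts[:, i].sum() if counts[:, i].sum() else 0.0
        r = tp / counts[i, :].sum() if counts[i, :].sum() else 0.0
        precision[lab] = float(p)
        recall[lab] = float(r)
        f1[lab] = float(2 * p * r / (p + r)) if (p + r) else 0.0
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=float(np.mean(list(precision.values()))),
        macro_recall=float(np.mean(list(recall.values()))),
        macro_f1=float(np.mean(list(f1.values()))),
        fold_index=fold_index,
        model_precision=model_precision,
    )


# ---------------------------------------------------------------------------
# Training


def _standardize_stack(images: list[PhantomImage], side: int,
                       augment: bool, cfg: AugmentationConfig,
                       rng: np.random.Generator) -> np.ndarray:
    out = np.empty((len(images), side, side), dtype=nn.DTYPE)
    for i, im in enumerate(images):
        px = im.pixels
        if augment and im.condition == "abnormal":
            px = _augment_pixels(px, cfg, rng)
        out[i] = preprocess_image(px, side=side)
    return out


def train_siamese(images: list[PhantomImage], spec: BackboneSpec | None = None,
                  weights: LossWeights | None = None, epochs: int = 15,
                  pairs_per_epoch: int = 200, batch_pairs: int = 32,
                  lr: float = 1e-3, boundaries: tuple = (1 / 3, 2 / 3),
                  curriculum: bool = True, augment: bool = True,
                  augmentation: AugmentationConfig | None = None,
                  seed: int = 0):
    """Train the shared-weight Siamese network on labelled phantoms.

    Returns ``(model, log)`` where ``log`` is a list of per-epoch dicts with
    the stage and the mean loss components. Raises on divergence.
    """
    if spec is None:
        spec = BackboneSpec.small(images[0].pixels.shape[0])
    if weights is None:
        weights = LossWeights()
    if augmentation is None:
        augmentation = AugmentationConfig(seed=seed)
    manifest = images_to_manifest(images)
    if manifest["condition"].nunique() < 2:
        raise ValueError("training set must contain both conditions")
    cond_idx = np.array([CONDITIONS.index(im.condition) for im in images])
    body_idx = np.array([BODY_PARTS.index(im.body_part) for im in images])
    id_pos = {im.id: i for i, im in enumerate(images)}

    model = SiameseNetwork(spec, seed=seed)
    params = model.params()
    opt = nn.Adam(params, lr=lr)
    rng = np.random.default_rng(seed + 1)
    base_std = _standardize_stack(images, spec.input_side, False, augmentation, rng)
    log = []
    for epoch in range(epochs):
        if curriculum:
            stage = stage_schedule(epoch, epochs, boundaries)
            # cross-source pairing is meaningless on single-source data
            if (stage == CurriculumStage.MEDIUM
                    and manifest["source_tag"].nunique() < 2):
                stage = CurriculumStage.EASY
            pairs = sample_pairs(manifest, stage, pairs_per_epoch,
                                 seed=seed * 100003 + epoch)
            stage_name = stage.name
        else:
            pairs = sample_random_pairs(manifest, pairs_per_epoch,
                                        seed=seed * 100003 + epoch)
            stage_name = "RANDOM"
        if augment:
            x_std = _standardize_stack(images, spec.input_side, True,
                                       augmentation, rng)
            x_std[cond_idx == 0] = base_std[cond_idx == 0]
        else:
            x_std = base_std
        ep_losses = np.zeros(4)
        n_batches = 0
        for start in range(0, len(pairs), batch_pairs):
            chunk = pairs[start : start + batch_pairs]
            ia = np.array([id_pos[p.id_a] for p in chunk])
            ib = np.array([id_pos[p.id_b] for p in chunk])
            y = np.array([p.y for p in chunk], dtype=float)
            xa = x_std[ia][:, None]
            xb = x_std[ib][:, None]
            ea, ca = model.forward_embed(xa, train=True, rng=rng)
            eb, cb = model.forward_embed(xb, train=True, rng=rng)
            diff = ea - eb
            d = np.sqrt((diff**2).sum(axis=1) + 1e-12)
            l_con = contrastive_loss(d, y, weights.margin)
            dL_dd = contrastive_loss_grad(d, y, weights.margin)
            dea = (dL_dd / d)[:, None] * diff
            # heads act on every image of the pair
            emb_all = np.concatenate([ea, eb], axis=0)
            labels_c = np.concatenate([cond_idx[ia], cond_idx[ib]])
            labels_b = np.concatenate([body_idx[ia], body_idx[ib]])
            heads, hcache = model.forward_heads(emb_all)
            l_abn, d_abn = cross_entropy(heads.abnormality_logits, labels_c)
            l_body, d_body = cross_entropy(heads.body_part_logits, labels_b)
            total = multitask_loss(l_con, l_abn, l_body, weights)
            if not np.isfinite(total):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss components "
                    f"({l_con}, {l_abn}, {l_body})"
                )
            demb_heads, hgrads = model.backward_heads(
                weights.w_abnormal * d_abn, weights.w_body * d_body, hcache
            )
            n = len(chunk)
            ga = model.backward_embed(
                weights.w_contrastive * dea + demb_heads[:n], ca
            )
            gb = model.backward_embed(
                -weights.w_contrastive * dea + demb_heads[n:], cb
            )
            grads = {k: ga[k] + gb[k] for k in ga}
            grads.update(hgrads)
            opt.step(grads)
            ep_losses += (total, l_con, l_abn, l_body)
            n_batches += 1
        ep_losses /= max(n_batches, 1)
        log.append(
            {
                "epoch": epoch,
                "stage": stage_name,
                "loss_total": float(ep_losses[0]),
                "loss_contrastive": float(ep_losses[1]),
                "loss_abnormal": float(ep_losses[2]),
                "loss_body": float(ep_losses[3]),
                "augmented_partition": "train" if augment else None,
            }
        )
    return model, log


def evaluate_model(model, images: list[PhantomImage], batch: int = 64,
                   fold_index: int | None = None, model_precision: str = "fp32"):
    """Head-based evaluation on labelled phantoms.

    ``model`` needs a ``predict(x_std) -> (condition_idx, body_part_idx)``
    method (both the FP32 network and the quantized model provide it).
    Returns (condition ConfusionMatrix, MetricsReport, body-part
    ConfusionMatrix).
    """
    if not images:
        raise ValueError("empty evaluation subset")
    side = getattr(getattr(model, "spec", None), "input_side", None)
    if side is None:
        side = getattr(model, "input_side", None) or images[0].pixels.shape[0]
    preds_c, preds_b = [], []
    for start in range(0, len(images), batch):
        chunk = images[start : start + batch]
        x = np.stack([preprocess_image(im.pixels, side=side) for im in chunk])
        pc, pb = model.predict(x)
        preds_c.append(pc)
        preds_b.append(pb)
    preds_c = np.concatenate(preds_c)
    preds_b = np.concatenate(preds_b)
    true_c = [im.condition for im in images]
    true_b = [im.body_part for im in images]
    cm_cond = ConfusionMatrix.from_predictions(
        true_c, [CONDITIONS[i] for i in preds_c], list(CONDITIONS)
    )
    cm_body = ConfusionMatrix.from_predictions(
        true_b, [BODY_PARTS[i] for i in preds_b], list(BODY_PARTS)
    )
    report = metrics_from_confusion(cm_cond, fold_index, model_precision)
    return cm_cond, report, cm_body


class SiameseNetworkClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn style front end to the Siamese training pipeline.

    ``X`` is an (n, side, side) stack of raw [0,1] grayscale images; ``y``
    gives the condition as 'normal'/'abnormal' strings (or 0/1 with
    1 = abnormal). Body part and source tags are optional fit keywords; when
    ``body_part`` is absent the anatomical head is disabled (weight 0).
    """

    def __init__(self, spec: BackboneSpec | None = None,
                 loss_weights: LossWeights | None = None, epochs: int = 15,
                 pairs_per_epoch: int = 200, batch_pairs: int = 32,
                 lr: float = 1e-3, boundaries: tuple = (1 / 3, 2 / 3),
                 curriculum: bool = True, augment: bool = True,
                 random_state: int = 0):
        self.spec = spec
        self.loss_weights = loss_weights
        self.epochs = epochs
        self.pairs_per_epoch = pairs_per_epoch
        self.batch_pairs = batch_pairs
        self.lr = lr
        self.boundaries = boundaries
        self.curriculum = curriculum
        self.augment = augment
        self.random_state = random_state

    def _as_condition(self, y):
        y = np.asarray(y)
        if y.dtype.kind in "US":
            bad = set(np.unique(y)) - set(CONDITIONS)
            if bad:
                raise ValueError(f"unknown condition labels: {sorted(bad)}")
            return y, np.array(CONDITIONS, dtype=object)
        y = y.astype(int)
        if not np.isin(y, (0, 1)).all():
            raise ValueError("numeric labels must be 0 (normal) or 1 (abnormal)")
        return np.array(CONDITIONS, dtype=object)[y], np.array([0, 1])

    def fit(self, X, y, body_part=None, source_tag=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be an (n, side, side) image stack")
        cond, self.classes_ = self._as_condition(y)
        n = len(X)
        parts = np.asarray(body_part) if body_part is not None else np.full(n, "brain")
        tags = np.asarray(source_tag) if source_tag is not None else np.full(n, "SRC_A")
        images = [
            PhantomImage(np.clip(X[i], 0, 1), parts[i], cond[i], tags[i], f"x{i:06d}")
            for i in range(n)
        ]
        weights = self.loss_weights if self.loss_weights is not None else LossWeights()
        if body_part is None:
            weights = LossWeights(weights.margin, weights.w_contrastive,
                                  weights.w_abnormal, 0.0)
        self.model_, self.history_ = train_siamese(
            images,
            spec=self.spec,
            weights=weights,
            epochs=self.epochs,
            pairs_per_epoch=self.pairs_per_epoch,
            batch_pairs=self.batch_pairs,
            lr=self.lr,
            boundaries=self.boundaries,
            curriculum=self.curriculum,
            augment=self.augment,
            seed=self.random_state,
        )
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")

    def predict(self, X):
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        side = self.model_.spec.input_side
        x = np.stack([preprocess_image(img, side=side) for img in X])
        idx, _ = self.model_.predict(x)
        return self.classes_[idx]

    def embed(self, X):
        """Eval-mode embeddings for raw [0,1] images."""
        self._check_fitted()
        side = self.model_.spec.input_side
        x = np.stack([preprocess_image(img, side=side) for img in np.asarray(X, dtype=float)])
        return self.model_.embed_images(x)


# ---------------------------------------------------------------------------
# Curriculum anti-leakage experiment


def anti_leakage_experiment(seeds=(0, 1, 2), n_normal: int = 90,
                            n_abnormal: int = 90, side: int = 32,
                            source_mixing: float = 0.20, epochs: int = 15,
                            pairs_per_epoch: int = 200,
                            n_test: int = 60) -> pd.DataFrame:
    """Curriculum vs naive random pairing on source-confounded phantoms,
    scored on tag-swapped test phantoms.

    Training data is 80% confounded (normal=SRC_A, abnormal=SRC_B); the 20%
    tag-mixing fraction populates the cross-source strata that the MEDIUM
    stage pairs from (the real-data analogue is the handful of cross-source
    same-class frames the mid-training stage relies on). The test set has the
    tags fully *swapped*, so any model leaning on source texture instead of
    the lesion is penalized. Training length matches the package's standard
    desk-scale run (15 epochs, 200 pairs/epoch). Returns one row per seed
    with both accuracies.
    """
    rows = []
    for s in seeds:
        train = generate_image_dataset(n_normal, n_abnormal, seed=1000 + s,
                                       side=side, source_mixing=source_mixing)
        test = generate_image_dataset(n_test // 2, n_test - n_test // 2,
                                      seed=5000 + s, side=side,
                                      swap_sources=True)
        accs = {}
        for label, use_curriculum in (("curriculum", True), ("naive", False)):
            model, _ = train_siamese(
                train,
                spec=BackboneSpec.small(side),
                epochs=epochs,
                pairs_per_epoch=pairs_per_epoch,
                curriculum=use_curriculum,
                augment=False,
                seed=s,
            )
            _, report, _ = evaluate_model(model, test)
            accs[label] = report.accuracy
        rows.append({"seed": s, "curriculum_accuracy": accs["curriculum"],
                     "naive_accuracy": accs["naive"]})
    return pd.DataFrame(rows)
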