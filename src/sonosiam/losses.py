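"""Pure loss functions: margin contrastive loss, the weighted multi-task
objective, softmax cross-entropy, and a composite distillation utility.

Label convention for pairs follows the contrastive-loss formulation of
Hadsell-style metric learning: y = 1 marks a *similar* pair (the d^2 term
pulls its embeddings together), y = 0 a *dissimilar* pair (the squared hinge
max(m - d, 0)^2 pushes them at least a margin m apart).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossWeights",
    "PairBatchDistances",
    "contrastive_loss",
    "contrastive_loss_grad",
    "multitask_loss",
    "distillation_loss",
    "softmax",
    "cross_entropy",
]


@dataclass
class LossWeights:
    """Margin and task weights of the hybrid objective.

    Defaults are the headline weighting (contrastive 1.0, abnormality 2.0 for
    clinical priority, body part 0.5 as a regularizer); ``lambda_variant``
    gives the alternative normalized preset (0.6, 0.3, 0.1).
    """

    margin: float = 1.0
    w_contrastive: float = 1.0
    w_abnormal: float = 2.0
    w_body: float = 0.5

    def __post_init__(self):
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        if min(self.w_contrastive, self.w_abnormal, self.w_body) < 0:
            raise ValueError("task weights must be >= 0")

    @classmethod
    def lambda_variant(cls) -> "LossWeights":
        return cls(margin=1.0, w_contrastive=0.6, w_abnormal=0.3, w_body=0.1)


@dataclass
class PairBatchDistances:
    d: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        self.y = np.asarray(self.y)
        if self.d.size == 0:
            raise ValueError("empty pair batch")
        if self.d.shape != self.y.shape:
            raise ValueError("d and y must have the same length")
        if not np.isfinite(self.d).all() or (self.d < 0).any():
            raise ValueError("distances must be finite and non-negative")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("similarity labels must be binary")


def contrastive_loss(d, y=None, m: float = 1.0) -> float:
    """(1/N) sum_i [ y_i d_i^2 + (1 - y_i) max(m - d_i, 0)^2 ].

    Accepts a :class:`PairBatchDistances` or separate (d, y) arrays. Zero iff
    every similar pair is coincident and every dissimilar pair is at least the
    margin apart.
    """
    batch = d if isinstance(d, PairBatchDistances) else PairBatchDistances(d, y)
    if m <= 0:
        raise ValueError("margin must be > 0")
    dd, yy = batch.d, batch.y.astype(float)
    hinge = np.maximum(m - dd, 0.0)
    return float(np.mean(yy * dd**2 + (1.0 - yy) * hinge**2))


def contrastive_loss_grad(d, y, m: float = 1.0) -> np.ndarray:
    """dL/dd_i for the mean contrastive loss."""
    batch = PairBatchDistances(d, y)
    dd, yy = batch.d, batch.y.astype(float)
    n = dd.size
    return (2.0 * yy * dd - 2.0 * (1.0 - yy) * np.maximum(m - dd, 0.0)) / n


def multitask_loss(l_contrastive: float, l_ce_abnormal: float, l_ce_body: float,
                   w: LossWeights | None = None) -> float:
    """w_c * L_contrastive + w_a * L_CE(abnormal) + w_b * L_CE(body part)."""
    if w is None:
        w = LossWeights()
    comps = (l_contrastive, l_ce_abnormal, l_ce_body)
    if any(not np.isfinite(c) or c < 0 for c in comps):
        raise ValueError("loss components must be finite and non-negative")
    return (
        w.w_contrastive * l_contrastive
        + w.w_abnormal * l_ce_abnormal
        + w.w_body * l_ce_body
    )


def distillation_loss(l_ce: float, l_kl: float, l_mse: float,
                      weights: tuple = (0.5, 0.3, 0.2)) -> float:
    """Composite teacher-student objective 0.5*CE + 0.3*KL + 0.2*MSE.

    The three scalars are supplied by the caller: cross-entropy of student
    predictions against teacher soft labels, KL divergence between output
    distributions, and MSE between intermediate embeddings.
    """
    comps = (l_ce, l_kl, l_mse)
    if any(not np.isfinite(c) or c < 0 for c in comps):
        raise ValueError("loss components must be finite and non-negative")
    return float(np.dot(weights, comps))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray,
                  class_weights: np.ndarray | None = None):
    """Mean softmax cross-entropy; returns (loss, dloss/dlogits).

    ``class_weights`` optionally reweights per-sample terms by true class
    (normalized so the loss stays a weighted mean).
    """
    logits = np.atleast_2d(np.asarray(logits, dtype=float))
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    per = -np.log(p[np.arange(n), labels] + eps)
    onehot = np.zeros_like(p)
    onehot[np.arange(n), labels] = 1.0
    if class_weights is not None:
        wvec = np.asarray(class_weights, dtype=float)[labels]
        wsum = wvec.sum()
        loss = float((per * wvec).sum() / wsum)
        dlogits = (p - onehot) * (wvec / wsum)[:, None]
    else:
        loss = float(per.mean())
        dlogits = (p - onehot) / n
    return loss, dlogits
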