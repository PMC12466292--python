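"""Shared-weight convolutional encoder, classification heads, and exact
parameter/size accounting.

The reference backbone is three conv blocks (64@5x5, 128@5x5, 256@3x3, each
Conv -> ReLU -> 2x2 max-pool -> dropout at 0.2/0.3/0.4), which takes a
224x224x1 standardized image to a 256x28x28 feature map, then a dense stack
200704 -> 512 -> 256 -> 128 producing the embedding. Two affine heads read the
embedding: abnormality (2 logits) and body part (3 logits). The dominant cost
is the flatten->512 matrix (~103M of the ~103.4M total parameters), which is
what puts the FP32 footprint at ~414 MB.

Smaller variants (``BackboneSpec.small``) keep the same block grammar at a
size trainable on CPU in minutes; they are the workhorse for end-to-end runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "BackboneSpec",
    "HeadOutputs",
    "SiameseNetwork",
    "embed",
    "predict_heads",
    "count_parameters",
    "model_size_bytes",
]

N_CONDITIONS = 2
N_BODY_PARTS = 3


@dataclass
class BackboneSpec:
    """Architecture description; all sizes derive analytically from it."""

    conv_blocks: list = field(
        default_factory=lambda: [(64, 5, 0.2), (128, 5, 0.3), (256, 3, 0.4)]
    )
    dense_dims: list = field(default_factory=lambda: [512, 256, 128])
    input_side: int = 224
    input_channels: int = 1

    @classmethod
    def small(cls, input_side: int = 32) -> "BackboneSpec":
        """CPU-scale variant: two conv blocks, 32-d embedding."""
        return cls(
            conv_blocks=[(8, 5, 0.0), (16, 3, 0.0)],
            dense_dims=[64, 32],
            input_side=input_side,
        )

    @property
    def embedding_dim(self) -> int:
        if not self.dense_dims:
            raise ValueError("spec has no dense stack, hence no embedding")
        return self.dense_dims[-1]

    def conv_output_shape(self) -> tuple[int, int, int]:
        """(channels, side, side) of the final conv feature map."""
        side = self.input_side
        ch = self.input_channels
        for out_ch, _, _ in self.conv_blocks:
            if side % 2:
                raise ValueError(f"side {side} not divisible by 2 at pooling")
            side //= 2
            ch = out_ch
        return ch, side, side

    def flatten_dim(self) -> int:
        ch, s, _ = self.conv_output_shape()
        return ch * s * s


@dataclass
class HeadOutputs:
    abnormality_logits: np.ndarray
    body_part_logits: np.ndarray

    def __post_init__(self):
        self.abnormality_logits = np.asarray(self.abnormality_logits)
        self.body_part_logits = np.asarray(self.body_part_logits)
        if self.abnormality_logits.shape[-1] != N_CONDITIONS:
            raise ValueError("abnormality head must emit 2 logits")
        if self.body_part_logits.shape[-1] != N_BODY_PARTS:
            raise ValueError("body-part head must emit 3 logits")
        if not (
            np.isfinite(self.abnormality_logits).all()
            and np.isfinite(self.body_part_logits).all()
        ):
            raise ValueError("non-finite logits")


def count_parameters(spec: BackboneSpec, include_heads: bool = True) -> int:
    """Closed-form trainable parameter count (weights + biases)."""
    total = 0
    ch = spec.input_channels
    for out_ch, k, _ in spec.conv_blocks:
        total += out_ch * ch * k * k + out_ch
        ch = out_ch
    if spec.dense_dims:
        d_in = spec.flatten_dim()
        for d_out in spec.dense_dims:
            total += d_in * d_out + d_out
            d_in = d_out
        if include_heads:
            emb = spec.embedding_dim
            total += emb * N_CONDITIONS + N_CONDITIONS
            total += emb * N_BODY_PARTS + N_BODY_PARTS
    return total


def model_size_bytes(spec: BackboneSpec, precision: str = "fp32") -> int:
    """On-disk payload: 4 bytes/parameter at FP32; at INT8, 1 byte per weight,
    int32 biases, plus per-channel weight scales and per-tensor activation
    scale/zero-point metadata (float32/int32 each)."""
    if precision == "fp32":
        return 4 * count_parameters(spec)
    if precision != "int8":
        raise ValueError("precision must be 'fp32' or 'int8'")
    weight_bytes = 0
    bias_bytes = 0
    meta_bytes = 0
    ch = spec.input_channels
    layers = []  # (n_weights, out_channels)
    for out_ch, k, _ in spec.conv_blocks:
        layers.append((out_ch * ch * k * k, out_ch))
        ch = out_ch
    if spec.dense_dims:
        d_in = spec.flatten_dim()
        for d_out in spec.dense_dims:
            layers.append((d_in * d_out, d_out))
            d_in = d_out
        emb = spec.embedding_dim
        layers.append((emb * N_CONDITIONS, N_CONDITIONS))
        layers.append((emb * N_BODY_PARTS, N_BODY_PARTS))
    for n_w, out_ch in layers:
        weight_bytes += n_w  # int8
        bias_bytes += 4 * out_ch  # int32
        meta_bytes += 4 * out_ch  # per-channel scales
        meta_bytes += 8  # activation scale + zero-point
    return weight_bytes + bias_bytes + meta_bytes


class SiameseNetwork:
    """Shared-weight encoder with abnormality and body-part heads.

    There is exactly one parameter store: both members of a pair are pushed
    through the same layer objects, which is the weight-sharing contract of a
    Siamese architecture.
    """

    def __init__(self, spec: BackboneSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        conv_layers = []
        ch = spec.input_channels
        for out_ch, k, drop in spec.conv_blocks:
            conv_layers.append(nn.Conv2d(ch, out_ch, k, rng))
            conv_layers.append(nn.ReLU())
            conv_layers.append(nn.MaxPool2())
            if drop > 0:
                conv_layers.append(nn.Dropout(drop))
            ch = out_ch
        self.conv_net = nn.Sequential(conv_layers)
        dense_layers = [nn.Flatten()]
        d_in = spec.flatten_dim()
        for i, d_out in enumerate(spec.dense_dims):
            dense_layers.append(nn.Dense(d_in, d_out, rng))
            if i < len(spec.dense_dims) - 1:
                dense_layers.append(nn.ReLU())
            d_in = d_out
        self.dense_net = nn.Sequential(dense_layers)
        emb = spec.embedding_dim
        self.head_abnormal = nn.Dense(emb, N_CONDITIONS, rng)
        self.head_body = nn.Dense(emb, N_BODY_PARTS, rng)

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> dict:
        out = {}
        for prefix, part in (
            ("conv", self.conv_net),
            ("dense", self.dense_net),
            ("abn", self.head_abnormal),
            ("body", self.head_body),
        ):
            for name, p in part.params().items():
                out[f"{prefix}.{name}"] = p
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params().values())

    def save(self, path: str) -> None:
        nn.save_params(path, self.params())

    def load(self, path: str) -> None:
        nn.load_params(path, self.params())

    # -- forward passes -----------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.shape[2] != self.spec.input_side or x.shape[3] != self.spec.input_side:
            raise ValueError(
                f"input side {x.shape[2]}x{x.shape[3]} does not match "
                f"spec input_side={self.spec.input_side}"
            )
        return x

    def forward_embed(self, x: np.ndarray, train: bool = False,
                      rng: np.random.Generator | None = None):
        """Returns (embeddings, caches); caches feed backward_embed."""
        x = self._check_input(x)
        fmap, c1 = self.conv_net.forward(x, train=train, rng=rng)
        emb, c2 = self.dense_net.forward(fmap, train=train, rng=rng)
        return emb, (c1, c2)

    def backward_embed(self, demb: np.ndarray, caches) -> dict:
        c1, c2 = caches
        dflat, g2 = self.dense_net.backward(demb, c2)
        _, g1 = self.conv_net.backward(dflat, c1)
        grads = {f"conv.{k}": v for k, v in g1.items()}
        grads.update({f"dense.{k}": v for k, v in g2.items()})
        return grads

    def embed_images(self, x: np.ndarray) -> np.ndarray:
        """Eval-mode embeddings (dropout off, deterministic)."""
        emb, _ = self.forward_embed(x, train=False)
        return emb

    def conv_features(self, x: np.ndarray) -> np.ndarray:
        x = self._check_input(x)
        fmap, _ = self.conv_net.forward(x, train=False)
        return fmap

    def forward_heads(self, emb: np.ndarray):
        la, ca = self.head_abnormal.forward(emb)
        lb, cb = self.head_body.forward(emb)
        return HeadOutputs(la, lb), (ca, cb)

    def backward_heads(self, d_abn, d_body, caches):
        ca, cb = caches
        demb_a, ga = self.head_abnormal.backward(d_abn, ca)
        demb_b, gb = self.head_body.backward(d_body, cb)
        grads = {f"abn.{k}": v for k, v in ga.items()}
        grads.update({f"body.{k}": v for k, v in gb.items()})
        return demb_a + demb_b, grads

    def predict(self, x: np.ndarray):
        """Eval-mode head argmaxes: (condition_idx, body_part_idx) arrays."""
        emb = self.embed_images(x)
        heads, _ = self.forward_heads(emb)
        return (
            heads.abnormality_logits.argmax(axis=-1),
            heads.body_part_logits.argmax(axis=-1),
        )


def embed(img: np.ndarray, model: SiameseNetwork, mode: str = "eval",
          rng: np.random.Generator | None = None) -> np.ndarray:
    """Embedding(s) for standardized input(s); dropout active in train mode."""
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    e, _ = model.forward_embed(img, train=(mode == "train"), rng=rng)
    return e


def predict_heads(e: np.ndarray, model: SiameseNetwork) -> HeadOutputs:
    e = np.asarray(e)
    if not np.isfinite(e).all():
        raise ValueError("non-finite embedding")
    out, _ = model.forward_heads(np.atleast_2d(e))
    return out
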