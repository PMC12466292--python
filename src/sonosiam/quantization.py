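"""From-scratch post-training INT8 quantization (PTQ).

The engine converts a trained FP32 network into integer arithmetic using only
calibration data: batch-norm layers are folded into the preceding conv/linear,
pass-through observers collect activation statistics (min-max, percentile, or
KL-optimal histogram clipping), weights get symmetric per-channel INT8 scales
(zero-point 0, scale max|W_k|/127), activations get per-tensor affine params
on an unsigned [0,255] grid after ReLU and a signed [-128,127] grid elsewhere,
biases are stored as int32 with scale s_W*s_x, accumulation runs in int32, and
layer outputs are requantized with the combined multiplier s_W*s_x/s_y.

Rounding is half-away-from-zero everywhere a ``round`` appears, for both the
kernels and the oracles. The requantization multiplier is applied in floating
point, so cross-platform bit-exactness holds at floating-point tolerance.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from . import nn
from .model import SiameseNetwork

__all__ = [
    "QuantParams",
    "QuantizedTensor",
    "BatchNormParams",
    "CalibrationConfig",
    "Observer",
    "round_half_away",
    "affine_qparams",
    "symmetric_channel_qparams",
    "quantize_tensor",
    "dequantize",
    "fold_batchnorm",
    "fuse_conv_bn",
    "calibrate_activations",
    "quantized_forward",
    "quantize_model",
    "QuantizedModel",
    "PostTrainingQuantizer",
]

SIGNED = (-128, 127)
UNSIGNED = (0, 255)


def round_half_away(x):
    """Round to nearest, ties away from zero (fixed convention for all kernels)."""
    x = np.asarray(x)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class QuantParams:
    scale: float | np.ndarray
    zero_point: int | np.ndarray
    q_min: int
    q_max: int
    scheme: str = "affine_per_tensor"  # or "symmetric_per_channel"
    channel_axis: int | None = None

    def __post_init__(self):
        s = np.asarray(self.scale, dtype=float)
        if (s <= 0).any():
            raise ValueError("scale must be positive")
        if self.scheme == "symmetric_per_channel":
            if np.any(np.asarray(self.zero_point) != 0):
                raise ValueError("symmetric scheme requires zero_point = 0")
        else:
            z = np.asarray(self.zero_point)
            if (z < self.q_min).any() or (z > self.q_max).any():
                raise ValueError("zero_point outside the integer grid")

    def _bcast(self, ndim: int):
        """Scale/zero-point shaped for broadcasting against an ndim array."""
        s = np.asarray(self.scale, dtype=float)
        z = np.asarray(self.zero_point, dtype=float)
        if self.channel_axis is not None and s.ndim == 1:
            shape = [1] * ndim
            shape[self.channel_axis] = -1
            s = s.reshape(shape)
            z = np.broadcast_to(z, s.shape) if z.ndim else z
        return s, z


@dataclass
class QuantizedTensor:
    q: np.ndarray
    params: QuantParams

    def __post_init__(self):
        q = np.asarray(self.q)
        if q.min() < self.params.q_min or q.max() > self.params.q_max:
            raise ValueError("quantized values outside the grid")
        self.q = q


@dataclass
class BatchNormParams:
    gamma: np.ndarray
    beta: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    eps: float = 1e-5

    def __post_init__(self):
        for name in ("gamma", "beta", "mean", "var"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if (self.var < 0).any():
            raise ValueError("variance must be non-negative")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


def affine_qparams(r_min: float, r_max: float, grid: tuple = UNSIGNED) -> QuantParams:
    """Per-tensor affine params: s = (r_max-r_min)/(q_max-q_min),
    z = round(q_min - r_min/s), clipped into the grid.

    The range is first extended to include zero so that the zero-point always
    lands inside the grid and real zero is exactly representable — the
    convention of every production affine-quantization scheme.
    """
    if not (np.isfinite(r_min) and np.isfinite(r_max)):
        raise ValueError("range must be finite")
    if r_min > r_max:
        raise ValueError("r_min must not exceed r_max")
    r_min = min(r_min, 0.0)
    r_max = max(r_max, 0.0)
    q_min, q_max = grid
    if r_min == r_max:
        widen = max(abs(r_min), 1.0) * 1e-8
        r_min, r_max = r_min - widen, r_max + widen
    s = (r_max - r_min) / (q_max - q_min)
    z = int(np.clip(round_half_away(q_min - r_min / s), q_min, q_max))
    return QuantParams(s, z, q_min, q_max, "affine_per_tensor")


def symmetric_channel_qparams(W: np.ndarray, channel_axis: int = 0) -> QuantParams:
    """Per-output-channel symmetric params: s_k = max|W_k| / 127, z_k = 0."""
    W = np.asarray(W, dtype=float)
    if not np.isfinite(W).all():
        raise ValueError("weights must be finite")
    moved = np.moveaxis(W, channel_axis, 0).reshape(W.shape[channel_axis], -1)
    amax = np.abs(moved).max(axis=1)
    s = np.where(amax > 0, amax / 127.0, 1e-12)
    return QuantParams(s, 0, *SIGNED, scheme="symmetric_per_channel",
                       channel_axis=channel_axis)


def quantize_tensor(r: np.ndarray, params: QuantParams) -> QuantizedTensor:
    """q = clip(round(r/s) + z, q_min, q_max)."""
    r = np.asarray(r, dtype=float)
    s, z = params._bcast(r.ndim)
    q = np.clip(round_half_away(r / s) + z, params.q_min, params.q_max)
    return QuantizedTensor(q.astype(np.int32), params)


def dequantize(t: QuantizedTensor) -> np.ndarray:
    """r_hat = s * (q - z)."""
    s, z = t.params._bcast(t.q.ndim)
    return s * (t.q.astype(float) - z)


def fold_batchnorm(W: np.ndarray, b: np.ndarray, bn: BatchNormParams):
    """Absorb BN into the preceding layer:
    W~ = gamma W / sqrt(var + eps), b~ = gamma (b - mean) / sqrt(var + eps) + beta.
    """
    W = np.asarray(W, dtype=float)
    b = np.zeros(W.shape[0]) if b is None else np.asarray(b, dtype=float)
    n_out = W.shape[0]
    if not (len(bn.gamma) == len(bn.mean) == len(bn.var) == n_out):
        raise ValueError("BN channel count does not match layer output channels")
    scale = bn.gamma / np.sqrt(bn.var + bn.eps)
    W_f = W * scale.reshape((n_out,) + (1,) * (W.ndim - 1))
    b_f = (b - bn.mean) * scale + bn.beta
    return W_f, b_f


def fuse_conv_bn(layers: list) -> list:
    """Return a new layer list with every Conv2d->BatchNorm2d pair folded.

    A BatchNorm2d not directly preceded by a Conv2d raises, and the output is
    guaranteed BN-free.
    """
    out = []
    for layer in layers:
        if isinstance(layer, nn.BatchNorm2d):
            if not out or not isinstance(out[-1], nn.Conv2d):
                raise ValueError("BatchNorm2d without a preceding Conv2d cannot be fused")
            conv = out[-1]
            bn = BatchNormParams(layer.gamma, layer.beta, layer.running_mean,
                                 layer.running_var, layer.eps)
            W_f, b_f = fold_batchnorm(conv.W, conv.b, bn)
            fused = nn.Conv2d(conv.in_channels, conv.out_channels, conv.k,
                              np.random.default_rng(0))
            fused.W = W_f.astype(nn.DTYPE)
            fused.b = b_f.astype(nn.DTYPE)
            out[-1] = fused
        else:
            out.append(layer)
    return out


# ---------------------------------------------------------------------------
# Calibration


@dataclass
class CalibrationConfig:
    method: str = "percentile"  # minmax | percentile | kl
    percentile: tuple = (0.1, 99.9)
    n_bins: int = 2048
    n_quant_bins: int = 256

    def __post_init__(self):
        if self.method not in ("minmax", "percentile", "kl"):
            raise ValueError(f"unknown calibration method {self.method!r}")


class Observer:
    """Pass-through recorder of activation values; derives (r_min, r_max)."""

    def __init__(self):
        self._chunks = []

    def update(self, x: np.ndarray):
        self._chunks.append(np.asarray(x, dtype=np.float32).ravel())

    def pooled(self) -> np.ndarray:
        if not self._chunks:
            raise ValueError("observer saw no data")
        return np.concatenate(self._chunks)

    def range(self, cfg: CalibrationConfig) -> tuple[float, float]:
        vals = self.pooled()
        if cfg.method == "minmax":
            return float(vals.min()), float(vals.max())
        if cfg.method == "percentile":
            lo, hi = np.percentile(vals, cfg.percentile)
            return float(lo), float(hi)
        return kl_optimal_range(vals, cfg.n_bins, cfg.n_quant_bins)


def _kl_div(p: np.ndarray, q: np.ndarray) -> float:
    eps = 1e-12
    p = p / p.sum()
    q = q / max(q.sum(), eps)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / np.maximum(q[mask], eps))))


def kl_divergence_for_threshold(hist: np.ndarray, i: int, n_quant: int = 256) -> float:
    """KL between the first-i-bin reference distribution (outliers absorbed
    into the last kept bin) and its n_quant-level requantized version."""
    p = hist[:i].astype(float).copy()
    p[-1] += hist[i:].sum()
    q = np.zeros_like(p)
    for chunk in np.array_split(np.arange(i), n_quant):
        seg = p[chunk]
        nz = seg > 0
        if nz.any():
            q_chunk = np.zeros_like(seg)
            q_chunk[nz] = seg.sum() / nz.sum()
            q[chunk] = q_chunk
    return _kl_div(p, q)


def kl_optimal_range(vals: np.ndarray, n_bins: int = 2048,
                     n_quant: int = 256) -> tuple[float, float]:
    """Histogram-based KL range selection: keep r_min at the observed minimum
    and exhaustively search the upper clipping threshold (from n_quant bins up
    to the full histogram, which reproduces min-max) for the one minimizing
    the KL divergence between the clipped reference distribution and its
    256-level requantization."""
    r_min, r_max = float(vals.min()), float(vals.max())
    if r_min == r_max:
        return r_min, r_max
    hist, edges = np.histogram(vals, bins=n_bins, range=(r_min, r_max))
    best_i, best_kl = n_bins, np.inf
    for i in range(n_quant, n_bins + 1):
        kl = kl_divergence_for_threshold(hist, i, n_quant)
        if kl < best_kl:
            best_kl, best_i = kl, i
    return r_min, float(edges[best_i])


# ---------------------------------------------------------------------------
# Integer kernels


def _bias_int32(b: np.ndarray, s_w: np.ndarray, s_x: float) -> np.ndarray:
    b32 = round_half_away(np.asarray(b, dtype=float) / (np.asarray(s_w) * s_x))
    if np.abs(b32).max(initial=0) >= 2**31:
        raise ValueError("bias does not fit int32")
    return b32.astype(np.int64)


def _check_int32(acc: np.ndarray):
    if acc.size and max(abs(int(acc.max())), abs(int(acc.min()))) >= 2**31:
        raise ValueError("int32 accumulator overflow")


def quantized_forward(x_q: QuantizedTensor, W_q: QuantizedTensor,
                      b: np.ndarray | None, out_params: QuantParams,
                      kernel_side: int | None = None) -> QuantizedTensor:
    """Integer conv/linear: int32 accumulation of (W_q - z_W)(x_q - z_x),
    int32 bias round(b/(s_W s_x)), float-applied requantization multiplier
    s_W s_x / s_y, then clip to the output grid.

    4-D ``x_q`` runs a stride-1 same-padded convolution (``kernel_side`` from
    the weight tensor); 2-D runs a dense layer.
    """
    s_x = float(np.asarray(x_q.params.scale))
    z_x = int(np.asarray(x_q.params.zero_point))
    s_w = np.asarray(W_q.params.scale, dtype=float)
    x_c = x_q.q.astype(np.int64) - z_x  # zero-point removed; padding is 0
    W = W_q.q.astype(np.int64)  # symmetric: z_w = 0
    if x_c.ndim == 4:
        n_out = W.shape[0]
        k = W.shape[-1] if kernel_side is None else kernel_side
        n, _, h, w = x_c.shape
        cols = nn.im2col(x_c, k, k)
        acc = cols @ W.reshape(n_out, -1).T
        acc = acc.reshape(n, h, w, n_out).transpose(0, 3, 1, 2)
        ch_axis = 1
    elif x_c.ndim == 2:
        n_out = W.shape[0]
        acc = x_c @ W.T
        ch_axis = 1
    else:
        raise ValueError("x_q must be 2-D (dense) or 4-D (conv)")
    if b is not None:
        b32 = _bias_int32(b, s_w, s_x)
        shape = [1] * acc.ndim
        shape[ch_axis] = -1
        acc = acc + b32.reshape(shape)
    _check_int32(acc)
    s_y = float(np.asarray(out_params.scale))
    z_y = int(np.asarray(out_params.zero_point))
    mult = (s_w * s_x) / s_y
    shape = [1] * acc.ndim
    shape[ch_axis] = -1
    y = round_half_away(np.asarray(mult).reshape(shape) * acc) + z_y
    y = np.clip(y, out_params.q_min, out_params.q_max)
    return QuantizedTensor(y.astype(np.int32), out_params)


# ---------------------------------------------------------------------------
# PTQ driver


def _plan(model: SiameseNetwork):
    """Flatten the network into (op, payload) steps; BN must be pre-fused."""
    steps = []
    conv_layers = fuse_conv_bn(model.conv_net.layers)
    seq = conv_layers + model.dense_net.layers
    i = 0
    while i < len(seq):
        layer = seq[i]
        if isinstance(layer, nn.BatchNorm2d):
            raise ValueError("unfused BatchNorm remaining at quantize time")
        if isinstance(layer, (nn.Conv2d, nn.Dense)):
            relu = i + 1 < len(seq) and isinstance(seq[i + 1], nn.ReLU)
            steps.append(("layer", layer, relu))
            if relu:
                i += 1
        elif isinstance(layer, nn.MaxPool2):
            steps.append(("pool", None, False))
        elif isinstance(layer, nn.Flatten):
            steps.append(("flatten", None, False))
        # Dropout and bare ReLU are identities at inference (ReLU is folded
        # into the preceding layer's step above)
        i += 1
    return steps


@dataclass
class _QLayer:
    kind: str  # conv | dense
    W_q: np.ndarray
    s_w: np.ndarray
    b: np.ndarray
    in_params: QuantParams
    out_params: QuantParams
    relu: bool
    kernel_side: int | None = None

    def run(self, x_q: QuantizedTensor) -> QuantizedTensor:
        Wt = QuantizedTensor(self.W_q, symmetric_channel_qparams_like(self.s_w))
        y = quantized_forward(x_q, Wt, self.b, self.out_params, self.kernel_side)
        if self.relu:
            z = int(np.asarray(self.out_params.zero_point))
            y = QuantizedTensor(np.maximum(y.q, z), self.out_params)
        return y


def symmetric_channel_qparams_like(s_w: np.ndarray) -> QuantParams:
    return QuantParams(np.asarray(s_w, dtype=float), 0, *SIGNED,
                       scheme="symmetric_per_channel", channel_axis=0)


class QuantizedModel:
    """Executable INT8 network: quantized encoder plus the two heads."""

    def __init__(self, input_params: QuantParams, steps: list,
                 head_abn: _QLayer, head_body: _QLayer,
                 input_side: int | None = None):
        self.input_params = input_params
        self.steps = steps  # ("layer", _QLayer) | ("pool", None) | ("flatten", None)
        self.head_abn = head_abn
        self.head_body = head_body
        self.input_side = input_side

    def _embed_q(self, x: np.ndarray) -> QuantizedTensor:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        t = quantize_tensor(x, self.input_params)
        for op, payload in self.steps:
            if op == "layer":
                t = payload.run(t)
            elif op == "pool":
                n, c, h, w = t.q.shape
                q = t.q.reshape(n, c, h // 2, 2, w // 2, 2).max(axis=(3, 5))
                t = QuantizedTensor(q, t.params)
            elif op == "flatten":
                t = QuantizedTensor(t.q.reshape(t.q.shape[0], -1), t.params)
        return t

    def forward_logits(self, x: np.ndarray):
        """Dequantized (FP32) head logits for standardized input images."""
        emb = self._embed_q(x)
        la = dequantize(self.head_abn.run(emb))
        lb = dequantize(self.head_body.run(emb))
        return la, lb

    def predict(self, x: np.ndarray):
        la, lb = self.forward_logits(x)
        return la.argmax(axis=-1), lb.argmax(axis=-1)

    # -- size accounting & export -------------------------------------------
    def _qlayers(self):
        return [p for op, p in self.steps if op == "layer"] + [
            self.head_abn, self.head_body
        ]

    def weight_payload_bytes(self) -> int:
        return int(sum(q.W_q.size for q in self._qlayers()))

    def size_bytes(self) -> int:
        total = 0
        for q in self._qlayers():
            total += q.W_q.size  # int8 weights
            total += 4 * q.b.size  # int32 bias
            total += 4 * q.s_w.size  # per-channel scales
            total += 8  # activation scale + zero-point
        return total

    def export(self, out_dir: str) -> None:
        """Raw little-endian int8 payload + JSON sidecar with all metadata."""
        os.makedirs(out_dir, exist_ok=True)
        payload = bytearray()
        meta = {
            "input_params": _params_to_json(self.input_params),
            "input_side": self.input_side,
            "steps": [],
            "heads": {},
        }
        offset = 0

        def emit(q: _QLayer):
            nonlocal offset
            raw = q.W_q.astype("<i1").tobytes()
            payload.extend(raw)
            entry = {
                "kind": q.kind,
                "shape": list(q.W_q.shape),
                "offset": offset,
                "s_w": q.s_w.tolist(),
                "bias": q.b.tolist(),
                "in_params": _params_to_json(q.in_params),
                "out_params": _params_to_json(q.out_params),
                "relu": q.relu,
                "kernel_side": q.kernel_side,
            }
            offset += len(raw)
            return entry

        for op, p in self.steps:
            meta["steps"].append({"op": op, "layer": emit(p) if op == "layer" else None})
        meta["heads"]["abnormal"] = emit(self.head_abn)
        meta["heads"]["body"] = emit(self.head_body)
        with open(os.path.join(out_dir, "weights.bin"), "wb") as fh:
            fh.write(bytes(payload))
        with open(os.path.join(out_dir, "model.json"), "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, out_dir: str) -> "QuantizedModel":
        with open(os.path.join(out_dir, "model.json")) as fh:
            meta = json.load(fh)
        raw = np.fromfile(os.path.join(out_dir, "weights.bin"), dtype="<i1")

        def build(entry):
            n = int(np.prod(entry["shape"]))
            W = raw[entry["offset"] : entry["offset"] + n].reshape(entry["shape"])
            return _QLayer(
                kind=entry["kind"],
                W_q=W.astype(np.int32),
                s_w=np.asarray(entry["s_w"], dtype=float),
                b=np.asarray(entry["bias"], dtype=float),
                in_params=_params_from_json(entry["in_params"]),
                out_params=_params_from_json(entry["out_params"]),
                relu=entry["relu"],
                kernel_side=entry["kernel_side"],
            )

        steps = [
            (s["op"], build(s["layer"]) if s["op"] == "layer" else None)
            for s in meta["steps"]
        ]
        return cls(
            _params_from_json(meta["input_params"]),
            steps,
            build(meta["heads"]["abnormal"]),
            build(meta["heads"]["body"]),
            input_side=meta.get("input_side"),
        )


def _params_to_json(p: QuantParams) -> dict:
    return {
        "scale": np.asarray(p.scale).tolist(),
        "zero_point": np.asarray(p.zero_point).tolist(),
        "q_min": p.q_min,
        "q_max": p.q_max,
        "scheme": p.scheme,
        "channel_axis": p.channel_axis,
    }


def _params_from_json(d: dict) -> QuantParams:
    scale = d["scale"]
    scale = np.asarray(scale, dtype=float) if isinstance(scale, list) else float(scale)
    zp = d["zero_point"]
    zp = np.asarray(zp) if isinstance(zp, list) else int(zp)
    return QuantParams(scale, zp, d["q_min"], d["q_max"], d["scheme"], d["channel_axis"])


def calibrate_activations(model: SiameseNetwork, calib_batches: list,
                          cfg: CalibrationConfig | None = None):
    """Forward-only calibration pass.

    Returns (input_params, list of per-step activation QuantParams aligned to
    the layer plan, head params pair). Post-ReLU taps get the unsigned grid;
    everything else (input, embedding layer, heads) the signed grid.
    """
    if cfg is None:
        cfg = CalibrationConfig()
    if not calib_batches:
        raise ValueError("need at least one calibration batch")
    steps = _plan(model)
    obs_in = Observer()
    obs_steps = [Observer() if op == "layer" else None for op, _, _ in steps]
    obs_abn, obs_body = Observer(), Observer()
    for batch in calib_batches:
        x = np.asarray(batch, dtype=nn.DTYPE)
        if x.ndim == 3:
            x = x[:, None]
        obs_in.update(x)
        t = x
        for idx, (op, layer, relu) in enumerate(steps):
            if op == "layer":
                t, _ = layer.forward(t, train=False)
                if relu:
                    t = np.maximum(t, 0.0)
                obs_steps[idx].update(t)
            elif op == "pool":
                t, _ = nn.MaxPool2().forward(t)
            elif op == "flatten":
                t = t.reshape(t.shape[0], -1)
        la, _ = model.head_abnormal.forward(t)
        lb, _ = model.head_body.forward(t)
        obs_abn.update(la)
        obs_body.update(lb)

    def act_params(obs: Observer, post_relu: bool) -> QuantParams:
        r_min, r_max = obs.range(cfg)
        if post_relu:
            r_min = max(r_min, 0.0)
            return affine_qparams(r_min, r_max, UNSIGNED)
        return affine_qparams(r_min, r_max, SIGNED)

    input_params = act_params(obs_in, post_relu=False)
    step_params = [
        act_params(obs_steps[i], relu) if op == "layer" else None
        for i, (op, _, relu) in enumerate(steps)
    ]
    head_params = (
        act_params(obs_abn, post_relu=False),
        act_params(obs_body, post_relu=False),
    )
    return input_params, step_params, head_params


def quantize_model(model: SiameseNetwork, calib_batches: list,
                   cfg: CalibrationConfig | None = None) -> QuantizedModel:
    """The PTQ driver: fuse BN, calibrate, derive params, quantize weights,
    assemble integer kernels."""
    if cfg is None:
        cfg = CalibrationConfig()
    input_params, step_params, head_params = calibrate_activations(
        model, calib_batches, cfg
    )
    steps = _plan(model)
    q_steps = []
    cur_params = input_params
    for idx, (op, layer, relu) in enumerate(steps):
        if op != "layer":
            q_steps.append((op, None))
            continue
        wp = symmetric_channel_qparams(layer.W, channel_axis=0)
        W_q = quantize_tensor(layer.W, wp)
        out_p = step_params[idx]
        q_steps.append(
            (
                "layer",
                _QLayer(
                    kind="conv" if isinstance(layer, nn.Conv2d) else "dense",
                    W_q=W_q.q,
                    s_w=np.asarray(wp.scale, dtype=float),
                    b=np.asarray(layer.b, dtype=float),
                    in_params=cur_params,
                    out_params=out_p,
                    relu=relu,
                    kernel_side=layer.k if isinstance(layer, nn.Conv2d) else None,
                ),
            )
        )
        cur_params = out_p

    def quant_head(head: nn.Dense, out_p: QuantParams) -> _QLayer:
        wp = symmetric_channel_qparams(head.W, channel_axis=0)
        return _QLayer(
            kind="dense",
            W_q=quantize_tensor(head.W, wp).q,
            s_w=np.asarray(wp.scale, dtype=float),
            b=np.asarray(head.b, dtype=float),
            in_params=cur_params,
            out_params=out_p,
            relu=False,
        )

    return QuantizedModel(
        input_params,
        q_steps,
        quant_head(model.head_abnormal, head_params[0]),
        quant_head(model.head_body, head_params[1]),
        input_side=model.spec.input_side,
    )


class PostTrainingQuantizer:
    """Estimator-style front end for the PTQ engine.

    Parameters mirror the calibration config; ``fit`` runs calibration +
    quantization and exposes the result as ``quantized_model_``.
    """

    def __init__(self, method: str = "percentile", percentile: tuple = (0.1, 99.9),
                 n_bins: int = 2048):
        self.method = method
        self.percentile = percentile
        self.n_bins = n_bins

    def get_params(self, deep: bool = True) -> dict:
        return {
            "method": self.method,
            "percentile": self.percentile,
            "n_bins": self.n_bins,
        }

    def set_params(self, **kw):
        for k, v in kw.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, model: SiameseNetwork, calib_batches: list) -> "PostTrainingQuantizer":
        cfg = CalibrationConfig(self.method, self.percentile, self.n_bins)
        self.quantized_model_ = quantize_model(model, calib_batches, cfg)
        return self

    def transform(self, model: SiameseNetwork = None, calib_batches: list = None):
        if calib_batches is not None:
            self.fit(model, calib_batches)
        return self.quantized_model_
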