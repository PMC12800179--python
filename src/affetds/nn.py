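"""A small NumPy convolutional network with manual backpropagation.

This is the gradient-capable image classifier of the package: three 3x3
convolution blocks (conv -> ReLU -> 2x2 max-pool, widths 16/32/64 by default)
followed by two fully connected layers (128 -> 2) and a softmax. Convolutions
use a channels-last im2col decomposition (one BLAS product per layer), which
keeps single-CPU training of the scaled-down experiments practical, and the
backward pass propagates all the way to the input pixels — exactly what
FGSM/PGD need.

All arithmetic is float32 and fully deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._exceptions import NumericalError, ParameterError, ShapeError

_DTYPE = np.float32


class _Workspace:
    """Reusable scratch buffers keyed by (name, shape).

    Fresh multi-megabyte allocations cost kernel page faults every call;
    reusing buffers across minibatches removes that overhead entirely.
    """

    def __init__(self) -> None:
        self._bufs: dict = {}

    def get(self, name: str, shape: tuple, dtype=_DTYPE) -> np.ndarray:
        # Keyed by name only: alternating batch shapes trigger a realloc
        # (cheap, once per epoch boundary) instead of keeping one buffer
        # set per shape (which would multiply peak memory).
        buf = self._bufs.get(name)
        if buf is None or buf.shape != shape or buf.dtype != dtype:
            buf = np.empty(shape, dtype=dtype)
            self._bufs[name] = buf
        return buf


def _conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, ws: _Workspace, tag: str):
    """3x3 same-padding convolution, channels last, via im2col + one GEMM.

    x: (N,H,W,C); w: (3,3,C,O); b: (O,). Returns (out, cols) where cols is
    the (N,H,W,9C) column matrix kept for the backward pass.
    """
    n, h, wd, c = x.shape
    o = w.shape[-1]
    xp = ws.get(f"{tag}:xp", (n, h + 2, wd + 2, c))
    xp[:, 0, :, :] = 0
    xp[:, -1, :, :] = 0
    xp[:, :, 0, :] = 0
    xp[:, :, -1, :] = 0
    xp[:, 1 : h + 1, 1 : wd + 1, :] = x
    cols = ws.get(f"{tag}:cols", (n, h, wd, 9 * c))
    k = 0
    for i in range(3):
        for j in range(3):
            cols[..., k * c : (k + 1) * c] = xp[:, i : i + h, j : j + wd, :]
            k += 1
    out = ws.get(f"{tag}:out", (n * h * wd, o))
    np.matmul(cols.reshape(n * h * wd, 9 * c), w.reshape(9 * c, o), out=out)
    pre = out.reshape(n, h, wd, o)
    pre += b
    return pre, cols


def _conv3x3_backward(
    dout: np.ndarray, cols: np.ndarray, w: np.ndarray, ws: _Workspace, tag: str, need_dx: bool = True
):
    """Gradients of the 3x3 convolution w.r.t. weights, bias, and input."""
    n, h, wd, o = dout.shape
    c = w.shape[2]
    dout_mat = dout.reshape(n * h * wd, o)
    dw = (cols.reshape(n * h * wd, 9 * c).T @ dout_mat).reshape(w.shape)
    db = dout_mat.sum(axis=0)
    dx = None
    if need_dx:
        dcols_mat = ws.get(f"{tag}:dcols", (n * h * wd, 9 * c))
        np.matmul(dout_mat, w.reshape(9 * c, o).T, out=dcols_mat)
        dcols = dcols_mat.reshape(n, h, wd, 9 * c)
        dxp = ws.get(f"{tag}:dxp", (n, h + 2, wd + 2, c))
        dxp[...] = 0
        k = 0
        for i in range(3):
            for j in range(3):
                dxp[:, i : i + h, j : j + wd, :] += dcols[..., k * c : (k + 1) * c]
                k += 1
        dx = dxp[:, 1 : h + 1, 1 : wd + 1, :]
    return dw, db, dx


def _pool2x2_forward(x: np.ndarray, ws: _Workspace, tag: str):
    """2x2 max-pool, channels last: (N,H,W,C) -> (N,H/2,W/2,C).

    The cache is four disjoint winner masks (ties route to the first of the
    scan order) so the backward pass is four masked scatter-writes.
    """
    n, h, wd, c_ = x.shape
    a = x[:, ::2, ::2, :]
    b = x[:, ::2, 1::2, :]
    c = x[:, 1::2, ::2, :]
    d = x[:, 1::2, 1::2, :]
    out = ws.get(f"{tag}:pool", (n, h // 2, wd // 2, c_))
    np.maximum(a, b, out=out)
    np.maximum(out, c, out=out)
    np.maximum(out, d, out=out)
    m0 = a >= out
    m1 = (b >= out) & ~m0
    m2 = (c >= out) & ~(m0 | m1)
    m3 = (d >= out) & ~(m0 | m1 | m2)
    return out, (m0, m1, m2, m3)


def _pool2x2_backward(dout: np.ndarray, masks, x_shape, ws: _Workspace, tag: str):
    dx = ws.get(f"{tag}:pooldx", x_shape)
    np.multiply(dout, masks[0], out=dx[:, ::2, ::2, :])
    np.multiply(dout, masks[1], out=dx[:, ::2, 1::2, :])
    np.multiply(dout, masks[2], out=dx[:, 1::2, ::2, :])
    np.multiply(dout, masks[3], out=dx[:, 1::2, 1::2, :])
    return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    n = probs.shape[0]
    p = np.clip(probs[np.arange(n), labels], 1e-12, 1.0)
    return float(-np.log(p).mean())


@dataclass
class CnnConfig:
    """Architecture and optimizer hyperparameters of the image CNN.

    Defaults: three conv blocks of widths 16/32/64 on a 224x224 single-
    channel input, a 2x average-pool before the flatten, a 128-unit hidden
    FC layer, two output classes; Adam with learning rate 1e-3, decoupled
    weight decay 1e-4, batch size 16, early stopping with patience 5 under
    an epoch cap of 50.
    """

    input_size: int = 224
    conv_widths: tuple[int, ...] = (16, 32, 64)
    fc_width: int = 128
    head_pool: str = "flatten"  # {"flatten", "max", "avg"} aggregation before FC
    head_downsample: int = 2  # extra average-pool factor before flattening
    n_classes: int = 2
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4  # decoupled L2 on weight matrices (not biases)
    batch_size: int = 16
    patience: int = 5
    max_epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size % (2 ** len(self.conv_widths)) != 0:
            raise ParameterError(
                f"input_size {self.input_size} must be divisible by 2^{len(self.conv_widths)}"
            )
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1 or self.patience < 1:
            raise ParameterError("invalid optimizer hyperparameters")
        if self.head_pool not in ("max", "avg", "flatten"):
            raise ParameterError(f"head_pool must be 'max', 'avg' or 'flatten', got {self.head_pool!r}")
        side = self.input_size // (2 ** len(self.conv_widths))
        if self.head_downsample < 1 or side % self.head_downsample != 0:
            raise ParameterError(
                f"head_downsample must divide the final map side {side}, got {self.head_downsample}"
            )
        if self.weight_decay < 0:
            raise ParameterError("weight_decay must be >= 0")


class SmallCnn:
    """The gradient-capable convolutional classifier.

    Satisfies the attack module's model contract: ``predict_proba`` gives the
    probability of the "manipulated" class (index 1) and
    ``loss_and_gradient`` returns the mean cross-entropy with its gradient
    w.r.t. the input pixels.
    """

    def __init__(self, config: Optional[CnnConfig] = None):
        self.config = config or CnnConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = 1
        for i, width in enumerate(cfg.conv_widths):
            fan_in = c_in * 9
            self.params[f"conv{i}_w"] = (
                rng.standard_normal((3, 3, c_in, width)) * np.sqrt(2.0 / fan_in)
            ).astype(_DTYPE)
            self.params[f"conv{i}_b"] = np.zeros(width, dtype=_DTYPE)
            c_in = width
        side = cfg.input_size // (2 ** len(cfg.conv_widths))
        if cfg.head_pool == "flatten":
            side //= cfg.head_downsample
            flat = side * side * c_in
        else:
            flat = c_in
        self._flat_dim = flat
        self.params["fc1_w"] = (rng.standard_normal((flat, cfg.fc_width)) * np.sqrt(2.0 / flat)).astype(_DTYPE)
        self.params["fc1_b"] = np.zeros(cfg.fc_width, dtype=_DTYPE)
        self.params["fc2_w"] = (
            rng.standard_normal((cfg.fc_width, cfg.n_classes)) * np.sqrt(2.0 / cfg.fc_width)
        ).astype(_DTYPE)
        self.params["fc2_b"] = np.zeros(cfg.n_classes, dtype=_DTYPE)
        self._ws = _Workspace()
        #: Optional Platt recalibration (slope, intercept) on the logit of
        #: the "manipulated" probability, fitted on validation data.
        self.calibration: Optional[tuple[float, float]] = None

    # ---- core passes -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=_DTYPE)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1] != self.config.input_size or x.shape[2] != self.config.input_size:
            raise ShapeError(
                f"expected (n, {self.config.input_size}, {self.config.input_size}) images, got {x.shape}"
            )
        return x

    #: Fixed input standardization: [0,1] intensities -> [-1,1]. Centered
    #: inputs are required for stable optimization from He-initialized
    #: weights; the factor re-enters the input-gradient chain rule.
    INPUT_SHIFT = 0.5
    INPUT_SCALE = 2.0

    def _forward(self, x: np.ndarray):
        """x: (N,H,W) -> logits (N,K) plus caches for backprop."""
        h = (x[..., None] - self.INPUT_SHIFT) * self.INPUT_SCALE  # channels last: (N,H,W,1)
        caches = []
        for i in range(len(self.config.conv_widths)):
            pre, cols = _conv3x3_forward(
                h, self.params[f"conv{i}_w"], self.params[f"conv{i}_b"], self._ws, f"c{i}"
            )
            relu_mask = pre > 0
            act = np.maximum(pre, 0, out=pre)  # in place; `pre` not reused below
            pooled, masks = _pool2x2_forward(act, self._ws, f"c{i}")
            caches.append((cols, relu_mask, masks, act.shape))
            h = pooled
        n = h.shape[0]
        conv_out_shape = h.shape  # pre-head shape, needed by conv backward
        head_cache = None
        if self.config.head_pool == "flatten":
            d = self.config.head_downsample
            if d > 1:
                _, sh, sw, c = h.shape
                h = h.reshape(n, sh // d, d, sw // d, d, c).mean(axis=(2, 4))
            flat = h.reshape(n, -1)
        elif self.config.head_pool == "avg":
            flat = h.mean(axis=(1, 2))
        else:  # max: "did any location fire" — suited to localized anomalies
            hm = h.reshape(n, -1, h.shape[-1])
            head_cache = hm.argmax(axis=1)
            flat = np.take_along_axis(hm, head_cache[:, None, :], axis=1)[:, 0, :]
        z1 = flat @ self.params["fc1_w"] + self.params["fc1_b"]
        a1 = np.maximum(z1, 0)
        logits = a1 @ self.params["fc2_w"] + self.params["fc2_b"]
        return logits, (caches, conv_out_shape, flat, z1, a1, head_cache)

    def _backward(self, dlogits: np.ndarray, cache, need_input_grad: bool):
        caches, pooled_shape, flat, z1, a1, head_cache = cache
        grads: dict[str, np.ndarray] = {}
        grads["fc2_w"] = a1.T @ dlogits
        grads["fc2_b"] = dlogits.sum(axis=0)
        da1 = dlogits @ self.params["fc2_w"].T
        dz1 = da1 * (z1 > 0)
        grads["fc1_w"] = flat.T @ dz1
        grads["fc1_b"] = dz1.sum(axis=0)
        dflat = dz1 @ self.params["fc1_w"].T
        n, sh, sw, c = pooled_shape
        if self.config.head_pool == "flatten":
            d = self.config.head_downsample
            if d > 1:
                small = dflat.reshape(n, sh // d, 1, sw // d, 1, c) / (d * d)
                dh = np.broadcast_to(small, (n, sh // d, d, sw // d, d, c)).reshape(pooled_shape)
            else:
                dh = dflat.reshape(pooled_shape)
        elif self.config.head_pool == "avg":
            dh = np.broadcast_to(dflat[:, None, None, :] / (sh * sw), pooled_shape).astype(dflat.dtype)
        else:  # max: gradient routes to the winning location per channel
            dhm = np.zeros((n, sh * sw, c), dtype=dflat.dtype)
            np.put_along_axis(dhm, head_cache[:, None, :], dflat[:, None, :], axis=1)
            dh = dhm.reshape(pooled_shape)
        dx = None
        for i in reversed(range(len(self.config.conv_widths))):
            cols, relu_mask, masks, act_shape = caches[i]
            dact = _pool2x2_backward(dh, masks, act_shape, self._ws, f"c{i}")
            dact *= relu_mask
            need_dx = i > 0 or need_input_grad
            dw, db, dh = _conv3x3_backward(
                dact, cols, self.params[f"conv{i}_w"], self._ws, f"c{i}", need_dx
            )
            grads[f"conv{i}_w"] = dw
            grads[f"conv{i}_b"] = db
            if i == 0 and need_input_grad:
                dx = dh[..., 0]
        return grads, dx

    # ---- public API --------------------------------------------------

    def logits(self, pixels: np.ndarray, batch: Optional[int] = None) -> np.ndarray:
        batch = batch or self.config.batch_size
        x = self._check_input(pixels)
        outs = [self._forward(x[i : i + batch])[0] for i in range(0, len(x), batch)]
        return np.concatenate(outs, axis=0)

    def predict_full_proba(self, pixels: np.ndarray) -> np.ndarray:
        """Per-class probabilities, shape (N, n_classes); rows sum to 1."""
        return softmax(self.logits(pixels).astype(np.float64))

    def predict_proba(self, pixels: np.ndarray) -> np.ndarray:
        """Probability of the "manipulated" class (index 1) per input.

        Applies the validation-fitted Platt recalibration when present
        (``predict_full_proba`` always returns the raw softmax).
        """
        single = np.asarray(pixels).ndim == 2
        p = self.predict_full_proba(pixels)[:, 1]
        if self.calibration is not None:
            a, b = self.calibration
            z = np.log(np.clip(p, 1e-12, 1 - 1e-12) / np.clip(1 - p, 1e-12, 1))
            p = 1.0 / (1.0 + np.exp(-(a * z + b)))
        return float(p[0]) if single else p

    def loss_and_gradient(self, pixels: np.ndarray, labels: np.ndarray | int) -> tuple[float, np.ndarray]:
        """Mean cross-entropy and its gradient w.r.t. the input pixels."""
        single = np.asarray(pixels).ndim == 2
        x = self._check_input(pixels)
        y = np.atleast_1d(np.asarray(labels, dtype=np.int64))
        if y.shape[0] != x.shape[0]:
            raise ShapeError(f"{y.shape[0]} labels for {x.shape[0]} images")
        logits, cache = self._forward(x)
        probs = softmax(logits.astype(np.float64))
        loss = cross_entropy(probs, y)
        if not np.isfinite(loss):
            raise NumericalError("non-finite loss")
        dlogits = probs.copy()
        dlogits[np.arange(len(y)), y] -= 1.0
        dlogits = (dlogits / len(y)).astype(_DTYPE)
        _, dx = self._backward(dlogits, cache, need_input_grad=True)
        dx = dx.astype(np.float64) * self.INPUT_SCALE  # chain through standardization
        return loss, dx[0] if single else dx

    def loss_and_param_grads(self, pixels: np.ndarray, labels: np.ndarray):
        """Mean cross-entropy and gradients for every trainable parameter."""
        x = self._check_input(pixels)
        y = np.asarray(labels, dtype=np.int64)
        logits, cache = self._forward(x)
        probs = softmax(logits.astype(np.float64))
        loss = cross_entropy(probs, y)
        dlogits = probs.copy()
        dlogits[np.arange(len(y)), y] -= 1.0
        dlogits = (dlogits / len(y)).astype(_DTYPE)
        grads, _ = self._backward(dlogits, cache, need_input_grad=False)
        return loss, grads

    def mean_loss(self, pixels: np.ndarray, labels: np.ndarray) -> float:
        probs = self.predict_full_proba(pixels)
        return cross_entropy(probs, np.asarray(labels, dtype=np.int64))

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()


@dataclass
class Adam:
    """Adam optimizer over a SmallCnn parameter dict.

    ``weight_decay`` is decoupled (AdamW-style) and applied only to weight
    matrices, never to biases.
    """

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    weight_decay: float = 0.0
    _m: dict = field(default_factory=dict)
    _v: dict = field(default_factory=dict)
    _t: int = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self._t += 1
        if self.weight_decay > 0:
            for k in params:
                if k.endswith("_w"):
                    params[k] -= np.float32(self.lr * self.weight_decay) * params[k]
        for k, g in grads.items():
            g = g.astype(_DTYPE)
            if k not in self._m:
                self._m[k] = np.zeros_like(g)
                self._v[k] = np.zeros_like(g)
            self._m[k] = self.beta1 * self._m[k] + (1 - self.beta1) * g
            self._v[k] = self.beta2 * self._v[k] + (1 - self.beta2) * g * g
            m_hat = self._m[k] / (1 - self.beta1**self._t)
            v_hat = self._v[k] / (1 - self.beta2**self._t)
            params[k] -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(_DTYPE)
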