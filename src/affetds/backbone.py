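"""Deep feature backbone: a seeded random residual convolutional network.

The fusion pipeline needs a 2048-dimensional penultimate-layer embedding of
each 224x224 image. This module provides it with a ResNet-style network —
strided 7x7 stem, max-pool, four residual stages of doubling width, a 1x1
expansion head, global average pooling — evaluated forward-only in NumPy
(channels-last, one BLAS product per kernel tap). Weights are He-initialized
from a fixed seed: random convolutional features are a standard,
deterministic, download-free embedding whose geometry (edge, texture, and
shape selectivity through depth) is what the downstream SVM consumes. The
network depth is deliberately modest so feature extraction stays cheap on one
CPU; the output dimension is exactly 2048 for any valid input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import ShapeError

_DTYPE = np.float32

#: Per-channel standardization constants (the usual natural-image convention).
CHANNEL_MEAN = np.array([0.485, 0.456, 0.406], dtype=_DTYPE)
CHANNEL_STD = np.array([0.229, 0.224, 0.225], dtype=_DTYPE)

FEATURE_DIM = 2048


def _conv(x: np.ndarray, w: np.ndarray, stride: int = 1, pad: int = 1) -> np.ndarray:
    """k x k convolution, channels last. x: (N,H,W,C); w: (k,k,C,O)."""
    k = w.shape[0]
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    h_out = (x.shape[1] - k) // stride + 1
    w_out = (x.shape[2] - k) // stride + 1
    out = np.zeros((x.shape[0], h_out, w_out, w.shape[-1]), dtype=_DTYPE)
    for i in range(k):
        for j in range(k):
            patch = x[:, i : i + stride * (h_out - 1) + 1 : stride,
                      j : j + stride * (w_out - 1) + 1 : stride, :]
            out += patch @ w[i, j]
    return out


def _maxpool(x: np.ndarray, k: int = 3, stride: int = 2, pad: int = 1) -> np.ndarray:
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)), constant_values=-np.inf)
    h_out = (x.shape[1] - k) // stride + 1
    w_out = (x.shape[2] - k) // stride + 1
    out = np.full((x.shape[0], h_out, w_out, x.shape[3]), -np.inf, dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            patch = x[:, i : i + stride * (h_out - 1) + 1 : stride,
                      j : j + stride * (w_out - 1) + 1 : stride, :]
            np.maximum(out, patch, out=out)
    return out


@dataclass
class BackboneConfig:
    """Widths and input geometry of the random backbone."""

    input_size: int = 224
    stem_width: int = 32
    stage_widths: tuple[int, ...] = (32, 64, 128, 256)
    feature_dim: int = FEATURE_DIM
    seed: int = 0


class RandomConvBackbone:
    """Seeded random residual CNN producing a fixed-length embedding.

    Deterministic: the same image and seed always give bit-identical
    features. Single-channel input is replicated to three channels and
    standardized per channel before the stem.
    """

    def __init__(self, config: BackboneConfig | None = None):
        self.config = config or BackboneConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)

        def he(k, c_in, c_out):
            fan_in = k * k * c_in
            return (rng.standard_normal((k, k, c_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(_DTYPE)

        self.stem = he(7, 3, cfg.stem_width)
        self.blocks = []
        c_in = cfg.stem_width
        for si, width in enumerate(cfg.stage_widths):
            stride = 1 if si == 0 else 2
            self.blocks.append({
                "conv1": he(3, c_in, width),
                "conv2": he(3, width, width),
                "stride": stride,
                "proj": he(1, c_in, width) if (stride != 1 or c_in != width) else None,
            })
            c_in = width
        self.head = he(1, c_in, cfg.feature_dim)

    def _check(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=_DTYPE)
        if x.ndim == 2:
            x = x[None]
        size = self.config.input_size
        if x.ndim != 3 or x.shape[1] != size or x.shape[2] != size:
            raise ShapeError(f"expected (n, {size}, {size}) grayscale images, got shape {x.shape}")
        return x

    def extract(self, pixels: np.ndarray, batch: int = 8) -> np.ndarray:
        """Embed images. (H,W) -> (2048,); (N,H,W) -> (N, 2048)."""
        single = np.asarray(pixels).ndim == 2
        x = self._check(pixels)
        feats = [self._extract_batch(x[i : i + batch]) for i in range(0, len(x), batch)]
        out = np.concatenate(feats, axis=0).astype(np.float64)
        return out[0] if single else out

    def _extract_batch(self, x: np.ndarray) -> np.ndarray:
        # grayscale -> 3 channels, per-channel standardization
        h = (x[..., None] - CHANNEL_MEAN) / CHANNEL_STD
        h = np.maximum(_conv(h, self.stem, stride=2, pad=3), 0)
        h = _maxpool(h)
        for block in self.blocks:
            shortcut = h if block["proj"] is None else _conv(h, block["proj"], stride=block["stride"], pad=0)
            y = np.maximum(_conv(h, block["conv1"], stride=block["stride"], pad=1), 0)
            y = _conv(y, block["conv2"], stride=1, pad=1)
            h = np.maximum(y + shortcut, 0)
        h = np.maximum(_conv(h, self.head, stride=1, pad=0), 0)
        return h.mean(axis=(1, 2))  # global average pool -> (N, feature_dim)
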