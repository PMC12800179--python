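"""Feature extraction and fusion: HOG + deep embedding -> 5828-d vector.

The fused representation concatenates, in this fixed order:

* positions 0..2047 — the 2048-d deep embedding (penultimate global-average-
  pool output of the convolutional backbone);
* positions 2048..5827 — the 3780-d HOG descriptor.

The 3780 figure is the canonical Dalal-Triggs geometry: a 64x128 detection
window, 8x8-pixel cells, 2x2-cell blocks at 1-cell stride, 9 unsigned
orientation bins, L2-Hys block normalization, giving 7*15 blocks * 4 cells
* 9 bins = 3780. Preprocessed 224x224 images are bilinearly resized to that
window inside the HOG op. No rescaling happens at fusion time — feature
standardization is the classifier pipeline's job.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import hog
from skimage.transform import resize

from ._exceptions import ParameterError, ShapeError
from .backbone import FEATURE_DIM, RandomConvBackbone

DEEP_DIM = FEATURE_DIM  # 2048
HOG_DIM = 3780
FUSED_DIM = DEEP_DIM + HOG_DIM  # 5828


@dataclass
class HogConfig:
    """Dalal-Triggs descriptor geometry (defaults give the 3780-d vector)."""

    window: tuple[int, int] = (128, 64)  # (rows, cols) of the detection window
    cell: tuple[int, int] = (8, 8)
    block: tuple[int, int] = (2, 2)  # in cells; stride is fixed at 1 cell
    orientations: int = 9

    def __post_init__(self) -> None:
        if self.window[0] % self.cell[0] or self.window[1] % self.cell[1]:
            raise ParameterError(
                f"window {self.window} must be divisible by cell {self.cell}"
            )
        if self.orientations < 1:
            raise ParameterError("orientations must be >= 1")

    @property
    def descriptor_length(self) -> int:
        cells_y = self.window[0] // self.cell[0]
        cells_x = self.window[1] // self.cell[1]
        blocks_y = cells_y - self.block[0] + 1
        blocks_x = cells_x - self.block[1] + 1
        return blocks_y * blocks_x * self.block[0] * self.block[1] * self.orientations


def hog_features(pixels: np.ndarray, config: HogConfig | None = None) -> np.ndarray:
    """Block-normalized gradient-orientation descriptor of one image.

    The image is bilinearly resized to the configured window, then the HOG
    descriptor is computed with unsigned gradients (0-180 degrees) and
    L2-Hys normalization. Default geometry yields exactly 3780 values.
    """
    config = config or HogConfig()
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ShapeError(f"expected a nonempty 2-D image, got shape {pixels.shape}")
    if pixels.shape != config.window:
        pixels = resize(pixels, config.window, order=1, mode="reflect",
                        anti_aliasing=False, preserve_range=True)
    return hog(
        pixels,
        orientations=config.orientations,
        pixels_per_cell=config.cell,
        cells_per_block=config.block,
        block_norm="L2-Hys",
        feature_vector=True,
    )


def deep_features(pixels: np.ndarray, backbone: RandomConvBackbone) -> np.ndarray:
    """2048-d penultimate-layer embedding; deterministic for fixed weights."""
    return backbone.extract(pixels)


def fuse(deep: np.ndarray, hog_vec: np.ndarray) -> np.ndarray:
    """Concatenate deep-first into the 5828-d fused vector (no rescaling)."""
    deep = np.asarray(deep, dtype=np.float64)
    hog_vec = np.asarray(hog_vec, dtype=np.float64)
    if deep.shape != (DEEP_DIM,):
        raise ShapeError(f"deep features must have length {DEEP_DIM}, got {deep.shape}")
    if hog_vec.shape != (HOG_DIM,):
        raise ShapeError(f"HOG features must have length {HOG_DIM}, got {hog_vec.shape}")
    fused = np.concatenate([deep, hog_vec])
    if not np.all(np.isfinite(fused)):
        raise ParameterError("fused feature vector contains non-finite entries")
    return fused


def fused_feature_matrix(
    images: np.ndarray,
    backbone: RandomConvBackbone,
    hog_config: HogConfig | None = None,
) -> np.ndarray:
    """Fused features for a stack of images: (N, H, W) -> (N, 5828)."""
    images = np.asarray(images, dtype=np.float64)
    deep = backbone.extract(images)
    hogs = np.stack([hog_features(img, hog_config) for img in images])
    return np.hstack([deep, hogs])
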