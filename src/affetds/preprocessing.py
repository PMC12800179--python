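"""Canonical preprocessing applied before feature extraction or attacks.

Pipeline (order pinned): bilinear resize to the target grid, per-image
min-max normalization to [0, 1], Gaussian denoising (sigma = 1.5 px,
reflective boundaries), final clip to [0, 1]. A constant image min-max
normalizes to all zeros by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from ._exceptions import ParameterError, ShapeError

_INTERP_ORDERS = {"nearest": 0, "bilinear": 1, "bicubic": 3}


@dataclass
class PreprocessConfig:
    """Target geometry and denoising strength.

    size: output side length in pixels (square grid).
    sigma: Gaussian denoising width in pixels; 0 disables the blur.
    interp: resize interpolation ("bilinear" by default).
    """

    size: int = 224
    sigma: float = 1.5
    interp: str = "bilinear"

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ParameterError(f"preprocess.size must be positive, got {self.size}")
        if self.sigma < 0:
            raise ParameterError(f"preprocess.sigma must be >= 0, got {self.sigma}")
        if self.interp not in _INTERP_ORDERS:
            raise ParameterError(
                f"preprocess.interp must be one of {sorted(_INTERP_ORDERS)}, got {self.interp!r}"
            )


def preprocess(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Resize, min-max normalize, and denoise one grayscale image.

    Parameters
    ----------
    image : ndarray, shape (H, W)
        Nonempty grayscale image with nonnegative finite intensities.
    config : PreprocessConfig, optional

    Returns
    -------
    ndarray of float64, shape (size, size), values in [0, 1].
    """
    config = config or PreprocessConfig()
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ShapeError(f"expected a nonempty 2-D image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ParameterError("image contains non-finite values")
    if image.min() < 0:
        raise ParameterError("image intensities must be nonnegative")

    out = image
    if out.shape != (config.size, config.size):
        out = resize(
            out,
            (config.size, config.size),
            order=_INTERP_ORDERS[config.interp],
            mode="reflect",
            anti_aliasing=False,
            preserve_range=True,
        )
    lo, hi = float(out.min()), float(out.max())
    if hi > lo:
        out = (out - lo) / (hi - lo)
    else:
        out = np.zeros_like(out)  # constant image convention
    if config.sigma > 0:
        out = ndimage.gaussian_filter(out, config.sigma, mode="reflect")
    return np.clip(out, 0.0, 1.0)
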