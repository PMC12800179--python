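"""Synthetic brain-phantom corpus with ground-truth tumor manipulations.

Real forged-MRI corpora are built from clinical archives plus undisclosed
editing tools, so this module emulates the statistical task instead: it draws
brain-like 2-D phantoms (elliptical head, bright skull rim, ventricles,
band-limited tissue texture) and produces two kinds of subtle local edits with
known ground truth:

* **insertion** — an irregular, textured, feather-blended blob mimicking an
  artificial tumor;
* **removal** — classical inpainting of a region by boundary-ring fill,
  matched-variance texture synthesis, and affine intensity renormalization,
  mimicking tumor-removal edits.

Everything is deterministic under a fixed seed, so corpora are reproducible
byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from ._exceptions import NoSurroundingTissueError, ParameterError, PlacementError, ShapeError
from .data import (
    LABEL_MANIPULATED,
    LABEL_REAL,
    DatasetManifest,
    ImageSample,
    ManifestRecord,
    save_png,
)

# Corpus composition emulated by default: 774 genuine + 604 altered scans.
DEFAULT_N_REAL = 774
DEFAULT_N_MANIPULATED = 604
DEFAULT_N_TOTAL = DEFAULT_N_REAL + DEFAULT_N_MANIPULATED

_TISSUE = 0.55
_RIM = 0.80
_VENTRICLE = 0.35


@dataclass
class PhantomParams:
    """Geometry and texture of one synthetic head phantom.

    size is the square image side in pixels; head_axes are the (row, col)
    semi-axes of the head ellipse; texture_amplitude scales the band-limited
    tissue texture (0 gives a piecewise-constant image); background_level is
    the intensity outside the head.
    """

    size: int = 224
    head_axes: tuple[float, float] = (88.0, 72.0)
    texture_amplitude: float = 0.06
    background_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ParameterError(f"phantom size must be >= 64, got {self.size}")
        if min(self.head_axes) <= 0:
            raise ParameterError(f"head axes must be positive, got {self.head_axes}")
        if self.texture_amplitude < 0 or self.background_level < 0:
            raise ParameterError("amplitudes and background level must be >= 0")


@dataclass
class TumorParams:
    """Shape and appearance of one synthetic tumor.

    center/radii are in pixels (row, col); boundary_irregularity in [0, 1]
    warps the ellipse outline with random low-order harmonics;
    intensity_offset is the signed brightness change of the lesion relative
    to surrounding tissue; texture_amplitude adds interior texture.
    """

    center: tuple[float, float]
    radii: tuple[float, float] = (10.0, 10.0)
    boundary_irregularity: float = 0.3
    intensity_offset: float = 0.25
    texture_amplitude: float = 0.03

    def __post_init__(self) -> None:
        if min(self.radii) <= 0:
            raise ParameterError(f"tumor radii must be positive, got {self.radii}")
        if not 0.0 <= self.boundary_irregularity <= 1.0:
            raise ParameterError("boundary_irregularity must be in [0, 1]")
        if self.texture_amplitude < 0:
            raise ParameterError("texture_amplitude must be >= 0")


#: Gaussian sigma (pixels) of the feathered blend at the tumor boundary.
FEATHER_SIGMA = 2.0
#: Kernel truncation used for the feather; support radius = ceil 2*2 = 4 px.
_FEATHER_TRUNCATE = 2.0
FEATHER_RADIUS = int(_FEATHER_TRUNCATE * FEATHER_SIGMA + 0.5)
#: Width (pixels) of the boundary ring used for inpainting statistics.
RING_WIDTH = 5


def _band_limited_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float = 6.0) -> np.ndarray:
    """Unit-std low-pass filtered white noise (the tissue texture prior)."""
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    std = noise.std()
    return noise / std if std > 0 else noise


def generate_phantom(params: PhantomParams) -> ImageSample:
    """Draw one genuine head phantom.

    The image is a piecewise composition — dark background, tissue-level head
    ellipse, brighter skull rim band, darker ventricle pair — plus band-limited
    texture inside the head scaled by ``texture_amplitude``. With zero texture
    amplitude the result is exactly piecewise constant. Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n = params.size
    cy = n / 2 + rng.uniform(-4, 4)
    cx = n / 2 + rng.uniform(-4, 4)
    ay = params.head_axes[0] * (n / 224.0) * rng.uniform(0.95, 1.05)
    ax = params.head_axes[1] * (n / 224.0) * rng.uniform(0.95, 1.05)
    ay = min(ay, n / 2 - 2)
    ax = min(ax, n / 2 - 2)
    theta = rng.uniform(-0.15, 0.15)

    rows, cols = np.mgrid[0:n, 0:n].astype(np.float64)
    dy, dx = rows - cy, cols - cx
    ry = dy * math.cos(theta) - dx * math.sin(theta)
    rx = dy * math.sin(theta) + dx * math.cos(theta)
    d = np.sqrt((ry / ay) ** 2 + (rx / ax) ** 2)

    img = np.full((n, n), params.background_level)
    head = d <= 1.0
    img[head] = _TISSUE
    img[(d >= 0.92) & head] = _RIM

    # Ventricle pair: two small dark ellipses flanking the midline.
    for side in (-1.0, 1.0):
        vy = cy - 0.12 * ay
        vx = cx + side * 0.18 * ax
        vd = ((rows - vy) / (0.22 * ay)) ** 2 + ((cols - vx) / (0.10 * ax)) ** 2
        img[(vd <= 1.0) & (d <= 0.85)] = _VENTRICLE

    if params.texture_amplitude > 0:
        texture = _band_limited_noise(rng, (n, n)) * params.texture_amplitude
        img = np.where(head, img + texture, img)

    img = np.clip(img, 0.0, 1.0)
    return ImageSample(id=f"phantom-{params.seed}", pixels=img, label=LABEL_REAL, provenance="phantom")


def _tumor_mask(shape: tuple[int, int], tumor: TumorParams, rng: np.random.Generator) -> np.ndarray:
    """Rasterize the irregular tumor outline as a boolean mask.

    The outline is an ellipse whose radius is modulated by random 2nd-5th
    order harmonics, scaled so the warp never exceeds half the base radius.
    """
    cy, cx = tumor.center
    ry, rx = tumor.radii
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    dy, dx = rows - cy, cols - cx
    ang = np.arctan2(dy, dx)
    warp = np.zeros_like(ang)
    if tumor.boundary_irregularity > 0:
        orders = (2, 3, 4, 5)
        amps = rng.uniform(-1, 1, len(orders))
        phases = rng.uniform(0, 2 * np.pi, len(orders))
        for order, amp, phase in zip(orders, amps, phases):
            warp += amp * np.cos(order * ang + phase)
        peak = np.max(np.abs(warp))
        if peak > 0:
            warp = warp / peak * 0.5 * tumor.boundary_irregularity
    radial = np.sqrt((dy / ry) ** 2 + (dx / rx) ** 2)
    return radial <= 1.0 + warp


def insert_tumor(sample: ImageSample, tumor: TumorParams, seed: int = 0) -> ImageSample:
    """Blend an artificial tumor into a genuine phantom.

    The lesion interior is surrounding-tissue intensity plus
    ``intensity_offset`` and band-limited texture; the blend weight is the
    tumor mask feathered with a 2-px Gaussian (truncated at 4 px), so pixels
    farther than :data:`FEATHER_RADIUS` from the mask are untouched. The
    returned sample is labeled manipulated and carries the binary
    (pre-feather) mask.
    """
    if sample.label != LABEL_REAL:
        raise ParameterError("insert_tumor expects a genuine (label='real') sample")
    rng = np.random.default_rng(seed)
    src = sample.pixels
    mask = _tumor_mask(src.shape, tumor, rng)
    if not mask.any():
        raise PlacementError("tumor mask is empty (radii too small for the grid?)")

    pad = FEATHER_RADIUS + 1
    rr, cc = np.nonzero(mask)
    if (
        rr.min() < pad
        or cc.min() < pad
        or rr.max() >= src.shape[0] - pad
        or cc.max() >= src.shape[1] - pad
    ):
        raise PlacementError("tumor extends outside the image interior")
    # The lesion must sit on tissue, not background: demand bright support.
    if np.mean(src[mask] > 0.25) < 0.9:
        raise PlacementError("tumor region falls outside the head tissue")

    feather = ndimage.gaussian_filter(mask.astype(np.float64), FEATHER_SIGMA, truncate=_FEATHER_TRUNCATE)
    feather = np.clip(feather, 0.0, 1.0)
    base = float(src[mask].mean()) + tumor.intensity_offset
    lesion = np.full_like(src, base)
    if tumor.texture_amplitude > 0:
        lesion = lesion + _band_limited_noise(rng, src.shape, sigma=2.0) * tumor.texture_amplitude
    out = np.clip((1.0 - feather) * src + feather * lesion, 0.0, 1.0)
    return ImageSample(
        id=sample.id, pixels=out, label=LABEL_MANIPULATED, mask=mask, provenance="inserted"
    )


def remove_tumor(sample: ImageSample, region_mask: np.ndarray, seed: int = 0) -> ImageSample:
    """Erase a region by classical inpainting.

    The region is (a) filled from the mean of a surrounding boundary ring,
    (b) given additive band-limited texture rescaled to the ring's standard
    deviation, and (c) affinely renormalized so the region mean/std match the
    ring's. Pixels outside the region are untouched. Degenerate rings
    (constant surroundings) refill with the constant.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != sample.pixels.shape:
        raise ShapeError(
            f"region mask shape {region_mask.shape} != image shape {sample.pixels.shape}"
        )
    if not region_mask.any():
        raise ParameterError("region mask is empty")
    ring = ndimage.binary_dilation(region_mask, iterations=RING_WIDTH) & ~region_mask
    if not ring.any():
        raise NoSurroundingTissueError("mask covers the whole image; no surrounding tissue to sample")

    rng = np.random.default_rng(seed)
    src = sample.pixels
    ring_mean = float(src[ring].mean())
    ring_std = float(src[ring].std())

    values = np.full(int(region_mask.sum()), ring_mean)
    if ring_std > 0:
        texture = _band_limited_noise(rng, src.shape, sigma=1.5)[region_mask]
        t_std = texture.std()
        if t_std > 0:
            values = values + (texture - texture.mean()) / t_std * ring_std
        # Affine renormalization: force region mean/std onto the ring's.
        v_std = values.std()
        if v_std > 0:
            values = (values - values.mean()) / v_std * ring_std + ring_mean

    out = src.copy()
    out[region_mask] = values
    out = np.clip(out, 0.0, 1.0)
    return ImageSample(
        id=sample.id, pixels=out, label=LABEL_MANIPULATED, mask=region_mask, provenance="removed"
    )


@dataclass
class CorpusParams:
    """Composition and geometry of a generated corpus.

    Defaults emulate the 1378-scan study corpus: 774 genuine + 604 altered,
    altered split evenly between insertion and removal edits (remainder to
    insertion).
    """

    n_total: int = DEFAULT_N_TOTAL
    real_fraction: float = DEFAULT_N_REAL / DEFAULT_N_TOTAL
    insert_fraction: float = 0.5
    image_size: int = 224
    phantom: PhantomParams = field(default_factory=PhantomParams)

    def counts(self) -> tuple[int, int, int]:
        """(n_real, n_inserted, n_removed) under round-half-up on real count."""
        if self.n_total < 2:
            raise ParameterError("corpus needs at least 2 samples")
        n_real = int(math.floor(self.n_total * self.real_fraction + 0.5))
        n_real = min(max(n_real, 1), self.n_total - 1)
        n_manip = self.n_total - n_real
        n_removed = int(math.floor(n_manip * (1.0 - self.insert_fraction)))
        n_inserted = n_manip - n_removed  # remainder goes to insertion
        return n_real, n_inserted, n_removed


def _random_tumor(rng: np.random.Generator, size: int) -> TumorParams:
    """Draw tumor parameters varying in size, shape, location, and polarity."""
    scale = size / 224.0
    center = (
        size / 2 + rng.uniform(-0.45, 0.45) * 60 * scale,
        size / 2 + rng.uniform(-0.45, 0.45) * 50 * scale,
    )
    radii = (rng.uniform(10, 22) * scale, rng.uniform(10, 22) * scale)
    sign = -1.0 if rng.random() < 0.25 else 1.0
    return TumorParams(
        center=center,
        radii=radii,
        boundary_irregularity=rng.uniform(0.2, 0.6),
        intensity_offset=sign * rng.uniform(0.20, 0.35),
        texture_amplitude=0.03,
    )


def _make_manipulated(rng: np.random.Generator, params: CorpusParams, kind: str, seed: int) -> ImageSample:
    phantom_params = PhantomParams(
        size=params.image_size,
        head_axes=params.phantom.head_axes,
        texture_amplitude=params.phantom.texture_amplitude,
        background_level=params.phantom.background_level,
        seed=seed,
    )
    phantom = generate_phantom(phantom_params)
    for _ in range(20):  # resample until the tumor lands on tissue
        tumor = _random_tumor(rng, params.image_size)
        try:
            inserted = insert_tumor(phantom, tumor, seed=int(rng.integers(0, 2**31)))
        except PlacementError:
            continue
        if kind == "inserted":
            return inserted
        return remove_tumor(inserted, inserted.mask, seed=int(rng.integers(0, 2**31)))
    raise PlacementError("could not place a tumor inside the head after 20 attempts")


def build_default_corpus(
    seed: int,
    out_dir: Optional[str | Path] = None,
    params: Optional[CorpusParams] = None,
) -> DatasetManifest:
    """Generate the full synthetic corpus (default: 1378 samples, 774 real).

    With ``out_dir`` set, images are written as 8-bit grayscale PNGs under
    ``out_dir/images`` (manipulation masks under ``images/masks``) and the
    manifest as ``out_dir/manifest.csv``; pixel data is additionally kept
    in memory on the returned manifest either way. Fully deterministic for a
    fixed seed.
    """
    params = params or CorpusParams()
    n_real, n_inserted, n_removed = params.counts()
    rng = np.random.default_rng(seed)
    phantom_seeds = rng.integers(0, 2**31, size=n_real + n_inserted + n_removed)

    records: list[ManifestRecord] = []
    samples: dict[str, ImageSample] = {}
    idx = 0
    for kind, count in (("phantom", n_real), ("inserted", n_inserted), ("removed", n_removed)):
        for i in range(count):
            sample_seed = int(phantom_seeds[idx])
            idx += 1
            if kind == "phantom":
                phantom_params = PhantomParams(
                    size=params.image_size,
                    head_axes=params.phantom.head_axes,
                    texture_amplitude=params.phantom.texture_amplitude,
                    background_level=params.phantom.background_level,
                    seed=sample_seed,
                )
                sample = generate_phantom(phantom_params)
            else:
                sample = _make_manipulated(rng, params, kind, sample_seed)
            sid = f"{kind[:3]}_{i:04d}"
            sample.id = sid
            path = f"images/{sid}.png"
            records.append(ManifestRecord(id=sid, path=path, label=sample.label, provenance=kind))
            samples[sid] = sample

    manifest = DatasetManifest(records=records, samples=samples)
    if out_dir is not None:
        out = Path(out_dir)
        (out / "images" / "masks").mkdir(parents=True, exist_ok=True)
        for record in records:
            sample = samples[record.id]
            save_png(sample.pixels, out / record.path)
            if sample.mask is not None and sample.mask.any():
                save_png(sample.mask.astype(np.float64), out / "images" / "masks" / f"{record.id}.png")
        manifest.save(out / "manifest.csv")
    return manifest


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(
    manifest: DatasetManifest,
    fractions: Sequence[float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> DatasetManifest:
    """Assign train/val/test splits preserving the class ratio.

    Per class, ids are shuffled with the given seed; the test and validation
    counts are round-half-up of their fractions of the class size and the
    training split takes the remainder. With the default 70/15/15 fractions a
    774/604 corpus yields splits of 964/207/207.
    """
    if len(fractions) != 3:
        raise ParameterError("fractions must be (train, val, test)")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ParameterError(f"fractions must sum to 1, got {sum(fractions)}")
    if any(f < 0 for f in fractions):
        raise ParameterError("fractions must be nonnegative")
    _, f_val, f_test = fractions
    counts = manifest.class_counts()
    if min(counts.values()) < 1:
        raise ParameterError("stratified split needs at least one sample per class")

    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for label in sorted(counts):
        ids = [r.id for r in manifest.records if r.label == label]
        rng.shuffle(ids)
        n = len(ids)
        n_test = _round_half_up(f_test * n)
        n_val = _round_half_up(f_val * n)
        if n_test + n_val > n:
            raise ParameterError(f"class {label!r} too small for the requested fractions")
        for sid in ids[: n - n_val - n_test]:
            assignment[sid] = "train"
        for sid in ids[n - n_val - n_test : n - n_test]:
            assignment[sid] = "val"
        for sid in ids[n - n_test :]:
            assignment[sid] = "test"

    records = [
        ManifestRecord(r.id, r.path, r.label, assignment[r.id], r.provenance)
        for r in manifest.records
    ]
    return DatasetManifest(records=records, samples=dict(manifest.samples))
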