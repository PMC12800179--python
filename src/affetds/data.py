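"""Core data containers: image samples and dataset manifests.

An :class:`ImageSample` is one grayscale 2-D image with its forgery label and,
for manipulated samples, the ground-truth mask of the edited region. A
:class:`DatasetManifest` is the roster of samples in a corpus with their
train/val/test split assignments, serialized as a plain CSV with header
``id,path,label,split,provenance``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from PIL import Image

from ._exceptions import ParameterError, ShapeError

LABEL_REAL = "real"
LABEL_MANIPULATED = "manipulated"
LABELS = (LABEL_REAL, LABEL_MANIPULATED)
SPLITS = ("train", "val", "test")

MANIFEST_COLUMNS = ["id", "path", "label", "split", "provenance"]


@dataclass
class ImageSample:
    """One grayscale image with label, optional manipulation mask, and id.

    Attributes
    ----------
    id : str
        Unique identifier within a corpus.
    pixels : ndarray of float, shape (H, W)
        Intensities in [0, 1].
    label : {"real", "manipulated"}
    mask : ndarray of bool, shape (H, W), optional
        True over the manipulated region. Present and nonempty iff the label
        is "manipulated".
    provenance : {"phantom", "inserted", "removed", ...}
        How the sample was produced. Adversarial copies append the attack
        name (e.g. "inserted+fgsm").
    """

    id: str
    pixels: np.ndarray
    label: str
    mask: Optional[np.ndarray] = None
    provenance: str = "phantom"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ShapeError(f"pixels must be a nonempty 2-D array, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ParameterError(f"sample {self.id!r}: pixels contain non-finite values")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ParameterError(f"sample {self.id!r}: intensities outside [0, 1] (min={lo}, max={hi})")
        if self.label not in LABELS:
            raise ParameterError(f"sample {self.id!r}: label must be one of {LABELS}, got {self.label!r}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise ShapeError(
                    f"sample {self.id!r}: mask shape {self.mask.shape} != pixels shape {self.pixels.shape}"
                )
        if self.mask is not None:
            # When a mask travels with the sample it must agree with the label.
            has_region = bool(self.mask.any())
            if self.label == LABEL_MANIPULATED and not has_region:
                raise ParameterError(f"sample {self.id!r}: manipulated samples need a nonempty mask")
            if self.label == LABEL_REAL and has_region:
                raise ParameterError(f"sample {self.id!r}: real samples must not carry a nonempty mask")

    def with_pixels(self, pixels: np.ndarray, provenance: Optional[str] = None) -> "ImageSample":
        """Copy with replaced pixel grid (label/mask preserved)."""
        return replace(self, pixels=pixels, provenance=provenance or self.provenance)


@dataclass
class ManifestRecord:
    id: str
    path: str
    label: str
    split: str = ""
    provenance: str = "phantom"


@dataclass
class DatasetManifest:
    """Roster of corpus samples with split assignments.

    Round-trips through CSV (``id,path,label,split,provenance``). The
    ``samples`` mapping optionally keeps in-memory pixel data for corpora
    that were never written to disk.
    """

    records: list[ManifestRecord] = field(default_factory=list)
    samples: dict[str, ImageSample] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ParameterError("manifest ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def class_counts(self, split: Optional[str] = None) -> dict[str, int]:
        counts = {lab: 0 for lab in LABELS}
        for r in self.records:
            if split is None or r.split == split:
                counts[r.label] += 1
        return counts

    def subset(self, split: str) -> "DatasetManifest":
        recs = [r for r in self.records if r.split == split]
        samples = {r.id: self.samples[r.id] for r in recs if r.id in self.samples}
        return DatasetManifest(records=recs, samples=samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.id, r.path, r.label, r.split, r.provenance) for r in self.records],
            columns=MANIFEST_COLUMNS,
        )

    def save(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "DatasetManifest":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
        if missing:
            raise ParameterError(f"manifest {path} lacks columns: {missing}")
        records = [ManifestRecord(*row) for row in frame[MANIFEST_COLUMNS].itertuples(index=False)]
        return cls(records=records)

    def load_sample(self, record: ManifestRecord, root: str | os.PathLike = ".") -> ImageSample:
        """Materialize one sample, from memory if available else from its PNG."""
        if record.id in self.samples:
            return self.samples[record.id]
        path = Path(root) / record.path
        pixels = load_png(path)
        mask = None
        mask_path = path.parent / "masks" / path.name
        if mask_path.exists():
            mask = load_png(mask_path) > 0.5
        return ImageSample(record.id, pixels, record.label, mask, record.provenance)

    def iter_samples(self, root: str | os.PathLike = ".") -> Iterable[ImageSample]:
        for record in self.records:
            yield self.load_sample(record, root)


def save_png(pixels: np.ndarray, path: str | os.PathLike) -> None:
    """Write a [0,1] float image as 8-bit grayscale PNG (lossless)."""
    arr = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255.0).astype(np.uint8), mode="L").save(path)


def load_png(path: str | os.PathLike) -> np.ndarray:
    """Read an 8-bit grayscale PNG into a [0,1] float array."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"), dtype=np.float64)
    return arr / 255.0
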