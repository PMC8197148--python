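"""Reading image patches, dataset manifests, grayscale conversion and blank-space QC.

Patches follow the public IDC breast-histopathology layout: small RGB tiles
(nominally 50x50 px) sorted into class directories named ``"0"`` (IDC negative)
and ``"1"`` (IDC positive).  Any other directory name leaves the patch
unlabelled.  A :class:`Manifest` is the flat, deterministic listing of such a
tree and round-trips through a small CSV (``path,label,source_id``).

The blank-space fraction is a quality-control statistic: patches dominated by
near-white or near-black pixels carry almost no tissue texture and are known
to be misclassified far more often than textured ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

log = logging.getLogger(__name__)

#: file suffixes accepted as patch images
IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")

#: a gray image is an H x W uint8 array with values in [0, 255]
GrayImage = np.ndarray


class EmptyDatasetError(RuntimeError):
    """Raised when a dataset root contains no decodable image."""


class ImageFormatError(ValueError):
    """Raised when a file cannot be decoded as an 8-bit RGB image."""


@dataclass
class ImagePatch:
    """A small RGB raster with an optional binary class label.

    ``pixels`` is H x W x 3 uint8; ``label`` is 0 (IDC negative) or
    1 (IDC positive) when known; ``source_id`` is an opaque identifier.
    """

    pixels: np.ndarray
    label: Optional[int] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] < 2 or p.shape[1] < 2:
            raise ValueError(f"patch must be H x W x 3 with H, W >= 2, got shape {p.shape}")
        if p.dtype != np.uint8:
            if p.min() < 0 or p.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            p = p.astype(np.uint8)
        self.pixels = p
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class Manifest:
    """Deterministic listing of a patch dataset: ``(path, label, source_id)`` records."""

    records: list[tuple[str, Optional[int], str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for _, label, _ in self.records:
            if label is not None:
                counts[label] = counts.get(label, 0) + 1
        return counts

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.records, columns=["path", "label", "source_id"])
        df.to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Manifest":
        df = pd.read_csv(path, dtype={"path": str, "source_id": str})
        if list(df.columns) != ["path", "label", "source_id"]:
            raise ValueError(f"malformed manifest header: {list(df.columns)}")
        records = [
            (row.path, None if pd.isna(row.label) else int(row.label), row.source_id)
            for row in df.itertuples()
        ]
        return cls(records=records)


def _label_from_dir(path: Path) -> Optional[int]:
    name = path.parent.name
    return int(name) if name in ("0", "1") else None


def read_patch(path: str | Path) -> ImagePatch:
    """Read a PNG/JPEG patch; the label comes from a parent directory named 0 or 1."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with Image.open(path) as im:
            rgb = im.convert("RGB")
            pixels = np.asarray(rgb, dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise ImageFormatError(f"cannot decode {path}: {exc}") from exc
    return ImagePatch(pixels=pixels, label=_label_from_dir(path), source_id=path.stem)


def scan_dataset(root: str | Path) -> Manifest:
    """List every decodable image under ``root`` in lexicographic order.

    Labels are taken from the immediate parent directory when it is named
    ``"0"`` or ``"1"``; ``source_id`` is the POSIX relative path without the
    suffix, so identifiers stay unique across class directories.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    records: list[tuple[str, Optional[int], str]] = []
    for path in sorted(root.rglob("*")):
        if not path.is_file() or path.suffix.lower() not in IMAGE_SUFFIXES:
            continue
        try:
            with Image.open(path) as im:
                im.verify()
        except (UnidentifiedImageError, OSError):
            log.warning("skipping undecodable image %s", path)
            continue
        rel = path.relative_to(root)
        records.append((str(path), _label_from_dir(path), rel.with_suffix("").as_posix()))
    manifest = Manifest(records=records)
    if not records:
        raise EmptyDatasetError(f"no decodable images under {root}")
    counts = manifest.class_counts
    if len(counts) == 1:
        log.warning("dataset under %s contains a single class: %s", root, counts)
    return manifest


def to_gray(patch: ImagePatch) -> GrayImage:
    """BT.601 luma: Y = round(0.299 R + 0.587 G + 0.114 B), half away from zero."""
    rgb = patch.pixels.astype(np.float64)
    y = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.clip(np.floor(y + 0.5), 0, 255).astype(np.uint8)


def resize_patch(patch: ImagePatch, size: int) -> ImagePatch:
    """Bilinearly resize an off-size patch to ``size`` x ``size`` (logged)."""
    if patch.shape == (size, size):
        return patch
    log.warning("resizing patch %s from %s to %dx%d", patch.source_id, patch.shape, size, size)
    im = Image.fromarray(patch.pixels).resize((size, size), Image.BILINEAR)
    return ImagePatch(np.asarray(im, dtype=np.uint8), label=patch.label, source_id=patch.source_id)


def blankspace_fraction(patch: ImagePatch, white_thr: int = 240, black_thr: int = 15) -> float:
    """Fraction of pixels that are near-white plus near-black.

    A pixel is near-white when every channel is >= ``white_thr`` and near-black
    when every channel is <= ``black_thr``.
    """
    if not (0 <= black_thr < white_thr <= 255):
        raise ValueError(f"need 0 <= black_thr < white_thr <= 255, got ({white_thr}, {black_thr})")
    px = patch.pixels
    white = np.all(px >= white_thr, axis=2)
    black = np.all(px <= black_thr, axis=2)
    return float(white.mean() + black.mean())
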