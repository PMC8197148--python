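"""Two-class synthetic H&E-like texture patches for download-free testing.

The public IDC patch dataset cannot be bundled, so this module generates
50x50 RGB patches whose two classes differ in second-order (co-occurrence)
statistics, the property the texture pipeline is built to detect:

* class 0 ("smooth", emulating stroma-dominated IDC-negative tiles):
  low-pass-filtered Gaussian noise -- locally smooth, low GLCM contrast;
* class 1 ("speckled", emulating nucleus-dense IDC-positive tiles):
  high-frequency speckle of dense dark blobs on a lighter ground -- high
  GLCM contrast and entropy.

Both classes share a multiplicative H&E-like purple tint so the RGB-to-gray
path is exercised nontrivially.  Every patch is a pure function of
``(seed, class_id, index)``; the whole dataset is a pure function of the
config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .patch_io import ImagePatch, Manifest, scan_dataset

log = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """Generator settings.

    ``class0_smoothness`` is the Gaussian blur radius (px) of the smooth
    class; ``class1_grain`` the speckle correlation length (px) of the dense
    class; ``contrast_gap`` the minimum difference in direction-averaged GLCM
    contrast (64 gray levels, distance 1) the two classes are designed to
    show; ``base_color`` the H&E-like tint applied multiplicatively.
    """

    n_per_class: int = 200
    patch_size: int = 50
    seed: int = 1
    class0_smoothness: float = 3.0
    class1_grain: float = 1.5
    contrast_gap: float = 50.0
    base_color: tuple[int, int, int] = (210, 170, 220)

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.patch_size < 8:
            raise ValueError("patch_size must be >= 8")
        if self.contrast_gap <= 0:
            raise ValueError("contrast_gap must be > 0")


def _patch_rng(cfg: SyntheticConfig, class_id: int, index: int) -> np.random.Generator:
    # per-patch stream: reproducible regardless of generation order
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(class_id, index)))


def _luminance_field(class_id: int, cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    s = cfg.patch_size
    if class_id == 0:
        g = gaussian_filter(rng.standard_normal((s, s)), sigma=cfg.class0_smoothness, mode="reflect")
        sd = g.std()
        if sd > 0:
            g = g / sd
        return np.clip(0.74 + 0.08 * g, 0.08, 0.97)
    # class 1: threshold a short-range correlated field into dark blobs (~45% cover)
    u = gaussian_filter(rng.standard_normal((s, s)), sigma=cfg.class1_grain / 2.0, mode="reflect")
    mask = u < np.quantile(u, 0.45)
    jitter = 0.05 * rng.standard_normal((s, s))
    lum = np.where(mask, 0.34, 0.84) + jitter
    return np.clip(lum, 0.08, 0.97)


def generate_patch(class_id: int, cfg: SyntheticConfig, index: int) -> ImagePatch:
    """Deterministically generate one labelled patch for ``(seed, class_id, index)``."""
    if class_id not in (0, 1):
        raise ValueError("class_id must be 0 or 1")
    rng = _patch_rng(cfg, class_id, index)
    lum = _luminance_field(class_id, cfg, rng)
    color = np.asarray(cfg.base_color, dtype=np.float64)
    pixels = np.clip(np.floor(lum[:, :, None] * color[None, None, :] + 0.5), 0, 255)
    return ImagePatch(
        pixels=pixels.astype(np.uint8),
        label=class_id,
        source_id=f"synth_{class_id}_{index:04d}",
    )


def generate_dataset(cfg: SyntheticConfig, out_dir: str | Path) -> Manifest:
    """Write ``n_per_class`` PNGs per class into ``0``/``1`` subdirs and scan them back.

    Re-running with the same config overwrites with byte-identical files, and
    the returned manifest is exactly ``patch_io.scan_dataset(out_dir)``.
    """
    out_dir = Path(out_dir)
    for class_id in (0, 1):
        sub = out_dir / str(class_id)
        sub.mkdir(parents=True, exist_ok=True)
        for index in range(cfg.n_per_class):
            patch = generate_patch(class_id, cfg, index)
            Image.fromarray(patch.pixels).save(sub / f"{patch.source_id}.png")
    log.info("wrote %d synthetic patches per class under %s", cfg.n_per_class, out_dir)
    return scan_dataset(out_dir)
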