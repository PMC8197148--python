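"""Keypoint descriptor extraction and fixed-length 256-dim aggregation.

Three descriptor families feed the fused feature vector:

* **SIFT** -- difference-of-Gaussians keypoints with 128-d gradient-histogram
  descriptors (scikit-image implementation);
* **SURF** -- a SURF-style Hessian/Haar backend implemented here:
  determinant-of-Hessian blob detection and an upright 4x4-subregion
  Haar-response descriptor in extended 128-d mode;
* **ORB** -- FAST keypoints with 256-bit binary BRIEF-style descriptors
  (scikit-image implementation), stored as 32 bytes per keypoint.

A patch yields a *variable* number of keypoints (possibly zero on blank
tissue), so each family is aggregated into exactly 256 per-image features:
real-valued 128-d descriptors become per-dimension mean concatenated with
per-dimension population standard deviation (128 + 128), and ORB's 256-bit
descriptors become per-bit frequency of ones.  Both schemes are invariant to
keypoint order and count, and a zero-keypoint patch maps to the zero vector
(the blank-space QC statistic is the intended flag for such patches).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.feature import ORB, SIFT, blob_doh

from .patch_io import GrayImage, ImagePatch, to_gray

log = logging.getLogger(__name__)

FAMILIES = ("SIFT", "SURF", "ORB")
FEATURE_LEN = 256


class BackendUnavailableError(RuntimeError):
    """Raised when no descriptor backend is registered for a family."""


@dataclass
class KeypointDescriptorSet:
    """All keypoints of one family on one image.

    ``descriptors`` is n_kp x 128 float for SIFT/SURF and n_kp x 32 uint8
    (packed 256-bit) for ORB; ``keypoints`` is n_kp x 4 ``(x, y, scale,
    orientation)``.
    """

    family: str
    descriptors: np.ndarray
    keypoints: np.ndarray

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        self.descriptors = np.asarray(self.descriptors)
        if self.descriptors.ndim != 2:
            raise ValueError("descriptors must be a 2-d matrix")
        width = 32 if self.family == "ORB" else 128
        if self.descriptors.shape[0] and self.descriptors.shape[1] != width:
            raise ValueError(
                f"{self.family} descriptors must have {width} columns, got {self.descriptors.shape[1]}"
            )

    @property
    def n_keypoints(self) -> int:
        return int(self.descriptors.shape[0])


@dataclass
class DescriptorFeature:
    """One family's 256 aggregated per-image features."""

    family: str
    values: np.ndarray
    n_keypoints_used: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (FEATURE_LEN,):
            raise ValueError(f"expected {FEATURE_LEN} values, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("aggregated features must be finite")


def _empty(family: str) -> KeypointDescriptorSet:
    width = 32 if family == "ORB" else 128
    dtype = np.uint8 if family == "ORB" else np.float64
    return KeypointDescriptorSet(family, np.empty((0, width), dtype=dtype), np.empty((0, 4)))


class DescriptorBackend(Protocol):
    family: str

    def detect_and_describe(self, gray: GrayImage) -> KeypointDescriptorSet: ...


class SiftBackend:
    """Difference-of-Gaussians SIFT via scikit-image; 128-d real descriptors."""

    family = "SIFT"

    def detect_and_describe(self, gray: GrayImage) -> KeypointDescriptorSet:
        sift = SIFT()
        try:
            sift.detect_and_extract(np.asarray(gray))
        except RuntimeError:  # no features found
            return _empty(self.family)
        kp = np.column_stack(
            [
                sift.keypoints[:, 1],  # x = column
                sift.keypoints[:, 0],  # y = row
                sift.scales,
                sift.orientations,
            ]
        )
        return KeypointDescriptorSet(self.family, sift.descriptors.astype(np.float64), kp)


class OrbBackend:
    """FAST + rotated-BRIEF via scikit-image; 256-bit descriptors packed to 32 bytes."""

    family = "ORB"

    def __init__(self, n_keypoints: int = 500, fast_threshold: float = 0.08) -> None:
        self.n_keypoints = n_keypoints
        self.fast_threshold = fast_threshold

    def detect_and_describe(self, gray: GrayImage) -> KeypointDescriptorSet:
        orb = ORB(n_keypoints=self.n_keypoints, fast_threshold=self.fast_threshold)
        try:
            orb.detect_and_extract(np.asarray(gray, dtype=np.float64) / 255.0)
        except (RuntimeError, IndexError):  # no features found
            return _empty(self.family)
        packed = np.packbits(orb.descriptors.astype(np.uint8), axis=1)  # MSB first
        kp = np.column_stack(
            [
                orb.keypoints[:, 1],
                orb.keypoints[:, 0],
                orb.scales,
                orb.orientations,
            ]
        )
        return KeypointDescriptorSet(self.family, packed, kp)


class HessianHaarBackend:
    """SURF-style detector/descriptor: det-of-Hessian blobs, Haar-response subregions.

    Keypoints are local maxima of the determinant of the Hessian across
    scales (``skimage.feature.blob_doh``).  Each keypoint is described
    upright (no orientation assignment) from a 16x16 window of first-order
    derivative responses: the window splits into 4x4 subregions and each
    subregion contributes the 8 extended sums

        sum dx | dy>=0,  sum dx | dy<0,  sum |dx| | dy>=0,  sum |dx| | dy<0,
        sum dy | dx>=0,  sum dy | dx<0,  sum |dy| | dx>=0,  sum |dy| | dx<0,

    giving 4 * 4 * 8 = 128 dimensions, L2-normalized per keypoint.  Fully
    deterministic and dependency-light.
    """

    family = "SURF"

    def __init__(
        self,
        min_sigma: float = 1.2,
        max_sigma: float = 6.0,
        num_sigma: int = 5,
        threshold: float = 0.001,
        window: int = 16,
    ) -> None:
        self.min_sigma = min_sigma
        self.max_sigma = max_sigma
        self.num_sigma = num_sigma
        self.threshold = threshold
        self.window = window

    def detect_and_describe(self, gray: GrayImage) -> KeypointDescriptorSet:
        img = np.asarray(gray, dtype=np.float64) / 255.0
        blobs = blob_doh(
            img,
            min_sigma=self.min_sigma,
            max_sigma=self.max_sigma,
            num_sigma=self.num_sigma,
            threshold=self.threshold,
        )
        if blobs.shape[0] == 0:
            return _empty(self.family)
        smooth = gaussian_filter(img, sigma=1.0, mode="reflect")
        dy, dx = np.gradient(smooth)
        half = self.window // 2
        dxp = np.pad(dx, half, mode="reflect")
        dyp = np.pad(dy, half, mode="reflect")
        cell = self.window // 4
        descriptors = []
        keypoints = []
        for y, x, sigma in blobs:
            r, c = int(round(y)) + half, int(round(x)) + half
            wx = dxp[r - half : r + half, c - half : c + half]
            wy = dyp[r - half : r + half, c - half : c + half]
            vec = np.empty(128)
            k = 0
            for a in range(4):
                for b in range(4):
                    sx = wx[a * cell : (a + 1) * cell, b * cell : (b + 1) * cell]
                    sy = wy[a * cell : (a + 1) * cell, b * cell : (b + 1) * cell]
                    pos_y, pos_x = sy >= 0, sx >= 0
                    vec[k : k + 8] = (
                        sx[pos_y].sum(),
                        sx[~pos_y].sum(),
                        np.abs(sx[pos_y]).sum(),
                        np.abs(sx[~pos_y]).sum(),
                        sy[pos_x].sum(),
                        sy[~pos_x].sum(),
                        np.abs(sy[pos_x]).sum(),
                        np.abs(sy[~pos_x]).sum(),
                    )
                    k += 8
            norm = np.linalg.norm(vec)
            if norm <= 1e-12:  # no gradient energy: flat region, not a keypoint
                continue
            descriptors.append(vec / norm)
            keypoints.append((x, y, sigma, 0.0))
        if not descriptors:
            return _empty(self.family)
        return KeypointDescriptorSet(self.family, np.asarray(descriptors), np.asarray(keypoints))


_DEFAULT_BACKENDS: dict[str, type] = {
    "SIFT": SiftBackend,
    "SURF": HessianHaarBackend,
    "ORB": OrbBackend,
}


def get_backend(family: str, **kwargs) -> DescriptorBackend:
    """Instantiate the registered default backend for a descriptor family."""
    try:
        return _DEFAULT_BACKENDS[family](**kwargs)
    except KeyError:
        raise BackendUnavailableError(f"no backend registered for family {family!r}") from None


def detect_and_describe(
    gray: GrayImage, family: str, backend: DescriptorBackend | None = None
) -> KeypointDescriptorSet:
    """Run one family's detector on a gray image (``n_kp`` may be zero)."""
    backend = backend or get_backend(family)
    if backend.family != family:
        raise BackendUnavailableError(f"backend serves {backend.family}, requested {family}")
    return backend.detect_and_describe(gray)


def aggregate_real(ds: KeypointDescriptorSet) -> DescriptorFeature:
    """mean (128) ++ population std (128) over keypoints; zero vector when n_kp = 0."""
    if ds.family not in ("SIFT", "SURF"):
        raise ValueError(f"aggregate_real expects SIFT/SURF, got {ds.family}")
    if ds.n_keypoints == 0:
        return DescriptorFeature(ds.family, np.zeros(FEATURE_LEN), 0)
    desc = ds.descriptors.astype(np.float64)
    values = np.concatenate([desc.mean(axis=0), desc.std(axis=0, ddof=0)])
    return DescriptorFeature(ds.family, values, ds.n_keypoints)


def aggregate_binary(ds: KeypointDescriptorSet) -> DescriptorFeature:
    """Per-bit frequency of ones over the unpacked 256-bit ORB descriptors."""
    if ds.family != "ORB":
        raise ValueError(f"aggregate_binary expects ORB, got {ds.family}")
    if ds.n_keypoints == 0:
        return DescriptorFeature(ds.family, np.zeros(FEATURE_LEN), 0)
    bits = np.unpackbits(ds.descriptors, axis=1)  # MSB first within each byte
    return DescriptorFeature(ds.family, bits.mean(axis=0), ds.n_keypoints)


def descriptor_features(
    patch: ImagePatch, family: str, backend: DescriptorBackend | None = None
) -> DescriptorFeature:
    """gray conversion -> detection -> family-appropriate 256-dim aggregation."""
    ds = detect_and_describe(to_gray(patch), family, backend)
    return aggregate_binary(ds) if family == "ORB" else aggregate_real(ds)
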