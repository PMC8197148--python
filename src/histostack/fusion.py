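"""Fusing the four feature families into one labelled table.

The full fused vector is 782-dimensional: 256 SIFT + 256 SURF + 256 ORB
aggregated descriptor features followed by the 14 direction-averaged Haralick
statistics, in that fixed order.  Any subset of families can be selected
(e.g. a 256-column SIFT-only table for standalone comparisons, or the
526-column no-SURF mode); the column count is always
``256 * n_descriptor_families + 14 * haralick_enabled``.

Tables are persisted as plain CSV: ``source_id`` first, feature columns,
integer ``label`` last.  Floats are written with full ``repr`` precision so a
write/read round-trip is lossless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import keypoints as kp
from .glcm import HARALICK_FEATURE_NAMES, haralick_patch
from .patch_io import ImagePatch, Manifest, read_patch, resize_patch

log = logging.getLogger(__name__)

ALL_FAMILIES = ("SIFT", "SURF", "ORB", "HARALICK")
FULL_DIM = 782  # 256 + 256 + 256 + 14


def feature_columns(families: Sequence[str] = ALL_FAMILIES) -> list[str]:
    """Ordered feature column names for the selected families."""
    cols: list[str] = []
    for fam in ALL_FAMILIES:
        if fam not in families:
            continue
        if fam == "HARALICK":
            cols.extend(f"har_{name}" for name in HARALICK_FEATURE_NAMES)
        else:
            cols.extend(f"{fam.lower()}_{i:03d}" for i in range(kp.FEATURE_LEN))
    return cols


@dataclass
class FusedFeatureRow:
    """One patch's concatenated features with its label and identifier."""

    values: np.ndarray
    label: Optional[int]
    source_id: str
    families: tuple[str, ...]


@dataclass
class FeatureTable:
    """Rectangular labelled feature table backed by a DataFrame.

    Columns are ``source_id``, the feature columns, and ``label`` (last).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.df.columns)
        if cols[0] != "source_id" or cols[-1] != "label":
            raise ValueError("table must have source_id first and label last")
        if len(set(cols)) != len(cols):
            raise ValueError("column names must be unique")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("source_id", "label")]

    @property
    def families(self) -> tuple[str, ...]:
        """Family mask inferred from the column-name prefixes."""
        present = []
        prefixes = {c.split("_", 1)[0] for c in self.feature_names}
        for fam in ALL_FAMILIES:
            key = "har" if fam == "HARALICK" else fam.lower()
            if key in prefixes:
                present.append(fam)
        return tuple(present)

    @property
    def X(self) -> np.ndarray:
        return self.df[self.feature_names].to_numpy(dtype=np.float64)

    @property
    def y(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=np.int64)

    @property
    def source_ids(self) -> list[str]:
        return self.df["source_id"].tolist()

    def restrict(self, families: Sequence[str]) -> "FeatureTable":
        """Project onto a subset of families (standalone / fusion comparison modes)."""
        cols = ["source_id", *feature_columns(families), "label"]
        missing = [c for c in cols if c not in self.df.columns]
        if missing:
            raise ValueError(f"table lacks columns for {families}: {missing[:3]}...")
        return FeatureTable(self.df[cols].copy())


def fuse(
    sift: Optional[kp.DescriptorFeature],
    surf: Optional[kp.DescriptorFeature],
    orb: Optional[kp.DescriptorFeature],
    har: Optional[np.ndarray],
) -> FusedFeatureRow:
    """Concatenate family features in the fixed [SIFT | SURF | ORB | Haralick] order.

    Absent slots are skipped (e.g. no-SURF mode gives 526 values); supplied
    descriptor features must sit in their own slot.
    """
    parts: list[np.ndarray] = []
    families: list[str] = []
    for slot, feat in (("SIFT", sift), ("SURF", surf), ("ORB", orb)):
        if feat is None:
            continue
        if feat.family != slot:
            raise ValueError(f"{feat.family} feature passed in the {slot} slot")
        parts.append(feat.values)
        families.append(slot)
    if har is not None:
        har = np.asarray(har, dtype=np.float64)
        if har.shape != (len(HARALICK_FEATURE_NAMES),):
            raise ValueError(f"expected 14 Haralick values, got shape {har.shape}")
        parts.append(har)
        families.append("HARALICK")
    if not parts:
        raise ValueError("at least one feature family is required")
    return FusedFeatureRow(np.concatenate(parts), None, "", tuple(families))


def extract_row(
    patch: ImagePatch,
    families: Sequence[str] = ALL_FAMILIES,
    glcm_levels: int = 64,
    glcm_distance: int = 1,
    backends: Optional[dict] = None,
) -> FusedFeatureRow:
    """Run the enabled extractors on one patch and fuse the results."""
    backends = backends or {}
    feats: dict[str, Optional[kp.DescriptorFeature]] = {f: None for f in ("SIFT", "SURF", "ORB")}
    for fam in ("SIFT", "SURF", "ORB"):
        if fam in families:
            feats[fam] = kp.descriptor_features(patch, fam, backends.get(fam))
    har = None
    if "HARALICK" in families:
        from .patch_io import to_gray

        har = haralick_patch(to_gray(patch), distance=glcm_distance, levels=glcm_levels)
    row = fuse(feats["SIFT"], feats["SURF"], feats["ORB"], har)
    row.label = patch.label
    row.source_id = patch.source_id
    return row


def build_table(
    manifest: Manifest,
    families: Sequence[str] = ALL_FAMILIES,
    patch_size: int = 50,
    glcm_levels: int = 64,
    glcm_distance: int = 1,
    backends: Optional[dict] = None,
) -> FeatureTable:
    """One fused row per manifest record, in manifest order; failures are skipped."""
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    if "SURF" not in families and any(f in families for f in ("SIFT", "ORB")):
        log.warning("SURF family disabled: running in %d-feature mode",
                    len(feature_columns(families)))
    cols = feature_columns(families)
    rows, labels, ids = [], [], []
    n_failed = 0
    for k, (path, label, source_id) in enumerate(manifest.records):
        try:
            patch = resize_patch(read_patch(path), patch_size)
            patch.label, patch.source_id = label, source_id
            row = extract_row(patch, families, glcm_levels, glcm_distance, backends)
        except Exception:  # noqa: BLE001 -- one bad patch must not kill the run
            log.exception("feature extraction failed for %s; row skipped", path)
            n_failed += 1
            continue
        rows.append(row.values)
        labels.append(label)
        ids.append(source_id)
        if (k + 1) % 1000 == 0:
            log.info("extracted %d / %d patches", k + 1, len(manifest))
    if n_failed:
        log.warning("skipped %d of %d patches due to extraction failures", n_failed, len(manifest))
    if not rows:
        raise ValueError("all rows failed feature extraction")
    df = pd.DataFrame(np.vstack(rows), columns=cols)
    df.insert(0, "source_id", ids)
    df["label"] = labels
    return FeatureTable(df)


def write_table(table: FeatureTable, path: str | Path) -> None:
    # %.17g round-trips any float64 exactly
    table.df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def read_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if not cols or cols[0] != "source_id" or cols[-1] != "label":
        raise ValueError(f"malformed feature table {path}: need source_id ... label columns")
    return FeatureTable(df)
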