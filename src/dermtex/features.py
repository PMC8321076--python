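"""Per-patch feature vectors and the on-disk feature table.

Each sampled window yields 28 features in a fixed order: ten on the
grayscale channel (the four first-order moments, min, max, and the four
aggregated co-occurrence descriptors) plus six first-order statistics for
each of the R, G and B channels.  A patch inherits the label of its source
image.  Datasets round-trip losslessly through CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import first_order, glcm
from .imaging import (DEFAULT_LEVELS, DEFAULT_PATCH_SIZE, Patch, RGBImage,
                      derive_seed, extract_patches, quantize, read_image)

_FO_NAMES = ("mean", "variance", "skewness", "kurtosis", "min", "max")
_TEXTURE_NAMES = ("energy", "entropy", "correlation", "contrast")

#: Fixed feature order shared by every vector in a dataset.
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"gray_{n}" for n in _FO_NAMES)
    + tuple(f"gray_{n}" for n in _TEXTURE_NAMES)
    + tuple(f"{ch}_{n}" for ch in ("r", "g", "b") for n in _FO_NAMES)
)

_META_COLUMNS = ("image_id", "x0", "y0", "label")

LABELS = ("melanoma", "nevus")
POSITIVE_LABEL = "melanoma"


@dataclass(frozen=True)
class FeatureVector:
    features: dict[str, float]
    label: str
    image_id: str
    patch_coords: tuple[int, int]


@dataclass
class FeatureDataset:
    """A labeled feature table backed by a pandas DataFrame.

    Columns are the metadata (`image_id`, `x0`, `y0`, `label`) followed by
    the feature columns in :data:`FEATURE_NAMES` order.
    """

    df: pd.DataFrame
    feature_names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def __post_init__(self) -> None:
        missing = [c for c in (*_META_COLUMNS, *self.feature_names)
                   if c not in self.df.columns]
        if missing:
            raise ValueError(f"feature table is missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def X(self) -> np.ndarray:
        return self.df[list(self.feature_names)].to_numpy(dtype=np.float64)

    @property
    def y(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    @property
    def image_ids(self) -> np.ndarray:
        return self.df["image_id"].to_numpy()

    @property
    def class_counts(self) -> dict[str, int]:
        return self.df["label"].value_counts().to_dict()

    def subset(self, mask) -> "FeatureDataset":
        return FeatureDataset(self.df.loc[mask].reset_index(drop=True),
                              self.feature_names)


def build_feature_vector(
    p: Patch,
    levels: int = DEFAULT_LEVELS,
    distances=glcm.DEFAULT_DISTANCES,
    angles=glcm.DEFAULT_ANGLES,
    symmetric: bool = True,
    label: str = "",
) -> FeatureVector:
    """Compute the 28-feature descriptor of one patch.

    Grayscale first-order moments are computed on the unquantized
    normalized values; the co-occurrence block is computed on the
    ``levels``-quantized grayscale; each RGB channel contributes its own
    first-order block on the [0, 1] scale.
    """
    feats: dict[str, float] = {}
    fo = first_order.first_order_features(p.gray.pixels)
    for name in _FO_NAMES:
        feats[f"gray_{name}"] = getattr(fo, name)
    tex = glcm.aggregate_texture(quantize(p.gray, levels),
                                 distances=distances, angles=angles,
                                 symmetric=symmetric)
    for name in _TEXTURE_NAMES:
        feats[f"gray_{name}"] = getattr(tex, name)
    for ci, ch in enumerate(("r", "g", "b")):
        channel = p.rgb.pixels[:, :, ci].astype(np.float64) / 255.0
        fo_ch = first_order.first_order_features(channel)
        for name in _FO_NAMES:
            feats[f"{ch}_{name}"] = getattr(fo_ch, name)
    return FeatureVector(features=feats, label=label, image_id=p.image_id,
                         patch_coords=(p.x0, p.y0))


def read_manifest(path) -> pd.DataFrame:
    """Load an image manifest CSV (columns: path, label, optional ROI corners)."""
    mf = pd.read_csv(path)
    required = {"path", "label"}
    missing = required - set(mf.columns)
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {sorted(missing)}")
    bad = set(mf["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"manifest {path} has unknown labels: {sorted(bad)}")
    return mf


def extract_dataset(
    manifest: pd.DataFrame,
    n_per_image: int = 10,
    patch_size: int = DEFAULT_PATCH_SIZE,
    seed: int = 0,
    levels: int = DEFAULT_LEVELS,
    distances=glcm.DEFAULT_DISTANCES,
    angles=glcm.DEFAULT_ANGLES,
) -> FeatureDataset:
    """Sample patches from every manifest image and assemble the feature table.

    Per-image sub-seeds are derived from the master seed and the image id,
    so manifest row order does not affect the result.  An unloadable image
    aborts the extraction (no silent skipping).
    """
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    rows = []
    for rec in manifest.to_dict("records"):
        img = read_image(rec["path"])
        # Key provenance and sub-seeds by the file stem, not the full path,
        # so a relocated dataset extracts identically.
        img = RGBImage(pixels=img.pixels, id=Path(rec["path"]).stem)
        roi = None
        if {"x0", "y0", "x1", "y1"} <= set(rec) and not pd.isna(rec.get("x0")):
            roi = (rec["x0"], rec["y0"], rec["x1"], rec["y1"])
        sub_seed = derive_seed(seed, "patches", img.id)
        patches = extract_patches(img, n=n_per_image, size=patch_size,
                                  seed=sub_seed, roi=roi)
        for p in patches:
            fv = build_feature_vector(p, levels=levels, distances=distances,
                                      angles=angles, label=rec["label"])
            rows.append({"image_id": fv.image_id, "x0": fv.patch_coords[0],
                         "y0": fv.patch_coords[1], "label": fv.label,
                         **fv.features})
    df = pd.DataFrame(rows, columns=[*_META_COLUMNS, *FEATURE_NAMES])
    return FeatureDataset(df)


def write_csv(ds: FeatureDataset, path) -> None:
    """Persist the feature table; floats keep full round-trip precision."""
    ds.df.to_csv(path, index=False, float_format="%.17g")


def read_csv(path) -> FeatureDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = [*_META_COLUMNS, *FEATURE_NAMES]
    if list(df.columns) != expected:
        missing = [c for c in expected if c not in df.columns]
        extra = [c for c in df.columns if c not in expected]
        raise ValueError(f"feature table {Path(path).name}: header mismatch "
                         f"(missing={missing}, extra={extra})")
    return FeatureDataset(df)
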