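"""Binary Random Forest classification of target species vs background.

The classifier follows the common remote-sensing defaults: 100 trees, Gini
impurity, square root of the number of features considered per split,
bootstrap sampling, no tuning and no class-balance correction.  Training
pixels inherit the label of their whole polygon — a target plot labels all
its pixels target regardless of its cover percentage, which is precisely
the design choice whose consequences the experiment measures.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .geo import GeoTransform
from .sampling import ReferencePolygon
from .scene import HyperCube

LABEL_BACKGROUND = 0
LABEL_TARGET = 1
LABEL_NODATA = 255


class LeakageError(RuntimeError):
    pass


@dataclass
class PixelDataset:
    """Per-pixel features and polygon-derived labels for one role."""

    features: np.ndarray       # (n_pixels, k)
    labels: np.ndarray         # (n_pixels,) in {0, 1}
    polygon_ids: np.ndarray    # (n_pixels,)
    role: str = "train"

    def __len__(self) -> int:
        return self.features.shape[0]


def assemble_pixel_dataset(mnf_cube: HyperCube,
                           polygons: Sequence[ReferencePolygon],
                           role: str) -> PixelDataset:
    """Stack every member pixel of every polygon with the given role."""
    if role not in ("train", "validation"):
        raise ValueError("role must be 'train' or 'validation'")
    rows, cols = mnf_cube.shape
    feats, labels, ids = [], [], []
    for poly in polygons:
        for r, c in poly.pixels:
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(
                    f"polygon {poly.id} has pixel ({r}, {c}) outside raster")
        px = np.array(poly.pixels)
        feats.append(mnf_cube.data[:, px[:, 0], px[:, 1]].T)
        lab = LABEL_TARGET if poly.klass == "target" else LABEL_BACKGROUND
        labels.append(np.full(len(px), lab, dtype=np.int64))
        ids.append(np.full(len(px), poly.id, dtype=np.int64))
    if not feats:
        return PixelDataset(np.empty((0, mnf_cube.n_bands)),
                            np.empty(0, dtype=np.int64),
                            np.empty(0, dtype=np.int64), role=role)
    features = np.vstack(feats)
    const = np.ptp(features, axis=0) == 0
    if features.shape[0] > 1 and np.any(const):
        warnings.warn(f"feature columns {np.nonzero(const)[0].tolist()} are "
                      "constant across all pixels", RuntimeWarning)
    return PixelDataset(features, np.concatenate(labels),
                        np.concatenate(ids), role=role)


def assert_no_leakage(train_polygons: Sequence[ReferencePolygon],
                      validation_polygons: Sequence[ReferencePolygon]) -> None:
    """Polygon-level leakage guard: a plot feeds training or validation, never both."""
    overlap = ({p.id for p in train_polygons}
               & {p.id for p in validation_polygons})
    if overlap:
        raise LeakageError(
            f"polygons {sorted(overlap)} appear in both training and validation")


def train_rf(dataset: PixelDataset, seed: int = 0) -> RandomForestClassifier:
    """Fit the 100-tree Gini Random Forest on polygon-labelled pixels."""
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    if np.unique(dataset.labels).size < 2:
        raise ValueError("training data contains a single class")
    model = RandomForestClassifier(n_estimators=100, criterion="gini",
                                   max_features="sqrt", bootstrap=True,
                                   random_state=seed, n_jobs=1)
    model.fit(dataset.features, dataset.labels)
    return model


@dataclass
class ClassifiedMap:
    """Binary presence-absence map plus the per-pixel tree-vote fraction."""

    labels: np.ndarray                 # (R, C) uint8: 0 bg, 1 target, 255 nodata
    probability: np.ndarray            # (R, C) float32, NaN at nodata
    gsd: float = 1.0
    transform: GeoTransform = field(default_factory=GeoTransform)
    threshold: float = 0.5

    @property
    def valid_mask(self) -> np.ndarray:
        return self.labels != LABEL_NODATA


def predict_map(model: RandomForestClassifier, mnf_cube: HyperCube,
                threshold: float = 0.5,
                pixels: np.ndarray | None = None,
                chunk: int = 200_000) -> ClassifiedMap:
    """Per-pixel vote fraction and thresholded presence-absence label.

    ``pixels`` optionally restricts prediction to an (n, 2) array of
    (row, col) indices; everything else is emitted as nodata.  Prediction is
    pixel-independent, so restricting the scope changes nothing about the
    predicted pixels themselves.
    """
    if model.n_features_in_ != mnf_cube.n_bands:
        raise ValueError(
            f"model expects {model.n_features_in_} bands, cube has "
            f"{mnf_cube.n_bands}")
    rows, cols = mnf_cube.shape
    labels = np.full((rows, cols), LABEL_NODATA, dtype=np.uint8)
    prob = np.full((rows, cols), np.nan, dtype=np.float32)

    if pixels is None:
        rr, cc = np.nonzero(~mnf_cube.nodata_mask)
    else:
        pixels = np.asarray(pixels)
        keep = ~mnf_cube.nodata_mask[pixels[:, 0], pixels[:, 1]]
        rr, cc = pixels[keep, 0], pixels[keep, 1]
    target_col = int(np.nonzero(model.classes_ == LABEL_TARGET)[0][0])
    for start in range(0, rr.size, chunk):
        sl = slice(start, start + chunk)
        X = mnf_cube.data[:, rr[sl], cc[sl]].T
        p = model.predict_proba(X)[:, target_col]
        prob[rr[sl], cc[sl]] = p
        labels[rr[sl], cc[sl]] = (p >= threshold).astype(np.uint8)
    return ClassifiedMap(labels=labels, probability=prob, gsd=mnf_cube.gsd,
                         transform=mnf_cube.transform, threshold=threshold)
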