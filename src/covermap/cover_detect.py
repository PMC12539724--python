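"""Ground-truth point purification, train/validation split, and the
binary with/without cover-crop classification.

The classifier is pluggable: the default is a random forest, and a pure
NDVI-threshold classifier is provided so that separable synthetic scenes
have an exact oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .errors import (
    DegenerateModelError,
    EmptyTrainingError,
    GridError,
    StratificationError,
)
from .grids import INT_NODATA, GridSpec

log = logging.getLogger(__name__)

COVER, NONE = "cover", "none"


@dataclass
class TrainingSet:
    """Labeled points with per-point feature values.

    ``points`` columns: x, y, label, one column per feature, and (after
    :func:`split_train_validation`) a ``split_tag`` in {train, validation}.
    """

    points: pd.DataFrame
    feature_names: tuple[str, ...]
    dropped_cover_points: int = 0

    def subset(self, tag: str) -> pd.DataFrame:
        return self.points[self.points["split_tag"] == tag]


@dataclass
class CoverRaster:
    """Binary cover map (1=cover, 0=none) over cultivated pixels only."""

    grid: np.ndarray
    year: int
    accuracy_report: pd.DataFrame | None = None

    @property
    def overall_accuracy(self) -> float | None:
        if self.accuracy_report is None:
            return None
        row = self.accuracy_report.loc[self.accuracy_report["class"] == "overall"]
        return float(row["accuracy"].iloc[0])

    def cover_acres(self, pixel_acres: float) -> float:
        return float((self.grid == 1).sum()) * pixel_acres


def _sample_features(points: pd.DataFrame, features: dict[str, np.ndarray],
                     spec: GridSpec) -> pd.DataFrame:
    out = points.copy()
    rows_cols = [spec.rowcol(x, y) for x, y in zip(out["x"], out["y"])]
    rows = np.array([rc[0] for rc in rows_cols], dtype=int)
    cols = np.array([rc[1] for rc in rows_cols], dtype=int)
    for name, layer in features.items():
        spec.check(layer)
        out[name] = layer[rows, cols]
    return out


def filter_training_points(points: pd.DataFrame, features: dict[str, np.ndarray],
                           spec: GridSpec, threshold: float = 0.3) -> TrainingSet:
    """Drop cover-labeled points whose pixel NDVI is not strictly above
    ``threshold``; none-labeled points are never filtered.

    ``features`` must contain an ``"ndvi"`` layer; extra layers are
    sampled alongside and become classifier features.
    """
    if "ndvi" not in features:
        raise KeyError("features must include an 'ndvi' layer")
    sampled = _sample_features(points, features, spec)
    is_cover = sampled["label"] == COVER
    keep = ~is_cover | (sampled["ndvi"] > threshold)
    dropped = int((~keep).sum())
    if dropped:
        log.info("filter_training_points: dropped %d/%d cover points at "
                 "NDVI <= %.2f", dropped, int(is_cover.sum()), threshold)
    retained = sampled[keep].reset_index(drop=True)
    if is_cover.any() and not (retained["label"] == COVER).any():
        raise EmptyTrainingError("all cover-labeled points fell below the "
                                 "NDVI threshold")
    return TrainingSet(points=retained, feature_names=tuple(features),
                       dropped_cover_points=dropped)


def split_train_validation(training: TrainingSet, fraction: float = 0.7,
                           seed: int = 0) -> TrainingSet:
    """Stratified train/validation split, deterministic per seed."""
    pts = training.points
    counts = pts["label"].value_counts()
    if (counts < 2).any():
        raise StratificationError(
            f"every label needs >= 2 points, got {counts.to_dict()}")
    pts = pts.copy()
    if fraction >= 1.0:
        warnings.warn("split fraction >= 1.0 leaves an empty validation set",
                      stacklevel=2)
        pts["split_tag"] = "train"
    else:
        train_idx, val_idx = train_test_split(
            pts.index.to_numpy(), train_size=fraction, random_state=seed,
            stratify=pts["label"])
        pts["split_tag"] = "validation"
        pts.loc[train_idx, "split_tag"] = "train"
    return TrainingSet(points=pts, feature_names=training.feature_names,
                       dropped_cover_points=training.dropped_cover_points)


class ThresholdClassifier:
    """Predict cover purely from NDVI > threshold; used as an oracle."""

    def __init__(self, threshold: float = 0.3):
        self.threshold = threshold

    def fit(self, X: np.ndarray, y: np.ndarray,
            feature_names: tuple[str, ...]) -> "ThresholdClassifier":
        self._ndvi_col = feature_names.index("ndvi")
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (X[:, self._ndvi_col] > self.threshold).astype(np.int8)


def _build_model(model_spec, seed: int):
    if model_spec in (None, "random_forest"):
        return RandomForestClassifier(n_estimators=100, random_state=seed,
                                      n_jobs=1)
    if model_spec == "threshold":
        return ThresholdClassifier()
    if isinstance(model_spec, dict) and model_spec.get("name") == "threshold":
        return ThresholdClassifier(threshold=model_spec.get("threshold", 0.3))
    if hasattr(model_spec, "fit") and hasattr(model_spec, "predict"):
        return model_spec
    raise ValueError(f"unknown model_spec {model_spec!r}")


def _accuracy_report(y_true: np.ndarray, y_pred: np.ndarray) -> pd.DataFrame:
    """Overall plus per-class user (precision) / producer (recall) accuracy."""
    rows = [dict(**{"class": "overall"},
                 accuracy=float((y_true == y_pred).mean()),
                 user_accuracy=np.nan, producer_accuracy=np.nan,
                 n=int(y_true.size))]
    for value, name in ((1, COVER), (0, NONE)):
        pred_v = y_pred == value
        true_v = y_true == value
        user = float((y_true[pred_v] == value).mean()) if pred_v.any() else np.nan
        producer = float((y_pred[true_v] == value).mean()) if true_v.any() else np.nan
        rows.append(dict(**{"class": name}, accuracy=np.nan,
                         user_accuracy=user, producer_accuracy=producer,
                         n=int(true_v.sum())))
    return pd.DataFrame(rows)


def train_and_classify(training: TrainingSet, features: dict[str, np.ndarray],
                       mask: np.ndarray, spec: GridSpec,
                       model_spec="random_forest", seed: int = 0,
                       year: int = 0) -> CoverRaster:
    """Fit the model on train points and predict over cultivated pixels.

    The accuracy report is computed on validation points only.  Masked
    pixels carry the nodata sentinel and can never hold a positive
    prediction.
    """
    pts = training.points
    if "split_tag" not in pts.columns:
        raise ValueError("call split_train_validation before training")
    train = pts[pts["split_tag"] == "train"]
    if train.empty:
        raise EmptyTrainingError("empty training subset")
    y_train = (train["label"] == COVER).to_numpy(dtype=np.int8)
    if np.unique(y_train).size < 2:
        raise DegenerateModelError("training subset has a single label")

    names = training.feature_names
    X_train = train[list(names)].to_numpy(dtype=float)
    model = _build_model(model_spec, seed)
    try:
        model.fit(X_train, y_train, feature_names=names)
    except TypeError:
        model.fit(X_train, y_train)

    for name, layer in features.items():
        spec.check(layer)
    if mask.shape != spec.shape:
        raise GridError("mask does not match grid")
    cult = mask == 1
    X_all = np.column_stack([features[n][cult] for n in names])
    grid = np.full(spec.shape, INT_NODATA, dtype=np.int32)
    grid[cult] = model.predict(X_all).astype(np.int32)

    report = None
    val = pts[pts["split_tag"] == "validation"]
    if not val.empty:
        y_val = (val["label"] == COVER).to_numpy(dtype=np.int8)
        pred_val = np.asarray(
            model.predict(val[list(names)].to_numpy(dtype=float)),
            dtype=np.int8)
        report = _accuracy_report(y_val, pred_val)
    return CoverRaster(grid=grid, year=year, accuracy_report=report)


def winter_wheat_grain_share(wheat_harvested_acres, total_cropland_acres):
    """Percent of cropland harvested as winter wheat for grain, per year.

    Used as a proxy for how much area the winter-wheat-as-cover-crop
    assumption could misattribute; reported standalone, never applied as
    a correction.
    """
    wheat = np.asarray(wheat_harvested_acres, dtype=float)
    total = np.asarray(total_cropland_acres, dtype=float)
    if np.any(wheat < 0) or np.any(total < 0):
        raise ValueError("acreages must be non-negative")
    if np.any(total == 0):
        raise ValueError("total cropland acres must be positive")
    return 100.0 * wheat / total
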