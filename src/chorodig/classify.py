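"""Random-forest classification of image objects by color.

Each image object is described by six features — per-band color mean and
standard deviation — and a random forest trained on a hand-labeled sample
of objects assigns a legend class to every object.  The pixel class layer
is derived from the object layer, so pixel and object classes always
agree.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .geo import Affine
from .legend import Legend
from .segmentation import SegmentMap

FEATURES = ["mean_R", "mean_G", "mean_B", "sd_R", "sd_G", "sd_B"]

#: provenance tags for how an object's class was decided
PROV_MODEL = "model"
PROV_RULE = "rule"
PROV_OVERRIDE = "override"
PROV_FALLBACK = "fallback-map"


@dataclass
class TrainingSet:
    """Hand-assigned classes for a sample of image objects."""

    labels: pd.Series  # index: object id, values: class_id

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels).astype(int)
        self.labels.index = self.labels.index.astype(int)
        self.labels.index.name = "object_id"
        self.labels.name = "class_id"

    def __len__(self) -> int:
        return len(self.labels)

    def validate(self, seg: SegmentMap) -> None:
        unknown = self.labels.index.difference(seg.objects.index)
        if len(unknown):
            raise ValueError(f"training object ids absent from segmentation: "
                             f"{sorted(unknown.tolist())[:10]}")

    def to_csv(self, path: str | Path) -> None:
        self.labels.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrainingSet":
        df = pd.read_csv(path)
        return cls(pd.Series(df["class_id"].values, index=df["object_id"].values))


@dataclass
class ClassifiedMap:
    """Per-pixel and per-object class assignment.

    ``classes`` is the per-pixel class raster (legend class ids; the
    legend's no-data id where nothing applies).  ``labels`` is the object
    id raster (0 = nodata).  ``object_classes``/``provenance`` are Series
    indexed by object id; every pixel's class equals its object's class.
    """

    classes: np.ndarray
    labels: np.ndarray
    object_classes: pd.Series
    provenance: pd.Series
    transform: Affine = field(default_factory=Affine.identity)
    crs: str = ""
    nodata_class: int = 0

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int16)
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.classes.shape != self.labels.shape:
            raise ValueError("class and label rasters must share a grid")
        self.object_classes = pd.Series(self.object_classes, dtype=int)
        self.provenance = pd.Series(self.provenance, dtype=object)

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    def copy(self) -> "ClassifiedMap":
        return ClassifiedMap(
            self.classes.copy(), self.labels.copy(),
            self.object_classes.copy(), self.provenance.copy(),
            self.transform, self.crs, self.nodata_class,
        )

    def pixel_class_counts(self) -> pd.Series:
        """Pixels per class over the whole raster."""
        flat = self.classes.ravel()
        vals, counts = np.unique(flat, return_counts=True)
        return pd.Series(counts, index=vals).rename_axis("class_id")


def class_raster_from_objects(
    labels: np.ndarray, object_classes: pd.Series, nodata_class: int
) -> np.ndarray:
    """Derive the pixel class layer from object classes via a lookup table."""
    nmax = int(labels.max(initial=0)) + 1
    lut = np.full(nmax, nodata_class, dtype=np.int16)
    if len(object_classes):
        lut[object_classes.index.to_numpy()] = object_classes.to_numpy()
    out = lut[labels]
    out[labels == 0] = nodata_class
    return out


class ObjectColorClassifier(BaseEstimator, ClassifierMixin):
    """Random forest over per-object color statistics.

    Parameters follow the usual forest conventions: ``n_estimators`` trees
    (default 500), sqrt-of-features splits, unlimited depth, and a
    mandatory ``random_state`` so a classification is exactly
    reproducible.  Out-of-bag accuracy is exposed as ``oob_score_`` after
    fitting.
    """

    def __init__(self, n_estimators: int = 500, max_features: str | int = "sqrt",
                 random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y) -> "ObjectColorClassifier":
        X = self._as_features(X)
        y = np.asarray(y)
        if len(X) == 0:
            raise ValueError("empty training set")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            oob_score=True,
            random_state=self.random_state,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            # tiny training sets can leave some samples with no OOB vote
            warnings.filterwarnings("ignore", message=".*out-of-bag.*")
            self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        self.oob_score_ = float(getattr(self.forest_, "oob_score_", float("nan")))
        self.feature_names_ = list(FEATURES)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        X = self._as_features(X)
        if len(X) == 0:
            return np.empty(0, dtype=self.classes_.dtype)
        return self.forest_.predict(X)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(self._as_features(X))

    @staticmethod
    def _as_features(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in FEATURES if c not in X.columns]
            if missing:
                raise ValueError(f"feature schema mismatch; missing {missing}")
            return X[FEATURES].to_numpy(float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or (X.size and X.shape[1] != len(FEATURES)):
            raise ValueError(
                f"expected {len(FEATURES)} color features, got shape {X.shape}"
            )
        return X


def train_classifier(
    objects: pd.DataFrame,
    train: TrainingSet,
    n_trees: int = 500,
    seed: int = 0,
    required_classes: Iterable[int] | None = None,
) -> ObjectColorClassifier:
    """Fit the object classifier from a labeled sample of image objects.

    ``required_classes`` lists the legend classes the model is expected to
    predict; any of them with zero training examples raises an error
    naming the class.
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    present = set(train.labels.unique().tolist())
    if required_classes is not None:
        missing = sorted(set(int(c) for c in required_classes) - present)
        if missing:
            raise ValueError(f"no training objects for classes {missing}")
    ids = train.labels.index
    unknown = ids.difference(objects.index)
    if len(unknown):
        raise ValueError(f"training ids not in object table: "
                         f"{sorted(unknown.tolist())[:10]}")
    X = objects.loc[ids, FEATURES]
    clf = ObjectColorClassifier(n_estimators=n_trees, random_state=seed)
    return clf.fit(X, train.labels.to_numpy())


def predict_classes(
    model: ObjectColorClassifier,
    seg: SegmentMap,
    legend: Legend,
) -> ClassifiedMap:
    """Assign every image object its majority-vote class; derive pixel layer."""
    objects = seg.objects
    if len(objects) == 0:
        empty = pd.Series(dtype=int)
        return ClassifiedMap(
            np.full(seg.labels.shape, legend.nodata_id, np.int16),
            seg.labels, empty, pd.Series(dtype=object),
            seg.transform, seg.crs, legend.nodata_id,
        )
    pred = model.predict(objects)
    object_classes = pd.Series(pred.astype(int), index=objects.index)
    bad = set(object_classes.unique()) - set(legend.class_ids)
    if bad:
        raise ValueError(f"model predicts classes absent from legend: {sorted(bad)}")
    classes = class_raster_from_objects(seg.labels, object_classes, legend.nodata_id)
    prov = pd.Series(PROV_MODEL, index=objects.index, dtype=object)
    return ClassifiedMap(classes, seg.labels, object_classes, prov,
                         seg.transform, seg.crs, legend.nodata_id)


def vote_fractions(model: ObjectColorClassifier, objects: pd.DataFrame) -> pd.DataFrame:
    """Per-object class vote fractions, for optional manual review."""
    proba = model.predict_proba(objects)
    return pd.DataFrame(proba, index=objects.index, columns=model.classes_)


def save_model(model: ObjectColorClassifier, path: str | Path,
               legend: Legend | None = None) -> None:
    """Persist a fitted model plus a JSON sidecar (seed, features, legend hash)."""
    import joblib

    path = Path(path)
    joblib.dump(model, path)
    sidecar = {
        "seed": model.random_state,
        "n_estimators": model.n_estimators,
        "features": FEATURES,
        "oob_score": getattr(model, "oob_score_", None),
        "legend_hash": None if legend is None else hash(
            tuple((c.class_id, c.color) for c in legend)
        ) & 0xFFFFFFFF,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> ObjectColorClassifier:
    import joblib

    return joblib.load(path)
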