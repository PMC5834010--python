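"""Three-class nucleus classification (cancer / stromal / lymphocyte).

Each segmented nucleus is summarised by seven morphology and intensity
features and classified with an RBF support-vector machine trained on
labelled examples (about 1000 per class in the intended regime).  Features
are standardised with constants stored in the trained model so that
prediction is self-contained.
"""
from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.measure import regionprops
from sklearn.svm import SVC

from .config import CELL_CLASSES
from .errors import ContractViolation, TrainingError
from .segmentation import NucleusObject

FEATURE_NAMES = (
    "area_um2",
    "eccentricity",
    "solidity",
    "equivalent_diameter_um",
    "mean_haematoxylin_od",
    "sd_haematoxylin_od",
    "circularity",
)

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class NucleusFeatureVector:
    area_um2: float
    eccentricity: float
    solidity: float
    equivalent_diameter_um: float
    mean_haematoxylin_od: float
    sd_haematoxylin_od: float
    circularity: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def extract_features(obj: NucleusObject, haematoxylin: np.ndarray,
                     microns_per_pixel: float) -> NucleusFeatureVector:
    """Morphology from the pixel mask, intensity statistics from the channel.

    Circularity is 4*pi*A/P^2 (1 for a disc), clipped to [0, 1] because the
    pixelated perimeter estimate can slightly exceed the continuous bound.
    """
    if obj.n_pixels == 0:
        raise ContractViolation("cannot extract features from an empty mask")
    coords = obj.coords
    rmin, cmin = coords.min(axis=0)
    local = np.zeros((coords[:, 0].max() - rmin + 1, coords[:, 1].max() - cmin + 1), dtype=np.uint8)
    local[coords[:, 0] - rmin, coords[:, 1] - cmin] = 1
    props = regionprops(local)[0]

    mpp = microns_per_pixel
    area_um2 = props.area * mpp * mpp
    perimeter = props.perimeter
    circularity = 1.0 if perimeter == 0 else min(1.0, 4.0 * math.pi * props.area / perimeter**2)
    vals = haematoxylin[coords[:, 0], coords[:, 1]].astype(float)
    return NucleusFeatureVector(
        area_um2=area_um2,
        eccentricity=float(props.eccentricity),
        solidity=float(props.solidity),
        equivalent_diameter_um=float(props.equivalent_diameter_area) * mpp,
        mean_haematoxylin_od=float(vals.mean()),
        sd_haematoxylin_od=float(vals.std()),
        circularity=float(circularity),
    )


def features_to_matrix(features: Sequence[NucleusFeatureVector]) -> np.ndarray:
    if len(features) == 0:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.vstack([f.as_array() for f in features])


@dataclass
class TrainedClassifier:
    """A fitted SVM plus the standardisation constants it was trained with."""

    svc: SVC
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    classes: tuple[str, ...] = CELL_CLASSES
    n_per_class: dict = field(default_factory=dict)
    seed: int = 0

    def _standardise(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != len(self.feature_mean):
            raise ContractViolation(
                f"feature dimensionality {X.shape[1]} != trained {len(self.feature_mean)}"
            )
        return (X - self.feature_mean) / self.feature_scale

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict(self._standardise(X))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self._standardise(X))

    def save(self, path) -> None:
        payload = {
            "format_version": _MODEL_FORMAT_VERSION,
            "svc": self.svc,
            "feature_mean": self.feature_mean,
            "feature_scale": self.feature_scale,
            "classes": self.classes,
            "n_per_class": self.n_per_class,
            "seed": self.seed,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        with open(Path(path), "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != _MODEL_FORMAT_VERSION:
            raise TrainingError(f"unsupported model format {payload.get('format_version')!r}")
        return cls(
            svc=payload["svc"],
            feature_mean=payload["feature_mean"],
            feature_scale=payload["feature_scale"],
            classes=tuple(payload["classes"]),
            n_per_class=payload["n_per_class"],
            seed=payload["seed"],
        )


def train_classifier(
    features,
    labels: Sequence[str],
    C: float = 1.0,
    gamma: str | float = "scale",
    seed: int = 0,
) -> TrainedClassifier:
    """Fit the 3-class RBF SVM (one-vs-one) on standardised features.

    All three classes must be present.  A feature that is constant in the
    training set is standardised with scale 1 (it carries no information;
    dividing by its zero spread would be undefined).
    """
    X = features if isinstance(features, np.ndarray) else features_to_matrix(features)
    y = np.asarray(labels, dtype=object)
    if len(X) != len(y):
        raise TrainingError("features and labels differ in length")
    present = set(y)
    missing = set(CELL_CLASSES) - present
    if missing:
        raise TrainingError(f"classes missing from training data: {sorted(missing)}")
    unknown = present - set(CELL_CLASSES)
    if unknown:
        raise TrainingError(f"unknown labels: {sorted(unknown)}")
    if any((y == c).sum() < 2 for c in CELL_CLASSES):
        raise TrainingError("need at least 2 examples per class")
    if not np.all(np.isfinite(X)):
        raise TrainingError("features must be finite")

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    svc = SVC(kernel="rbf", C=C, gamma=gamma, decision_function_shape="ovo",
              random_state=seed)
    svc.fit((X - mean) / scale, y)
    counts = {c: int((y == c).sum()) for c in CELL_CLASSES}
    return TrainedClassifier(svc=svc, feature_mean=mean, feature_scale=scale,
                             n_per_class=counts, seed=seed)


def classify_cells(clf: TrainedClassifier, features) -> list[str]:
    """One predicted class per input feature vector, in input order."""
    X = features if isinstance(features, np.ndarray) else features_to_matrix(features)
    if len(X) == 0:
        return []
    if not np.all(np.isfinite(X)):
        raise ContractViolation("features must be finite")
    return [str(c) for c in clf.predict(X)]


def predictions_to_frame(objects: Sequence[NucleusObject], labels: Sequence[str]) -> pd.DataFrame:
    """Predictions CSV layout: cell_id, x_um, y_um, predicted_class."""
    return pd.DataFrame(
        {
            "cell_id": np.arange(len(objects)),
            "x_um": [o.centroid_um[0] for o in objects],
            "y_um": [o.centroid_um[1] for o in objects],
            "predicted_class": list(labels),
        }
    )
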