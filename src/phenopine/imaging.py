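"""Seedling/background coverage inside the spectroradiometer footprint.

During each spectral measurement an RGB photograph of the fibre-optic
field of view is taken.  The footprint is the circle of radius
``distance * tan(FOV/2)`` around the marked optical-cable centre;
supervised k-nearest-neighbour classification of pixel colours into
seedling vs black background yields the coverage fractions C1, C2 used
by the spectral unmixing correction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "FovGeometry",
    "PixelTrainingSet",
    "CoverageEstimate",
    "fov_radius_cm",
    "train_pixel_classifier",
    "classify_pixels",
    "coverage_fractions",
    "estimate_coverage",
]

SEEDLING = "seedling"
BACKGROUND = "background"


def fov_radius_cm(distance_cm: float, full_angle_deg: float) -> float:
    """Footprint radius of a conical field of view on a plane target.

    ``radius = distance * tan(full_angle / 2)``.  The study geometry
    (24 cm working distance, 25 degree fibre-optic FOV) gives 5.3 cm.
    """
    if distance_cm <= 0:
        raise ValueError(f"distance must be positive, got {distance_cm}")
    if not 0 <= full_angle_deg < 180:
        raise ValueError(f"full angle must be in [0, 180) deg, got {full_angle_deg}")
    return distance_cm * math.tan(math.radians(full_angle_deg) / 2.0)


@dataclass(frozen=True)
class FovGeometry:
    """Photograph-to-footprint geometry.

    ``pixels_per_cm`` comes from the calibration photo (ruler sheet at
    the working distance); ``center_px`` is the marked cable centre as
    (row, col).
    """

    distance_cm: float = 24.0
    full_angle_deg: float = 25.0
    pixels_per_cm: float = 10.0
    center_px: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.distance_cm <= 0 or self.pixels_per_cm <= 0:
            raise ValueError("distance_cm and pixels_per_cm must be positive")
        if not 0 < self.full_angle_deg < 180:
            raise ValueError("full_angle_deg must be in (0, 180)")

    @property
    def radius_px(self) -> float:
        return fov_radius_cm(self.distance_cm, self.full_angle_deg) * self.pixels_per_cm


@dataclass(frozen=True)
class PixelTrainingSet:
    """Labelled pixel colours for the two-class segmentation.

    Features are per-pixel colour channels scaled to [0, 1]; labels are
    ``'seedling'`` or ``'background'``.
    """

    features: np.ndarray
    labels: np.ndarray
    source_images: tuple = ()

    def __post_init__(self):
        feats = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels)
        if feats.ndim != 2:
            raise ValueError("features must be (n_pixels, n_channels)")
        if feats.shape[0] != labels.shape[0]:
            raise ValueError("label count must equal feature count")
        if len(np.unique(labels)) < 2:
            raise ValueError("training set must contain both classes")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_csv(cls, path) -> "PixelTrainingSet":
        df = pd.read_csv(path)
        return cls(df[["r", "g", "b"]].to_numpy() , df["label"].to_numpy(), (str(path),))

    def balanced(self, rng: np.random.Generator) -> "PixelTrainingSet":
        """Subsample to equal class counts (optional; off by default)."""
        labs, counts = np.unique(self.labels, return_counts=True)
        n = counts.min()
        keep = np.concatenate([
            rng.choice(np.flatnonzero(self.labels == lab), n, replace=False)
            for lab in labs
        ])
        keep.sort()
        return PixelTrainingSet(self.features[keep], self.labels[keep], self.source_images)


@dataclass(frozen=True)
class CoverageEstimate:
    """Seedling/background fractions inside the FOV circle."""

    c_seedling: float
    c_background: float
    n_pixels_in_circle: int

    def __post_init__(self):
        if not (0 <= self.c_seedling <= 1 and 0 <= self.c_background <= 1):
            raise ValueError("coverage fractions must lie in [0, 1]")
        if abs(self.c_seedling + self.c_background - 1.0) > 1e-9:
            raise ValueError("coverage fractions must sum to 1")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"c_seedling": self.c_seedling,
                 "c_background": self.c_background,
                 "n_pixels_in_circle": self.n_pixels_in_circle},
                fh, indent=2,
            )


class PixelClassifier:
    """Deterministic kNN wrapper over colour space.

    Prediction order-invariance: with an odd ``k`` and two classes the
    vote cannot tie; residual distance ties at the k-th neighbour are
    irrelevant for well-separated colour clusters.
    """

    def __init__(self, knn: KNeighborsClassifier, n_features: int):
        self._knn = knn
        self.n_features = n_features

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.shape[1] != self.n_features:
            raise ValueError(
                f"query has {features.shape[1]} channels, classifier was "
                f"trained on {self.n_features}"
            )
        proba = self._knn.predict_proba(features)
        classes = np.asarray(self._knn.classes_)
        # argmax on probabilities breaks any residual vote tie by class
        # name order (classes_ is sorted), deterministically
        return classes[np.argmax(proba, axis=1)]


def train_pixel_classifier(train: PixelTrainingSet, k: int = 5) -> PixelClassifier:
    """Fit a k-nearest-neighbour pixel classifier (Euclidean, colour space)."""
    if k < 1 or k % 2 == 0:
        raise ValueError(f"k must be an odd positive integer, got {k}")
    if k > train.features.shape[0]:
        raise ValueError(f"k={k} exceeds training size {train.features.shape[0]}")
    knn = KNeighborsClassifier(n_neighbors=k, metric="euclidean", algorithm="brute")
    knn.fit(train.features, train.labels)
    return PixelClassifier(knn, train.features.shape[1])


def _as_float_image(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 3:
        raise ValueError("expected an (H, W, channels) colour image")
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    return arr.astype(float)


def classify_pixels(image, classifier: PixelClassifier) -> np.ndarray:
    """Label every pixel of an RGB image as seedling or background."""
    arr = _as_float_image(image)
    h, w, c = arr.shape
    labels = classifier.predict(arr.reshape(-1, c))
    return labels.reshape(h, w)


def circle_mask(shape: tuple[int, int], center_px, radius_px: float) -> np.ndarray:
    """Pixels whose centre lies strictly inside the circle."""
    rows = np.arange(shape[0])[:, None] - center_px[0]
    cols = np.arange(shape[1])[None, :] - center_px[1]
    return rows * rows + cols * cols < radius_px * radius_px


def coverage_fractions(mask: np.ndarray, geometry: FovGeometry) -> CoverageEstimate:
    """Coverage fractions from a label mask restricted to the FOV circle.

    ``mask`` is either a boolean array (True = seedling) or a string
    label mask.  Only pixels inside the footprint circle count.
    """
    mask = np.asarray(mask)
    if mask.dtype.kind in "US":
        seedling = mask == SEEDLING
    else:
        seedling = mask.astype(bool)
    inside = circle_mask(seedling.shape, geometry.center_px, geometry.radius_px)
    n = int(inside.sum())
    if n == 0:
        raise ValueError("FOV circle does not cover any pixel of the image")
    c1 = float(seedling[inside].sum()) / n
    return CoverageEstimate(c1, 1.0 - c1, n)


def estimate_coverage(
    image, classifier: PixelClassifier, geometry: FovGeometry
) -> CoverageEstimate:
    """Classify an image and measure coverage inside the footprint."""
    return coverage_fractions(
        classify_pixels(image, classifier) == SEEDLING, geometry
    )


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))
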