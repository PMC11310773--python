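"""Maximum-entropy pixel classification for vegetation coverage.

Each pixel is described by nine color features — normalized R, G, B plus
their HSV and CIELAB transforms (sRGB, D65 white point) — and classified by
a multinomial logistic (maximum-entropy) model trained on user-labeled
pixel samples, up to five classes.  Coverage is the fraction of classified
pixels whose class belongs to a designated vegetation subset.  Classes are
separable only by color: objects that match the soil (or each other) in
color cannot be told apart by this model.

The training contract is the L2-penalized multinomial maximum-likelihood
estimate on standardized features; the objective is

    (1/N) * sum_i -log p(y_i | x_i; W) + (l2_strength / 2) * ||W||^2

with the intercepts unpenalized.  Any convex solver reaching that optimum
is acceptable; we use scikit-learn's lbfgs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import color as skcolor
from sklearn.linear_model import LogisticRegression

from plotpheno.geodata import OrthoImage

MAX_CLASSES = 5
DEFAULT_L2 = 1e-4
UNLABELED = -1

FEATURE_NAMES = ("r", "g", "b", "h", "s", "v", "L", "a_star", "b_star")


def rgb_to_hsv(r, g, b):
    """Hexcone HSV from 8-bit RGB; h in [0, 1) with red at 0, h = 0 when s = 0."""
    rgb = np.stack(
        [np.asarray(r, float), np.asarray(g, float), np.asarray(b, float)], axis=-1
    ) / 255.0
    hsv = skcolor.rgb2hsv(rgb)
    return hsv[..., 0], hsv[..., 1], hsv[..., 2]


def rgb_to_lab(r, g, b):
    """CIELAB (D65, 2 degree observer) from 8-bit sRGB."""
    rgb = np.stack(
        [np.asarray(r, float), np.asarray(g, float), np.asarray(b, float)], axis=-1
    ) / 255.0
    lab = skcolor.rgb2lab(rgb)
    return lab[..., 0], lab[..., 1], lab[..., 2]


def color_features(r, g, b) -> np.ndarray:
    """Stack the 9 color features (R, G, B, H, S, V, L, a*, b*) for 8-bit inputs.

    Output shape is ``input_shape + (9,)``.
    """
    r = np.asarray(r, float)
    g = np.asarray(g, float)
    b = np.asarray(b, float)
    h, s, v = rgb_to_hsv(r, g, b)
    L, a_star, b_star = rgb_to_lab(r, g, b)
    return np.stack([r / 255.0, g / 255.0, b / 255.0, h, s, v, L, a_star, b_star], axis=-1)


@dataclass
class TrainingSet:
    """Labeled pixel color samples for 2-5 classes."""

    classes: list[str]
    features: np.ndarray  # (N, 9)
    labels: np.ndarray  # (N,) indices into classes

    def __post_init__(self) -> None:
        if not 2 <= len(self.classes) <= MAX_CLASSES:
            raise ValueError(f"between 2 and {MAX_CLASSES} classes are required")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("class labels must be unique")
        counts = np.bincount(self.labels, minlength=len(self.classes))
        if (counts == 0).any():
            empty = [c for c, n in zip(self.classes, counts) if n == 0]
            raise ValueError(f"classes with no samples: {empty}")

    @classmethod
    def from_rgb(cls, classes: list[str], rgb_per_class) -> "TrainingSet":
        """Build from per-class lists of (r, g, b) 8-bit triples."""
        feats, labels = [], []
        for k, samples in enumerate(rgb_per_class):
            arr = np.asarray(samples, dtype=float)
            feats.append(color_features(arr[:, 0], arr[:, 1], arr[:, 2]))
            labels.append(np.full(len(arr), k))
        return cls(classes=list(classes), features=np.vstack(feats), labels=np.concatenate(labels))

    @classmethod
    def from_csv(cls, path) -> "TrainingSet":
        """Read ``class_label,r,g,b`` rows of user-marked pixels."""
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
        classes = list(dict.fromkeys(df["class_label"].astype(str)))
        index = {c: k for k, c in enumerate(classes)}
        feats = color_features(
            df["r"].to_numpy(float), df["g"].to_numpy(float), df["b"].to_numpy(float)
        )
        labels = df["class_label"].astype(str).map(index).to_numpy()
        return cls(classes=classes, features=feats, labels=labels)


@dataclass
class CoverageModel:
    """Trained multinomial max-ent classifier over standardized color features.

    ``weights`` is (n_classes, 9) and ``intercepts`` (n_classes,) in softmax
    form: ``p_k propto exp(w_k . x_std + b_k)``.
    """

    classes: list[str]
    weights: np.ndarray
    intercepts: np.ndarray
    feature_means: np.ndarray
    feature_scales: np.ndarray
    vegetation_classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        unknown = set(self.vegetation_classes) - set(self.classes)
        if unknown:
            raise ValueError(f"vegetation classes not in model classes: {sorted(unknown)}")

    def _scores(self, features: np.ndarray) -> np.ndarray:
        X = (features - self.feature_means) / self.feature_scales
        return X @ self.weights.T + self.intercepts

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for (N, 9) feature rows."""
        s = self._scores(np.atleast_2d(features))
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Argmax class indices; ties resolved toward the earlier class."""
        return np.argmax(self._scores(np.atleast_2d(features)), axis=1)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "weights": self.weights.tolist(),
            "intercepts": self.intercepts.tolist(),
            "feature_means": self.feature_means.tolist(),
            "feature_scales": self.feature_scales.tolist(),
            "vegetation_classes": self.vegetation_classes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoverageModel":
        return cls(
            classes=list(d["classes"]),
            weights=np.asarray(d["weights"], float),
            intercepts=np.asarray(d["intercepts"], float),
            feature_means=np.asarray(d["feature_means"], float),
            feature_scales=np.asarray(d["feature_scales"], float),
            vegetation_classes=list(d.get("vegetation_classes", [])),
        )

    def save(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f)

    @classmethod
    def load(cls, path) -> "CoverageModel":
        with open(path) as f:
            return cls.from_dict(json.load(f))


def train_model(
    training: TrainingSet,
    l2_strength: float = DEFAULT_L2,
    seed: int = 0,
    vegetation_classes: list[str] | None = None,
) -> CoverageModel:
    """Fit the penalized multinomial maximum-entropy model.

    Features are standardized to zero mean / unit variance over the training
    set (constant features get scale 1).  ``l2_strength`` multiplies the
    squared weight norm in the per-sample-averaged objective; intercepts are
    unpenalized.  Deterministic given the seed.
    """
    X = training.features
    y = training.labels
    n, n_feat = X.shape
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales[scales == 0] = 1.0
    Xs = (X - means) / scales

    # sklearn minimizes sum(nll) + (1/(2C))||W||^2; ours is mean(nll) + (l2/2)||W||^2
    C = 1.0 / (l2_strength * n)
    clf = LogisticRegression(
        C=C, solver="lbfgs", max_iter=5000, tol=1e-10, random_state=seed
    )
    clf.fit(Xs, y)
    k = len(training.classes)
    if k == 2 and clf.coef_.shape[0] == 1:
        # binomial parametrization -> softmax form (class 0 pinned at zero)
        weights = np.vstack([np.zeros(n_feat), clf.coef_[0]])
        intercepts = np.array([0.0, float(clf.intercept_[0])])
    else:
        weights = clf.coef_.copy()
        intercepts = clf.intercept_.copy()
    return CoverageModel(
        classes=list(training.classes),
        weights=weights,
        intercepts=intercepts,
        feature_means=means,
        feature_scales=scales,
        vegetation_classes=list(vegetation_classes or []),
    )


def classify_pixels(model: CoverageModel, ortho: OrthoImage, mask: np.ndarray) -> np.ndarray:
    """Per-pixel argmax class map over ``mask``; invalid/unmasked pixels get -1."""
    if mask.shape != ortho.grid.shape:
        raise ValueError("mask shape must match the image grid")
    class_map = np.full(ortho.grid.shape, UNLABELED, dtype=np.int32)
    sel = mask & ortho.valid
    if not sel.any():
        return class_map
    feats = color_features(ortho.red[sel], ortho.green[sel], ortho.blue[sel])
    class_map[sel] = model.predict(feats)
    return class_map


def class_fractions(
    class_map: np.ndarray,
    classes: list[str],
    vegetation_classes: list[str] | None = None,
) -> tuple[dict[str, float], float]:
    """Per-class proportions of labeled pixels and total vegetation coverage."""
    labeled = class_map[class_map != UNLABELED]
    if labeled.size == 0:
        raise ValueError("no labeled pixels")
    counts = np.bincount(labeled, minlength=len(classes))
    fractions = {c: float(counts[k]) / labeled.size for k, c in enumerate(classes)}
    veg = vegetation_classes or []
    coverage = float(sum(fractions[c] for c in veg))
    return fractions, coverage
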