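"""Subject-level cross-validation splits and the pluggable image classifier.

The By-ID split assigns every image of one boar to exactly one of the
train / validation / test roles within a fold, so a model can never score
well by memorizing individual anatomy.  The baseline classifier is a
regularized logistic regression on hand-crafted intensity features in two
capacity tiers ("small": histogram features only; "medium": the full
feature set plus all pairwise interaction features).  Any external model
can be plugged into the pipeline instead, as long as it honors the
``train`` / ``predict_proba`` contract (a probability of the positive
high-quality class per image).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .synthetic import HIGH_QUALITY, UltrasoundImage, central_box

SMALL = "small"
MEDIUM = "medium"

#: documented feature ordering of :func:`extract_features`
FEATURE_NAMES = ("mean", "variance",
                 "d10", "d20", "d30", "d40", "d50", "d60", "d70", "d80", "d90",
                 "central_mean", "gradient_energy", "row_profile_max")
#: histogram-summary subset used by the small capacity tier
SMALL_FEATURES = FEATURE_NAMES[:11]

_DECILES = np.arange(10, 100, 10)
#: deciles are estimated on this regular pixel subsample (keeps batch
#: feature extraction cheap; the estimate is exact for constant images)
_DECILE_STRIDE = 4


@dataclass(frozen=True)
class SplitAssignment:
    """Role assignment of boar ids for one cross-validation fold."""

    fold: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


def by_id_kfold(boar_ids: Sequence[str], k: int = 5, seed: int = 0) -> list[SplitAssignment]:
    """Randomized grouped k-fold split over boar ids.

    Each boar appears in exactly one test set across the k folds; within a
    fold, one of the non-test chunks serves as the validation set and the
    rest train.  Deterministic given ``seed``.
    """
    unique = sorted(set(map(str, boar_ids)))
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if len(unique) < k:
        raise ValueError(f"need at least k={k} distinct boar ids, got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    chunks = [tuple(unique[i] for i in chunk) for chunk in np.array_split(order, k)]
    splits = []
    for fold in range(k):
        test = chunks[fold]
        val = chunks[(fold + 1) % k]
        train = tuple(b for j in range(k) if j not in (fold, (fold + 1) % k)
                      for b in chunks[j])
        splits.append(SplitAssignment(fold, train, val, test))
    return splits


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def extract_features_stack(pixels: np.ndarray) -> np.ndarray:
    """Feature matrix (n_images, 14) for a stack of same-sized images.

    Per image: mean, variance, the nine intensity deciles, the mean of the
    central 50% box, mean squared finite-difference gradient energy, and
    the maximum row-mean intensity (a bright-band detector).
    """
    stack = np.asarray(pixels, dtype=np.float32)
    if stack.ndim == 2:
        stack = stack[None]
    n, h, w = stack.shape
    flat = stack.reshape(n, -1)
    mean = flat.mean(axis=1)
    var = flat.var(axis=1)
    dec = np.percentile(flat[:, ::_DECILE_STRIDE], _DECILES, axis=1).T
    rows, cols = central_box(h, w, 0.5)
    cmean = stack[:, rows, cols].reshape(n, -1).mean(axis=1)
    # gradient energy on a 2x subsampled grid (adequate for speckle scale)
    sub = stack[:, ::2, ::2]
    gy = sub[:, 1:, :] - sub[:, :-1, :]
    gx = sub[:, :, 1:] - sub[:, :, :-1]
    genergy = (gy * gy).reshape(n, -1).mean(axis=1) + (gx * gx).reshape(n, -1).mean(axis=1)
    rowmax = stack.mean(axis=2).max(axis=1)
    return np.column_stack([mean, var, dec, cmean, genergy, rowmax]).astype(np.float64)


def extract_features(image: UltrasoundImage | np.ndarray) -> np.ndarray:
    """Feature vector of a single image, ordered as :data:`FEATURE_NAMES`."""
    pixels = image.pixels if isinstance(image, UltrasoundImage) else image
    return extract_features_stack(np.asarray(pixels))[0]


def _interaction_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    ii, jj = np.triu_indices(n, k=1)
    return ii, jj


def expand_features(features: np.ndarray, tier: str) -> np.ndarray:
    """Select the tier's feature columns (adds pairwise products for medium)."""
    if tier == SMALL:
        return features[:, :len(SMALL_FEATURES)]
    if tier == MEDIUM:
        ii, jj = _interaction_pairs(features.shape[1])
        return np.hstack([features, features[:, ii] * features[:, jj]])
    raise ValueError(f"unknown capacity tier {tier!r}")


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierSpec:
    """Capacity tier and fitting hyperparameters of the baseline classifier."""

    tier: str = SMALL
    regularization: float = 1.0  # inverse L2 strength (sklearn's C)
    max_iter: int = 50
    seed: int = 0


class ImageClassifier(Protocol):
    """Contract any plug-in model must honor to join the pipeline."""

    def predict_proba_images(self, images: Sequence[UltrasoundImage]) -> np.ndarray:
        """Probability of the positive (high-quality) class per image."""


@dataclass
class TrainedModel:
    """Fitted baseline classifier (weights over expanded, standardized features)."""

    spec: ClassifierSpec
    scaler: StandardScaler
    estimator: LogisticRegression
    n_base_features: int

    def predict_proba_features(self, features: np.ndarray) -> np.ndarray:
        x = self.scaler.transform(expand_features(features, self.spec.tier))
        pos = list(self.estimator.classes_).index(1)
        return self.estimator.predict_proba(x)[:, pos]

    def predict_proba_images(self, images: Sequence[UltrasoundImage]) -> np.ndarray:
        stack = np.stack([im.pixels for im in images])
        return self.predict_proba_features(extract_features_stack(stack))


def fit_features(spec: ClassifierSpec, features: np.ndarray,
                 y: np.ndarray) -> TrainedModel:
    """Fit the tiered logistic baseline on a precomputed feature matrix.

    ``y`` holds 1 for high-quality and 0 for underperforming.  The class
    imbalance of the population is handled by class-weighted
    likelihood.  Newton iterations make the fit deterministic and fast
    even when the features carry no signal.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    x = expand_features(np.asarray(features, dtype=np.float64), spec.tier)
    scaler = StandardScaler().fit(x)
    est = LogisticRegression(C=spec.regularization, max_iter=spec.max_iter,
                             class_weight="balanced", solver="newton-cholesky",
                             random_state=spec.seed)
    est.fit(scaler.transform(x), y)
    return TrainedModel(spec, scaler, est, features.shape[1])


def train(spec: ClassifierSpec, images: Sequence[UltrasoundImage],
          labels: Sequence[str], pipeline=None) -> TrainedModel:
    """Train the baseline classifier on (optionally augmented) images.

    ``labels`` are class names; high-quality is the positive class.  When an
    augmentation ``pipeline`` is given, each training image passes through
    it once; evaluation images are never augmented.
    """
    if len(images) != len(labels):
        raise ValueError("images and labels differ in length")
    pixels = [im.pixels if isinstance(im, UltrasoundImage) else np.asarray(im)
              for im in images]
    if pipeline is not None:
        pixels = [pipeline.transform_pixels(px) for px in pixels]
    stack = np.stack(pixels)
    y = np.asarray([1 if lab == HIGH_QUALITY else 0 for lab in labels])
    return fit_features(spec, extract_features_stack(stack), y)


def predict_proba(model: TrainedModel, image: UltrasoundImage | np.ndarray) -> float:
    """Probability that ``image`` comes from a high-quality boar."""
    if not isinstance(model, TrainedModel):
        raise ValueError("model is not a trained classifier")
    pixels = image.pixels if isinstance(image, UltrasoundImage) else np.asarray(image)
    return float(model.predict_proba_features(
        extract_features_stack(pixels[None] if pixels.ndim == 2 else pixels))[0])
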