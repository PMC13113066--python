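"""Boar-level decision aggregation and performance metrics.

Image-level positive-class probabilities are averaged per boar and the mean
is compared against a decision threshold of 0.3 (decisions use >=, so a
mean of exactly 0.3 is called high-quality).  High-quality is the positive
class throughout: precision = TP / (TP + FP), recall = TP / (TP + FN), and
F1 = 2 * precision * recall / (precision + recall), with all three defined
as 0 when their denominator vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import augment, harness
from .synthetic import (CROPPED, FULL, HIGH_QUALITY, UNDERPERFORMING, Dataset,
                        central_box)

DEFAULT_THRESHOLD = 0.3


@dataclass(frozen=True)
class BoarPrediction:
    boar_id: str
    mean_probability: float
    predicted_label: str
    n_images: int


@dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int


def aggregate(probabilities: Sequence[float], threshold: float = DEFAULT_THRESHOLD,
              boar_id: str = "") -> BoarPrediction:
    """Average a boar's image probabilities and threshold the mean."""
    probs = np.asarray(probabilities, dtype=float)
    if probs.size == 0:
        raise ValueError("aggregate requires at least one probability")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    mean = float(probs.mean())
    label = HIGH_QUALITY if mean >= threshold else UNDERPERFORMING
    return BoarPrediction(boar_id, mean, label, int(probs.size))


def score(predictions: Mapping[str, str], truths: Mapping[str, str]) -> MetricSet:
    """Confusion counts and precision/recall/F1 with high-quality positive."""
    if set(predictions) != set(truths):
        raise ValueError("prediction and truth boar ids do not match")
    if not predictions:
        raise ValueError("score requires at least one boar")
    tp = fp = fn = tn = 0
    for boar_id, pred in predictions.items():
        pos_pred = pred == HIGH_QUALITY
        pos_true = truths[boar_id] == HIGH_QUALITY
        if pos_pred and pos_true:
            tp += 1
        elif pos_pred:
            fp += 1
        elif pos_true:
            fn += 1
        else:
            tn += 1
    return metrics_from_counts(tp, fp, fn, tn)


def metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> MetricSet:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2.0 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return MetricSet(precision, recall, f1, tp, fp, fn, tn)


@dataclass(frozen=True)
class RunResult:
    """One observation of the factorial experiment: a config's metrics."""

    region: str
    angle: str
    augmentation: str
    model: str
    run: int
    seed: int
    precision: float
    recall: float
    f1: float


def evaluate_config(dataset: Dataset, config, seed: int = 0, *,
                    run: int = 0, n_folds: int = 5,
                    threshold: float = DEFAULT_THRESHOLD,
                    pooling: str = "pooled",
                    aug_params: augment.AugmentationParams = augment.DEFAULT_AUG_PARAMS,
                    cache: dict | None = None) -> RunResult:
    """Run one factor-grid cell end to end and score it.

    Filters the dataset to the config's probe angle, applies the region
    treatment, trains the config's capacity tier under the config's
    augmentation group inside a By-ID 5-fold cross-validation, aggregates
    image probabilities per test boar at ``threshold``, and scores either
    the union of the five test folds (``pooling="pooled"``, each boar
    tested exactly once) or the fold-average (``pooling="per_fold"``).

    ``cache`` may be shared across calls on the same dataset to reuse
    angle/region pixel stacks and clean (never augmented) feature matrices.
    """
    if pooling not in ("pooled", "per_fold"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    cache = cache if cache is not None else {}
    key = (config.angle, config.region)
    if key not in cache:
        imgs = [im for im in dataset.images if im.angle == config.angle]
        if not imgs:
            raise ValueError(f"dataset has no {config.angle!r} images")
        if any(im.region != FULL for im in imgs):
            raise ValueError("dataset images must be full-region")
        pixels = np.stack([im.pixels for im in imgs])
        if config.region == CROPPED:
            rows, cols = central_box(pixels.shape[1], pixels.shape[2])
            pixels = np.ascontiguousarray(pixels[:, rows, cols])
        boar_ids = np.array([im.boar_id for im in imgs])
        cache[key] = (pixels, boar_ids, harness.extract_features_stack(pixels))
    pixels, boar_ids, clean_features = cache[key]

    truth = dataset.true_classes
    y = np.array([1 if truth[b] == HIGH_QUALITY else 0 for b in boar_ids])

    # splits and the augmented pass depend only on (angle, region,
    # augmentation, seed); the two capacity tiers of a run therefore train
    # on identical augmented data, a paired comparison of model capacity
    run_key = (config.angle, config.region, config.augmentation,
               int(seed) & 0x7FFFFFFF, n_folds)
    if run_key not in cache:
        ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF])
        split_seed, aug_seed = ss.spawn(2)
        splits = harness.by_id_kfold(np.unique(boar_ids), k=n_folds,
                                     seed=split_seed)
        pipeline = augment.build_pipeline(config.augmentation, seed=aug_seed,
                                          params=aug_params)
        aug_features = harness.extract_features_stack(
            np.stack([pipeline.transform_pixels(px) for px in pixels]))
        cache[run_key] = (splits, aug_features)
    splits, aug_features = cache[run_key]

    spec = harness.ClassifierSpec(tier=config.model)
    fold_metrics = []
    boar_probs: dict[str, np.ndarray] = {}
    for split in splits:
        train_mask = np.isin(boar_ids, split.train_ids)
        test_mask = np.isin(boar_ids, split.test_ids)
        # rare degenerate fold: a single-class training chunk widens into the
        # validation chunk; failing that, predict the training prevalence
        if len(np.unique(y[train_mask])) < 2:
            train_mask |= np.isin(boar_ids, split.val_ids)
        if len(np.unique(y[train_mask])) < 2:
            probs = np.full(int(test_mask.sum()), float(y[train_mask].mean()))
        else:
            model = harness.fit_features(spec, aug_features[train_mask],
                                         y[train_mask])
            probs = model.predict_proba_features(clean_features[test_mask])
        fold_preds = {}
        for b in np.unique(boar_ids[test_mask]):
            p = probs[boar_ids[test_mask] == b]
            boar_probs[b] = p
            fold_preds[b] = aggregate(p, threshold, boar_id=b).predicted_label
        if pooling == "per_fold":
            fold_metrics.append(score(fold_preds, {b: truth[b] for b in fold_preds}))

    if pooling == "per_fold":
        precision = float(np.mean([m.precision for m in fold_metrics]))
        recall = float(np.mean([m.recall for m in fold_metrics]))
        f1 = float(np.mean([m.f1 for m in fold_metrics]))
    else:
        preds = {b: aggregate(p, threshold, boar_id=b).predicted_label
                 for b, p in boar_probs.items()}
        m = score(preds, {b: truth[b] for b in preds})
        precision, recall, f1 = m.precision, m.recall, m.f1
    return RunResult(config.region, config.angle, config.augmentation,
                     config.model, run, int(seed) & 0x7FFFFFFF,
                     precision, recall, f1)


def results_to_frame(results: Sequence[RunResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
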