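"""Stratified 3:1:1 splitting, classification accuracy, gradient saliency.

The saliency statistic is the absolute gradient of the pre-softmax class
score with respect to the input spectrum, w = |dS_c/dX| at X_0, evaluated for
every correctly classified test sample at its true class, averaged over those
samples per band, and divided by its maximum so the most important wavelength
has importance 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .dataset import SpectralDataset


class EmptySaliencyError(ValueError):
    """No correctly classified test samples to aggregate over."""


@dataclass
class SplitIndices:
    """Disjoint train/val/test index lists covering all samples (ratio 3:1:1)."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    seed: int = 0
    stratify_on: str = "level"

    def __post_init__(self) -> None:
        self.train = np.asarray(self.train, dtype=int)
        self.val = np.asarray(self.val, dtype=int)
        self.test = np.asarray(self.test, dtype=int)
        all_idx = np.concatenate([self.train, self.val, self.test])
        if len(np.unique(all_idx)) != all_idx.size:
            raise ValueError("split index lists overlap")

    @property
    def n_samples(self) -> int:
        return self.train.size + self.val.size + self.test.size

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "stratify_on": self.stratify_on,
                       "train": self.train.tolist(), "val": self.val.tolist(),
                       "test": self.test.tolist()}, fh)

    @classmethod
    def from_json(cls, path) -> "SplitIndices":
        with open(path) as fh:
            d = json.load(fh)
        return cls(train=d["train"], val=d["val"], test=d["test"],
                   seed=d.get("seed", 0), stratify_on=d.get("stratify_on", "level"))


def split_dataset(ds: SpectralDataset, seed: int,
                  stratify_on: str = "level") -> SplitIndices:
    """Shuffled stratified 60/20/20% assignment, remainder going train-first.

    Strata are residue levels (``level``) or level-by-variety cells
    (``level_x_variety``). Each stratum must hold at least 5 samples so every
    split receives at least one.
    """
    if stratify_on == "level":
        strata_keys = ds.y.astype(str)
    elif stratify_on in ("level_x_variety", "level×variety"):
        strata_keys = np.array([f"{v}|{l}" for v, l in zip(ds.variety, ds.y)])
    else:
        raise ValueError(f"unknown stratify_on {stratify_on!r}")

    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for key in np.unique(strata_keys):
        idx = np.flatnonzero(strata_keys == key)
        if idx.size < 5:
            raise ValueError(f"stratum {key!r} has only {idx.size} samples (< 5)")
        idx = rng.permutation(idx)
        n = idx.size
        n_train, n_val, n_test = (3 * n) // 5, n // 5, n // 5
        remainder = n - (n_train + n_val + n_test)  # 0..4 leftover samples
        extras = [0, 0, 0]
        for i in range(remainder):  # distributed train-first, then val, then test
            extras[i % 3] += 1
        n_train += extras[0]
        n_val += extras[1]
        n_test += extras[2]
        train.extend(idx[:n_train])
        val.extend(idx[n_train:n_train + n_val])
        test.extend(idx[n_train + n_val:])
    return SplitIndices(train=np.sort(train), val=np.sort(val), test=np.sort(test),
                        seed=seed, stratify_on=stratify_on)


def accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of predictions agreeing with the true labels."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    if predicted.size == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(predicted == truth))


@runtime_checkable
class DifferentiableScorer(Protocol):
    """A classifier exposing pre-softmax class scores and their input gradients."""

    def class_scores(self, X: np.ndarray) -> np.ndarray:
        """n x n_classes score matrix (pre-softmax)."""

    def score_input_gradient(self, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
        """d S_c / d x per sample, for the given class index per row."""


@dataclass
class LinearScoreModel:
    """Adapter giving a linear classifier (LR, linear SVM) the scorer interface.

    Scores are W x + b; the input gradient for class c is the constant row
    W[c], independent of the input.
    """

    weights: np.ndarray  # n_classes x n_bands
    bias: np.ndarray     # n_classes

    def class_scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.weights.T + self.bias

    def score_input_gradient(self, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
        return self.weights[np.asarray(classes, dtype=int)]


@dataclass
class SaliencyProfile:
    """Per-wavelength importance in [0, 1] (max-normalized mean |gradient|)."""

    wavelengths_nm: np.ndarray
    importance: np.ndarray
    n_samples_used: int
    per_class_profiles: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        imp = np.asarray(self.importance)
        if imp.shape != np.asarray(self.wavelengths_nm).shape:
            raise ValueError("importance length must match the band count")
        if self.n_samples_used < 1:
            raise EmptySaliencyError("no samples contributed to the profile")
        if not np.isclose(imp.max(), 1.0):
            raise ValueError("importance must be max-normalized to 1")

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = {"wavelength_nm": self.wavelengths_nm, "importance": self.importance}
        for c, prof in sorted(self.per_class_profiles.items()):
            cols[f"class_{c}"] = prof
        pd.DataFrame(cols).to_csv(path, index=False)


def saliency_map(model: DifferentiableScorer, test: SpectralDataset) -> SaliencyProfile:
    """Mean absolute score gradient over correctly classified test samples.

    For each test sample predicted correctly, the gradient of the true
    (= predicted) class's pre-softmax score with respect to the input spectrum
    is taken; its absolute value is averaged across those samples per band and
    the profile is divided by its maximum. Per-class profiles (same statistic
    restricted to each class) are attached as a breakdown.
    """
    scores = model.class_scores(test.X)
    pred = np.argmax(scores, axis=1)
    correct = pred == test.y
    if not correct.any():
        raise EmptySaliencyError("zero correctly classified samples in the test set")

    X_ok = test.X[correct]
    y_ok = test.y[correct]
    grads = np.abs(model.score_input_gradient(X_ok, y_ok))
    mean_w = grads.mean(axis=0)
    norm = mean_w.max()
    per_class = {}
    for c in np.unique(y_ok):
        per_class[int(c)] = grads[y_ok == c].mean(axis=0) / norm
    return SaliencyProfile(
        wavelengths_nm=test.wavelengths_nm,
        importance=mean_w / norm,
        n_samples_used=int(correct.sum()),
        per_class_profiles=per_class,
    )
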