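"""Grid-search-tuned SVM, logistic regression, and random forest classifiers.

The protocol mirrors a three-way-split experiment: every grid point is
trained on the training split, the point with the highest validation-split
accuracy is selected (ties break to the first point in deterministic
lexicographic grid order), and the selected model's accuracy is reported on
all three splits. Search ranges:

* SVM: kernel in {poly, rbf, sigmoid, linear}; C and gamma log-spaced over
  [1e-5, 50].
* LR: solver in {newton-cg, lbfgs, liblinear, sag}; C log-spaced over
  [1e-5, 1e5]; L2 penalty.
* RF: n_estimators 100..1000 in steps of 50; max_depth 4..8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .dataset import SpectralDataset
from .evaluation import LinearScoreModel, SplitIndices, accuracy

MODEL_KINDS = ("svm", "lr", "rf", "cnn", "resnet")


@dataclass
class SearchSpace:
    """Hyperparameter grids for the three classical models.

    Continuous axes (C, gamma) are discretized log-uniformly with
    ``grid_points`` values per axis.
    """

    svm_kernels: tuple[str, ...] = ("poly", "rbf", "sigmoid", "linear")
    svm_c_range: tuple[float, float] = (1e-5, 50.0)
    svm_gamma_range: tuple[float, float] = (1e-5, 50.0)
    lr_solvers: tuple[str, ...] = ("newton-cg", "lbfgs", "liblinear", "sag")
    lr_c_range: tuple[float, float] = (1e-5, 1e5)
    rf_n_estimators: tuple[int, int] = (100, 1000)
    rf_n_estimators_step: int = 50
    rf_max_depth: tuple[int, int] = (4, 8)
    grid_points: int = 7

    def __post_init__(self) -> None:
        if self.grid_points < 2:
            raise ValueError("grid_points must be >= 2 for continuous axes")
        for lo, hi in (self.svm_c_range, self.svm_gamma_range, self.lr_c_range):
            if not 0 < lo < hi:
                raise ValueError("continuous ranges must satisfy 0 < lo < hi")

    def _log_axis(self, rng: tuple[float, float]) -> np.ndarray:
        return np.geomspace(rng[0], rng[1], self.grid_points)

    def grid(self, kind: str) -> list[dict]:
        """Deterministic lexicographic list of grid points for one model kind."""
        if kind == "svm":
            return [
                {"kernel": k, "C": float(c), "gamma": float(g)}
                for k, c, g in product(self.svm_kernels,
                                       self._log_axis(self.svm_c_range),
                                       self._log_axis(self.svm_gamma_range))
            ]
        if kind == "lr":
            return [
                {"solver": s, "C": float(c)}
                for s, c in product(self.lr_solvers, self._log_axis(self.lr_c_range))
            ]
        if kind == "rf":
            lo, hi = self.rf_n_estimators
            ns = range(lo, hi + 1, self.rf_n_estimators_step)
            depths = range(self.rf_max_depth[0], self.rf_max_depth[1] + 1)
            return [{"n_estimators": n, "max_depth": d} for n, d in product(ns, depths)]
        raise ValueError(f"unknown classical model kind {kind!r}")


@dataclass
class ModelResult:
    """A fitted classifier with its tuned parameters and split accuracies."""

    model_kind: str
    best_params: Mapping[str, object]
    accuracies: dict[str, float]
    predictions: dict[str, np.ndarray]
    seed: int
    model: object = None
    loss_history: np.ndarray | None = None
    validation_curve: list[tuple[dict, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        for split, acc in self.accuracies.items():
            if not 0.0 <= acc <= 1.0:
                raise ValueError(f"{split} accuracy {acc} outside [0, 1]")


def _build(kind: str, params: dict, seed: int):
    if kind == "svm":
        return SVC(kernel=params["kernel"], C=params["C"], gamma=params["gamma"],
                   random_state=seed)
    if kind == "lr":
        # L2 penalty throughout (sklearn's default); liblinear is inherently
        # binary and is applied one-vs-rest, its classic multiclass scheme
        lr = LogisticRegression(solver=params["solver"], C=params["C"],
                                max_iter=500, random_state=seed)
        if params["solver"] == "liblinear":
            return OneVsRestClassifier(lr)
        return lr
    if kind == "rf":
        return RandomForestClassifier(n_estimators=params["n_estimators"],
                                      max_depth=params["max_depth"],
                                      random_state=seed)
    raise ValueError(f"unknown classical model kind {kind!r}")


def tune_and_train(kind: str, ds: SpectralDataset, split: SplitIndices,
                   space: SearchSpace | None = None, seed: int = 0) -> ModelResult:
    """Exhaustive grid search selected by validation accuracy.

    The final model is refit on the training split only (the validation split
    is used solely for selection, the test split solely for reporting).
    """
    if kind not in ("svm", "lr", "rf"):
        raise ValueError(f"unknown classical model kind {kind!r}")
    if split.n_samples != ds.n_samples:
        raise ValueError("split does not cover the dataset")
    space = space or SearchSpace()
    n_classes = len(np.unique(ds.y))
    for name in ("train", "val", "test"):
        if getattr(split, name).size < n_classes:
            raise ValueError(f"{name} split smaller than the number of classes")

    X_tr, y_tr = ds.X[split.train], ds.y[split.train]
    X_val, y_val = ds.X[split.val], ds.y[split.val]

    best_params, best_val, curve = None, -1.0, []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", FutureWarning)
        for params in space.grid(kind):
            model = _build(kind, params, seed)
            model.fit(X_tr, y_tr)
            val_acc = accuracy(model.predict(X_val), y_val)
            curve.append((params, val_acc))
            if val_acc > best_val:  # strict: ties keep the earlier grid point
                best_val, best_params = val_acc, params

        final = _build(kind, best_params, seed)
        final.fit(X_tr, y_tr)

    preds = {name: final.predict(ds.X[getattr(split, name)])
             for name in ("train", "val", "test")}
    accs = {name: accuracy(preds[name], ds.y[getattr(split, name)])
            for name in ("train", "val", "test")}
    return ModelResult(model_kind=kind, best_params=best_params, accuracies=accs,
                       predictions=preds, seed=seed, model=final,
                       validation_curve=curve)


def linear_scorer(result: ModelResult) -> LinearScoreModel:
    """Expose a fitted LR or linear-kernel SVM as a differentiable linear scorer.

    Only models with a linear decision function have a well-defined constant
    input gradient; RF and nonlinear kernels are rejected.
    """
    model = result.model
    if isinstance(model, LogisticRegression):
        return LinearScoreModel(weights=model.coef_, bias=model.intercept_)
    if isinstance(model, OneVsRestClassifier) and all(
        isinstance(est, LogisticRegression) for est in model.estimators_
    ):
        return LinearScoreModel(
            weights=np.vstack([est.coef_ for est in model.estimators_]),
            bias=np.concatenate([est.intercept_ for est in model.estimators_]),
        )
    if isinstance(model, SVC) and model.kernel == "linear":
        # one-vs-one decision functions; use the aggregated per-class vote
        # weights via the primal coefficients of each pairwise machine
        raise NotImplementedError(
            "per-class scores of a one-vs-one SVC are not a single linear map; "
            "use LR for linear saliency"
        )
    raise ValueError("saliency via the linear path requires a logistic regression")
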