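"""RBF-SVM training, cross-validated fitness and FPSO hyperparameter search.

The soft-margin quadratic program is delegated to scikit-learn's SVC; this
module owns the kernel contract, the constraint echoes exposed for testing
(dual coefficients in the [0, C] box, zero-sum equality) and the search
wrapper: penalty factor C and kernel width gamma are tuned by the fuzzy
self-tuning swarm over a box (default [0, 30]^2, the printed range), with
both parameters floored at 1e-6 before each evaluation because an RBF-SVM
is degenerate at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data import Dataset
from .fpso import FPSOResult, SearchSpace, fpso_minimize

__all__ = ["SVMHyperparams", "TrainedSVM", "TuneResult",
           "rbf_kernel", "train_svm", "fitness", "tune_svm", "DEFAULT_BOX"]

PARAM_FLOOR = 1e-6
DEFAULT_BOX = SearchSpace(lower=(0.0, 0.0), upper=(30.0, 30.0))


@dataclass(frozen=True)
class SVMHyperparams:
    """Penalty factor C and RBF width gamma."""

    C: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")

    @staticmethod
    def floored(C: float, gamma: float) -> "SVMHyperparams":
        return SVMHyperparams(max(C, PARAM_FLOOR), max(gamma, PARAM_FLOOR))


def rbf_kernel(x, y, gamma: float) -> float:
    """``exp(-gamma * ||x - y||^2)``; 1 at x = y for any gamma."""
    a, b = np.asarray(x, float), np.asarray(y, float)
    if a.shape != b.shape:
        raise ValueError("dimension mismatch")
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    return float(np.exp(-gamma * np.sum((a - b) ** 2)))


@dataclass
class TrainedSVM:
    """Fitted RBF-SVM exposing decision scores and sign labels."""

    model: SVC
    hyperparams: SVMHyperparams

    @property
    def support_vectors(self) -> np.ndarray:
        return self.model.support_vectors_

    @property
    def dual_coef(self) -> np.ndarray:
        """Signed products beta_i * y_i of the support vectors."""
        return self.model.dual_coef_[0]

    @property
    def bias(self) -> float:
        return float(self.model.intercept_[0])

    def decision_scores(self, ds: Dataset) -> np.ndarray:
        return self.model.decision_function(ds.features.to_numpy(float))

    def predict(self, ds: Dataset) -> np.ndarray:
        """Sign of the decision function mapped to {0, 1} labels."""
        return (self.decision_scores(ds) > 0).astype(np.int64)


def train_svm(ds: Dataset, hp: SVMHyperparams) -> TrainedSVM:
    """Fit a soft-margin RBF-SVM on a numeric-encoded dataset."""
    if not ds.is_numeric():
        raise ValueError("dataset must be numeric-encoded")
    if len(np.unique(ds.labels)) < 2:
        raise ValueError("both classes must be present")
    model = SVC(C=hp.C, gamma=hp.gamma, kernel="rbf")
    model.fit(ds.features.to_numpy(float), ds.labels)
    return TrainedSVM(model, hp)


def fitness(ds_train: Dataset, hp: SVMHyperparams, folds: int = 5,
            seed: int = 0) -> float:
    """Mean stratified k-fold cross-validated accuracy on the training set.

    This is the quantity the swarm maximizes (it receives ``1 - fitness``);
    computing it on held-out folds of the *training* partition keeps the
    test set out of the tuning loop.
    """
    n0, n1 = ds_train.class_counts()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if min(n0, n1) < folds:
        raise ValueError("both classes need >= folds members")
    x = ds_train.features.to_numpy(float)
    y = ds_train.labels
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(x, y):
        m = SVC(C=hp.C, gamma=hp.gamma, kernel="rbf")
        m.fit(x[tr], y[tr])
        accs.append(float(np.mean(m.predict(x[te]) == y[te])))
    return float(np.mean(accs))


@dataclass
class TuneResult:
    """Best hyperparameters, the refit model and the optimizer trace."""

    hyperparams: SVMHyperparams
    model: TrainedSVM
    best_fitness: float
    fpso: FPSOResult

    def trace_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"iteration": t["iteration"],
              "best_C": max(t["best_position"][0], PARAM_FLOOR),
              "best_gamma": max(t["best_position"][1], PARAM_FLOOR),
              "best_cv_accuracy": 1.0 - t["best_fitness"]}
             for t in self.fpso.trace])


def tune_svm(ds_train: Dataset, box: SearchSpace = DEFAULT_BOX,
             max_iter: int = 30, seed: int = 0, folds: int = 5,
             rulebase=None) -> TuneResult:
    """FPSO search for (C, gamma) maximizing cross-validated accuracy.

    The swarm minimizes ``1 - CV accuracy`` over ``box``; fold assignment
    is fixed from ``seed`` so every (C, gamma) is scored on identical
    folds.  The returned model is refit on all of ``ds_train``.
    """
    fold_seed = seed % (2**31)

    def objective(point: np.ndarray) -> float:
        hp = SVMHyperparams.floored(point[0], point[1])
        return 1.0 - fitness(ds_train, hp, folds=folds, seed=fold_seed)

    res = fpso_minimize(objective, box, max_iter=max_iter, seed=seed,
                        rulebase=rulebase)
    hp = SVMHyperparams.floored(res.best_position[0], res.best_position[1])
    return TuneResult(hp, train_svm(ds_train, hp), 1.0 - res.best_fitness, res)
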