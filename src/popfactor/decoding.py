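"""Regularized linear read-outs of population codes.

Two classifier families, matching the two experimental read-outs they
serve: a max-margin (support vector) decoder for the binary few-shot
simulation, and multinomial logistic regression for multi-way object
identity (whose class probabilities also feed the behavioral-signature
module).  Cross-validated accuracy uses stratified folds with the
regularization strength chosen by an inner loop on training folds only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data import ResponseMatrix
from .errors import StratificationError
from .simulate import BinaryFactorSimConfig, gen_binary_factor_data

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
_SOLVER_TOL = 1e-6


@dataclass
class LinearDecoder:
    """Trained linear classifier with a uniform predict interface."""

    kind: str
    model: object
    classes: np.ndarray

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict(x)

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        return self.model.decision_function(x)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if self.kind != "multinomial_logistic":
            raise ValueError("class probabilities require the logistic decoder")
        return self.model.predict_proba(x)

    def accuracy(self, x: np.ndarray, y: Sequence) -> float:
        return float(np.mean(self.predict(x) == np.asarray(y)))


@dataclass
class DecodingReport:
    accuracy: float
    per_class_accuracy: dict[str, float]
    chance_level: float
    n_train: int
    n_test: int
    regularization: dict[int, float] = field(default_factory=dict)
    seed: int = 0


def train_linear_decoder(
    train_points: np.ndarray,
    train_labels: Sequence,
    kind: str = "max_margin",
    regularization: float = 1.0,
) -> LinearDecoder:
    """Fit a linear decoder.

    ``max_margin`` is a linear-kernel SVM (binary labels only);
    ``multinomial_logistic`` a multinomial logistic regression exposing
    per-class probabilities.  ``regularization`` is the inverse penalty C.
    Fits are deterministic given inputs and the fixed solver tolerance.
    """
    y = np.asarray(train_labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    if kind == "max_margin":
        if len(classes) != 2:
            raise ValueError("max_margin decoder is binary")
        model = SVC(kernel="linear", C=regularization, tol=_SOLVER_TOL)
    elif kind == "multinomial_logistic":
        model = LogisticRegression(
            C=regularization, tol=_SOLVER_TOL, max_iter=5000, solver="lbfgs"
        )
    else:
        raise ValueError(f"unknown decoder kind {kind!r}")
    model.fit(np.asarray(train_points, dtype=float), y)
    return LinearDecoder(kind=kind, model=model, classes=classes)


def _select_c(
    x: np.ndarray,
    y: np.ndarray,
    kind: str,
    grid: Sequence[float],
    inner_folds: int,
    seed: int,
) -> float:
    """Inner-CV choice of the inverse regularization strength."""
    if len(grid) == 1:
        return float(grid[0])
    counts = pd.Series(y).value_counts()
    folds = min(inner_folds, int(counts.min()))
    if folds < 2:
        return float(grid[len(grid) // 2])
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best_c, best_acc = float(grid[0]), -1.0
    for c in grid:
        accs = []
        for tr, te in splitter.split(x, y):
            dec = train_linear_decoder(x[tr], y[tr], kind, c)
            accs.append(dec.accuracy(x[te], y[te]))
        acc = float(np.mean(accs))
        if acc > best_acc:
            best_acc, best_c = acc, float(c)
    return best_c


def cv_decode(
    responses: ResponseMatrix | np.ndarray,
    labels: Sequence,
    folds: int = 5,
    kind: str = "multinomial_logistic",
    regularization_grid: Sequence[float] = DEFAULT_C_GRID,
    seed: int = 0,
) -> DecodingReport:
    """Stratified k-fold decoding accuracy with nested model selection."""
    x = responses.values if isinstance(responses, ResponseMatrix) else np.asarray(
        responses, dtype=float
    )
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise StratificationError(
            f"smallest class has {counts.min()} members < {folds} folds"
        )
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=y.dtype)
    chosen: dict[int, float] = {}
    for fold, (tr, te) in enumerate(splitter.split(x, y)):
        c = _select_c(x[tr], y[tr], kind, regularization_grid, 3, seed + fold)
        chosen[fold] = c
        dec = train_linear_decoder(x[tr], y[tr], kind, c)
        pred[te] = dec.predict(x[te])
    correct = pred == y
    per_class = {
        str(c): float(np.mean(correct[y == c])) for c in classes
    }
    return DecodingReport(
        accuracy=float(np.mean(correct)),
        per_class_accuracy=per_class,
        chance_level=1.0 / len(classes),
        n_train=len(y) - len(y) // folds,
        n_test=len(y),
        regularization=chosen,
        seed=seed,
    )


def alignment_sweep(
    base_config: BinaryFactorSimConfig,
    alignments: Sequence[float],
    k_values: Sequence[int],
    n_replicates: int = 100,
    seed: int = 0,
    regularization: float = 1.0,
) -> pd.DataFrame:
    """Few-shot decoding accuracy over an alignment x training-size grid.

    For every (alignment, K, replicate) cell a fresh binary-feature dataset
    is sampled, a max-margin decoder trained on the K-per-sign training
    examples of each target variable, and held-out accuracy averaged over
    the two targets.  Returns a tidy table (alignment, k, replicate,
    accuracy).
    """
    rows = []
    for ai, alignment in enumerate(alignments):
        for ki, k in enumerate(k_values):
            for rep in range(n_replicates):
                cfg = BinaryFactorSimConfig(
                    n_dims=base_config.n_dims,
                    alignment=float(alignment),
                    noise_sd=base_config.noise_sd,
                    k_train=int(k),
                    n_test=base_config.n_test,
                    seed=seed + 1_000_003 * ai + 10_007 * ki + rep,
                )
                data = gen_binary_factor_data(cfg)
                accs = []
                for target in (0, 1):
                    dec = train_linear_decoder(
                        data.train_x[target],
                        data.train_y[target],
                        "max_margin",
                        regularization,
                    )
                    accs.append(dec.accuracy(data.test_x, data.test_y[:, target]))
                rows.append(
                    {
                        "alignment": float(alignment),
                        "k": int(k),
                        "replicate": rep,
                        "accuracy": float(np.mean(accs)),
                    }
                )
    return pd.DataFrame(rows)
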