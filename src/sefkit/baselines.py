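"""Desk-scale QSAR reference models and evaluation metrics.

Two baselines accompany the SEF descriptors:

- :class:`TanimotoKNN` — k-nearest-neighbour prediction over Tanimoto
  similarity of ECFP4 fingerprints (Morgan, radius 2); the mean target
  of the k most similar training molecules for regression, majority
  vote for classification.  k is swept over {1, 2, 3} and selected on a
  held-out validation split of the training set.
- :class:`RandomForestGrid` — a random forest fitted by exhaustive grid
  search over trees in {25, 100, 200}, minimum samples per leaf in
  {1, 2, 5} and minimum samples per split in {2, 3, 5}, with at least
  5-fold cross-validation; the best combination is refit on all of
  train.

:func:`evaluate` computes the standard regression metrics (MAPE with
zero-target exclusion, MAE, RMSE, R^2) and classification metrics
(ROC AUC by rank statistic, accuracy at threshold 0.5).
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import (
    accuracy_score,
    mean_absolute_error,
    r2_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, train_test_split

from . import entropy as ent
from .errors import EmptyInputError
from .featurize import DescriptorMatrix, MoleculeRecord

__all__ = [
    "KnnConfig",
    "RfConfig",
    "MetricReport",
    "TanimotoKNN",
    "RandomForestGrid",
    "knn_predict",
    "rf_fit_predict",
    "evaluate",
]


@dataclass(frozen=True)
class KnnConfig:
    """Configuration of the Tanimoto-kNN baseline."""

    k_sweep: tuple[int, ...] = (1, 2, 3)
    task: str = "regression"
    fp_radius: int = 2  # ECFP4 = diameter 4
    fp_bits: int = 2048
    val_fraction: float = 0.2
    random_state: int | None = 0


@dataclass(frozen=True)
class RfConfig:
    """Configuration of the grid-searched random forest baseline."""

    n_trees_grid: tuple[int, ...] = (25, 100, 200)
    min_leaf_grid: tuple[int, ...] = (1, 2, 5)
    min_split_grid: tuple[int, ...] = (2, 3, 5)
    cv_folds: int = 5
    task: str = "regression"
    random_state: int | None = 0

    def __post_init__(self) -> None:
        if not (self.n_trees_grid and self.min_leaf_grid and self.min_split_grid):
            raise ValueError("hyperparameter grids must be non-empty")
        if self.cv_folds < 5:
            raise ValueError("at least 5 cross-validation folds are required")


@dataclass
class MetricReport:
    """Standard QSAR evaluation metrics for one prediction set."""

    task: str
    n: int
    mae: float | None = None
    rmse: float | None = None
    mape: float | None = None
    r2: float | None = None
    r2_defined: bool = True
    n_zero_targets_excluded: int = 0
    roc_auc: float | None = None
    accuracy: float | None = None
    n_train: int | None = None
    n_test: int | None = None
    replicates: int = 1

    def to_dict(self) -> dict:
        return {k: v for k, v in dataclasses.asdict(self).items() if v is not None}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _smiles_of(x) -> str:
    return x.smiles if isinstance(x, MoleculeRecord) else str(x)


class TanimotoKNN(BaseEstimator):
    """k-nearest-neighbour model over Tanimoto similarity of ECFP4 bits.

    For each query molecule the k most Tanimoto-similar training
    molecules are found; the prediction is the mean of their targets
    (regression) or the majority vote, ties broken toward the more
    similar neighbour (classification).  When ``k_sweep`` has several
    values, the k minimizing MAE (maximizing accuracy) on a seeded
    held-out validation split of the training set is selected and the
    final model uses all of train.

    Similarity ties at the k-th rank are resolved by stable
    training-set order.  A query whose fingerprint has no bits set has
    no defined similarity; it still receives a prediction (from the
    stable order) but is flagged in ``flags_`` after ``predict``.

    Attributes
    ----------
    best_k_ : int
        The selected neighbourhood size.
    flags_ : np.ndarray of bool
        Per-query flag from the most recent ``predict`` call, True where
        the query fingerprint was all-zero.
    """

    def __init__(
        self,
        k_sweep: Sequence[int] = (1, 2, 3),
        task: str = "regression",
        fp_radius: int = 2,
        fp_bits: int = 2048,
        val_fraction: float = 0.2,
        random_state: int | None = 0,
    ):
        self.k_sweep = k_sweep
        self.task = task
        self.fp_radius = fp_radius
        self.fp_bits = fp_bits
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _fingerprint(self, smiles: str):
        mol = Chem.RemoveHs(ent.mol_from_smiles(smiles))
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=self.fp_radius, fpSize=self.fp_bits
        )
        return gen.GetFingerprint(mol)

    def fit(self, X: Sequence, y: Sequence[float]) -> "TanimotoKNN":
        if len(X) == 0:
            raise EmptyInputError("empty training set")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        ks = tuple(int(k) for k in self.k_sweep)
        if any(k < 1 or k > len(X) for k in ks):
            raise ValueError("k values must be positive and <= training-set size")
        self._fps = [self._fingerprint(_smiles_of(x)) for x in X]
        self._y = np.asarray(y, dtype=float)
        self.best_k_ = self._select_k(ks)
        return self

    def _select_k(self, ks: tuple[int, ...]) -> int:
        if len(ks) == 1:
            return ks[0]
        idx = np.arange(len(self._fps))
        n_val = max(1, int(round(self.val_fraction * len(idx))))
        if len(idx) - n_val < max(ks):
            return ks[0]
        fit_idx, val_idx = train_test_split(
            idx, test_size=n_val, random_state=self.random_state, shuffle=True
        )
        fit_fps = [self._fps[i] for i in fit_idx]
        fit_y = self._y[fit_idx]
        best_k, best_score = None, None
        for k in ks:
            preds = np.array(
                [
                    self._neighbour_predict(self._fps[i], fit_fps, fit_y, k)[0]
                    for i in val_idx
                ]
            )
            if self.task == "classification":
                score = -accuracy_score(self._y[val_idx], preds >= 0.5)
            else:
                score = mean_absolute_error(self._y[val_idx], preds)
            if best_score is None or score < best_score:
                best_k, best_score = k, score
        return best_k

    def _neighbour_predict(self, fp, fps, y, k) -> tuple[float, bool]:
        sims = np.asarray(DataStructs.BulkTanimotoSimilarity(fp, fps))
        flagged = fp.GetNumOnBits() == 0
        order = np.argsort(-sims, kind="stable")[:k]
        if self.task == "classification":
            votes = Counter(y[order])
            top = votes.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                # vote tie: side with the more similar neighbour
                return float(y[order[0]]), flagged
            return float(top[0][0]), flagged
        return float(np.mean(y[order])), flagged

    def predict(self, X: Sequence) -> np.ndarray:
        if not hasattr(self, "best_k_"):
            raise RuntimeError("TanimotoKNN must be fit before predict")
        out, flags = [], []
        for x in X:
            fp = self._fingerprint(_smiles_of(x))
            pred, flagged = self._neighbour_predict(
                fp, self._fps, self._y, self.best_k_
            )
            out.append(pred)
            flags.append(flagged)
        self.flags_ = np.asarray(flags)
        return np.asarray(out)


class RandomForestGrid(BaseEstimator):
    """Random forest fitted by exhaustive grid search with k-fold CV.

    The full 3x3x3 grid (trees x min-leaf x min-split by default) is
    scored by cross-validation on the training set; the best triple is
    refit on all of train.  Seed-reproducible via ``random_state``.

    Attributes
    ----------
    best_params_ : dict
        Selected ``n_estimators`` / ``min_samples_leaf`` /
        ``min_samples_split``.
    best_estimator_ : sklearn forest
        The refit model used for prediction.
    """

    def __init__(
        self,
        n_trees_grid: Sequence[int] = (25, 100, 200),
        min_leaf_grid: Sequence[int] = (1, 2, 5),
        min_split_grid: Sequence[int] = (2, 3, 5),
        cv_folds: int = 5,
        task: str = "regression",
        random_state: int | None = 0,
    ):
        self.n_trees_grid = n_trees_grid
        self.min_leaf_grid = min_leaf_grid
        self.min_split_grid = min_split_grid
        self.cv_folds = cv_folds
        self.task = task
        self.random_state = random_state

    def fit(self, X, y) -> "RandomForestGrid":
        cfg = RfConfig(
            tuple(self.n_trees_grid),
            tuple(self.min_leaf_grid),
            tuple(self.min_split_grid),
            self.cv_folds,
            self.task,
            self.random_state,
        )
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(X) < cfg.cv_folds:
            raise ValueError(
                f"{len(X)} training rows < {cfg.cv_folds} cross-validation folds"
            )
        if cfg.task == "classification":
            base = RandomForestClassifier(random_state=cfg.random_state)
            scoring = "accuracy"
        else:
            base = RandomForestRegressor(random_state=cfg.random_state)
            scoring = "neg_mean_absolute_error"
        grid = GridSearchCV(
            base,
            param_grid={
                "n_estimators": list(cfg.n_trees_grid),
                "min_samples_leaf": list(cfg.min_leaf_grid),
                "min_samples_split": list(cfg.min_split_grid),
            },
            cv=cfg.cv_folds,
            scoring=scoring,
        )
        grid.fit(X, y)
        self.best_params_ = grid.best_params_
        self.best_estimator_ = grid.best_estimator_
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "best_estimator_"):
            raise RuntimeError("RandomForestGrid must be fit before predict")
        return self.best_estimator_.predict(np.asarray(X, dtype=float))


def knn_predict(
    train: Sequence,
    train_targets: Sequence[float],
    test: Sequence,
    config: KnnConfig | None = None,
) -> tuple[np.ndarray, int]:
    """Tanimoto-kNN predictions for ``test``; returns (predictions, k)."""
    config = config or KnnConfig()
    model = TanimotoKNN(**dataclasses.asdict(config))
    model.fit(train, train_targets)
    return model.predict(test), model.best_k_


def rf_fit_predict(
    train: DescriptorMatrix,
    test: DescriptorMatrix,
    config: RfConfig | None = None,
) -> tuple[np.ndarray, dict]:
    """Grid-searched random forest: fit on train, predict test.

    Train and test must have identical feature columns; train must carry
    targets.  Returns (predictions, chosen hyperparameters).
    """
    config = config or RfConfig()
    if train.feature_names != test.feature_names:
        raise ValueError("train and test feature columns differ")
    if train.targets is None:
        raise ValueError("training matrix has no targets")
    model = RandomForestGrid(**dataclasses.asdict(config))
    model.fit(train.values, train.targets)
    return model.predict(test.values), dict(model.best_params_)


def evaluate(
    predictions: Sequence[float],
    truths: Sequence[float],
    task: str = "regression",
) -> MetricReport:
    """Standard QSAR metrics for a prediction set.

    Regression: MAPE (percent, zero-target rows excluded and counted),
    MAE, RMSE and R^2 (flagged undefined when the truths are constant).
    Classification: ROC AUC of the scores and accuracy at threshold 0.5.
    """
    yhat = np.asarray(predictions, dtype=float)
    y = np.asarray(truths, dtype=float)
    if yhat.shape != y.shape:
        raise ValueError("predictions and truths have different lengths")
    if y.size == 0:
        raise EmptyInputError("nothing to evaluate")
    report = MetricReport(task=task, n=int(y.size))
    if task == "classification":
        report.roc_auc = float(roc_auc_score(y, yhat))
        report.accuracy = float(accuracy_score(y, yhat >= 0.5))
        return report
    report.mae = float(mean_absolute_error(y, yhat))
    report.rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    nonzero = y != 0
    report.n_zero_targets_excluded = int((~nonzero).sum())
    if nonzero.any():
        report.mape = float(
            np.mean(np.abs((y[nonzero] - yhat[nonzero]) / y[nonzero])) * 100.0
        )
    if np.allclose(y, y[0]):
        report.r2_defined = False
        report.r2 = None
    else:
        report.r2 = float(r2_score(y, yhat))
    return report
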