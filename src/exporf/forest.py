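"""Random-forest classifier with per-tree vote access and OOB bookkeeping.

The ensemble grows ``ntree`` CART trees, each on a bootstrap sample of the
training subjects, sampling ``mtry`` candidate features at every split and
honoring ``nodesize`` (minimum observations in terminal nodes) and
``maxnodes`` (maximum terminal nodes, unbounded when None). The predicted
risk of the positive class is the fraction of trees voting for it — hard
per-tree class votes, not averaged leaf probabilities — so predictions are
multiples of 1/ntree. Out-of-bag membership per tree is recorded for the
permutation-importance computation.

Individual trees are scikit-learn ``DecisionTreeClassifier`` objects; the
bagging loop, OOB bookkeeping, and vote aggregation are explicit so that
the bootstrap stream is fully controlled by the run seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from ._rng import stage_seed
from .exceptions import ContractError, ParameterError, SchemaError, StratificationError
from .metrics import roc_auc

__all__ = [
    "RFHyperParams",
    "RandomForest",
    "TuningResult",
    "default_tuning_grid",
    "stratified_split",
    "fit_forest",
    "tune_forest",
    "predict_risk",
]


@dataclass(frozen=True)
class RFHyperParams:
    """The four tuned forest hyperparameters."""

    mtry: int
    ntree: int = 500
    nodesize: int = 1
    maxnodes: int | None = None

    def __post_init__(self) -> None:
        if self.mtry < 1:
            raise ParameterError("mtry must be >= 1")
        if self.ntree < 1:
            raise ParameterError("ntree must be >= 1")
        if self.nodesize < 1:
            raise ParameterError("nodesize must be >= 1")
        if self.maxnodes is not None and self.maxnodes < 2:
            raise ParameterError("maxnodes must be >= 2 or None (unbounded)")

    def with_mtry_cap(self, p: int) -> "RFHyperParams":
        return RFHyperParams(min(self.mtry, p), self.ntree, self.nodesize, self.maxnodes)


def default_tuning_grid(
    p: int,
    ntrees: Sequence[int] = (500, 1000),
    nodesizes: Sequence[int] = (1, 5, 10),
    maxnodes: Sequence[int | None] = (None, 64, 256),
) -> tuple[RFHyperParams, ...]:
    """Default grid: mtry in {floor(sqrt p), floor(p/5), floor(p/3)} x the rest."""
    mtrys = sorted({max(1, int(np.sqrt(p))), max(1, p // 5), max(1, p // 3)})
    return tuple(
        RFHyperParams(m, t, ns, mx)
        for m in mtrys
        for t in ntrees
        for ns in nodesizes
        for mx in maxnodes
    )


def _as_matrix(
    features: pd.DataFrame | np.ndarray, feature_ids: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        if feature_ids is not None:
            missing = set(feature_ids) - set(features.columns)
            if missing:
                raise SchemaError(f"feature columns missing: {sorted(missing)}")
            features = features.loc[:, list(feature_ids)]
        ids = [str(c) for c in features.columns]
        X = np.ascontiguousarray(features.to_numpy(dtype=np.float32))
    else:
        X = np.ascontiguousarray(np.asarray(features, dtype=np.float32))
        if feature_ids is not None and X.shape[1] != len(feature_ids):
            raise SchemaError(
                f"feature matrix has {X.shape[1]} columns, model expects {len(feature_ids)}"
            )
        ids = (
            list(feature_ids)
            if feature_ids is not None
            else [f"x{j}" for j in range(X.shape[1])]
        )
    return X, ids


def stratified_split(
    labels: Sequence[int], test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Class-stratified random train/test split.

    Per-class test counts follow largest-remainder rounding of
    test_fraction * n_class toward a total of round(test_fraction * n), then
    are clamped so every class keeps at least one member on each side.
    """
    labels = np.asarray(labels, dtype=int)
    if not 0 < test_fraction < 1:
        raise ParameterError("test_fraction must be in (0, 1)")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("both classes must be present")
    if counts.min() < 2:
        raise StratificationError("each class needs >= 2 members to stratify")
    rng = np.random.default_rng(seed)
    n_test_total = int(round(test_fraction * len(labels)))
    targets = test_fraction * counts
    alloc = np.floor(targets).astype(int)
    remainder_order = np.argsort(-(targets - alloc), kind="stable")
    for k in remainder_order:
        if alloc.sum() >= n_test_total:
            break
        alloc[k] += 1
    alloc = np.clip(alloc, 1, counts - 1)  # guard: both sides keep every class
    test_parts, train_parts = [], []
    for cls, n_test in zip(classes, alloc):
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(idx)
        test_parts.append(perm[:n_test])
        train_parts.append(perm[n_test:])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    return train, test


@dataclass
class RandomForest:
    """Trained ensemble with per-tree votes and out-of-bag membership."""

    params: RFHyperParams
    feature_ids: list[str]
    trees: list[DecisionTreeClassifier] = field(repr=False)
    oob_mask: np.ndarray = field(repr=False)  # (ntree, n_train) bool
    training_seed: int = 0
    _X_train: np.ndarray = field(repr=False, default=None)
    _y_train: np.ndarray = field(repr=False, default=None)

    @property
    def ntree(self) -> int:
        return len(self.trees)

    def _prepare(self, features) -> np.ndarray:
        X, _ = _as_matrix(features, self.feature_ids)
        return X

    def tree_votes(self, features) -> np.ndarray:
        """(ntree, n) matrix of hard class votes."""
        X = self._prepare(features)
        votes = np.empty((self.ntree, len(X)), dtype=np.int8)
        for t, tree in enumerate(self.trees):
            votes[t] = tree.predict(X, check_input=False).astype(np.int8)
        return votes

    def predict_risk(self, features) -> np.ndarray:
        """Fraction of trees voting the positive class, per subject."""
        X = self._prepare(features)
        acc = np.zeros(len(X))
        for tree in self.trees:
            acc += tree.predict(X, check_input=False)
        return acc / self.ntree

    def oob_coverage(self) -> float:
        return float(self.oob_mask.any(axis=0).mean())


def fit_forest(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence[int],
    params: RFHyperParams,
    seed: int,
    feature_ids: Sequence[str] | None = None,
) -> RandomForest:
    """Grow a forest on bootstrap samples; record OOB membership per tree."""
    X, ids = _as_matrix(features, None if isinstance(features, pd.DataFrame) else feature_ids)
    y = np.asarray(labels, dtype=int)
    if np.isnan(X).any():
        raise ContractError("features contain missing values; impute before fitting")
    n, p = X.shape
    if params.mtry > p:
        raise ParameterError(f"mtry={params.mtry} exceeds the {p} available features")
    rng = np.random.default_rng(seed)
    trees = []
    oob_mask = np.zeros((params.ntree, n), dtype=bool)
    for t in range(params.ntree):
        boot = rng.integers(0, n, n)
        in_bag = np.zeros(n, dtype=bool)
        in_bag[boot] = True
        oob_mask[t] = ~in_bag
        tree = DecisionTreeClassifier(
            max_features=params.mtry,
            min_samples_leaf=params.nodesize,
            max_leaf_nodes=params.maxnodes,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        trees.append(tree)
    model = RandomForest(
        params=params,
        feature_ids=ids,
        trees=trees,
        oob_mask=oob_mask,
        training_seed=int(seed),
        _X_train=X,
        _y_train=y,
    )
    if n > 0 and model.oob_coverage() < 0.99:
        warnings.warn(
            f"OOB coverage {model.oob_coverage():.3f} < 0.99 at ntree={params.ntree}; "
            "importance estimates may be unstable",
            stacklevel=2,
        )
    return model


def predict_risk(model: RandomForest, features) -> np.ndarray:
    return model.predict_risk(features)


@dataclass
class TuningResult:
    """Grid-search + k-fold CV outcome."""

    grid: tuple[RFHyperParams, ...]
    cv_auc: np.ndarray
    best: RFHyperParams
    folds: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mtry": [g.mtry for g in self.grid],
                "ntree": [g.ntree for g in self.grid],
                "nodesize": [g.nodesize for g in self.grid],
                "maxnodes": [g.maxnodes if g.maxnodes is not None else -1 for g in self.grid],
                "cv_auc": self.cv_auc,
                "selected": [g == self.best for g in self.grid],
            }
        )


def _tiebreak_key(auc: float, g: RFHyperParams):
    # highest AUC; then cheapest/most regularized: smallest ntree, largest
    # nodesize, smallest mtry, smallest maxnodes (unbounded last)
    mx = g.maxnodes if g.maxnodes is not None else np.inf
    return (-round(auc, 12), g.ntree, -g.nodesize, g.mtry, mx)


def _cv_folds(y: np.ndarray, folds: int, seed: int):
    if folds < 2:
        raise ParameterError("cv_folds must be >= 2")
    if np.bincount(y, minlength=2).min() < folds:
        raise StratificationError(
            f"minority class smaller than the number of folds ({folds})"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31 - 1))
    assignment = list(skf.split(np.zeros(len(y)), y))
    for _, val in assignment:
        if len(np.unique(y[val])) < 2:
            raise StratificationError("a CV fold contains a single class")
    return assignment


def tune_forest(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence[int],
    grid: Sequence[RFHyperParams],
    folds: int,
    seed: int,
) -> TuningResult:
    """Mean out-of-fold AUC per grid point; fold assignment shared across points.

    Tree seeds depend only on (seed, fold), never on the grid point or its
    position, so permuting the grid cannot change the selected combination.
    """
    grid = tuple(grid)
    if not grid:
        raise ParameterError("tuning grid is empty")
    X, ids = _as_matrix(features)
    y = np.asarray(labels, dtype=int)
    assignment = _cv_folds(y, folds, seed)
    fold_seeds = [stage_seed(seed, f"cv_fold_{k}") for k in range(folds)]
    cv_auc = np.zeros(len(grid))
    for gi, g in enumerate(grid):
        aucs = []
        for k, (tr, val) in enumerate(assignment):
            model = fit_forest(X[tr], y[tr], g.with_mtry_cap(X.shape[1]), fold_seeds[k], ids)
            aucs.append(roc_auc(model.predict_risk(X[val]), y[val]))
        cv_auc[gi] = float(np.mean(aucs))
    best = min(zip(cv_auc, grid), key=lambda t: _tiebreak_key(*t))[1]
    return TuningResult(grid=grid, cv_auc=cv_auc, best=best, folds=folds, seed=int(seed))
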