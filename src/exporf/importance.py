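"""Permutation variable importance and cross-validated feature-count selection.

The importance of a feature is its mean decrease in accuracy (MDA): for
each tree, the tree's accuracy on its out-of-bag subjects minus its
accuracy on the same subjects after the feature's column is randomly
permuted (one fresh permutation per tree), averaged over trees. Raw,
unscaled values are reported so they stay in accuracy units; noise
features can be slightly negative, and a feature the ensemble never split
on scores exactly zero.

The number of retained top-ranked features q is treated as an extra tuning
parameter: for each candidate q, the forest is refit on the top-q features
under k-fold cross-validation (with the previously selected
hyperparameters, mtry capped at q) and the mean CV AUC is recorded. The
"flattening" of the resulting curve is operationalized as the smallest q
whose CV AUC comes within epsilon of the curve's maximum; the full curve
is always emitted so the choice can be overridden by eye.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import stage_seed
from .exceptions import ContractError, ParameterError
from .forest import RandomForest, RFHyperParams, _cv_folds, fit_forest
from .metrics import roc_auc

__all__ = [
    "ImportanceRanking",
    "QCurve",
    "permutation_importance",
    "q_performance_curve",
    "select_q",
]


@dataclass
class ImportanceRanking:
    """Features ordered by descending MDA (ties broken by feature id)."""

    feature_ids: list[str]
    mda: np.ndarray
    permutation_seed: int
    n_top_displayed: int = 30

    def top(self, q: int) -> list[str]:
        return self.feature_ids[:q]

    def rank_of(self, feature_id: str) -> int:
        """1-based rank of a feature."""
        return self.feature_ids.index(feature_id) + 1

    def to_frame(self, feature_meta: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.feature_ids) + 1),
                "feature_id": self.feature_ids,
                "mda": self.mda,
            }
        )
        if feature_meta is not None:
            df.insert(2, "kind", feature_meta.loc[df["feature_id"], "kind"].to_numpy())
            df.insert(3, "domain", feature_meta.loc[df["feature_id"], "domain"].to_numpy())
        return df


def permutation_importance(
    model: RandomForest,
    features=None,
    labels=None,
    seed: int = 0,
    n_repeats: int = 1,
) -> ImportanceRanking:
    """OOB permutation importance (mean decrease in accuracy) per feature.

    Computed on the model's own training data, out-of-bag per tree. If
    ``features``/``labels`` are passed they must match the training set.
    """
    X = model._X_train
    y = model._y_train
    if X is None:
        raise ContractError("model carries no training data")
    if features is not None:
        Xq = model._prepare(features)
        if Xq.shape != X.shape or not np.array_equal(Xq, X):
            raise ContractError("supplied rows do not match the model's training set")
    if labels is not None and not np.array_equal(np.asarray(labels, dtype=int), y):
        raise ContractError("supplied labels do not match the model's training labels")

    p = X.shape[1]
    rng = np.random.default_rng(seed)
    drops = np.zeros((model.ntree, p))
    used = np.zeros(model.ntree, dtype=bool)
    for t, tree in enumerate(model.trees):
        oob = np.flatnonzero(model.oob_mask[t])
        if len(oob) == 0:
            continue
        used[t] = True
        Xo = np.ascontiguousarray(X[oob])
        yo = y[oob]
        base_acc = float((tree.predict(Xo, check_input=False) == yo).mean())
        split_on = np.zeros(p, dtype=bool)
        feat_idx = tree.tree_.feature
        split_on[feat_idx[feat_idx >= 0]] = True
        for j in range(p):
            if not split_on[j]:
                continue  # permuting an unused feature is a no-op: drop stays 0
            acc = 0.0
            col = Xo[:, j].copy()
            for _ in range(n_repeats):
                Xo[:, j] = col[rng.permutation(len(col))]
                acc += float((tree.predict(Xo, check_input=False) == yo).mean())
            Xo[:, j] = col
            drops[t, j] = base_acc - acc / n_repeats
    if not used.any():
        raise ContractError("no tree has out-of-bag rows; cannot compute importance")
    mda = drops[used].mean(axis=0)
    order = sorted(range(p), key=lambda j: (-mda[j], model.feature_ids[j]))
    return ImportanceRanking(
        feature_ids=[model.feature_ids[j] for j in order],
        mda=mda[order],
        permutation_seed=int(seed),
    )


@dataclass
class QCurve:
    """(q, CV AUC) pairs and the q selected by the flattening rule."""

    q_values: np.ndarray
    cv_auc: np.ndarray
    selected_q: int
    epsilon: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "q": self.q_values,
                "cv_auc": self.cv_auc,
                "selected": self.q_values == self.selected_q,
            }
        )


def select_q(curve: QCurve | Sequence[tuple[int, float]], epsilon: float = 0.005) -> int:
    """Smallest q whose CV AUC is within epsilon of the curve maximum."""
    if isinstance(curve, QCurve):
        qs, aucs = np.asarray(curve.q_values), np.asarray(curve.cv_auc)
    else:
        pairs = list(curve)
        qs = np.asarray([q for q, _ in pairs])
        aucs = np.asarray([a for _, a in pairs])
    if len(qs) == 0:
        raise ContractError("empty q curve")
    cutoff = aucs.max() - epsilon
    order = np.argsort(qs)
    for i in order:
        if aucs[i] >= cutoff:
            return int(qs[i])
    return int(qs[order[-1]])  # unreachable: the max itself qualifies


def q_performance_curve(
    features: pd.DataFrame,
    labels: Sequence[int],
    ranking: ImportanceRanking,
    params: RFHyperParams,
    q_grid: Sequence[int],
    folds: int,
    seed: int,
    epsilon: float = 0.005,
) -> QCurve:
    """CV AUC of the top-q-feature model for each q; fold assignment shared."""
    y = np.asarray(labels, dtype=int)
    p = len(ranking.feature_ids)
    q_values = sorted(set(int(q) for q in q_grid))
    if not q_values:
        raise ParameterError("q_grid is empty")
    if q_values[0] < 1 or q_values[-1] > p:
        raise ParameterError(f"q_grid must lie within [1, {p}]")
    assignment = _cv_folds(y, folds, seed)
    fold_seeds = [stage_seed(seed, f"q_cv_fold_{k}") for k in range(folds)]
    cv_auc = np.zeros(len(q_values))
    for qi, q in enumerate(q_values):
        cols = ranking.top(q)
        Xq = features.loc[:, cols]
        pq = params.with_mtry_cap(q)
        aucs = []
        for k, (tr, val) in enumerate(assignment):
            model = fit_forest(Xq.iloc[tr], y[tr], pq, fold_seeds[k])
            aucs.append(roc_auc(model.predict_risk(Xq.iloc[val]), y[val]))
        cv_auc[qi] = float(np.mean(aucs))
    curve = QCurve(
        q_values=np.asarray(q_values),
        cv_auc=cv_auc,
        selected_q=0,
        epsilon=float(epsilon),
    )
    curve.selected_q = select_q(curve, epsilon)
    return curve
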