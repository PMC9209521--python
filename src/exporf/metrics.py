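"""Discrimination, threshold, and calibration metrics for binary risk scores.

The positive class (label 1) is the poor/fair health outcome throughout.
The AUC is the Mann-Whitney probability that a random positive outscores a
random negative, with ties counted 1/2; its confidence interval uses the
DeLong structural-components variance with a normal approximation (a
stratified bootstrap is provided as a cross-check). The "optimal" ROC
threshold maximizes sensitivity + specificity (the Youden criterion), with
ties broken toward the smaller threshold, which favors sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ContractError

__all__ = [
    "roc_auc",
    "auc_ci",
    "bootstrap_auc_ci",
    "optimal_threshold",
    "threshold_metrics",
    "calibration_in_the_large",
    "calibration_curve",
    "evaluate",
    "EvaluationReport",
]


def _check_binary(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if not set(classes) <= {0, 1} or len(classes) < 2:
        raise ContractError("labels must contain both classes 0 and 1")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_binary(labels)
    m = int(labels.sum())
    n = len(labels) - m
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - m * (m + 1) / 2) / (m * n))


def _midrank_components(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def auc_ci(
    scores: Sequence[float], labels: Sequence[int], level: float = 0.95
) -> tuple[float, float]:
    """DeLong normal-approximation confidence interval, truncated to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_binary(labels)
    if min((labels == 1).sum(), (labels == 0).sum()) < 2:
        raise ContractError("need >= 2 members of each class for a CI")
    v10, v01 = _midrank_components(scores, labels)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def bootstrap_auc_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified percentile-bootstrap interval (cross-check for `auc_ci`)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_binary(labels)
    rng = np.random.default_rng(seed)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    aucs = np.empty(n_boot)
    ones = np.ones(len(pos), dtype=int)
    zeros = np.zeros(len(neg), dtype=int)
    lab = np.concatenate([ones, zeros])
    for b in range(n_boot):
        sb = np.concatenate(
            [rng.choice(pos, len(pos)), rng.choice(neg, len(neg))]
        )
        aucs[b] = roc_auc(sb, lab)
    alpha = (1 - level) / 2
    return (float(np.quantile(aucs, alpha)), float(np.quantile(aucs, 1 - alpha)))


def _threshold_scan(scores: np.ndarray, labels: np.ndarray):
    """Sensitivity/specificity at every candidate threshold (score >= t is positive)."""
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    m = labels.sum()
    n = len(labels) - m
    sens = np.array([(scores[labels == 1] >= t).sum() / m for t in candidates])
    spec = np.array([(scores[labels == 0] < t).sum() / n for t in candidates])
    return candidates, sens, spec


def optimal_threshold(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float]:
    """Youden-optimal ROC threshold; returns (threshold, sensitivity, specificity)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_binary(labels)
    candidates, sens, spec = _threshold_scan(scores, labels)
    # round so mathematically tied sums compare equal despite float addition order
    j = np.round(sens + spec, 12)
    best = int(np.flatnonzero(j == j.max())[0])  # smallest threshold among ties
    return float(candidates[best]), float(sens[best]), float(spec[best])


def threshold_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) classifying score >= threshold as positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_binary(labels)
    pred = (scores >= threshold).astype(int)
    sens = float((pred[labels == 1] == 1).mean())
    spec = float((pred[labels == 0] == 0).mean())
    acc = float((pred == labels).mean())
    return sens, spec, acc


def calibration_in_the_large(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float]:
    """(mean predicted risk, observed prevalence, their difference)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) == 0:
        raise ContractError("empty input")
    mp = float(scores.mean())
    prev = float(labels.mean())
    return mp, prev, mp - prev


def calibration_curve(
    scores: Sequence[float], labels: Sequence[int], n_bins: int = 10
) -> pd.DataFrame:
    """Quantile-binned calibration curve: mean predicted vs observed per bin.

    Decile bins by default; duplicate quantile edges (massive score ties)
    are merged, so a constant score vector yields a single bin.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) == 0:
        raise ContractError("empty input")
    edges = np.unique(np.quantile(scores, np.linspace(0, 1, n_bins + 1)))
    if len(edges) == 1:
        assign = np.zeros(len(scores), dtype=int)
        n_eff = 1
    else:
        assign = np.clip(np.searchsorted(edges, scores, side="right") - 1, 0, len(edges) - 2)
        n_eff = len(edges) - 1
    rows = []
    for k in range(n_eff):
        in_bin = assign == k
        if not in_bin.any():
            continue
        rows.append(
            {
                "bin": k,
                "mean_predicted": float(scores[in_bin].mean()),
                "observed_fraction": float(labels[in_bin].mean()),
                "n": int(in_bin.sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Discrimination, threshold, and calibration summary for one model."""

    auc: float
    auc_ci: tuple[float, float]
    optimal_threshold: float
    sens_at_optimal: float
    spec_at_optimal: float
    sens_spec_sum: float
    accuracy_at_half: float
    sens_at_half: float
    spec_at_half: float
    mean_predicted_risk: float
    observed_prevalence: float
    calibration_difference: float
    calibration_bins: pd.DataFrame = field(repr=False, default=None)
    n: int = 0

    def to_row(self, model: str = "total") -> dict:
        return {
            "model": model,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "threshold": self.optimal_threshold,
            "specificity_at_optimal": self.spec_at_optimal,
            "sensitivity_at_optimal": self.sens_at_optimal,
            "sens_spec_sum": self.sens_spec_sum,
            "accuracy_at_half": self.accuracy_at_half,
            "specificity_at_half": self.spec_at_half,
            "sensitivity_at_half": self.sens_at_half,
            "mean_predicted_risk": self.mean_predicted_risk,
            "observed_prevalence": self.observed_prevalence,
            "n": self.n,
        }


def evaluate(
    scores: Sequence[float],
    labels: Sequence[int],
    level: float = 0.95,
    n_bins: int = 10,
) -> EvaluationReport:
    """Full evaluation of a risk score vector against binary labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    thr, sens, spec = optimal_threshold(scores, labels)
    sens_h, spec_h, acc_h = threshold_metrics(scores, labels, 0.5)
    mp, prev, diff = calibration_in_the_large(scores, labels)
    return EvaluationReport(
        auc=roc_auc(scores, labels),
        auc_ci=auc_ci(scores, labels, level),
        optimal_threshold=thr,
        sens_at_optimal=sens,
        spec_at_optimal=spec,
        sens_spec_sum=sens + spec,
        accuracy_at_half=acc_h,
        sens_at_half=sens_h,
        spec_at_half=spec_h,
        mean_predicted_risk=mp,
        observed_prevalence=prev,
        calibration_difference=diff,
        calibration_bins=calibration_curve(scores, labels, n_bins),
        n=len(labels),
    )
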