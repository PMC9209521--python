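"""Partial dependence and accumulated local effects curves.

A PDP answers "what is the average predicted risk when everyone's value of
this feature is forced to g, with all other features kept at their own
values", evaluated on a grid of g spanning the feature's 5th-95th
percentiles (by default). An ALE curve instead accumulates *local* effects:
within each empirical quantile bin of the feature, the mean difference in
prediction between the bin's upper and lower edge is computed using only
the subjects in that bin, the differences are cumulatively summed across
bins, and the result is centered so its data-weighted mean is zero. Because
each difference is evaluated only on subjects actually located in the bin,
ALE largely avoids extrapolating into feature combinations that never
occur.

Any object exposing ``predict_risk(features) -> probabilities`` and
``feature_ids`` can be curved, so exact-function stubs can stand in for a
forest in tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ContractError

__all__ = ["EffectCurve", "ConcordanceSummary", "pdp", "ale", "curve_concordance"]

logger = logging.getLogger("exporf")

MAX_DISCRETE_LEVELS = 10  # features with <= this many unique values keep exact levels


@dataclass
class EffectCurve:
    """Grid and effect values for one feature's PDP or ALE curve."""

    feature_id: str
    kind: str  # "PDP" | "ALE"
    grid: np.ndarray
    effect: np.ndarray
    clip: tuple[float, float]
    n_bins: int | None = None
    reference_level: float | None = None
    n_in_bin: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature_id": self.feature_id,
                "kind": self.kind,
                "grid_value": self.grid,
                "effect": self.effect,
            }
        )
        if self.n_in_bin is not None:
            # bin counts attach to the upper edge of each ALE bin
            df["n_in_bin"] = np.concatenate([[0], self.n_in_bin])
        return df


def _column(features: pd.DataFrame, feature_id: str) -> np.ndarray:
    if feature_id not in features.columns:
        raise ContractError(f"feature {feature_id!r} not in the feature table")
    return features[feature_id].to_numpy(dtype=float)


def _predict_with_column(model, features: pd.DataFrame, feature_id: str, value) -> np.ndarray:
    modified = features.copy()
    modified[feature_id] = value
    return np.asarray(model.predict_risk(modified), dtype=float)


def pdp(
    model,
    features: pd.DataFrame,
    feature_id: str,
    grid_size: int = 50,
    clip: tuple[float, float] = (0.05, 0.95),
    reference_level: float | None = None,
) -> EffectCurve:
    """Partial dependence of the predicted risk on one feature.

    Continuous features get ``grid_size`` equally spaced points between the
    clip percentiles; features with few unique values (indicators,
    proportions of five rounds) keep their exact observed levels.
    """
    x = _column(features, feature_id)
    levels = np.unique(x)
    if len(levels) == 1:
        warnings.warn(f"{feature_id} has zero variance; returning a single-point curve",
                      stacklevel=2)
        grid = levels
    elif len(levels) <= MAX_DISCRETE_LEVELS:
        grid = levels
    else:
        lo, hi = np.quantile(x, clip)
        grid = np.linspace(lo, hi, grid_size)
    effect = np.array(
        [_predict_with_column(model, features, feature_id, g).mean() for g in grid]
    )
    return EffectCurve(
        feature_id=feature_id,
        kind="PDP",
        grid=grid,
        effect=effect,
        clip=clip,
        reference_level=reference_level,
    )


def ale(
    model,
    features: pd.DataFrame,
    feature_id: str,
    n_bins: int = 20,
    clip: tuple[float, float] = (0.05, 0.95),
) -> EffectCurve:
    """Accumulated local effects over empirical quantile bins.

    The effect is reported at the bin edges; centering subtracts the mean
    accumulated effect over the data (the curve interpolated at each
    subject's own value), so the curve's data-weighted mean is zero. Duplicate
    quantile edges from heavy ties are merged (and logged); indicator
    features fall back to a centered two-level difference.
    """
    if n_bins < 1:
        raise ContractError("n_bins must be >= 1")
    x = _column(features, feature_id)
    levels = np.unique(x)
    if len(levels) == 1:
        return EffectCurve(feature_id, "ALE", levels, np.zeros(1), clip, n_bins=0)
    if len(levels) == 2:
        lo, hi = levels
        in_hi = x == hi
        delta = float(
            (
                _predict_with_column(model, features, feature_id, hi)
                - _predict_with_column(model, features, feature_id, lo)
            ).mean()
        )
        center = in_hi.mean() * delta
        return EffectCurve(
            feature_id,
            "ALE",
            np.array([lo, hi]),
            np.array([-center, delta - center]),
            clip,
            n_bins=1,
            n_in_bin=np.array([len(x)]),
        )

    lo, hi = np.quantile(x, clip)
    keep = (x >= lo) & (x <= hi)
    xk = x[keep]
    rows = features.loc[keep]
    edges = np.unique(np.quantile(xk, np.linspace(0, 1, n_bins + 1)))
    if len(edges) - 1 < n_bins:
        logger.info(
            "%s: merged %d tied quantile bins", feature_id, n_bins - (len(edges) - 1)
        )
    n_eff = len(edges) - 1
    assign = np.clip(np.searchsorted(edges, xk, side="right") - 1, 0, n_eff - 1)
    deltas = np.zeros(n_eff)
    counts = np.zeros(n_eff, dtype=int)
    for k in range(n_eff):
        in_bin = assign == k
        counts[k] = int(in_bin.sum())
        if counts[k] == 0:
            continue
        sub = rows.loc[in_bin]
        upper = _predict_with_column(model, sub, feature_id, edges[k + 1])
        lower = _predict_with_column(model, sub, feature_id, edges[k])
        deltas[k] = float((upper - lower).mean())
    accumulated = np.concatenate([[0.0], np.cumsum(deltas)])
    # center at the data: each subject contributes the accumulated effect
    # interpolated at their own feature value
    center = float(np.interp(xk, edges, accumulated).mean())
    return EffectCurve(
        feature_id,
        "ALE",
        edges,
        accumulated - center,
        clip,
        n_bins=n_eff,
        n_in_bin=counts,
    )


@dataclass
class ConcordanceSummary:
    """Sign agreement of PDP and ALE slopes on shared grid segments."""

    feature_id: str
    agreement: float
    n_segments: int
    discordant_segments: list[tuple[float, float]]


def _slope_signs(grid: np.ndarray, effect: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    slopes = np.diff(effect) / np.diff(grid)
    signs = np.sign(slopes)
    signs[np.abs(slopes) < tol] = 0.0
    return signs


def curve_concordance(pdp_curve: EffectCurve, ale_curve: EffectCurve) -> ConcordanceSummary:
    """Compare slope signs of a PDP and an ALE curve for the same feature."""
    if pdp_curve.feature_id != ale_curve.feature_id:
        raise ContractError("curves describe different features")
    lo = max(pdp_curve.grid.min(), ale_curve.grid.min())
    hi = min(pdp_curve.grid.max(), ale_curve.grid.max())
    keep = (pdp_curve.grid >= lo) & (pdp_curve.grid <= hi)
    grid = pdp_curve.grid[keep]
    if len(grid) < 2 or lo >= hi:
        raise ContractError("curves have no overlapping grid segment")
    pdp_eff = pdp_curve.effect[keep]
    ale_eff = np.interp(grid, ale_curve.grid, ale_curve.effect)
    s_pdp = _slope_signs(grid, pdp_eff)
    s_ale = _slope_signs(grid, ale_eff)
    agree = s_pdp == s_ale
    discordant = [
        (float(grid[i]), float(grid[i + 1])) for i in np.flatnonzero(~agree)
    ]
    return ConcordanceSummary(
        feature_id=pdp_curve.feature_id,
        agreement=float(agree.mean()),
        n_segments=len(agree),
        discordant_segments=discordant,
    )
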