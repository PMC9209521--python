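"""Optional matplotlib renderings of the emitted result tables.

Everything here re-draws data already written as CSV; nothing downstream
depends on these figures. Requires the ``plot`` extra (matplotlib).
"""

from __future__ import annotations

import numpy as np

from .effects import EffectCurve
from .importance import ImportanceRanking, QCurve

__all__ = ["plot_effect_curve", "plot_q_curve", "plot_importance"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(4.5, 3.2))
    return ax


def plot_effect_curve(curve: EffectCurve, ax=None):
    """One PDP or ALE curve; PDPs get the dotted prevalence reference line."""
    ax = _ax(ax)
    ax.plot(curve.grid, curve.effect, marker="." if len(curve.grid) <= 2 else None)
    if curve.kind == "PDP" and curve.reference_level is not None:
        ax.axhline(curve.reference_level, color="gray", linestyle=":", linewidth=1)
    ax.set_xlabel(curve.feature_id)
    ax.set_ylabel("mean predicted risk" if curve.kind == "PDP" else "accumulated local effect")
    ax.set_title(f"{curve.kind}: {curve.feature_id}", fontsize=9)
    return ax


def plot_q_curve(curve: QCurve, ax=None):
    """CV AUC against the number of retained top-ranked exposures q."""
    ax = _ax(ax)
    ax.plot(curve.q_values, curve.cv_auc, marker="o", markersize=3)
    ax.axvline(curve.selected_q, color="gray", linestyle=":", linewidth=1)
    ax.set_xlabel("number of exposures q")
    ax.set_ylabel("cross-validated AUC")
    return ax


def plot_importance(ranking: ImportanceRanking, n_top: int | None = None, ax=None):
    """Horizontal bar chart of the top-ranked exposures by MDA."""
    ax = _ax(ax)
    n = n_top if n_top is not None else ranking.n_top_displayed
    ids = ranking.feature_ids[:n][::-1]
    vals = np.asarray(ranking.mda[:n][::-1])
    ax.barh(ids, vals)
    ax.set_xlabel("mean decrease in accuracy")
    ax.tick_params(axis="y", labelsize=7)
    return ax
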