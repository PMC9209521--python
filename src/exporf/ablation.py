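"""Domain ablation: refit the pipeline with one exposure domain removed.

Each ablated model is tuned (optionally), fitted on the same training
split, and evaluated on the same held-out test subjects as the total
model, so differences in test AUC isolate the removed domain's
contribution to discrimination. All variants share the same tuning and
fitting seeds; ablating a domain that contains no features therefore
reproduces the total model's row exactly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import stage_seed
from .config import RunConfig
from .exceptions import ParameterError
from .forest import default_tuning_grid, fit_forest, stratified_split, tune_forest
from .metrics import evaluate
from .summaries import SummaryFeatureTable

__all__ = ["domain_ablation"]


def domain_ablation(
    table: SummaryFeatureTable,
    labels: Sequence[int],
    config: RunConfig,
    base_params=None,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """One evaluation row per model: total, then minus each domain present.

    With ``config.ablation_retune`` (default) every variant re-runs the
    grid search on the training split; otherwise ``base_params`` (e.g. the
    total model's tuned parameters) are reused everywhere.
    """
    y = np.asarray(labels, dtype=int)
    if split is None:
        split = stratified_split(y, config.test_fraction, stage_seed(config.seed, "split"))
    train, test = split
    tune_seed = stage_seed(config.seed, "ablation_tune")
    fit_seed = stage_seed(config.seed, "ablation_fit")

    variants = [("total", table)]
    for domain in table.domains:
        variants.append((f"without_{domain}", table.drop_domain(domain)))

    rows = []
    for name, sub in variants:
        if sub.n_features == 0:
            raise ParameterError(f"ablating every feature ({name}) leaves an empty model")
        X = sub.values
        if config.ablation_retune:
            grid = config.tuning_grid or default_tuning_grid(sub.n_features)
            grid = tuple(g.with_mtry_cap(sub.n_features) for g in grid)
            tuning = tune_forest(X.iloc[train], y[train], grid, config.cv_folds, tune_seed)
            params = tuning.best
        else:
            if base_params is None:
                raise ParameterError("base_params required when ablation_retune is off")
            params = base_params.with_mtry_cap(sub.n_features)
        model = fit_forest(X.iloc[train], y[train], params, fit_seed)
        report = evaluate(
            model.predict_risk(X.iloc[test]), y[test],
            level=config.ci_level, n_bins=config.calibration_bins,
        )
        rows.append(report.to_row(model=name))
    return pd.DataFrame(rows)
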