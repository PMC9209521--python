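"""Model / results facade for the six-step exposome prediction pipeline.

``ExposomeForestModel`` is built from a summary feature table (or directly
from a longitudinal cohort) and a binary outcome; ``fit()`` executes the
whole pipeline — stratified split, grid-search tuning, final forest,
held-out evaluation, permutation-importance ranking, cross-validated
selection of the number of predictors q, the reduced top-q model, PDP/ALE
effect curves for the selected predictors, and the domain ablation — and
returns an ``ExposomeForestResults`` carrying every artifact, with a
``summary()`` table and a ``save()`` that writes the report bundle.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import stage_seed
from .ablation import domain_ablation
from .cohort import ExposureSchemaEntry, LongitudinalCohort
from .config import RunConfig
from .effects import EffectCurve, ale, pdp
from .exceptions import ContractError
from .forest import (
    RandomForest,
    TuningResult,
    default_tuning_grid,
    fit_forest,
    stratified_split,
    tune_forest,
)
from .importance import ImportanceRanking, QCurve, permutation_importance, q_performance_curve
from .metrics import EvaluationReport, evaluate
from .summaries import SummaryFeatureTable, summarize_cohort

__all__ = ["ExposomeForestModel", "ExposomeForestResults", "run_pipeline"]

logger = logging.getLogger("exporf")


class ExposomeForestModel:
    """Random-forest exposome predictor of a binary health outcome."""

    def __init__(
        self,
        feature_table: SummaryFeatureTable,
        outcome: pd.Series | Sequence[int],
        config: RunConfig | None = None,
    ) -> None:
        self.table = feature_table
        if isinstance(outcome, pd.Series):
            missing = [s for s in feature_table.subjects if s not in outcome.index]
            if missing:
                raise ContractError(f"subjects without outcome: {missing[:5]}")
            outcome = outcome.loc[feature_table.subjects]
        self.outcome = np.asarray(outcome, dtype=int)
        if len(self.outcome) != len(feature_table.subjects):
            raise ContractError("outcome length does not match the feature table")
        self.config = config or RunConfig()

    @classmethod
    def from_cohort(
        cls,
        cohort: LongitudinalCohort,
        schema: Sequence[ExposureSchemaEntry] | None = None,
        config: RunConfig | None = None,
    ) -> "ExposomeForestModel":
        table = summarize_cohort(cohort, schema)
        return cls(table, cohort.outcome, config)

    # -- pipeline ----------------------------------------------------------

    def fit(self) -> "ExposomeForestResults":
        cfg = self.config
        t0 = time.time()
        X = self.table.values
        y = self.outcome
        p = self.table.n_features

        train, test = stratified_split(y, cfg.test_fraction, stage_seed(cfg.seed, "split"))
        logger.info("split: %d train / %d test", len(train), len(test))

        grid = cfg.tuning_grid or default_tuning_grid(p)
        tuning = tune_forest(
            X.iloc[train], y[train], grid, cfg.cv_folds, stage_seed(cfg.seed, "tune")
        )
        logger.info("tuned: best %s (cv auc %.3f)", tuning.best, tuning.cv_auc.max())

        full_forest = fit_forest(
            X.iloc[train], y[train], tuning.best, stage_seed(cfg.seed, "fit_full")
        )
        full_eval = evaluate(
            full_forest.predict_risk(X.iloc[test]), y[test],
            level=cfg.ci_level, n_bins=cfg.calibration_bins,
        )
        logger.info("full model test AUC %.3f", full_eval.auc)

        if cfg.importance_on == "full":
            logger.warning(
                "importance_on='full': the ranking sees the test rows; "
                "the held-out AUC of the reduced model is optimistic"
            )
            rank_forest = fit_forest(
                X, y, tuning.best, stage_seed(cfg.seed, "fit_rank_full")
            )
        else:
            rank_forest = full_forest
        ranking = permutation_importance(
            rank_forest, seed=stage_seed(cfg.seed, "importance"),
            n_repeats=cfg.importance_repeats,
        )

        q_curve = q_performance_curve(
            X.iloc[train], y[train], ranking, tuning.best,
            cfg.resolved_q_grid(p), cfg.cv_folds,
            stage_seed(cfg.seed, "q_curve"), cfg.flattening_epsilon,
        )
        selected_q = q_curve.selected_q
        logger.info("selected q = %d", selected_q)

        top_features = ranking.top(selected_q)
        Xq = X.loc[:, top_features]
        reduced_forest = fit_forest(
            Xq.iloc[train], y[train],
            tuning.best.with_mtry_cap(selected_q),
            stage_seed(cfg.seed, "fit_reduced"),
        )
        reduced_eval = evaluate(
            reduced_forest.predict_risk(Xq.iloc[test]), y[test],
            level=cfg.ci_level, n_bins=cfg.calibration_bins,
        )
        logger.info("reduced model test AUC %.3f", reduced_eval.auc)

        prevalence = float(y.mean())
        curves: dict[str, dict[str, EffectCurve]] = {}
        for fid in top_features:
            curves[fid] = {
                "pdp": pdp(
                    reduced_forest, Xq, fid, cfg.pdp_grid_size,
                    cfg.percentile_clip, reference_level=prevalence,
                ),
                "ale": ale(reduced_forest, Xq, fid, cfg.ale_bins, cfg.percentile_clip),
            }

        ablation = None
        if cfg.run_ablation:
            ablation = domain_ablation(
                self.table, y, cfg,
                base_params=tuning.best, split=(train, test),
            )

        logger.info("pipeline done in %.1f s", time.time() - t0)
        return ExposomeForestResults(
            model=self,
            config=cfg,
            train_idx=train,
            test_idx=test,
            tuning=tuning,
            full_forest=full_forest,
            full_eval=full_eval,
            importance=ranking,
            q_curve=q_curve,
            selected_q=selected_q,
            reduced_forest=reduced_forest,
            reduced_eval=reduced_eval,
            effect_curves=curves,
            ablation=ablation,
        )


@dataclass
class ExposomeForestResults:
    """Artifacts of one pipeline run."""

    model: ExposomeForestModel
    config: RunConfig
    train_idx: np.ndarray
    test_idx: np.ndarray
    tuning: TuningResult
    full_forest: RandomForest
    full_eval: EvaluationReport
    importance: ImportanceRanking
    q_curve: QCurve
    selected_q: int
    reduced_forest: RandomForest
    reduced_eval: EvaluationReport
    effect_curves: dict[str, dict[str, EffectCurve]] = field(default_factory=dict)
    ablation: pd.DataFrame | None = None

    @property
    def table(self) -> SummaryFeatureTable:
        return self.model.table

    @property
    def selected_features(self) -> list[str]:
        return self.importance.top(self.selected_q)

    def evaluation_frame(self) -> pd.DataFrame:
        rows = [
            self.full_eval.to_row("full"),
            self.reduced_eval.to_row(f"reduced_top_{self.selected_q}"),
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Exposome random-forest pipeline",
            "=" * 64,
            f"subjects: {len(self.model.outcome)}   features: {self.table.n_features}"
            f"   prevalence: {self.model.outcome.mean():.3f}",
            f"split: {len(self.train_idx)} train / {len(self.test_idx)} test"
            f" (test fraction {cfg.test_fraction})",
            f"tuned parameters: mtry={self.tuning.best.mtry} ntree={self.tuning.best.ntree}"
            f" nodesize={self.tuning.best.nodesize} maxnodes={self.tuning.best.maxnodes}",
            "-" * 64,
            f"full model   test AUC {self.full_eval.auc:.3f}"
            f" (95% CI {self.full_eval.auc_ci[0]:.3f}-{self.full_eval.auc_ci[1]:.3f})",
            f"  sens/spec at optimal threshold: {self.full_eval.sens_at_optimal:.3f}"
            f"/{self.full_eval.spec_at_optimal:.3f}"
            f"   mean risk {self.full_eval.mean_predicted_risk:.3f}"
            f" vs prevalence {self.full_eval.observed_prevalence:.3f}",
            f"selected q = {self.selected_q} (epsilon {cfg.flattening_epsilon})",
            f"reduced model test AUC {self.reduced_eval.auc:.3f}"
            f" (95% CI {self.reduced_eval.auc_ci[0]:.3f}-{self.reduced_eval.auc_ci[1]:.3f})",
            "-" * 64,
            "top predictors (mean decrease in accuracy):",
        ]
        n_show = min(self.importance.n_top_displayed, self.selected_q)
        for rank, fid in enumerate(self.importance.top(n_show), start=1):
            lines.append(f"  {rank:2d}. {fid:45s} {self.importance.mda[rank - 1]:+.4f}")
        return "\n".join(lines)

    def save(self, out_dir) -> dict:
        from .reports import write_report_bundle

        return write_report_bundle(self, out_dir)


def run_pipeline(
    cohort: LongitudinalCohort,
    schema: Sequence[ExposureSchemaEntry] | None = None,
    config: RunConfig | None = None,
) -> ExposomeForestResults:
    """Summarize a cohort and run the full pipeline."""
    return ExposomeForestModel.from_cohort(cohort, schema, config).fit()
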