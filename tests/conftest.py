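import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import exporf
from exporf import (
    CategoricalExposure,
    ContinuousExposure,
    EffectSpec,
    RFHyperParams,
    RunConfig,
    SingleRoundExposure,
    SyntheticSpec,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_spec(seed: int = 0, n_subjects: int = 500) -> SyntheticSpec:
    """Compact cohort: 8 exposures -> 14 features, 3 planted signals."""
    exposures = (
        ContinuousExposure("income", "demographic"),
        ContinuousExposure("activity", "lifestyle"),
        ContinuousExposure("noise", "environmental"),
        ContinuousExposure("bmi", "biological"),
        ContinuousExposure("sbp", "biological"),
        CategoricalExposure(
            exposure_id="marital", domain="demographic",
            states=("single", "married", "widowed", "divorced"),
            initial_probs=(0.2, 0.7, 0.03, 0.07),
            transition=(
                (0.9, 0.1, 0.0, 0.0),
                (0.0, 0.92, 0.03, 0.05),
                (0.0, 0.02, 0.98, 0.0),
                (0.0, 0.05, 0.0, 0.95),
            ),
            aue_states=("married",),
            reference_states=("married",),
            target_states=("widowed", "divorced"),
        ),
        SingleRoundExposure("loneliness", "environmental", round=5, mean=3.0, sd=2.0),
        SingleRoundExposure(
            "sex", "demographic", round=1,
            states=("male", "female"), state_probs=(0.5, 0.5), aue_states=("female",),
        ),
    )
    signals = (
        EffectSpec("bmi.AUE", beta=0.8),
        EffectSpec("activity.AUE", beta=-0.8),
        EffectSpec("marital.TOE.married_to_widowed_divorced", beta=0.6),
    )
    return SyntheticSpec(
        n_subjects=n_subjects,
        exposures=exposures,
        signal_set=signals,
        target_prevalence=0.16,
        mcar_rates=(0.02, 0.04, 0.06, 0.08, 0.10),
        dropout_hazards=(0.02, 0.03, 0.04, 0.05),
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    cohort, ledger = exporf.generate_cohort(small_spec(seed=3))
    return cohort, ledger


@pytest.fixture(scope="session")
def small_table(small_cohort):
    cohort, _ = small_cohort
    table = exporf.summarize_cohort(cohort)
    y = cohort.outcome.loc[table.subjects].to_numpy()
    return table, y


@pytest.fixture
def fast_config():
    return RunConfig(
        cv_folds=3,
        tuning_grid=(RFHyperParams(mtry=3, ntree=40, nodesize=5),),
        q_grid=(2, 3, 5, 14),
        seed=11,
        calibration_bins=5,
    )


class StubModel:
    """Exact-function risk model for effect-curve oracles."""

    def __init__(self, fn, feature_ids):
        self.fn = fn
        self.feature_ids = list(feature_ids)

    def predict_risk(self, features):
        if isinstance(features, pd.DataFrame):
            features = features.loc[:, self.feature_ids].to_numpy(dtype=float)
        return np.asarray(self.fn(np.asarray(features, dtype=float)), dtype=float)


@pytest.fixture
def stub_model_factory():
    return StubModel
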