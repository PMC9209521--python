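"""Synthetic longitudinal exposome cohorts with known ground truth.

The generator emulates the structure of a five-round population cohort in
which exposures from four domains (demographic, lifestyle, environmental,
biological) are measured every round and a binary health outcome is
observed at a later round: ~3400 subjects, 96 summary features derived
from 45 multi-round and 6 single-round exposures, ~16% outcome prevalence,
and round-dependent missingness.

Continuous trajectories follow a random-intercept / random-slope model
with independent within-subject noise, so each subject's true AUE and TOE
map directly onto the latent intercept and slope. Categorical exposures
evolve as Markov chains. The outcome is Bernoulli with log-odds equal to a
baseline plus a sum of planted effects of the *true* (pre-missingness)
trajectory summaries — linear, threshold, or U-shaped on the standardized
feature — which makes AUE/TOE the correct feature representation by
construction and gives every downstream stage a ground truth to recover.
Missingness (visit-level dropout plus record-level MCAR) is applied only
to the exposure records, never to the outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._rng import stage_rng
from .cohort import ExposureSchemaEntry, LongitudinalCohort
from .exceptions import SchemaError
from .summaries import AUE, AUE_STATE, RAW, TOE, TOE_TRANSITION

__all__ = [
    "ContinuousExposure",
    "CategoricalExposure",
    "SingleRoundExposure",
    "EffectSpec",
    "SyntheticSpec",
    "GroundTruthLedger",
    "generate_cohort",
    "default_study_spec",
    "recovery_report",
]


@dataclass(frozen=True)
class ContinuousExposure:
    """Blueprint for a repeatedly measured continuous exposure.

    Per subject: value(r) = a + b * (r - mean(rounds)) + noise, with
    a ~ N(mean_intercept, sd_intercept), b ~ N(mean_slope, sd_slope) and
    independent N(0, noise_sd) noise per round.
    """

    exposure_id: str
    domain: str
    rounds: tuple[int, ...] = (1, 2, 3, 4, 5)
    mean_intercept: float = 0.0
    sd_intercept: float = 1.0
    mean_slope: float = 0.0
    sd_slope: float = 0.3
    noise_sd: float = 0.3
    label: str = ""


@dataclass(frozen=True)
class CategoricalExposure:
    """Blueprint for a categorical exposure evolving as a Markov chain."""

    exposure_id: str
    domain: str
    states: tuple[str, ...]
    initial_probs: tuple[float, ...]
    transition: tuple[tuple[float, ...], ...]  # row-stochastic, per round step
    aue_states: tuple[str, ...]
    reference_states: tuple[str, ...]
    target_states: tuple[str, ...]
    rounds: tuple[int, ...] = (1, 2, 3, 4, 5)
    label: str = ""

    def __post_init__(self) -> None:
        mat = np.asarray(self.transition, dtype=float)
        if mat.shape != (len(self.states), len(self.states)) or not np.allclose(
            mat.sum(axis=1), 1.0
        ):
            raise SchemaError(f"{self.exposure_id}: transition matrix must be row-stochastic")
        if not math.isclose(sum(self.initial_probs), 1.0, abs_tol=1e-9):
            raise SchemaError(f"{self.exposure_id}: initial_probs must sum to 1")


@dataclass(frozen=True)
class SingleRoundExposure:
    """Blueprint for an exposure measured in one round only.

    Continuous unless ``states`` is given, in which case a categorical
    value is drawn and the summary feature is the indicator of membership
    in ``aue_states``.
    """

    exposure_id: str
    domain: str
    round: int
    mean: float = 0.0
    sd: float = 1.0
    states: tuple[str, ...] = ()
    state_probs: tuple[float, ...] = ()
    aue_states: tuple[str, ...] = ()
    label: str = ""


EFFECT_SHAPES = ("linear", "threshold", "u_shape")


@dataclass(frozen=True)
class EffectSpec:
    """Planted effect of one true summary feature on the outcome log-odds.

    Shapes act on the standardized feature z:
      linear    -> beta * z
      threshold -> beta * 1[z > 0.5]
      u_shape   -> beta * (z**2 - 1) / sqrt(2)   (mean ~0, SD ~|beta|)
    """

    feature_id: str
    beta: float
    shape: str = "linear"

    def __post_init__(self) -> None:
        if self.shape not in EFFECT_SHAPES:
            raise SchemaError(f"unknown effect shape {self.shape!r}")

    def contribution(self, z: np.ndarray) -> np.ndarray:
        if self.shape == "linear":
            return self.beta * z
        if self.shape == "threshold":
            return self.beta * (z > 0.5).astype(float)
        return self.beta * (z**2 - 1.0) / np.sqrt(2.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic cohort draw."""

    n_subjects: int
    exposures: tuple = ()
    signal_set: tuple[EffectSpec, ...] = ()
    baseline_log_odds: float | None = None
    target_prevalence: float | None = 0.16
    mcar_rates: tuple[float, ...] = ()  # one rate per round index position (1-based rounds)
    dropout_hazards: tuple[float, ...] = ()  # hazard of dropping out before round r, r >= 2
    dropout_outcome_coef: float = 0.0
    outcome_round: int = 6
    seed: int = 0

    @property
    def n_rounds(self) -> int:
        return max(max(e.rounds) if hasattr(e, "rounds") else e.round for e in self.exposures)

    def schema(self) -> tuple[ExposureSchemaEntry, ...]:
        entries = []
        for e in self.exposures:
            if isinstance(e, ContinuousExposure):
                entries.append(
                    ExposureSchemaEntry(
                        exposure_id=e.exposure_id, label=e.label, var_type="continuous",
                        rounds_measured=e.rounds, domain=e.domain,
                    )
                )
            elif isinstance(e, CategoricalExposure):
                entries.append(
                    ExposureSchemaEntry(
                        exposure_id=e.exposure_id, label=e.label, var_type="categorical",
                        rounds_measured=e.rounds, domain=e.domain, categories=e.states,
                        aue_states=e.aue_states, reference_states=e.reference_states,
                        target_states=e.target_states,
                    )
                )
            elif isinstance(e, SingleRoundExposure):
                if e.states:
                    entries.append(
                        ExposureSchemaEntry(
                            exposure_id=e.exposure_id, label=e.label, var_type="categorical",
                            rounds_measured=(e.round,), domain=e.domain, categories=e.states,
                            aue_states=e.aue_states,
                        )
                    )
                else:
                    entries.append(
                        ExposureSchemaEntry(
                            exposure_id=e.exposure_id, label=e.label, var_type="continuous",
                            rounds_measured=(e.round,), domain=e.domain,
                        )
                    )
            else:
                raise SchemaError(f"unknown exposure blueprint {type(e).__name__}")
        return tuple(entries)


@dataclass
class GroundTruthLedger:
    """Per-subject truths recorded before missingness is applied."""

    true_features: pd.DataFrame  # subjects x true summary features
    log_odds: pd.Series
    probability: pd.Series
    signal_features: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        df = self.true_features.copy()
        df["true_log_odds"] = self.log_odds
        df["true_probability"] = self.probability
        return df


def _true_aue_toe(values: np.ndarray, rounds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized AUE/TOE of complete trajectories (trapezoid / mean slope)."""
    r = rounds.astype(float)
    gaps = np.diff(r)
    w = np.zeros(len(r))
    w[:-1] += gaps / 2
    w[1:] += gaps / 2
    aue = values @ (w / (r[-1] - r[0]))
    toe = (np.diff(values, axis=1) / gaps) .mean(axis=1)
    return aue, toe


def _feature_name(e, kind: str) -> str:
    if kind == AUE_STATE:
        return f"{e.exposure_id}.AUE.{'_'.join(e.aue_states)}"
    if kind == TOE_TRANSITION:
        return (
            f"{e.exposure_id}.TOE.{'_'.join(e.reference_states)}_to_"
            f"{'_'.join(e.target_states)}"
        )
    if kind == RAW:
        return f"{e.exposure_id}.raw"
    return f"{e.exposure_id}.{kind}"


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Solve mean(expit(c + eta)) = target by bisection."""
    lo, hi = -20.0, 20.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if expit(mid + eta).mean() < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def generate_cohort(spec: SyntheticSpec) -> tuple[LongitudinalCohort, GroundTruthLedger]:
    """Draw one cohort and its ground-truth ledger; deterministic given the seed."""
    n = spec.n_subjects
    if n < 2:
        raise SchemaError("need at least two subjects")
    subjects = [f"s{str(i).zfill(len(str(n)))}" for i in range(1, n + 1)]
    subj_index = pd.Index(subjects, name="subject_id")

    complete: dict[str, tuple[np.ndarray, object]] = {}  # exposure_id -> (matrix, blueprint)
    truths: dict[str, np.ndarray] = {}
    for e in spec.exposures:
        rng = stage_rng(spec.seed, f"exposure:{e.exposure_id}")
        if isinstance(e, ContinuousExposure):
            r = np.asarray(e.rounds, dtype=float)
            a = rng.normal(e.mean_intercept, e.sd_intercept, n)
            b = rng.normal(e.mean_slope, e.sd_slope, n)
            noise = rng.normal(0.0, e.noise_sd, (n, len(r)))
            vals = a[:, None] + b[:, None] * (r - r.mean())[None, :] + noise
            complete[e.exposure_id] = (vals, e)
            aue, toe = _true_aue_toe(vals, np.asarray(e.rounds))
            truths[_feature_name(e, AUE)] = aue
            truths[_feature_name(e, TOE)] = toe
        elif isinstance(e, CategoricalExposure):
            k = len(e.states)
            trans = np.asarray(e.transition, dtype=float)
            cum_init = np.cumsum(e.initial_probs)
            state_idx = np.empty((n, len(e.rounds)), dtype=int)
            state_idx[:, 0] = np.searchsorted(cum_init, rng.random(n), side="right")
            cum_trans = np.cumsum(trans, axis=1)
            for j in range(1, len(e.rounds)):
                u = rng.random(n)
                prev = state_idx[:, j - 1]
                state_idx[:, j] = (u[:, None] > cum_trans[prev]).sum(axis=1)
            labels = np.asarray(e.states, dtype=object)[state_idx]
            complete[e.exposure_id] = (labels, e)
            in_aue = np.isin(labels, list(e.aue_states))
            truths[_feature_name(e, AUE_STATE)] = in_aue.mean(axis=1)
            in_ref = np.isin(labels, list(e.reference_states))
            in_tgt = np.isin(labels, list(e.target_states))
            seen_ref = np.zeros(n, dtype=bool)
            fired = np.zeros(n, dtype=bool)
            for j in range(labels.shape[1]):
                fired |= seen_ref & in_tgt[:, j]
                seen_ref |= in_ref[:, j]
            truths[_feature_name(e, TOE_TRANSITION)] = fired.astype(float)
        elif isinstance(e, SingleRoundExposure):
            if e.states:
                cum = np.cumsum(e.state_probs)
                idx = np.searchsorted(cum, rng.random(n), side="right")
                labels = np.asarray(e.states, dtype=object)[idx[:, None]]
                complete[e.exposure_id] = (labels, e)
                truths[_feature_name(e, RAW)] = np.isin(
                    labels[:, 0], list(e.aue_states)
                ).astype(float)
            else:
                vals = rng.normal(e.mean, e.sd, (n, 1))
                complete[e.exposure_id] = (vals, e)
                truths[_feature_name(e, RAW)] = vals[:, 0]
        else:
            raise SchemaError(f"unknown exposure blueprint {type(e).__name__}")

    true_features = pd.DataFrame(truths, index=subj_index)

    # planted effects on standardized true features
    eta = np.zeros(n)
    for eff in spec.signal_set:
        if eff.feature_id not in true_features.columns:
            raise SchemaError(f"signal feature {eff.feature_id!r} not among generated features")
        col = true_features[eff.feature_id].to_numpy()
        sd = col.std()
        z = (col - col.mean()) / (sd if sd > 0 else 1.0)
        eta += eff.contribution(z)

    if spec.target_prevalence is not None:
        intercept = _calibrate_intercept(eta, spec.target_prevalence)
    elif spec.baseline_log_odds is not None:
        intercept = spec.baseline_log_odds
    else:
        raise SchemaError("set either target_prevalence or baseline_log_odds")
    log_odds = intercept + eta
    prob = expit(log_odds)
    y = (stage_rng(spec.seed, "outcome").random(n) < prob).astype(int)
    outcome = pd.Series(y, index=subj_index, name="label")

    # missingness: monotone dropout (never out of the outcome) then MCAR records
    n_rounds = spec.n_rounds
    drop_rng = stage_rng(spec.seed, "dropout")
    dropped_from = np.full(n, n_rounds + 1)  # first round the subject misses onward
    hazards = list(spec.dropout_hazards)
    if hazards:
        active = np.ones(n, dtype=bool)
        for j, hz in enumerate(hazards[: n_rounds - 1], start=2):
            hz_i = np.full(n, hz)
            if spec.dropout_outcome_coef:
                hz_i = expit(logit(np.clip(hz_i, 1e-9, 1 - 1e-9)) + spec.dropout_outcome_coef * y)
            drops = active & (drop_rng.random(n) < hz_i)
            dropped_from[drops & (dropped_from > j)] = j
            active &= ~drops

    mcar_rng = stage_rng(spec.seed, "mcar")
    records: list[pd.DataFrame] = []
    for e in spec.exposures:
        vals, bp = complete[e.exposure_id]
        rounds = bp.rounds if hasattr(bp, "rounds") else (bp.round,)
        for j, r in enumerate(rounds):
            observed = dropped_from > r
            rate = spec.mcar_rates[r - 1] if r - 1 < len(spec.mcar_rates) else 0.0
            if rate > 0:
                observed = observed & (mcar_rng.random(n) >= rate)
            if not observed.any():
                continue
            col = vals[observed, j]
            records.append(
                pd.DataFrame(
                    {
                        "subject_id": np.asarray(subjects, dtype=object)[observed],
                        "exposure_id": e.exposure_id,
                        "round": r,
                        "value": col,
                    }
                )
            )
    record_frame = pd.concat(records, ignore_index=True)

    cohort = LongitudinalCohort.from_frames(
        record_frame, outcome, spec.schema(), outcome_round=spec.outcome_round
    )
    ledger = GroundTruthLedger(
        true_features=true_features,
        log_odds=pd.Series(log_odds, index=subj_index),
        probability=pd.Series(prob, index=subj_index),
        signal_features=tuple(eff.feature_id for eff in spec.signal_set),
    )
    return cohort, ledger


# --- default study-like specification ------------------------------------

def _cont(eid, domain, rounds=(1, 2, 3, 4, 5), mi=0.0, si=1.0, ms=0.0, ss=0.3, ns=0.3):
    return ContinuousExposure(
        exposure_id=eid, domain=domain, rounds=rounds, mean_intercept=mi,
        sd_intercept=si, mean_slope=ms, sd_slope=ss, noise_sd=ns,
    )


def _yes_no(eid, domain, p_yes, p_become, p_quit=0.02, rounds=(1, 2, 3, 4, 5)):
    """Two-state yes/no chain; AUE = % of time yes, TOE = no -> yes."""
    return CategoricalExposure(
        exposure_id=eid, domain=domain, rounds=rounds, states=("no", "yes"),
        initial_probs=(1 - p_yes, p_yes),
        transition=((1 - p_become, p_become), (p_quit, 1 - p_quit)),
        aue_states=("yes",), reference_states=("no",), target_states=("yes",),
    )


def default_study_spec(seed: int = 0) -> SyntheticSpec:
    """Study-conditions cohort: 3419 subjects, 5 rounds, 96 summary features.

    45 multi-round exposures (39 continuous, 6 categorical) and 6
    single-round exposures across the four domains yield exactly 96
    features. Nine of them carry planted effects on the outcome log-odds —
    a mix of AUE, TOE, a state proportion, a transition indicator, a
    single-round raw score, one U-shaped and one thresholded effect —
    with magnitudes around 0.5 per SD (odds ratios ~1.6-1.8), i.e. strong
    but epidemiologically plausible predictors. The intercept is calibrated
    so the outcome prevalence is ~0.16, and missingness rises with round
    (record-level MCAR plus a monotone dropout hazard).
    """
    dem_cont = ["age", "work_hours", "household_size", "education_years"]
    life_cont = [
        "alcohol_glasses", "cigarettes_per_day", "pack_years", "diet_score",
        "sleep_hours", "mvpa_hours", "sedentary_hours", "coffee_cups",
    ]
    env_cont = [
        "no2", "pm25", "elemental_carbon", "road_noise", "rail_noise",
        "ndvi_300m", "ndvi_1000m", "social_support_pos", "social_support_neg",
        "urban_density", "traffic_distance", "neighborhood_score",
    ]
    bio_cont = [
        "bmi", "whr", "waist", "pulse", "sbp", "dbp", "total_chol", "hdl_chol",
        "chol_ratio", "glucose", "creatinine", "hemoglobin", "crp",
        "triglycerides", "egfr",
    ]
    exposures: list = []
    for eid in dem_cont:
        exposures.append(_cont(eid, "demographic"))
    exposures.append(
        CategoricalExposure(
            exposure_id="marital", domain="demographic",
            states=("single", "married", "widowed", "divorced"),
            initial_probs=(0.20, 0.72, 0.02, 0.06),
            transition=(
                (0.92, 0.08, 0.00, 0.00),
                (0.00, 0.93, 0.03, 0.04),
                (0.00, 0.02, 0.98, 0.00),
                (0.00, 0.05, 0.00, 0.95),
            ),
            aue_states=("married",),
            reference_states=("married",),
            target_states=("widowed", "divorced"),
        )
    )
    exposures.append(
        CategoricalExposure(
            exposure_id="household", domain="demographic",
            states=("with_partner", "single_household", "other"),
            initial_probs=(0.70, 0.20, 0.10),
            transition=(
                (0.93, 0.05, 0.02),
                (0.06, 0.90, 0.04),
                (0.10, 0.10, 0.80),
            ),
            aue_states=("with_partner",),
            reference_states=("with_partner",),
            target_states=("single_household",),
        )
    )
    for eid in life_cont:
        exposures.append(_cont(eid, "lifestyle"))
    exposures.append(_yes_no("smoking_status", "lifestyle", p_yes=0.30, p_become=0.03, p_quit=0.08))
    exposures.append(_yes_no("alcohol_use", "lifestyle", p_yes=0.80, p_become=0.10, p_quit=0.04))
    for eid in env_cont:
        exposures.append(_cont(eid, "environmental"))
    exposures.append(_yes_no("damp_stains", "environmental", p_yes=0.20, p_become=0.06, p_quit=0.15))
    for eid in bio_cont:
        exposures.append(_cont(eid, "biological"))
    exposures.append(_yes_no("bp_medication", "biological", p_yes=0.08, p_become=0.04, p_quit=0.01))
    # single-round exposures (one round only, raw pass-through)
    exposures.append(
        SingleRoundExposure(
            exposure_id="sex", domain="demographic", round=1,
            states=("male", "female"), state_probs=(0.48, 0.52), aue_states=("female",),
        )
    )
    exposures.append(
        SingleRoundExposure(
            exposure_id="nationality", domain="demographic", round=1,
            states=("dutch", "non_dutch"), state_probs=(0.95, 0.05), aue_states=("non_dutch",),
        )
    )
    exposures.append(SingleRoundExposure("loneliness", "environmental", round=5, mean=3.0, sd=2.5))
    exposures.append(
        SingleRoundExposure("social_support_elderly", "environmental", round=5, mean=36.0, sd=6.0)
    )
    exposures.append(SingleRoundExposure("green_perception", "environmental", round=3))
    exposures.append(SingleRoundExposure("noise_annoyance", "environmental", round=3))

    signal_set = (
        EffectSpec("work_hours.AUE", beta=-0.55),
        EffectSpec("marital.TOE.married_to_widowed_divorced", beta=0.45),
        EffectSpec("pack_years.AUE", beta=0.55),
        EffectSpec("smoking_status.AUE.yes", beta=0.45),
        EffectSpec("loneliness.raw", beta=0.50),
        EffectSpec("bmi.AUE", beta=0.50, shape="u_shape"),
        EffectSpec("bmi.TOE", beta=0.45),
        EffectSpec("chol_ratio.TOE", beta=0.45),
        EffectSpec("sbp.AUE", beta=0.50, shape="threshold"),
    )
    return SyntheticSpec(
        n_subjects=3419,
        exposures=tuple(exposures),
        signal_set=signal_set,
        target_prevalence=0.16,
        mcar_rates=(0.02, 0.05, 0.08, 0.10, 0.12),
        dropout_hazards=(0.03, 0.04, 0.05, 0.06),
        outcome_round=6,
        seed=seed,
    )


def recovery_report(
    ledger: GroundTruthLedger,
    ranking,
    selected_q: int,
    pdp_curves: dict | None = None,
    spec: SyntheticSpec | None = None,
) -> dict:
    """How well the pipeline recovered the planted structure.

    Reports the fraction of planted features inside the selected top-q set,
    each planted feature's rank, the sign agreement of PDP slope with the
    planted direction for monotone effects, and whether the U-shaped
    effect's PDP changes slope sign within the clip window.
    """
    planted = list(ledger.signal_features)
    top = set(ranking.top(selected_q))
    ranks = {f: ranking.rank_of(f) for f in planted}
    in_top = [f for f in planted if f in top]
    out = {
        "n_planted": len(planted),
        "selected_q": int(selected_q),
        "n_planted_in_top_q": len(in_top),
        "recovery_fraction": len(in_top) / len(planted),
        "ranks": ranks,
    }
    if pdp_curves is not None and spec is not None:
        shapes = {eff.feature_id: eff for eff in spec.signal_set}
        sign_agreement = {}
        u_shape_detected = {}
        for fid, curve in pdp_curves.items():
            eff = shapes.get(fid)
            if eff is None or len(curve.grid) < 3:
                continue
            slopes = np.diff(curve.effect) / np.diff(curve.grid)
            if eff.shape == "linear":
                sign_agreement[fid] = float(np.mean(np.sign(slopes) == np.sign(eff.beta)))
            elif eff.shape == "u_shape":
                u_shape_detected[fid] = bool(slopes.min() < 0 < slopes.max())
        out["pdp_sign_agreement"] = sign_agreement
        out["u_shape_detected"] = u_shape_detected
    return out
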