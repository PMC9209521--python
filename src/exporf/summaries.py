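"""Trajectory summary features: Area-Under-the-Exposure and Trend-of-the-Exposure.

Repeatedly measured exposures are reduced to two interpretable per-subject
numbers. For a continuous exposure observed at rounds r_1 < ... < r_k with
values v_1, ..., v_k:

* AUE — the time-average of the piecewise-linear interpolant through the
  observed points: the trapezoidal area between r_1 and r_k divided by the
  span r_k - r_1. For a linear trajectory v(r) = a + b r this equals
  a + b (r_1 + r_k) / 2.
* TOE — the unweighted mean of the per-pair slopes
  (v_{i+1} - v_i) / (r_{i+1} - r_i); positive means an upward trend.

For a categorical exposure, AUE is the proportion of observed rounds spent
in a configured state set, and TOE is the indicator that a directed
transition from a reference state to a target state occurred at some later
observed round (e.g. "from married to widowed or divorced").

Both summaries are defined on the *observed* rounds only, so they remain
computable for subjects with missing visits. A subject with no observation
at all for an exposure is flagged in the missing mask and imputed by the
cohort median (continuous-valued features) or mode (indicator features).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import ExposureSchemaEntry, LongitudinalCohort
from .exceptions import ContractError, SchemaError

__all__ = [
    "ExposureTrajectory",
    "SummaryFeatureTable",
    "aue_continuous",
    "toe_continuous",
    "aue_categorical",
    "toe_categorical",
    "summarize_cohort",
]

logger = logging.getLogger("exporf")

# feature kinds
AUE = "AUE"
TOE = "TOE"
AUE_STATE = "AUE_state"
TOE_TRANSITION = "TOE_transition"
RAW = "raw"

INDICATOR_KINDS = frozenset({TOE_TRANSITION})


@dataclass(frozen=True)
class ExposureTrajectory:
    """One subject's observed (round, value) pairs for one exposure."""

    subject_id: str
    exposure_id: str
    rounds: tuple[int, ...]
    values: tuple

    def __post_init__(self) -> None:
        if len(self.rounds) != len(self.values) or len(self.rounds) < 1:
            raise ContractError("trajectory needs parallel, non-empty rounds and values")
        if any(b <= a for a, b in zip(self.rounds, self.rounds[1:])):
            raise ContractError("trajectory rounds must be strictly increasing")


def aue_continuous(traj: ExposureTrajectory) -> float:
    """Time-averaged exposure over the observed rounds.

    Trapezoidal area under the piecewise-linear interpolant divided by the
    observed span; a single observation returns that value.
    """
    r = np.asarray(traj.rounds, dtype=float)
    v = np.asarray(traj.values, dtype=float)
    if len(r) == 1:
        return float(v[0])
    return float(np.trapezoid(v, r) / (r[-1] - r[0]))


def toe_continuous(traj: ExposureTrajectory) -> float:
    """Mean slope between consecutive observed rounds (0 for one observation)."""
    r = np.asarray(traj.rounds, dtype=float)
    v = np.asarray(traj.values, dtype=float)
    if len(r) == 1:
        return 0.0
    return float(np.mean(np.diff(v) / np.diff(r)))


def aue_categorical(
    traj: ExposureTrajectory,
    states: Iterable[str],
    categories: Iterable[str] | None = None,
) -> float:
    """Proportion of observed rounds spent in ``states``."""
    states = set(states)
    if categories is not None and not states <= set(categories):
        raise SchemaError(f"states {sorted(states - set(categories))} not in schema categories")
    vals = list(traj.values)
    return float(sum(v in states for v in vals) / len(vals))


def toe_categorical(
    traj: ExposureTrajectory,
    reference_states: Iterable[str],
    target_states: Iterable[str],
) -> int:
    """1 iff a reference-state observation is later followed by a target state.

    Direction-sensitive: a target state observed before any reference state
    does not count, so (divorced, married) scores 0 for married -> divorced.
    """
    ref = set(reference_states)
    tgt = set(target_states)
    if ref & tgt:
        raise SchemaError("reference_states and target_states must be disjoint")
    seen_ref = False
    for v in traj.values:
        if seen_ref and v in tgt:
            return 1
        if v in ref:
            seen_ref = True
    return 0


@dataclass
class SummaryFeatureTable:
    """Subjects x summary-features matrix with provenance and missingness.

    ``values`` holds the modelling matrix (already imputed); ``missing_mask``
    is True where a subject had no observation for the source exposure and
    the entry was imputed. ``feature_meta`` carries, per feature, the source
    exposure, the feature kind (AUE, TOE, AUE_state, TOE_transition, raw)
    and the exposome domain.
    """

    values: pd.DataFrame
    missing_mask: pd.DataFrame
    feature_meta: pd.DataFrame  # index: feature_id; columns: exposure_id, kind, domain
    imputed_counts: dict[str, int] = field(default_factory=dict)

    @property
    def subjects(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def domain_of(self, feature_id: str) -> str:
        return str(self.feature_meta.loc[feature_id, "domain"])

    @property
    def domains(self) -> list[str]:
        seen: list[str] = []
        for d in self.feature_meta["domain"]:
            if d not in seen:
                seen.append(d)
        return seen

    def restrict(self, feature_ids: Sequence[str]) -> "SummaryFeatureTable":
        ids = list(feature_ids)
        return SummaryFeatureTable(
            values=self.values.loc[:, ids],
            missing_mask=self.missing_mask.loc[:, ids],
            feature_meta=self.feature_meta.loc[ids],
            imputed_counts={k: v for k, v in self.imputed_counts.items() if k in ids},
        )

    def drop_domain(self, domain: str) -> "SummaryFeatureTable":
        keep = [f for f in self.feature_ids if self.domain_of(f) != domain]
        return self.restrict(keep)

    def to_csv(self, values_path: str | Path, mask_path: str | Path | None = None) -> None:
        self.values.rename_axis("subject_id").to_csv(values_path, float_format="%.12g")
        if mask_path is not None:
            self.missing_mask.astype(int).rename_axis("subject_id").to_csv(mask_path)


def _trapezoid_weights(rounds: np.ndarray) -> np.ndarray:
    """Weights w with AUE = w @ values for observed rounds (k >= 2)."""
    gaps = np.diff(rounds)
    w = np.zeros(len(rounds))
    w[:-1] += gaps / 2.0
    w[1:] += gaps / 2.0
    return w / (rounds[-1] - rounds[0])


def _slope_weights(rounds: np.ndarray) -> np.ndarray:
    """Weights w with TOE = w @ values for observed rounds (k >= 2)."""
    gaps = np.diff(rounds)
    k = len(gaps)
    w = np.zeros(len(rounds))
    w[:-1] -= 1.0 / (k * gaps)
    w[1:] += 1.0 / (k * gaps)
    return w


def _continuous_summaries(wide: pd.DataFrame, rounds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized AUE/TOE for a subjects x rounds value matrix with NaN gaps.

    Subjects sharing an observation pattern share linear weights, so each
    distinct pattern costs one matrix product. Returns (aue, toe) with NaN
    for all-missing subjects.
    """
    vals = wide.to_numpy(dtype=float)
    observed = ~np.isnan(vals)
    aue = np.full(len(vals), np.nan)
    toe = np.full(len(vals), np.nan)
    patterns, inverse = np.unique(observed, axis=0, return_inverse=True)
    for p_idx, mask in enumerate(patterns):
        rows = np.nonzero(inverse == p_idx)[0]
        k = int(mask.sum())
        if k == 0:
            continue
        sub = vals[np.ix_(rows, np.nonzero(mask)[0])]
        if k == 1:
            aue[rows] = sub[:, 0]
            toe[rows] = 0.0
        else:
            r_obs = rounds[mask].astype(float)
            aue[rows] = sub @ _trapezoid_weights(r_obs)
            toe[rows] = sub @ _slope_weights(r_obs)
    return aue, toe


def _categorical_summaries(
    wide: pd.DataFrame, entry: ExposureSchemaEntry
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized AUE-state proportion and TOE-transition indicator."""
    vals = wide.to_numpy(dtype=object)
    observed = ~pd.isna(vals)
    in_aue = np.isin(vals, list(entry.aue_states)) & observed
    n_obs = observed.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        aue = np.where(n_obs > 0, in_aue.sum(axis=1) / np.where(n_obs > 0, n_obs, 1), np.nan)
    in_ref = np.isin(vals, list(entry.reference_states)) & observed
    in_tgt = np.isin(vals, list(entry.target_states)) & observed
    seen_ref = np.zeros(len(vals), dtype=bool)
    fired = np.zeros(len(vals), dtype=bool)
    for j in range(vals.shape[1]):
        fired |= seen_ref & in_tgt[:, j]
        seen_ref |= in_ref[:, j]
    toe = np.where(n_obs > 0, fired.astype(float), np.nan)
    return aue, toe


def _feature_id(entry: ExposureSchemaEntry, kind: str) -> str:
    eid = entry.exposure_id
    if kind == AUE_STATE:
        return f"{eid}.AUE.{'_'.join(entry.aue_states)}"
    if kind == TOE_TRANSITION:
        return (
            f"{eid}.TOE.{'_'.join(entry.reference_states)}_to_{'_'.join(entry.target_states)}"
        )
    if kind == RAW:
        return f"{eid}.raw"
    return f"{eid}.{kind}"


def summarize_cohort(
    cohort: LongitudinalCohort,
    schema: Iterable[ExposureSchemaEntry] | None = None,
) -> SummaryFeatureTable:
    """Reduce a longitudinal cohort to its summary feature table.

    Each multi-round continuous exposure contributes an AUE and a TOE
    feature; each multi-round categorical exposure contributes one
    state-occupancy proportion and one transition indicator; single-round
    exposures pass through as raw features (membership indicator for
    categorical ones). Subjects with zero observations for an exposure are
    masked and imputed by the cohort median (continuous) or mode
    (indicator), with the imputation count logged.
    """
    schema = tuple(schema) if schema is not None else cohort.schema
    if not schema:
        raise SchemaError("no schema supplied")
    subjects = cohort.subjects
    in_cohort = set(cohort.records["exposure_id"])
    unknown = in_cohort - {e.exposure_id for e in schema}
    if unknown:
        raise SchemaError(f"cohort exposures missing from schema: {sorted(unknown)}")

    groups = dict(tuple(cohort.records.groupby("exposure_id", sort=False)))
    columns: dict[str, np.ndarray] = {}
    meta_rows: list[tuple[str, str, str, str]] = []

    for entry in schema:
        grp = groups.get(entry.exposure_id)
        if grp is None:
            wide = pd.DataFrame(index=subjects, columns=list(entry.rounds_measured))
        else:
            wide = grp.pivot(index="subject_id", columns="round", values="value")
            wide = wide.reindex(index=subjects, columns=list(entry.rounds_measured))
        if entry.is_multi_round:
            if entry.var_type == "continuous":
                aue, toe = _continuous_summaries(wide, np.asarray(entry.rounds_measured))
                kinds = ((AUE, aue), (TOE, toe))
            else:
                aue, toe = _categorical_summaries(wide, entry)
                kinds = ((AUE_STATE, aue), (TOE_TRANSITION, toe))
            for kind, col in kinds:
                fid = _feature_id(entry, kind)
                columns[fid] = col
                meta_rows.append((fid, entry.exposure_id, kind, entry.domain))
        else:
            col_vals = wide.iloc[:, -1]
            if entry.var_type == "continuous":
                raw = pd.to_numeric(col_vals, errors="coerce").to_numpy(dtype=float)
            else:
                obs = ~col_vals.isna().to_numpy()
                raw = np.where(
                    obs, col_vals.isin(entry.aue_states).to_numpy(dtype=float), np.nan
                )
            fid = _feature_id(entry, RAW)
            columns[fid] = raw
            meta_rows.append((fid, entry.exposure_id, RAW, entry.domain))

    values = pd.DataFrame(columns, index=pd.Index(subjects, name="subject_id"))
    missing_mask = values.isna()
    meta = pd.DataFrame(
        meta_rows, columns=["feature_id", "exposure_id", "kind", "domain"]
    ).set_index("feature_id")

    imputed_counts: dict[str, int] = {}
    for fid in values.columns:
        n_missing = int(missing_mask[fid].sum())
        if n_missing == 0:
            continue
        col = values[fid]
        kind = meta.loc[fid, "kind"]
        is_indicator = kind in INDICATOR_KINDS or set(col.dropna().unique()) <= {0.0, 1.0}
        if is_indicator:
            nonmiss = col.dropna()
            fill = 0.0 if nonmiss.empty else float(nonmiss.round().mode().iloc[0])
        else:
            fill = float(col.median()) if col.notna().any() else 0.0
        values[fid] = col.fillna(fill)
        imputed_counts[fid] = n_missing
        logger.info("imputed %d/%d entries of %s with %s", n_missing, len(values), fid, fill)

    return SummaryFeatureTable(
        values=values,
        missing_mask=missing_mask,
        feature_meta=meta,
        imputed_counts=imputed_counts,
    )
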