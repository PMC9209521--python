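"""Long-format longitudinal cohort tables and their exposure schema.

A cohort is stored the way unbalanced panels are most naturally written:
one row per subject x exposure x round, with missing visits simply absent.
The schema declares, per exposure, its type (continuous or categorical),
the rounds in which it was measured, its category labels and the state
sets used for the categorical trajectory summaries, and the exposome
domain it belongs to (demographic, lifestyle, environmental, biological).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    CohortValidationError,
    CompletenessError,
    DuplicateRecordError,
    SchemaError,
)

__all__ = [
    "DOMAINS",
    "ExposureSchemaEntry",
    "LongitudinalCohort",
    "load_schema",
    "read_cohort",
    "write_cohort",
]

DOMAINS = ("demographic", "lifestyle", "environmental", "biological")

RECORD_COLUMNS = ("subject_id", "exposure_id", "round", "value")


@dataclass(frozen=True)
class ExposureSchemaEntry:
    """Declaration of one exposure.

    For categorical exposures, ``aue_states`` is the state set whose
    occupied-time proportion becomes the AUE-type feature (e.g. "% of the
    time married"), and ``reference_states`` -> ``target_states`` is the
    directed transition whose occurrence becomes the TOE-type indicator
    (e.g. "from married to widowed or divorced").
    """

    exposure_id: str
    var_type: str  # "continuous" | "categorical"
    rounds_measured: tuple[int, ...]
    domain: str
    label: str = ""
    categories: tuple[str, ...] = ()
    aue_states: tuple[str, ...] = ()
    reference_states: tuple[str, ...] = ()
    target_states: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.var_type not in ("continuous", "categorical"):
            raise SchemaError(f"{self.exposure_id}: var_type must be continuous or categorical")
        if self.domain not in DOMAINS:
            raise SchemaError(f"{self.exposure_id}: unknown domain {self.domain!r}")
        rounds = tuple(sorted(int(r) for r in self.rounds_measured))
        if not rounds or any(r < 1 for r in rounds):
            raise SchemaError(f"{self.exposure_id}: rounds_measured must be non-empty integers >= 1")
        if len(set(rounds)) != len(rounds):
            raise SchemaError(f"{self.exposure_id}: duplicate rounds in rounds_measured")
        object.__setattr__(self, "rounds_measured", rounds)
        if self.var_type == "categorical":
            cats = tuple(self.categories)
            if len(cats) < 2:
                raise SchemaError(f"{self.exposure_id}: categorical exposures need >= 2 categories")
            for name, states in (
                ("aue_states", self.aue_states),
                ("reference_states", self.reference_states),
                ("target_states", self.target_states),
            ):
                if not set(states) <= set(cats):
                    raise SchemaError(f"{self.exposure_id}: {name} not a subset of categories")
            if set(self.reference_states) & set(self.target_states):
                raise SchemaError(
                    f"{self.exposure_id}: reference_states and target_states must be disjoint"
                )
            if self.is_multi_round:
                if not self.aue_states:
                    raise SchemaError(f"{self.exposure_id}: multi-round categorical needs aue_states")
                if not (self.reference_states and self.target_states):
                    raise SchemaError(
                        f"{self.exposure_id}: multi-round categorical needs a "
                        "reference->target transition"
                    )
            elif not self.aue_states:
                # single-round categorical enters as a membership indicator
                raise SchemaError(f"{self.exposure_id}: single-round categorical needs aue_states")
        elif self.categories:
            raise SchemaError(f"{self.exposure_id}: continuous exposures take no categories")

    @property
    def is_single_round(self) -> bool:
        return len(self.rounds_measured) == 1

    @property
    def is_multi_round(self) -> bool:
        return len(self.rounds_measured) > 1


@dataclass
class LongitudinalCohort:
    """Validated long-format cohort with a complete binary outcome.

    ``records`` has columns (subject_id, exposure_id, round, value); value
    is float for continuous exposures and a state label for categorical
    ones. ``outcome`` maps every subject to 1 (poor/fair, the predicted
    class) or 0 (good). The outcome round is stored separately and never
    appears among the exposure rounds.
    """

    records: pd.DataFrame
    outcome: pd.Series
    outcome_round: int
    schema: tuple[ExposureSchemaEntry, ...] = field(default=(), repr=False)

    @property
    def subjects(self) -> list:
        return list(self.outcome.index)

    @property
    def n_subjects(self) -> int:
        return len(self.outcome)

    def schema_by_id(self) -> dict[str, ExposureSchemaEntry]:
        return {e.exposure_id: e for e in self.schema}

    @classmethod
    def from_frames(
        cls,
        records: pd.DataFrame,
        outcome: pd.Series,
        schema: Iterable[ExposureSchemaEntry],
        outcome_round: int = 6,
    ) -> "LongitudinalCohort":
        """Validate raw frames against the schema and build a cohort."""
        schema = tuple(schema)
        by_id = {e.exposure_id: e for e in schema}
        records = records.loc[:, list(RECORD_COLUMNS)].copy()

        unknown = set(records["exposure_id"]) - set(by_id)
        if unknown:
            raise SchemaError(f"exposure ids not in schema: {sorted(unknown)}")

        records["round"] = records["round"].astype(int)
        # validate per exposure group (vectorized; row numbers count the CSV
        # header as row 1, so data row = original index + 2)
        value_out = records["value"].astype(object)
        for eid, grp in records.groupby("exposure_id", sort=False):
            entry = by_id[eid]
            bad_round = ~grp["round"].isin(entry.rounds_measured)
            if bad_round.any():
                idx = grp.index[bad_round][0]
                raise CohortValidationError(
                    f"row {idx + 2}: round {grp.loc[idx, 'round']} not measured for "
                    f"{eid} (rounds {entry.rounds_measured})"
                )
            if entry.var_type == "continuous":
                num = pd.to_numeric(grp["value"], errors="coerce")
                bad = num.isna()
                if bad.any():
                    idx = grp.index[bad][0]
                    raise CohortValidationError(
                        f"row {idx + 2}: cannot parse {grp.loc[idx, 'value']!r} as a "
                        f"number for continuous exposure {eid}"
                    )
                value_out.loc[grp.index] = num.astype(object)
            else:
                vals = grp["value"].astype(str)
                bad = ~vals.isin(entry.categories)
                if bad.any():
                    idx = grp.index[bad][0]
                    raise CohortValidationError(
                        f"row {idx + 2}: value {grp.loc[idx, 'value']!r} not among "
                        f"categories of {eid}"
                    )
                value_out.loc[grp.index] = vals
        records["value"] = value_out

        dup = records.duplicated(subset=["subject_id", "exposure_id", "round"])
        if dup.any():
            first = records.loc[dup].iloc[0]
            raise DuplicateRecordError(
                f"duplicate record for subject {first['subject_id']!r}, "
                f"exposure {first['exposure_id']!r}, round {first['round']}"
            )

        outcome = outcome.astype(int)
        if not set(np.unique(outcome)) <= {0, 1}:
            raise CohortValidationError("outcome labels must be 0/1")
        missing = set(records["subject_id"]) - set(outcome.index)
        if missing:
            raise CompletenessError(
                f"subjects without an outcome label: {sorted(missing)[:5]}"
                f"{' ...' if len(missing) > 5 else ''}"
            )
        records = records.reset_index(drop=True)
        return cls(records=records, outcome=outcome, outcome_round=int(outcome_round), schema=schema)


def _schema_entry_from_mapping(m: Mapping) -> ExposureSchemaEntry:
    return ExposureSchemaEntry(
        exposure_id=str(m["exposure_id"]),
        label=str(m.get("label", "")),
        var_type=str(m["var_type"]),
        rounds_measured=tuple(int(r) for r in m["rounds_measured"]),
        domain=str(m["domain"]),
        categories=tuple(m.get("categories", ()) or ()),
        aue_states=tuple(m.get("aue_states", ()) or ()),
        reference_states=tuple(m.get("reference_states", ()) or ()),
        target_states=tuple(m.get("target_states", ()) or ()),
    )


def load_schema(path: str | Path) -> tuple[ExposureSchemaEntry, ...]:
    """Read an exposure schema from YAML (JSON is a YAML subset)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    entries = doc["exposures"] if isinstance(doc, Mapping) else doc
    if not entries:
        raise SchemaError(f"no exposures found in {path}")
    return tuple(_schema_entry_from_mapping(e) for e in entries)


def schema_to_mappings(schema: Iterable[ExposureSchemaEntry]) -> list[dict]:
    out = []
    for e in schema:
        d = {
            "exposure_id": e.exposure_id,
            "label": e.label,
            "var_type": e.var_type,
            "rounds_measured": list(e.rounds_measured),
            "domain": e.domain,
        }
        if e.var_type == "categorical":
            d["categories"] = list(e.categories)
            d["aue_states"] = list(e.aue_states)
            d["reference_states"] = list(e.reference_states)
            d["target_states"] = list(e.target_states)
        out.append(d)
    return out


def read_cohort(
    cohort_path: str | Path,
    outcome_path: str | Path,
    schema_path: str | Path,
    outcome_round: int = 6,
) -> LongitudinalCohort:
    """Read and validate a long-format cohort.

    The cohort CSV has header ``subject_id,exposure_id,round,value``; the
    outcome CSV has header ``subject_id,label``. Empty values (and the
    literal "NA") denote absent measurements and are dropped on read.
    """
    schema = load_schema(schema_path)
    records = pd.read_csv(
        cohort_path, dtype={"subject_id": str, "exposure_id": str, "value": str},
        keep_default_na=False, na_values=["", "NA"],
    )
    missing_cols = set(RECORD_COLUMNS) - set(records.columns)
    if missing_cols:
        raise CohortValidationError(f"cohort file missing columns: {sorted(missing_cols)}")
    records = records.dropna(subset=["value"])
    outcome_df = pd.read_csv(outcome_path, dtype={"subject_id": str})
    if not {"subject_id", "label"} <= set(outcome_df.columns):
        raise CohortValidationError("outcome file must have columns subject_id,label")
    outcome = outcome_df.set_index("subject_id")["label"]
    if outcome.index.duplicated().any():
        raise DuplicateRecordError("duplicate subject in outcome file")
    return LongitudinalCohort.from_frames(records, outcome, schema, outcome_round)


def write_cohort(
    cohort: LongitudinalCohort,
    out_dir: str | Path,
    schema: Iterable[ExposureSchemaEntry] | None = None,
) -> dict[str, str]:
    """Write cohort.csv, outcome.csv and schema.yaml; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema = tuple(schema) if schema is not None else cohort.schema
    paths = {
        "cohort": str(out / "cohort.csv"),
        "outcome": str(out / "outcome.csv"),
        "schema": str(out / "schema.yaml"),
    }
    rec = cohort.records.copy()
    rec["value"] = [
        f"{v:.12g}" if isinstance(v, float) else v for v in rec["value"]
    ]
    rec.to_csv(paths["cohort"], index=False)
    cohort.outcome.rename("label").rename_axis("subject_id").to_csv(paths["outcome"])
    with open(paths["schema"], "w") as fh:
        yaml.safe_dump({"exposures": schema_to_mappings(schema)}, fh, sort_keys=False)
    return paths


def sha256_of(path: str | Path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
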