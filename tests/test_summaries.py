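"""AUE/TOE trajectory summaries: worked examples, oracles, and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import exporf
from exporf import ExposureTrajectory, aue_categorical, aue_continuous, toe_categorical, toe_continuous
from exporf.exceptions import ContractError, SchemaError


def traj(rounds, values):
    return ExposureTrajectory("s1", "e1", tuple(rounds), tuple(values))


def dense_integration_aue(rounds, values):
    """Independent oracle: dense numerical integration of the interpolant."""
    if len(rounds) == 1:
        return float(values[0])
    # dense grid including the knots, so trapezoidal integration of the
    # piecewise-linear interpolant is exact to machine precision
    grid = np.union1d(np.linspace(rounds[0], rounds[-1], 20001), np.asarray(rounds, float))
    interp = np.interp(grid, rounds, values)
    return float(np.trapezoid(interp, grid) / (rounds[-1] - rounds[0]))


def pairwise_slope_mean(rounds, values):
    """Independent oracle: brute-force mean of consecutive-pair slopes."""
    if len(rounds) == 1:
        return 0.0
    slopes = [
        (values[i + 1] - values[i]) / (rounds[i + 1] - rounds[i])
        for i in range(len(rounds) - 1)
    ]
    return float(sum(slopes) / len(slopes))


@pytest.mark.parametrize(
    "rounds, values, expected",
    [
        ((1, 2, 3, 4, 5), (5, 5, 5, 5, 5), 5.0),
        ((1, 3, 5), (2, 4, 8), 4.5),
        ((2,), (7,), 7.0),
    ],
)
def test_aue_continuous_examples(rounds, values, expected):
    assert aue_continuous(traj(rounds, values)) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "rounds, values, expected",
    [
        ((1, 2, 3, 4, 5), (3, 3, 3, 3, 3), 0.0),
        ((1, 2, 3, 4, 5), (1, 2, 3, 4, 5), 1.0),
        ((1, 3, 5), (2, 4, 8), 1.5),
        ((2,), (7,), 0.0),
    ],
)
def test_toe_continuous_examples(rounds, values, expected):
    assert toe_continuous(traj(rounds, values)) == pytest.approx(expected, abs=1e-12)


def test_empty_or_disordered_trajectory_rejected():
    with pytest.raises(ContractError):
        ExposureTrajectory("s", "e", (), ())
    with pytest.raises(ContractError):
        ExposureTrajectory("s", "e", (3, 1), (1.0, 2.0))


@st.composite
def random_trajectory(draw):
    k = draw(st.integers(1, 5))
    rounds = tuple(sorted(draw(st.sets(st.integers(1, 5), min_size=k, max_size=k))))
    values = tuple(
        draw(st.lists(st.floats(-50, 50), min_size=len(rounds), max_size=len(rounds)))
    )
    return rounds, values


@given(random_trajectory())
def test_aue_matches_dense_integration_oracle(rv):
    rounds, values = rv
    got = aue_continuous(traj(rounds, values))
    want = dense_integration_aue(rounds, values)
    assert got == pytest.approx(want, rel=1e-9, abs=1e-9)


@given(random_trajectory())
def test_toe_matches_pairwise_slope_oracle(rv):
    rounds, values = rv
    assert toe_continuous(traj(rounds, values)) == pytest.approx(
        pairwise_slope_mean(rounds, values), abs=1e-12
    )


@given(random_trajectory(), st.floats(-5, 5), st.floats(-20, 20))
def test_shift_scale_equivariance(rv, a, b):
    rounds, values = rv
    scaled = tuple(a * v + b for v in values)
    assert aue_continuous(traj(rounds, scaled)) == pytest.approx(
        a * aue_continuous(traj(rounds, values)) + b, rel=1e-9, abs=1e-7
    )
    assert toe_continuous(traj(rounds, scaled)) == pytest.approx(
        a * toe_continuous(traj(rounds, values)), rel=1e-9, abs=1e-7
    )


@given(
    st.sets(st.integers(1, 5), min_size=2, max_size=5),
    st.floats(-10, 10),
    st.floats(-3, 3),
)
def test_linear_trajectory_closed_form(rounds, a, b):
    """v(r) = a + b r has AUE = a + b (r_first + r_last)/2 and TOE = b."""
    rounds = tuple(sorted(rounds))
    values = tuple(a + b * r for r in rounds)
    assert aue_continuous(traj(rounds, values)) == pytest.approx(
        a + b * (rounds[0] + rounds[-1]) / 2, rel=1e-9, abs=1e-9
    )
    assert toe_continuous(traj(rounds, values)) == pytest.approx(b, abs=1e-9)


@pytest.mark.parametrize(
    "rounds, values, states, expected",
    [
        ((1, 2, 3, 4), ("A", "A", "B", "A"), {"A"}, 0.75),
        ((1, 2, 3, 4), ("A", "A", "B", "A"), {"C"}, 0.0),
        ((1, 3), ("A", "B"), {"A"}, 0.5),
    ],
)
def test_aue_categorical_examples(rounds, values, states, expected):
    assert aue_categorical(traj(rounds, values), states, categories={"A", "B", "C"}) == expected


def test_aue_categorical_rejects_states_outside_schema():
    with pytest.raises(SchemaError):
        aue_categorical(traj((1,), ("A",)), {"Z"}, categories={"A", "B"})


@pytest.mark.parametrize(
    "values, expected",
    [
        (("married", "married", "divorced"), 1),
        (("married", "married"), 0),
        (("divorced", "married"), 0),
        (("married", "single", "widowed"), 1),  # non-adjacent transition still counts
    ],
)
def test_toe_categorical_direction_sensitive(values, expected):
    got = toe_categorical(
        traj(tuple(range(1, len(values) + 1)), values),
        reference_states={"married"},
        target_states={"widowed", "divorced"},
    )
    assert got == expected


def test_toe_categorical_rejects_overlapping_sets():
    with pytest.raises(SchemaError):
        toe_categorical(traj((1,), ("A",)), {"A"}, {"A", "B"})


def test_categorical_aue_partition_sums_to_one(small_cohort):
    """State-occupancy proportions over a partition of states sum to 1."""
    cohort, _ = small_cohort
    entry = cohort.schema_by_id()["marital"]
    grp = cohort.records[cohort.records.exposure_id == "marital"]
    for sid, sub in list(grp.groupby("subject_id"))[:50]:
        t = ExposureTrajectory(
            sid, "marital", tuple(sub["round"]), tuple(sub["value"])
        )
        total = sum(aue_categorical(t, {s}) for s in entry.categories)
        assert total == pytest.approx(1.0, abs=1e-12)


# --- cohort-level summarization ------------------------------------------


def _mini_cohort(records, outcome, schema):
    rec = pd.DataFrame(records, columns=["subject_id", "exposure_id", "round", "value"])
    return exporf.LongitudinalCohort.from_frames(
        rec, pd.Series(outcome).rename_axis("subject_id"), schema
    )


def test_summarize_feature_count_arithmetic():
    schema = (
        exporf.ExposureSchemaEntry("x", "continuous", (1, 2, 3, 4, 5), "biological"),
        exporf.ExposureSchemaEntry("score", "continuous", (5,), "lifestyle"),
    )
    cohort = _mini_cohort(
        [("a", "x", 1, 1.0), ("a", "x", 3, 2.0), ("a", "score", 5, 9.0),
         ("b", "x", 2, 4.0), ("b", "score", 5, 1.0)],
        {"a": 0, "b": 1},
        schema,
    )
    table = exporf.summarize_cohort(cohort)
    assert table.feature_ids == ["x.AUE", "x.TOE", "score.raw"]
    assert table.values.loc["a", "x.AUE"] == pytest.approx(1.5)
    assert table.values.loc["b", "x.TOE"] == 0.0  # single observation
    assert not table.missing_mask.any().any()


def test_summarize_imputes_and_masks_missing_exposure(caplog):
    schema = (
        exporf.ExposureSchemaEntry("x", "continuous", (1, 2, 3), "biological"),
    )
    cohort = _mini_cohort(
        [("a", "x", 1, 2.0), ("b", "x", 1, 4.0)],
        {"a": 0, "b": 1, "c": 1},
        schema,
    )
    import logging

    with caplog.at_level(logging.INFO, logger="exporf"):
        table = exporf.summarize_cohort(cohort)
    assert bool(table.missing_mask.loc["c", "x.AUE"])
    assert table.values.loc["c", "x.AUE"] == pytest.approx(3.0)  # cohort median
    assert table.imputed_counts["x.AUE"] == 1
    assert any("imputed" in r.message for r in caplog.records)


def test_summarize_order_insensitive(small_cohort):
    """Permuting the input record order never changes any summary."""
    cohort, _ = small_cohort
    table = exporf.summarize_cohort(cohort)
    shuffled = cohort.records.sample(frac=1, random_state=5).reset_index(drop=True)
    cohort2 = exporf.LongitudinalCohort(
        records=shuffled, outcome=cohort.outcome,
        outcome_round=cohort.outcome_round, schema=cohort.schema,
    )
    table2 = exporf.summarize_cohort(cohort2)
    pd.testing.assert_frame_equal(table.values, table2.values)


def test_summarize_rejects_exposure_missing_from_schema(small_cohort):
    cohort, _ = small_cohort
    with pytest.raises(SchemaError):
        exporf.summarize_cohort(cohort, schema=cohort.schema[:2])
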