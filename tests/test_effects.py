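"""PDP and ALE effect curves checked against exact-function stub models."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import exporf
from exporf import ale, curve_concordance, pdp
from exporf.exceptions import ContractError


@pytest.fixture(scope="module")
def xy_frame():
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {"x1": rng.uniform(0, 1, 2000), "x2": rng.normal(0, 1, 2000)}
    )


def test_constant_model_flat_pdp_zero_ale(stub_model_factory, xy_frame):
    model = stub_model_factory(lambda X: np.full(len(X), 0.3), ["x1", "x2"])
    c = pdp(model, xy_frame, "x1", grid_size=20)
    assert np.allclose(c.effect, 0.3)
    a = ale(model, xy_frame, "x1", n_bins=10)
    assert np.allclose(a.effect, 0.0, atol=1e-12)


def test_pdp_matches_closed_form_average(stub_model_factory, xy_frame):
    """PDP of f = sigmoid(3 x1) + 0 * x2 equals the direct averaging oracle."""
    model = stub_model_factory(lambda X: expit(3 * X[:, 0]), ["x1", "x2"])
    c = pdp(model, xy_frame, "x1", grid_size=30)
    # oracle: forcing x1 = g makes every subject's prediction sigmoid(3 g)
    assert np.allclose(c.effect, expit(3 * c.grid), atol=1e-9)
    assert (np.diff(c.effect) > 0).all()


def test_pdp_mixed_feature_closed_form(stub_model_factory, xy_frame):
    """With a second active feature the PDP is the mean over the data."""
    model = stub_model_factory(lambda X: expit(3 * X[:, 0] + X[:, 1]), ["x1", "x2"])
    c = pdp(model, xy_frame, "x1", grid_size=15)
    x2 = xy_frame["x2"].to_numpy()
    oracle = np.array([expit(3 * g + x2).mean() for g in c.grid])
    assert np.allclose(c.effect, oracle, atol=1e-9)


def test_pdp_binary_indicator_two_point_grid(stub_model_factory):
    rng = np.random.default_rng(1)
    frame = pd.DataFrame(
        {"ind": (rng.random(500) < 0.3).astype(float), "x2": rng.normal(size=500)}
    )
    model = stub_model_factory(lambda X: 0.2 + 0.4 * X[:, 0], ["ind", "x2"])
    c = pdp(model, frame, "ind", grid_size=50)
    assert np.array_equal(c.grid, [0.0, 1.0])
    assert np.allclose(c.effect, [0.2, 0.6], atol=1e-12)


def test_pdp_degenerate_feature_warns(stub_model_factory):
    frame = pd.DataFrame({"z": np.ones(50), "x2": np.arange(50.0)})
    model = stub_model_factory(lambda X: X[:, 1] / 100, ["z", "x2"])
    with pytest.warns(UserWarning, match="zero variance"):
        c = pdp(model, frame, "z")
    assert len(c.grid) == 1


def test_pdp_grid_respects_percentile_clip(stub_model_factory, xy_frame):
    model = stub_model_factory(lambda X: X[:, 0], ["x1", "x2"])
    c = pdp(model, xy_frame, "x2", grid_size=40)
    lo, hi = np.quantile(xy_frame["x2"], [0.05, 0.95])
    assert c.grid.min() >= lo - 1e-12 and c.grid.max() <= hi + 1e-12


def test_ale_linear_model_matches_analytic_centered_line(stub_model_factory, xy_frame):
    """f = 3 x1 + g(x2): ALE(x1) ~ 3 (x1 - mean x1), max deviation < 0.02."""
    model = stub_model_factory(lambda X: 3 * X[:, 0] + np.sin(X[:, 1]), ["x1", "x2"])
    a = ale(model, xy_frame, "x1", n_bins=20)
    lo, hi = np.quantile(xy_frame["x1"], [0.05, 0.95])
    kept = xy_frame["x1"][(xy_frame["x1"] >= lo) & (xy_frame["x1"] <= hi)]
    oracle = 3 * (a.grid - kept.mean())
    assert np.max(np.abs(a.effect - oracle)) < 0.02


def test_ale_irrelevant_feature_is_null(stub_model_factory, xy_frame):
    model = stub_model_factory(lambda X: expit(2 * X[:, 0]), ["x1", "x2"])
    a = ale(model, xy_frame, "x2", n_bins=20)
    assert np.max(np.abs(a.effect)) < 0.01


def test_ale_centering_invariant(stub_model_factory, xy_frame):
    """Data-weighted mean of the ALE effect is zero to 1e-12."""
    model = stub_model_factory(lambda X: expit(X[:, 0] ** 2 - X[:, 1]), ["x1", "x2"])
    a = ale(model, xy_frame, "x1", n_bins=20)
    x = xy_frame["x1"].to_numpy()
    lo, hi = np.quantile(x, a.clip)
    xk = x[(x >= lo) & (x <= hi)]
    # the curve interpolated at every subject's own value averages to zero
    weighted = float(np.interp(xk, a.grid, a.effect).mean())
    assert abs(weighted) < 1e-12


def test_ale_binary_indicator_fallback(stub_model_factory):
    rng = np.random.default_rng(2)
    frame = pd.DataFrame(
        {"ind": (rng.random(1000) < 0.4).astype(float), "x2": rng.normal(size=1000)}
    )
    model = stub_model_factory(lambda X: 0.1 + 0.5 * X[:, 0], ["ind", "x2"])
    a = ale(model, frame, "ind")
    assert len(a.grid) == 2
    assert a.effect[1] - a.effect[0] == pytest.approx(0.5, abs=1e-12)
    p1 = frame["ind"].mean()
    assert p1 * a.effect[1] + (1 - p1) * a.effect[0] == pytest.approx(0.0, abs=1e-12)


def test_ale_merges_tied_bins(stub_model_factory):
    rng = np.random.default_rng(3)
    x = np.round(rng.uniform(0, 1, 800), 1)  # heavy ties -> duplicate quantiles
    frame = pd.DataFrame({"x1": x, "x2": rng.normal(size=800)})
    model = stub_model_factory(lambda X: X[:, 0], ["x1", "x2"])
    a = ale(model, frame, "x1", n_bins=50)
    assert a.n_bins < 50
    assert np.all(np.diff(a.grid) > 0)


def test_pdp_invariant_to_subject_order(stub_model_factory, xy_frame):
    model = stub_model_factory(lambda X: expit(X[:, 0] + X[:, 1]), ["x1", "x2"])
    shuffled = xy_frame.sample(frac=1, random_state=9)
    c1 = pdp(model, xy_frame, "x1", grid_size=12)
    c2 = pdp(model, shuffled, "x1", grid_size=12)
    assert np.allclose(c1.effect, c2.effect, atol=1e-12)


def test_concordance_trivial_cases():
    grid = np.linspace(0, 1, 11)
    up = exporf.EffectCurve("f", "PDP", grid, grid.copy(), (0.05, 0.95))
    up_ale = exporf.EffectCurve("f", "ALE", grid, 2 * grid, (0.05, 0.95))
    down = exporf.EffectCurve("f", "ALE", grid, -grid, (0.05, 0.95))
    assert curve_concordance(up, up_ale).agreement == 1.0
    assert curve_concordance(up, down).agreement == 0.0
    other = exporf.EffectCurve("g", "ALE", grid, grid, (0.05, 0.95))
    with pytest.raises(ContractError):
        curve_concordance(up, other)
    disjoint = exporf.EffectCurve("f", "ALE", grid + 10, grid, (0.05, 0.95))
    with pytest.raises(ContractError):
        curve_concordance(up, disjoint)


def test_additive_model_pdp_ale_agree(stub_model_factory, xy_frame):
    """Additivity makes PDP and ALE identical up to a constant."""
    model = stub_model_factory(
        lambda X: 0.3 + 0.2 * X[:, 0] + 0.1 * np.tanh(X[:, 1]), ["x1", "x2"]
    )
    c = pdp(model, xy_frame, "x1", grid_size=30)
    a = ale(model, xy_frame, "x1", n_bins=20)
    summary = curve_concordance(c, a)
    assert summary.agreement >= 0.95
    ale_on_grid = np.interp(c.grid, a.grid, a.effect)
    centered_diff = (c.effect - c.effect.mean()) - (ale_on_grid - ale_on_grid.mean())
    assert np.max(np.abs(centered_diff)) < 0.02
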