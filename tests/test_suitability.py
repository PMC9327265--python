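"""Maxent stage: fitting, importance accounting, evaluation, curves."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import logsumexp

from teaprod import suitability as suit
from .conftest import bayes_auc, build_strong_world, build_two_var_world


# --- aspect transform -------------------------------------------------------

@pytest.mark.parametrize("deg,expected", [
    (90.0, (1.0, 0.0)),
    (0.0, (0.0, 1.0)),
    (225.0, (-0.7071, -0.7071)),
    (450.0, (1.0, 0.0)),  # reduced modulo 360
])
def test_aspect_decomposes_into_sine_and_cosine(deg, expected):
    ew, ns = suit.transform_aspect(deg)
    assert ew == pytest.approx(expected[0], abs=1e-4)
    assert ns == pytest.approx(expected[1], abs=1e-4)


def test_aspect_rejects_non_finite_input():
    with pytest.raises(ValueError):
        suit.transform_aspect(np.nan)


# --- fitting and contribution accounting ------------------------------------

def test_contributions_are_nonnegative_and_sum_to_100():
    _, _, pres, bg = build_two_var_world(0)
    fit = suit.fit_maxent(pres, bg, 1.0, ["v1", "v2"])
    vals = np.array(list(fit.contributions.values()))
    assert np.all(vals >= 0)
    assert vals.sum() == pytest.approx(100.0, abs=0.01)


@pytest.mark.parametrize("seed", range(5))
def test_informative_variable_dominates_contribution(seed):
    _, _, pres, bg = build_two_var_world(seed)
    fit = suit.fit_maxent(pres, bg, 1.0, ["v1", "v2"])
    assert fit.contributions["v1"] == max(fit.contributions.values())
    assert fit.contributions["v1"] > 50.0


def test_single_variable_model_gets_full_contribution():
    _, _, pres, bg = build_two_var_world(0)
    fit = suit.fit_maxent(pres, bg, 1.0, ["v1"])
    assert fit.contributions["v1"] == pytest.approx(100.0)


def test_constant_variable_dropped_with_warning():
    _, _, pres, bg = build_two_var_world(0)
    pres = pres.assign(flat=1.0)
    bg = bg.assign(flat=1.0)
    with pytest.warns(UserWarning, match="constant"):
        fit = suit.fit_maxent(pres, bg, 1.0, ["v1", "v2", "flat"])
    assert "flat" not in fit.variables and "flat" in fit.dropped


def test_outputs_are_bounded():
    _, _, pres, bg = build_two_var_world(1)
    fit = suit.fit_maxent(pres, bg, 1.0, ["v1", "v2"])
    logistic = fit.logistic(bg)
    assert np.all((logistic >= 0) & (logistic <= 1))
    assert np.all(fit.raw(bg) >= 0)


# --- permutation importance -------------------------------------------------

def test_permutation_importance_sums_to_100_and_tracks_signal():
    _, _, pres, bg = build_two_var_world(0)
    fit = suit.fit_maxent(pres, bg, 1.0, ["v1", "v2"])
    imp = suit.permutation_importance(fit, pres, bg, seed=0)
    assert sum(imp.values()) == pytest.approx(100.0, abs=0.01)
    assert imp["v1"] > imp["v2"]


def test_zero_weight_variable_has_zero_importance():
    _, _, pres, bg = build_two_var_world(0)
    fit = suit.fit_maxent(pres, bg, 1.0, ["v1", "v2"])
    fit.weights[2:] = 0.0  # silence v2's features entirely
    imp = suit.permutation_importance(fit, pres, bg, seed=0)
    assert imp["v2"] == pytest.approx(0.0, abs=1e-9)


# --- jackknife ---------------------------------------------------------------

def test_jackknife_gain_structure():
    _, _, pres, bg = build_two_var_world(0)
    jk = suit.jackknife_gains(pres, bg, ["v1", "v2"])
    full = jk["_full"]["gain"]
    # a noise-only variable carries almost no standalone gain
    assert jk["v2"]["with_only"] < 0.1 * full
    # removing any variable never increases the regularized gain
    for v in ("v1", "v2"):
        assert jk[v]["without"] <= full + 1e-9


def test_duplicated_informative_variable_is_redundant():
    _, _, pres, bg = build_two_var_world(0)
    pres = pres.assign(v3=pres["v1"])
    bg = bg.assign(v3=bg["v1"])
    jk = suit.jackknife_gains(pres, bg, ["v1", "v2", "v3"])
    full = jk["_full"]["gain"]
    # the signal survives removal of the duplicate (ridge weight-sharing
    # means the drop is small but not zero), unlike a no-signal model
    assert jk["v3"]["without"] > 0.8 * full
    assert jk["v2"]["with_only"] < 0.1 * full


# --- evaluation ---------------------------------------------------------------

def test_no_signal_presences_score_chance_auc():
    _, _, _, bg = build_two_var_world(0)
    rng = np.random.default_rng(4)
    pres = bg.iloc[rng.choice(len(bg), 500, replace=False)].reset_index(drop=True)
    res = suit.evaluate(suit.EvaluationProtocol(folds=5, seed=0), pres, bg,
                        1.0, ["v1", "v2"])
    assert abs(res["mean"] - 0.5) < 0.05


def test_separable_world_reaches_perfect_auc():
    rng = np.random.default_rng(0)
    pres = pd.DataFrame({"v1": rng.uniform(8, 10, 100),
                         "v2": rng.uniform(0, 10, 100)})
    bg = pd.DataFrame({"v1": rng.uniform(0, 2, 1000),
                       "v2": rng.uniform(0, 10, 1000)})
    res = suit.evaluate(suit.EvaluationProtocol(folds=4, seed=0), pres, bg,
                        1.0, ["v1", "v2"])
    assert all(a == pytest.approx(1.0) for a in res["replicates"])


def test_strong_signal_world_discriminates_well():
    """Narrow-bump world: Bayes AUC > 0.95, fitted CV AUC > 0.9."""
    grid, truth, pres, bg = build_strong_world(0)
    assert bayes_auc(grid, truth) > 0.95
    res = suit.evaluate(suit.EvaluationProtocol(folds=5, seed=0), pres, bg,
                        1.0, ["v1", "v2"])
    assert res["mean"] > 0.9
    assert len(res["replicates"]) == 5


def test_subsample_protocol_runs():
    _, _, pres, bg = build_two_var_world(0)
    proto = suit.EvaluationProtocol(kind="subsample", replicates=3,
                                    test_fraction=0.25, seed=1)
    res = suit.evaluate(proto, pres, bg, 1.0, ["v1", "v2"])
    assert len(res["replicates"]) == 3


# --- response curves -----------------------------------------------------------

@pytest.mark.parametrize("seed", range(5))
def test_response_curve_peaks_near_generating_optimum(seed):
    _, truth, pres, bg = build_strong_world(seed)
    fit = suit.fit_maxent(pres, bg, 1.0, ["v1", "v2"])
    curve = suit.response_curve(fit, "v1", n_points=400)
    assert curve["logistic"].between(0, 1).all()
    (_, mu, rho, _), = truth.variables
    argmax = curve["x"].iloc[int(curve["logistic"].to_numpy().argmax())]
    assert abs(argmax - mu) < rho / 2


def test_response_curve_is_unimodal_for_quadratic_features():
    _, _, pres, bg = build_strong_world(1)
    fit = suit.fit_maxent(pres, bg, 1.0, ["v1", "v2"])
    curve = suit.response_curve(fit, "v1", n_points=200)
    d = np.diff(curve["logistic"].to_numpy())
    sign_changes = int(np.sum(np.diff(np.sign(d[np.abs(d) > 1e-12])) != 0))
    assert sign_changes <= 1


def test_response_curve_unknown_variable_errors():
    _, _, pres, bg = build_two_var_world(0)
    fit = suit.fit_maxent(pres, bg, 1.0, ["v1", "v2"])
    with pytest.raises(ValueError, match="not in model"):
        suit.response_curve(fit, "nope")


# --- equivalence with a generic optimizer -------------------------------------

def test_coordinate_ascent_matches_direct_numerical_maximization():
    """On a 50-cell problem the fitted weights match a generic optimizer."""
    rng = np.random.default_rng(0)
    bg = pd.DataFrame({"v1": rng.uniform(0, 10, 50),
                       "v2": rng.uniform(0, 10, 50)})
    pres = pd.DataFrame({"v1": rng.normal(5, 1, 40),
                         "v2": rng.uniform(0, 10, 40)})
    fit = suit.fit_maxent(pres, bg, 1.0, ["v1", "v2"], tol=1e-14,
                          max_epochs=5000)
    m = bg[["v1", "v2"]].mean().to_numpy()
    s = bg[["v1", "v2"]].std(ddof=0).to_numpy()

    def feats(df):
        z = (df[["v1", "v2"]].to_numpy() - m) / s
        return np.column_stack([z[:, 0], z[:, 0] ** 2, z[:, 1], z[:, 1] ** 2])

    f_pr, f_bg = feats(pres), feats(bg)
    reg = 1.0 / np.sqrt(len(pres))

    def neg_gain(w):
        return (-(f_pr @ w).mean() + logsumexp(f_bg @ w) - np.log(len(bg))
                + 0.5 * reg * w @ w)

    res = optimize.minimize(neg_gain, np.zeros(4), method="BFGS",
                            options={"gtol": 1e-12})
    np.testing.assert_allclose(fit.weights, res.x, atol=1e-4)
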