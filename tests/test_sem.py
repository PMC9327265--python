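"""Covariance-structure engine: algebra, fitting, indices, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import logsumexp  # noqa: F401  (parallel import pattern)

from teaprod import sem
from teaprod import synthetic as syn
from .conftest import true_standardized_paths


# --- sample moments ---------------------------------------------------------

def test_sample_covariance_uses_unbiased_divisor():
    df = pd.DataFrame({"x": [0.0, 2.0]})
    # not enough rows for the engine; compute directly at n=3 instead
    df3 = pd.DataFrame({"x": [0.0, 2.0, 1.0], "y": [0.0, 2.0, 1.0]})
    m = sem.sample_covariance(df3, ["x", "y"])
    assert m.cov[0, 0] == pytest.approx(1.0)          # var with n-1 divisor
    assert m.cov[0, 1] == pytest.approx(m.cov[0, 0])  # duplicated column
    assert np.var(df["x"], ddof=1) == pytest.approx(2.0)


def test_sample_covariance_matches_two_pass_oracle():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.normal(size=(1000, 3)), columns=list("abc"))
    m = sem.sample_covariance(df, ["a", "b", "c"])
    x = df.to_numpy()
    centered = x - x.mean(axis=0)          # textbook two-pass computation
    oracle = centered.T @ centered / (len(x) - 1)
    np.testing.assert_allclose(m.cov, oracle, atol=1e-12)


def test_sample_covariance_rejects_constant_column_and_logs_missing():
    df = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0, 4.0]})
    with pytest.raises(ValueError, match="a"):
        sem.sample_covariance(df, ["a", "b"])
    df2 = pd.DataFrame({"a": [1.0, 2.0, np.nan, 4.0], "b": [1.0, 2.0, 3.0, 0.0]})
    m = sem.sample_covariance(df2, ["a", "b"])
    assert m.n == 3 and m.n_dropped == 1


# --- implied covariance -----------------------------------------------------

def identity_measurement_spec():
    """Three 'latents' observed directly: Sigma must equal Psi."""
    obs = ["x1", "x2", "x3"]
    lats = ["l1", "l2", "l3"]
    return sem.PathModelSpec(
        observed=obs, latents=lats,
        loadings=[(o, l, 1.0) for o, l in zip(obs, lats)],
        paths=[("l1", "l2", None), ("l1", "l3", None), ("l2", "l3", None)],
        latent_variances=[(l, None) for l in lats],
        residual_variances=[(o, 0.0) for o in obs])


def test_implied_covariance_reduces_to_psi_without_paths():
    spec = identity_measurement_spec()
    # paths 0, variances (2, 3, 4)
    sigma = sem.implied_covariance(spec, np.array([0, 0, 0, 2.0, 3.0, 4.0]))
    np.testing.assert_allclose(sigma, np.diag([2.0, 3.0, 4.0]), atol=1e-14)


def test_two_indicator_factor_has_closed_form_cross_covariance():
    spec = sem.PathModelSpec(
        observed=["x1", "x2"], latents=["f"],
        loadings=[("x1", "f", 1.0), ("x2", "f", None)],
        paths=[], latent_variances=[("f", None)],
        residual_variances=[("x1", None), ("x2", None)])
    lam, phi, t1, t2 = 0.7, 2.5, 0.3, 0.4
    sigma = sem.implied_covariance(spec, np.array([lam, phi, t1, t2]))
    assert sigma[0, 1] == pytest.approx(lam * phi)
    assert sigma[0, 0] == pytest.approx(phi + t1)
    assert sigma[1, 1] == pytest.approx(lam ** 2 * phi + t2)


def test_implied_covariance_matches_monte_carlo_simulation():
    """Sigma(theta) on the final spec agrees with 1e6 simulated draws."""
    spec = sem.final_model_spec()
    rng = np.random.default_rng(5)
    values = []
    for kind, _ in spec.free_parameters():
        values.append(rng.uniform(0.4, 0.9) if kind != "path"
                      else rng.uniform(-0.3, 0.5))
    values = np.array(values)
    sigma = sem.implied_covariance(spec, values)
    lam, b, psi, theta = spec.matrices(values)
    m, p = len(spec.latents), len(spec.observed)
    n = 1_000_000
    zeta = rng.standard_normal((n, m)) * np.sqrt(np.diag(psi))
    eta = zeta @ np.linalg.inv(np.eye(m) - b).T
    x = eta @ lam.T + rng.standard_normal((n, p)) * np.sqrt(np.diag(theta))
    mc = np.cov(x, rowvar=False)
    scale = np.sqrt(np.outer(np.diag(sigma), np.diag(sigma)))
    assert np.max(np.abs(mc - sigma) / scale) < 0.01


def test_nonrecursive_path_order_rejected():
    with pytest.raises(ValueError, match="causal"):
        sem.PathModelSpec(
            observed=["x1", "x2"], latents=["a", "b"],
            loadings=[("x1", "a", 1.0), ("x2", "b", 1.0)],
            paths=[("b", "a", None)],
            latent_variances=[("a", None), ("b", None)],
            residual_variances=[("x1", None), ("x2", None)])


# --- degrees of freedom -----------------------------------------------------

def test_model_dof_of_pinned_specs_and_saturated_model():
    assert sem.model_dof(sem.final_model_spec()) == (7, 20, 8)
    assert sem.model_dof(sem.initial_model_spec()) == (17, 39, 114)
    assert sem.model_dof(identity_measurement_spec()) == (3, 6, 0)


# --- ML fitting -------------------------------------------------------------

def test_saturated_model_fits_any_covariance_perfectly():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(200, 3))
    x[:, 1] += 0.5 * x[:, 0]
    m = sem.sample_covariance(pd.DataFrame(x, columns=["x1", "x2", "x3"]),
                              ["x1", "x2", "x3"])
    fit = sem.fit_ml(m, identity_measurement_spec(), restarts=2, seed=0)
    assert fit.chi2 == pytest.approx(0.0, abs=1e-5)
    chi2, df, gfi, agfi, cfi, aic = sem.fit_indices(fit, m)
    assert df == 0 and agfi is None
    assert gfi == pytest.approx(1.0, abs=1e-6)
    assert cfi == pytest.approx(1.0, abs=1e-6)
    assert aic == pytest.approx(2 * 6, abs=1e-4)


def test_population_covariance_recovers_generating_parameters():
    """Fitting Sigma(theta0) itself returns theta0 (and F_ML = 0)."""
    spec = sem.final_model_spec()
    labels = [lab for _, lab in spec.free_parameters()]
    theta0 = {
        "environment=~bio6": 0.8, "growth=~crown_width": 0.7,
        "management=~protection": 0.75,
        "environment->management": -0.5, "environment->growth": 0.1,
        "management->growth": 0.3, "environment->productivity": 0.3,
        "management->productivity": 0.1, "growth->productivity": 0.8,
        "psi[environment]": 1.0, "psi[management]": 0.7, "psi[growth]": 0.8,
        "psi[productivity]": 0.5,
        "theta[bio12]": 0.4, "theta[bio6]": 0.5, "theta[ground_diameter]": 0.3,
        "theta[crown_width]": 0.45, "theta[harvest_intensity]": 0.35,
        "theta[protection]": 0.55, "theta[total_value_rmb]": 0.0,
    }
    vec = np.array([theta0[lab] for lab in labels])
    sigma = sem.implied_covariance(spec, vec)
    mom = sem.SampleMoments(sigma, np.zeros(7), 1282, spec.observed)
    fit = sem.fit_ml(mom, spec, restarts=2, seed=0)
    assert fit.f_ml < 1e-7
    for lab in labels:
        assert fit.estimates[lab] == pytest.approx(theta0[lab], abs=1e-4), lab


def test_fml_is_invariant_to_variable_ordering(recovery_truth):
    df, _ = syn.generate_tree_table(recovery_truth, 600, seed=8,
                                    field_units=False, extras=False)
    spec = sem.final_model_spec()
    d = spec.to_dict()
    d["observed"] = list(reversed(d["observed"]))
    spec_rev = sem.PathModelSpec.from_dict(d)
    mom = sem.sample_covariance(df, spec.observed)
    f1 = sem.fit_ml(mom, spec, restarts=1, seed=0)
    f2 = sem.fit_ml(mom, spec_rev, restarts=1, seed=0)
    assert f1.f_ml == pytest.approx(f2.f_ml, rel=1e-6, abs=1e-10)


# --- standardization --------------------------------------------------------

def test_standardization_recovers_unit_variance_truth(recovery_truth):
    """Population fit of a correlation-scale truth reproduces its paths."""
    sigma = recovery_truth.implied_covariance()
    names = recovery_truth.indicators
    mom = sem.SampleMoments(sigma, np.zeros(len(names)), 1282, names)
    spec = sem.final_model_spec()
    fit = sem.fit_ml(mom.reorder(spec.observed), spec, restarts=2, seed=0)
    std = sem.standardize(fit)
    truth_std = true_standardized_paths(recovery_truth)
    for key, val in truth_std.items():
        assert std[key] == pytest.approx(val, abs=1e-3), key


def test_reference_indicator_standardized_loading_closed_form():
    spec = sem.PathModelSpec(
        observed=["x1", "x2", "x3"], latents=["f"],
        loadings=[("x1", "f", 1.0), ("x2", "f", None), ("x3", "f", None)],
        paths=[], latent_variances=[("f", None)],
        residual_variances=[("x1", None), ("x2", None), ("x3", None)])
    vec = np.array([0.6, 0.9, 2.0, 0.5, 0.3, 0.4])  # lam2, lam3, phi, thetas
    mom = sem.SampleMoments(sem.implied_covariance(spec, vec),
                            np.zeros(3), 500, ["x1", "x2", "x3"])
    fit = sem.fit_ml(mom, spec, restarts=1, seed=0)
    std = sem.standardize(fit)
    phi, t1 = fit.estimates["psi[f]"], fit.estimates["theta[x1]"]
    # loading fixed at 1: standardized value is sd(latent)/sd(indicator)
    assert std["f=~x1"] == pytest.approx(np.sqrt(phi) / np.sqrt(phi + t1),
                                         abs=1e-6)


# --- fit indices ------------------------------------------------------------

def test_aic_identity_holds_exactly(recovery_truth):
    df, _ = syn.generate_tree_table(recovery_truth, 1282, seed=3,
                                    field_units=False, extras=False)
    spec = sem.final_model_spec()
    mom = sem.sample_covariance(df, spec.observed)
    fit = sem.fit_ml(mom, spec, restarts=1, seed=0)
    chi2, df_, gfi, agfi, cfi, aic = sem.fit_indices(fit, mom)
    q = len(spec.free_parameters())
    assert aic - chi2 == pytest.approx(2 * q, abs=1e-12)
    assert df_ == fit.df
    assert 0 <= cfi <= 1 and gfi <= 1


# --- parameter recovery across sample sizes ---------------------------------

def test_recovery_bias_shrinks_with_sample_size(recovery_truth):
    spec = sem.final_model_spec()
    truth_std = true_standardized_paths(recovery_truth)

    def mae(n, seed):
        df, _ = syn.generate_tree_table(recovery_truth, n, seed=seed,
                                        field_units=False, extras=False)
        mom = sem.sample_covariance(df, spec.observed)
        std = sem.standardize(sem.fit_ml(mom, spec, restarts=1, seed=0))
        return np.mean([abs(std[k] - truth_std[k]) for k in truth_std])

    small = np.mean([mae(500, 30 + i) for i in range(3)])
    large = np.mean([mae(10_000, 60 + i) for i in range(3)])
    assert large < small
    assert large < 0.02


# --- dual-route agreement oracle --------------------------------------------

def test_engine_agrees_with_independent_direct_minimizer(recovery_truth):
    """chi^2 from the engine matches a from-scratch generic minimization.

    The oracle below builds Sigma with its own matrix code (no shared
    routines with the engine) and minimizes the same discrepancy with a
    generic quasi-Newton optimizer over an unconstrained parameterization.
    """
    df, _ = syn.generate_tree_table(recovery_truth, 1282, seed=17,
                                    field_units=False, extras=False)
    spec = sem.final_model_spec()
    mom = sem.sample_covariance(df, spec.observed)
    fit = sem.fit_ml(mom, spec, restarts=3, seed=0)

    s = mom.reorder(spec.observed).cov
    _, logdet_s = np.linalg.slogdet(s)

    # independent construction: x = (lam_b6, lam_cw, lam_pr, 6 paths,
    # 4 log-psi, 7 log-theta)
    def sigma_of(x):
        l_b6, l_cw, l_pr = x[0], x[1], x[2]
        p_em, p_eg, p_mg, p_ep, p_mp, p_gp = x[3:9]
        psi = np.exp(x[9:13])
        th = np.exp(x[13:20])
        lam = np.zeros((7, 4))  # latent order: E, M, G, P
        lam[0, 0] = 1.0; lam[1, 0] = l_b6
        lam[2, 2] = 1.0; lam[3, 2] = l_cw
        lam[4, 1] = 1.0; lam[5, 1] = l_pr
        lam[6, 3] = 1.0
        b = np.zeros((4, 4))
        b[1, 0] = p_em; b[2, 0] = p_eg; b[2, 1] = p_mg
        b[3, 0] = p_ep; b[3, 1] = p_mp; b[3, 2] = p_gp
        a = np.linalg.inv(np.eye(4) - b)
        return lam @ a @ np.diag(psi) @ a.T @ lam.T + np.diag(th)

    def obj(x):
        sig = sigma_of(x)
        sign, logdet = np.linalg.slogdet(sig)
        if sign <= 0:
            return 1e9
        return logdet - logdet_s + np.trace(np.linalg.solve(sig, s)) - 7

    x0 = np.concatenate([np.ones(3), np.full(6, 0.1),
                         np.log(0.5 * np.ones(4)), np.log(0.5 * np.diag(s))])
    best = None
    for shift in (0.0, 0.2):
        res = optimize.minimize(obj, x0 + shift, method="L-BFGS-B",
                                options={"maxiter": 5000, "ftol": 1e-12})
        if best is None or res.fun < best:
            best = res.fun
    chi2_oracle = (mom.n - 1) * best
    assert fit.chi2 == pytest.approx(chi2_oracle, rel=1e-3, abs=1e-6)


# --- spec serialization -----------------------------------------------------

def test_spec_round_trips_through_json(tmp_path):
    spec = sem.final_model_spec()
    p = tmp_path / "spec.json"
    import json
    p.write_text(json.dumps(spec.to_dict()))
    back = sem.load_spec(str(p))
    assert back.to_dict() == spec.to_dict()
    assert sem.model_dof(back) == (7, 20, 8)
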