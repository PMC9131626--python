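import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from llfrailty.fit import (
    Covariate,
    FitOptions,
    LoglikEngine,
    ModelSpec,
    build_design,
    fit_model,
    standard_errors,
    summary_table,
    time_ratio,
    wald_pvalue,
)
from llfrailty.numdiff import numeric_gradient, numeric_hessian
from llfrailty.simulate import generate_population, model_spec_for

from conftest import two_covariate_config


# --- reporting helpers ------------------------------------------------------


def test_time_ratio_is_exp():
    assert time_ratio(0.0) == 1.0
    assert time_ratio(np.log(2.0)) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        time_ratio(np.inf)


def test_wald_pvalue():
    assert wald_pvalue(0.0, 1.0) == 1.0
    assert wald_pvalue(1.96, 1.0) == pytest.approx(0.05, abs=5e-4)
    assert wald_pvalue(1.96, 1.0) == pytest.approx(
        2 * stats.norm.sf(1.96), rel=1e-12
    )
    # the middle-wealth style borderline case: |z| ~ 1.914 -> p ~ 0.056
    assert wald_pvalue(-0.0142430, 0.0074423) == pytest.approx(0.0557, abs=5e-4)
    with pytest.raises(ValueError):
        wald_pvalue(1.0, 0.0)


# --- finite-difference utilities -------------------------------------------


def test_numeric_hessian_exact_on_quadratic():
    A = np.array([[4.0, 1.0, 0.5], [1.0, 3.0, 0.2], [0.5, 0.2, 2.0]])
    b = np.array([1.0, -2.0, 0.5])

    def f(x):
        return 0.5 * x @ A @ x + b @ x

    x0 = np.array([0.3, -1.2, 2.0])
    assert numeric_hessian(f, x0) == pytest.approx(A, rel=1e-7, abs=1e-7)
    assert numeric_gradient(f, x0) == pytest.approx(A @ x0 + b, rel=1e-7)


# --- likelihood engine gradient --------------------------------------------


@pytest.mark.parametrize("mode", ["aft", "ph"])
@pytest.mark.parametrize("theta", [0.0, 0.4])
def test_engine_gradient_matches_finite_differences(mode, theta, rng):
    n, G = 120, 8
    X = rng.normal(size=(n, 2))
    codes = rng.integers(0, G, size=n)
    times = rng.uniform(0.5, 30.0, size=n)
    events = rng.integers(0, 2, size=n)
    engine = LoglikEngine(times, events, codes, X, mode)

    inter0 = 2.0 if mode == "aft" else -6.0

    def ll(y):
        return engine.loglik(y[0], y[1:3], y[3], theta if theta == 0 else y[4])

    y0 = np.array([inter0, 0.2, -0.1, 3.0] + ([] if theta == 0 else [theta]))
    _, grad = engine.loglik_grad(
        y0[0], y0[1:3], y0[3], theta if theta == 0 else y0[4]
    )
    num = numeric_gradient(ll, y0)
    expect = grad[: y0.size] if theta == 0 else np.concatenate(
        [grad[:4], [grad[4]]]
    )
    assert expect[: y0.size] == pytest.approx(num, rel=1e-5, abs=1e-5)


# --- design matrix ----------------------------------------------------------


def test_design_reference_coding():
    df = pd.DataFrame({"grp": ["a", "b", "b", "c"]})
    spec = ModelSpec(
        covariates=(Covariate("grp", ("a", "b", "c"), "a"),), frailty=False
    )
    X, names = build_design(df, spec)
    assert names == ["grp:b", "grp:c"]
    assert X.tolist() == [[0, 0], [1, 0], [1, 0], [0, 1]]


def test_design_unknown_category_rejected():
    df = pd.DataFrame({"grp": ["a", "z"]})
    spec = ModelSpec(covariates=(Covariate("grp", ("a", "b"), "a"),))
    with pytest.raises(ValueError, match="outside the schema"):
        build_design(df, spec)


def test_design_empty_category_dropped_with_warning():
    df = pd.DataFrame({"grp": ["a", "b", "a", "b"]})
    spec = ModelSpec(covariates=(Covariate("grp", ("a", "b", "c"), "a"),))
    with pytest.warns(UserWarning, match="zero rows"):
        X, names = build_design(df, spec)
    assert names == ["grp:b"]


def test_design_collinear_rejected():
    df = pd.DataFrame({"g1": ["a", "b", "a", "b"], "g2": ["x", "y", "x", "y"]})
    spec = ModelSpec(
        covariates=(
            Covariate("g1", ("a", "b"), "a"),
            Covariate("g2", ("x", "y"), "x"),
        )
    )
    with pytest.raises(ValueError, match="singular design"):
        build_design(df, spec)


# --- fitting ----------------------------------------------------------------


def test_fit_preconditions(small_cohort):
    cfg, df, _ = small_cohort
    spec = model_spec_for(cfg)
    one_cluster = df[df["cluster"] == df["cluster"].iloc[0]]
    with pytest.raises(ValueError, match="single cluster"):
        fit_model(one_cluster, spec)
    censored = df.copy()
    censored["event"] = 0
    with pytest.raises(ValueError, match="no events"):
        fit_model(censored, spec)


def test_parameter_recovery_single_dataset(small_cohort):
    cfg, df, truth = small_cohort
    fit = fit_model(df, model_spec_for(cfg))
    assert fit.converged
    for name, true_val in [
        ("grp:b", 0.3),
        ("exposure:hi", -0.2),
    ]:
        assert abs(fit.beta[name] - true_val) < 3 * fit.se[name]
    assert abs(fit.intercept - cfg.true_intercept) < 4 * fit.se["intercept"]
    assert abs(fit.shape_k - cfg.true_shape_k) < 4 * fit.se["shape_k"]
    # optimum dominates the generating truth
    engine_ll_true = _loglik_at_truth(df, cfg)
    assert fit.loglik >= engine_ll_true - 1e-6
    assert fit.loglik >= fit.loglik_nofrailty - 1e-6
    assert fit.tau == pytest.approx(fit.theta / (fit.theta + 2), rel=1e-12)


def _loglik_at_truth(df, cfg):
    spec = model_spec_for(cfg)
    X, names = build_design(df, spec)
    codes = pd.Categorical(df["cluster"]).codes
    engine = LoglikEngine(
        df["time"].to_numpy(), df["event"].to_numpy(), codes, X, cfg.mode
    )
    beta = np.array([cfg.true_beta.get(n, 0.0) for n in names])
    return engine.loglik(
        cfg.true_intercept, beta, cfg.true_shape_k, cfg.true_theta
    )


def test_fit_invariant_to_row_order(small_cohort):
    cfg, df, _ = small_cohort
    spec = model_spec_for(cfg)
    fit1 = fit_model(df, spec, FitOptions(compute_se=False))
    shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
    fit2 = fit_model(shuffled, spec, FitOptions(compute_se=False))
    assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-5)
    assert fit1.theta == pytest.approx(fit2.theta, abs=1e-4)
    for n in fit1.beta:
        assert fit1.beta[n] == pytest.approx(fit2.beta[n], abs=1e-4)


def test_fit_stable_under_perturbed_start(small_cohort):
    cfg, df, _ = small_cohort
    spec = model_spec_for(cfg)
    fit1 = fit_model(df, spec, FitOptions(compute_se=False))
    fit2 = fit_model(df, spec, FitOptions(compute_se=False, theta_start=0.9))
    assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-4)


def test_time_rescaling_shifts_intercept_only(small_cohort):
    """AFT reparameterisation: t -> c*t adds log(c) to the intercept and
    leaves beta, k, theta unchanged."""
    cfg, df, _ = small_cohort
    spec = model_spec_for(cfg)
    fit1 = fit_model(df, spec, FitOptions(compute_se=False))
    scaled = df.copy()
    c = 12.0
    scaled["time"] = scaled["time"] * c
    fit2 = fit_model(scaled, spec, FitOptions(compute_se=False))
    assert fit2.intercept - fit1.intercept == pytest.approx(np.log(c), abs=1e-3)
    for n in fit1.beta:
        assert fit2.beta[n] == pytest.approx(fit1.beta[n], abs=1e-3)
    assert fit2.shape_k == pytest.approx(fit1.shape_k, rel=1e-3)
    assert fit2.theta == pytest.approx(fit1.theta, abs=1e-3)


def test_no_frailty_fit_matches_lifelines_aft():
    """Independent cross-check: with frailty off, coefficients agree with
    lifelines' log-logistic AFT fitter within a fraction of a SE."""
    from lifelines import LogLogisticAFTFitter

    cfg = two_covariate_config(G=20, n_i=150, theta=0.0, seed=5)
    df, _ = generate_population(cfg)
    spec = model_spec_for(cfg, frailty=False)
    fit = fit_model(df, spec)

    ll_df = pd.DataFrame(
        {
            "time": df["time"],
            "event": df["event"],
            "grp_b": (df["grp"].astype(str) == "b").astype(float),
            "exp_hi": (df["exposure"].astype(str) == "hi").astype(float),
        }
    )
    llf = LogLogisticAFTFitter()
    llf.fit(ll_df, duration_col="time", event_col="event")
    params = llf.params_
    pairs = [
        (fit.intercept, params[("alpha_", "Intercept")], fit.se["intercept"]),
        (fit.beta["grp:b"], params[("alpha_", "grp_b")], fit.se["grp:b"]),
        (fit.beta["exposure:hi"], params[("alpha_", "exp_hi")], fit.se["exposure:hi"]),
    ]
    for ours, theirs, se in pairs:
        assert abs(ours - theirs) < 0.5 * se
    # shape: lifelines' beta_ is our k
    assert fit.shape_k == pytest.approx(
        float(np.exp(params[("beta_", "Intercept")])), rel=1e-2
    )
    assert fit.loglik == pytest.approx(llf.log_likelihood_, abs=0.01)


def test_se_shrink_with_sample_size():
    ses = []
    for n_i, G in [(25, 20), (100, 20), (400, 20)]:
        cfg = two_covariate_config(G=G, n_i=n_i, theta=0.2, seed=11)
        df, _ = generate_population(cfg)
        fit = fit_model(df, model_spec_for(cfg))
        ses.append(fit.se["grp:b"])
    assert ses[0] > ses[1] > ses[2]
    # 1/sqrt(n) scaling: quadrupling n halves the SE, within simulation slack
    assert ses[0] / ses[1] == pytest.approx(2.0, rel=0.35)
    assert ses[1] / ses[2] == pytest.approx(2.0, rel=0.35)


def test_ses_positive_and_vcov_psd(small_cohort):
    cfg, df, _ = small_cohort
    fit = fit_model(df, model_spec_for(cfg))
    se = standard_errors(fit)
    for name in fit.param_names:
        assert se[name] > 0
    eigvals = np.linalg.eigvalsh(fit.vcov)
    assert np.all(eigvals > -1e-10)


# --- summary table ----------------------------------------------------------


def test_summary_table_structure(small_cohort):
    cfg, df, _ = small_cohort
    spec = model_spec_for(cfg)
    fit = fit_model(df, spec)
    tab = summary_table(fit, spec)
    assert list(tab["covariate"]) == ["constant", "grp", "exposure"]
    assert tab["phi"].to_numpy() == pytest.approx(np.exp(tab["coef"].to_numpy()))
    footer = tab.attrs["footer"]
    assert footer["tau"] == pytest.approx(footer["theta"] / (footer["theta"] + 2))
    assert footer["gamma"] == pytest.approx(1.0 / fit.shape_k)


def test_summary_table_zero_covariates():
    cfg = two_covariate_config(G=15, n_i=40, theta=0.3, seed=9).replace(
        covariate_schema={}, true_beta={}
    )
    df, _ = generate_population(cfg)
    spec = model_spec_for(cfg)
    fit = fit_model(df, spec)
    tab = summary_table(fit, spec)
    assert len(tab) == 1 and tab.loc[0, "covariate"] == "constant"
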