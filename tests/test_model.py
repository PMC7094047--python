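import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from types import SimpleNamespace

from serpens.gmrf import rw1_structure, sum_to_zero_basis
from serpens.model import (ConvergenceError, HyperParams, LatentField,
                           ModelSpec, RW1PoissonModel, compute_offset,
                           log_joint)
from serpens.results import (LaplaceResults, gaussian_mixture_quantile,
                             rr_table)
from serpens.simulate import ScenarioConfig, simulate_scenario


# ---------------------------------------------------------------- offset
def test_offset_uniform_and_conservation():
    y = np.full(12, 10.0)
    pop = np.full(12, 50_000.0)
    e = compute_offset(y, pop)
    np.testing.assert_allclose(e, 10.0)
    rng = np.random.default_rng(1)
    y2 = rng.poisson(12.0, 144).astype(float)
    pop2 = rng.uniform(4e5, 6e5, 144)
    np.testing.assert_allclose(compute_offset(y2, pop2).sum(), y2.sum())


def test_offset_proportional_to_population_and_zero_error():
    y = np.array([5.0, 5.0, 5.0])
    pop = np.array([1e5, 2e5, 1e5])
    e = compute_offset(y, pop)
    assert e[1] == pytest.approx(2 * e[0])
    with pytest.raises(ValueError, match="zero"):
        compute_offset(np.zeros(3), pop)


# -------------------------------------------------------------- log joint
def _tiny_problem(T=6, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.poisson(8.0, T).astype(float)
    e = np.full(T, 8.0)
    X = rng.normal(size=(T, 2))
    B = sum_to_zero_basis(T)
    omega = B @ rng.normal(size=T - 1) * 0.2
    delta = B @ rng.normal(size=T - 1) * 0.1
    latent = LatentField(0.1, np.array([0.2, -0.3]), omega, delta)
    hyper = HyperParams(50.0, 80.0)
    return y, e, X, latent, hyper


def _log_joint_oracle(latent, hyper, y, e, X, spec):
    """Independent term-by-term summation with scalar loops."""
    T = len(y)
    lp = 0.0
    for t in range(T):
        eta = latent.beta0 + latent.omega[t] + latent.delta[t]
        for j in range(X.shape[1]):
            eta += X[t, j] * latent.beta[j]
        lp += y[t] * eta - e[t] * np.exp(eta)
    V = spec.beta_prior_variance
    for b in [latent.beta0, *latent.beta]:
        lp += -0.5 * b * b / V - 0.5 * np.log(2 * np.pi * V)
    a, r = spec.tau_prior_shape, spec.tau_prior_rate
    quad_w = sum((latent.omega[t] - latent.omega[t - 1]) ** 2 for t in range(1, T))
    lp += 0.5 * (T - 1) * np.log(hyper.tau_omega / (2 * np.pi)) \
        - 0.5 * hyper.tau_omega * quad_w \
        + (a - 1) * np.log(hyper.tau_omega) - r * hyper.tau_omega
    quad_d = sum(d * d for d in latent.delta)
    lp += 0.5 * (T - 1) * np.log(hyper.tau_delta / (2 * np.pi)) \
        - 0.5 * hyper.tau_delta * quad_d \
        + (a - 1) * np.log(hyper.tau_delta) - r * hyper.tau_delta
    return lp


def test_log_joint_matches_brute_force_oracle():
    y, e, X, latent, hyper = _tiny_problem()
    spec = ModelSpec(covariates=("a", "b"))
    got = log_joint(latent, hyper, y, e, X, spec)
    want = _log_joint_oracle(latent, hyper, y, e, X, spec)
    assert got == pytest.approx(want, abs=1e-10)


def test_log_joint_null_model_reduces_to_likelihood_term():
    T = 5
    y = np.full(T, 3.0)
    e = y.copy()
    latent = LatentField(0.0, np.zeros(0), np.zeros(T), np.zeros(T))
    hyper = HyperParams(1.0, 1.0)
    spec = ModelSpec(covariates=())
    got = log_joint(latent, hyper, y, e, None, spec)
    # likelihood term is sum(y*0 - e) = -15; the rest are prior constants
    consts = _log_joint_oracle(latent, hyper, y, e, np.zeros((T, 0)), spec) + 15.0
    assert got == pytest.approx(-15.0 + consts)


def test_log_joint_prior_dominates_in_tails():
    y, e, X, latent, hyper = _tiny_problem()
    spec = ModelSpec(covariates=("a", "b"))
    vals = []
    for b1 in (0.0, 5.0, 10.0, 20.0):
        lat = LatentField(latent.beta0, np.array([b1, -0.3]), latent.omega,
                          latent.delta)
        vals.append(log_joint(lat, hyper, y, e, X, spec))
    assert vals[0] > vals[1] > vals[2] > vals[3]


def test_log_joint_rejects_nonfinite_covariates():
    y, e, X, latent, hyper = _tiny_problem()
    X = X.copy()
    X[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        log_joint(latent, hyper, y, e, X, ModelSpec(covariates=("a", "b")))


# ------------------------------------------------------- Laplace machinery
def test_newton_mode_matches_independent_optimizer():
    """The Newton mode equals the maximiser found by a generic optimizer on
    an independently-coded penalised objective (T=10)."""
    rng = np.random.default_rng(3)
    T = 10
    y = rng.poisson(10.0, T).astype(float)
    e = np.full(T, 10.0)
    X = rng.normal(size=(T, 1))
    spec = ModelSpec(covariates=("x",))
    m = RW1PoissonModel(y, X, e, spec=spec, covariate_names=["x"])
    tau_w, tau_d = 40.0, 60.0
    P0 = m._prior_precision(tau_w, tau_d)
    zhat, _, _ = m._newton_mode(P0)

    A = m._A

    def neg_obj(z):
        eta = A @ z
        return -(y @ eta - e @ np.exp(eta) - 0.5 * z @ P0 @ z)

    res = optimize.minimize(neg_obj, np.zeros(m._n), method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 2000})
    np.testing.assert_allclose(zhat, res.x, atol=1e-6)


def test_one_newton_step_exact_for_quadratic_objective():
    """With the Poisson terms replaced by a quadratic (Gaussian) pseudo-
    likelihood, a single Newton step from zero lands on the exact posterior
    mean of the conjugate Gaussian-Gaussian model."""
    rng = np.random.default_rng(4)
    T = 12
    obs = rng.normal(0.5, 0.3, T)
    prec_obs = 25.0
    B = sum_to_zero_basis(T)
    tau = 10.0
    Ru = B.T @ rw1_structure(T) @ B
    # posterior precision and mean of u for model obs = B u + noise
    P = prec_obs * (B.T @ B) + tau * Ru
    mean_exact = np.linalg.solve(P, prec_obs * B.T @ obs)
    grad0 = prec_obs * B.T @ obs          # gradient at u=0
    step = np.linalg.solve(P, grad0)      # one Newton step from zero
    np.testing.assert_allclose(step, mean_exact, atol=1e-12)


def test_huge_exposure_concentrates_posterior():
    rng = np.random.default_rng(5)
    T = 24
    X = rng.normal(size=(T, 1))
    spec = ModelSpec(covariates=("x",), include_trend=False, include_iid=False)
    beta = 0.2
    sds = []
    for e0 in (10.0, 1e6):
        e = np.full(T, e0)
        y = np.round(e * np.exp(0.1 + beta * X[:, 0]))
        fit = RW1PoissonModel(y, X, e, spec=spec, covariate_names=["x"]).fit(grid_size=1)
        sds.append(fit.bse["x"])
    assert sds[1] < sds[0] / 100


def test_nonconvergence_raises_with_trace():
    rng = np.random.default_rng(6)
    T = 10
    y = rng.poisson(5.0, T).astype(float)
    e = np.full(T, 5.0)
    m = RW1PoissonModel(y, None, e,
                        spec=ModelSpec(covariates=(), include_trend=False,
                                       include_iid=False))
    with pytest.raises(ConvergenceError) as exc:
        m._newton_mode(m._prior_precision(None, None), maxiter=1, tol=1e-14)
    assert exc.value.trace


# ------------------------------------------------------------- hyper grid
def test_grid_weights_normalised_and_mode_interior(small_bundle):
    m = RW1PoissonModel.from_series(small_bundle.series)
    fit = m.fit(grid_size=5, compute_trend=False)
    assert fit.weights.sum() == pytest.approx(1.0)
    assert not fit.diagnostics["boundary_mode"]


def test_single_point_grid_reproduces_empirical_bayes(small_bundle):
    m = RW1PoissonModel.from_series(small_bundle.series)
    fit1 = m.fit(grid_size=1, compute_trend=False)
    fit9 = m.fit(grid_size=5, compute_trend=False)
    assert fit1.diagnostics["grid_points"] == 1
    # EB point estimate close to the full-grid posterior mean
    assert fit1.params["humidity"] == pytest.approx(fit9.params["humidity"],
                                                    abs=0.01)
    # and its quantiles are exactly Gaussian
    q = fit1.coef_quantiles((0.025, 0.975))
    mu, sd = fit1.params["humidity"], fit1.bse["humidity"]
    assert q.loc["humidity", "0.025"] == pytest.approx(mu - 1.959964 * sd, rel=1e-6)
    assert q.loc["humidity", "0.975"] == pytest.approx(mu + 1.959964 * sd, rel=1e-6)


# -------------------------------------------------------------- marginals
def test_mixture_quantiles_match_monte_carlo_oracle():
    w = np.array([0.3, 0.7])
    mu = np.array([-1.0, 2.0])
    sd = np.array([0.5, 1.5])
    rng = np.random.default_rng(12)
    comp = rng.choice(2, size=200_000, p=w)
    draws = rng.normal(mu[comp], sd[comp])
    for q in (0.025, 0.5, 0.975):
        got = gaussian_mixture_quantile(w, mu, sd, q)
        assert got == pytest.approx(np.quantile(draws, q), abs=2e-2)


def test_rr_quantiles_are_exp_of_beta_quantiles(small_bundle):
    m = RW1PoissonModel.from_series(small_bundle.series)
    fit = m.fit(grid_size=3, compute_trend=False)
    q = fit.coef_quantiles((0.025, 0.5, 0.975))
    rr = fit.rr_frame()
    for name in m.covariate_names:
        assert rr.loc[name, "rr"] == np.exp(q.loc[name, "0.5"])
        assert rr.loc[name, "rr_lower"] == np.exp(q.loc[name, "0.025"])
        assert rr.loc[name, "rr_upper"] == np.exp(q.loc[name, "0.975"])
    assert (q["0.025"] < q["0.5"]).all() and (q["0.5"] < q["0.975"]).all()


def _stub_results(beta_mu, beta_sd, names):
    model = SimpleNamespace(covariate_names=names, index=list(range(1, 4)),
                            spec=ModelSpec(covariates=tuple(names)),
                            T=3)
    k = 1 + len(names)
    return LaplaceResults(
        model=model, weights=np.array([1.0]), thetas=np.zeros((1, 0)),
        theta_names=[], fixed_mu=np.array([beta_mu]),
        fixed_sd=np.array([beta_sd]), omega_mu=None, omega_sd=None,
        delta_mu=None, delta_sd=None)


def test_rr_table_reproduces_published_cell_format():
    # beta_humidity ~ N(0.077, 0.026^2) renders as "1.08 (1.03-1.14)"
    fit = _stub_results([0.0, 0.077], [0.1, 0.026], ["humidity"])
    tab = rr_table(fit)
    assert tab.loc["Humidity", "estimate (95% CrI)"] == "1.08 (1.03-1.14)"
    assert list(tab.index) == ["Humidity", "beta_0"]


def test_rr_table_zero_covariate_model_and_csv_text_consistency(tmp_path, small_bundle):
    spec = ModelSpec(covariates=(), include_trend=True, include_iid=True)
    m = RW1PoissonModel(small_bundle.y, None, small_bundle.e, spec=spec)
    fit = m.fit(grid_size=3, compute_trend=False)
    tab = rr_table(fit)
    assert list(tab.index) == ["beta_0", "tau_omega", "tau_delta"]
    path = tmp_path / "rr.csv"
    tab.to_csv(path)
    back = pd.read_csv(path, index_col=0)
    assert (back["estimate (95% CrI)"] == tab["estimate (95% CrI)"]).all()
    assert tab.to_string().count("(") >= 3


def test_trend_frame_bands_are_monotone_and_exp_linked(small_bundle):
    m = RW1PoissonModel.from_series(small_bundle.series)
    fit = m.fit(grid_size=3)
    tf = fit.trend_frame()
    assert len(tf) == m.T
    assert (tf["q025"] <= tf["q50"]).all() and (tf["q50"] <= tf["q975"]).all()
    np.testing.assert_allclose(tf["rr_q50"], np.exp(tf["q50"]))
    tf2 = fit.trend_frame(include_iid=True)
    assert (tf2["sd"] >= 0).all()


def test_plot_trend_draws_band_and_reference_line(small_bundle):
    import matplotlib

    matplotlib.use("Agg")
    m = RW1PoissonModel.from_series(small_bundle.series)
    fit = m.fit(grid_size=3)
    ax = fit.plot_trend()
    assert len(ax.lines) >= 2 and len(ax.collections) == 1


def test_summary_runs_and_mentions_components(small_bundle):
    m = RW1PoissonModel.from_series(small_bundle.series)
    fit = m.fit(grid_size=3, compute_trend=False)
    text = fit.summary()
    assert "Relative risks" in text and "tau_omega" in text
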