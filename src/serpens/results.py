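"""Posterior summaries for the latent-Gaussian Poisson model.

:class:`LaplaceResults` represents every latent marginal as a finite mixture
of Gaussians over the hyperparameter grid; means, standard deviations and
central quantiles come from the mixture, quantiles by numerical inversion of
the mixture CDF.  Relative risks are exponentials of the corresponding
coefficient quantiles (a monotone transform, so the quantiles map exactly).

:class:`MCMCResults` holds draws from the Metropolis-within-Gibbs sampler of
the identical posterior together with split-chain convergence diagnostics;
it is the package's independent cross-check on the Laplace fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr

from ._util import round_half_up

__all__ = ["LaplaceResults", "MCMCResults", "gaussian_mixture_quantile", "rr_table"]


def gaussian_mixture_quantile(weights, mus, sds, q: float) -> float:
    """Quantile of a finite Gaussian mixture by inverting its CDF."""
    weights = np.asarray(weights, float)
    mus = np.asarray(mus, float)
    sds = np.asarray(sds, float)
    lo = float(np.min(mus - 8 * sds))
    hi = float(np.max(mus + 8 * sds))

    def cdf_minus_q(x):
        return float(weights @ ndtr((x - mus) / sds)) - q

    return brentq(cdf_minus_q, lo, hi, xtol=1e-12)


def _mixture_moments(weights, mus, sds):
    mean = weights @ mus
    var = weights @ (sds**2 + mus**2) - mean**2
    return mean, np.sqrt(max(var, 0.0))


@dataclass
class LaplaceResults:
    """Posterior fit from the nested Laplace scheme."""

    model: object
    weights: np.ndarray            # (K,)
    thetas: np.ndarray             # (K, nh) log-precisions
    theta_names: list
    fixed_mu: np.ndarray           # (K, 1+p)
    fixed_sd: np.ndarray
    omega_mu: np.ndarray | None    # (K, T)
    omega_sd: np.ndarray | None
    delta_mu: np.ndarray | None
    delta_sd: np.ndarray | None
    diagnostics: dict = field(default_factory=dict)
    omdel_cov: np.ndarray | None = None   # (K, T) cov(omega_t, delta_t) per grid point

    # -- coefficient marginals ----------------------------------------
    @property
    def param_names(self):
        return ["beta0"] + list(self.model.covariate_names)

    @property
    def params(self) -> pd.Series:
        means = [
            _mixture_moments(self.weights, self.fixed_mu[:, j], self.fixed_sd[:, j])[0]
            for j in range(self.fixed_mu.shape[1])
        ]
        return pd.Series(means, index=self.param_names)

    @property
    def bse(self) -> pd.Series:
        sds = [
            _mixture_moments(self.weights, self.fixed_mu[:, j], self.fixed_sd[:, j])[1]
            for j in range(self.fixed_mu.shape[1])
        ]
        return pd.Series(sds, index=self.param_names)

    def coef_quantiles(self, qs=(0.025, 0.5, 0.975)) -> pd.DataFrame:
        rows = {}
        for j, name in enumerate(self.param_names):
            rows[name] = [
                gaussian_mixture_quantile(self.weights, self.fixed_mu[:, j],
                                          self.fixed_sd[:, j], q)
                for q in qs
            ]
        return pd.DataFrame.from_dict(rows, orient="index", columns=[str(q) for q in qs])

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = self.coef_quantiles((alpha / 2, 1 - alpha / 2))
        q.columns = ["lower", "upper"]
        return q

    def rr_frame(self) -> pd.DataFrame:
        """Relative risks per natural covariate unit: exp of beta quantiles."""
        q = self.coef_quantiles((0.025, 0.5, 0.975))
        cov = q.loc[self.model.covariate_names]
        out = pd.DataFrame({
            "rr": np.exp(cov["0.5"]),
            "rr_lower": np.exp(cov["0.025"]),
            "rr_upper": np.exp(cov["0.975"]),
        })
        return out

    # -- temporal field marginals -------------------------------------
    def trend_frame(self, rr: bool = True, include_iid: bool = False) -> pd.DataFrame:
        """Monthly temporal-trend marginals: exp(omega_t) with 95% bands.

        With ``include_iid=True`` the band is for exp(omega_t + delta_t);
        by default only the smooth RW1 component is shown.
        """
        if self.omega_mu is None:
            raise ValueError("fit was run with compute_trend=False or no trend component")
        mu, sd = self.omega_mu, self.omega_sd
        if include_iid:
            if self.delta_mu is None:
                raise ValueError("model has no iid component")
            var = self.omega_sd**2 + self.delta_sd**2
            if self.omdel_cov is not None:
                var = var + 2.0 * self.omdel_cov
            mu = self.omega_mu + self.delta_mu
            sd = np.sqrt(np.maximum(var, 0.0))
        T = mu.shape[1]
        rows = []
        for t in range(T):
            m, s = _mixture_moments(self.weights, mu[:, t], sd[:, t])
            lo = gaussian_mixture_quantile(self.weights, mu[:, t], sd[:, t], 0.025)
            md = gaussian_mixture_quantile(self.weights, mu[:, t], sd[:, t], 0.5)
            hi = gaussian_mixture_quantile(self.weights, mu[:, t], sd[:, t], 0.975)
            rows.append((m, s, lo, md, hi))
        out = pd.DataFrame(rows, columns=["mean", "sd", "q025", "q50", "q975"])
        out.insert(0, "period", list(self.model.index))
        if rr:
            for c in ("q025", "q50", "q975"):
                out["rr_" + c] = np.exp(out[c])
        return out

    # -- hyperparameters ----------------------------------------------
    def hyper_frame(self) -> pd.DataFrame:
        """Weighted-grid summaries of the precisions tau."""
        rows = {}
        for i, name in enumerate(self.theta_names):
            taus = np.exp(self.thetas[:, i])
            order = np.argsort(taus)
            tv, wv = taus[order], self.weights[order]
            cdf = np.cumsum(wv)
            mean = float(self.weights @ taus)
            sd = float(np.sqrt(max(self.weights @ taus**2 - mean**2, 0.0)))
            qs = np.interp([0.025, 0.5, 0.975], cdf, tv)
            rows[name] = [mean, sd, *qs]
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["mean", "sd", "q025", "q50", "q975"])

    # -- presentation --------------------------------------------------
    def summary(self) -> str:
        lines = []
        m = self.model
        lines.append("Latent-Gaussian Poisson time-series model (nested Laplace fit)")
        lines.append(f"  T = {m.T} months, covariates = {m.covariate_names}")
        lines.append(f"  latent components: trend(RW1)={m.spec.include_trend}, "
                     f"iid={m.spec.include_iid}; sum-to-zero constrained")
        d = self.diagnostics
        lines.append(f"  hyper grid: {d.get('grid_points')} points; Newton iterations: "
                     f"{d.get('newton_iterations')}; log-mlik (unnormalised): "
                     f"{d.get('log_mlik', float('nan')):.3f}")
        if d.get("boundary_mode"):
            lines.append("  WARNING: hyperparameter mode on grid boundary")
        q = self.coef_quantiles()
        tab = pd.DataFrame({
            "mean": self.params, "sd": self.bse,
            "q025": q["0.025"], "q50": q["0.5"], "q975": q["0.975"],
        })
        lines.append("")
        lines.append("Coefficients (log scale):")
        lines.append(tab.to_string(float_format=lambda x: f"{x: .4f}"))
        if m.covariate_names:
            lines.append("")
            lines.append("Relative risks per covariate unit:")
            lines.append(rr_table(self).to_string())
        if self.theta_names:
            lines.append("")
            lines.append("Hyperparameters (precisions):")
            lines.append(self.hyper_frame().to_string(float_format=lambda x: f"{x: .2f}"))
        return "\n".join(lines)

    def plot_trend(self, ax=None, include_iid: bool = False):
        """Plot the monthly relative-risk trend exp(omega_t) with 95% band."""
        import matplotlib.pyplot as plt

        tf = self.trend_frame(rr=True, include_iid=include_iid)
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3.5))
        x = np.arange(len(tf))
        ax.plot(x, tf["rr_q50"], color="C0", lw=1.5, label="RR (median)")
        ax.fill_between(x, tf["rr_q025"], tf["rr_q975"], color="C0", alpha=0.25,
                        label="95% CrI")
        ax.axhline(1.0, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("month index")
        ax.set_ylabel("relative risk")
        ax.legend(frameon=False)
        return ax


def _fmt2(x: float) -> str:
    return f"{round_half_up(x, 2):.2f}"


def rr_table(fit: LaplaceResults) -> pd.DataFrame:
    """Publication-style table: one 'estimate (2.5%-97.5%)' cell per row.

    Covariate rows are on the relative-risk scale (exp of the coefficient
    quantiles); the intercept row is on the natural log scale; precision rows
    summarise the hyperparameter grid.  All cells at two decimals, half-up.
    """
    q = fit.coef_quantiles((0.025, 0.5, 0.975))
    rows = {}
    label = {"rainfall": "Rainfall", "humidity": "Humidity",
             "lstd": "LSTD", "lstn": "LSTN"}
    for name in fit.model.covariate_names:
        est, lo, hi = (np.exp(q.loc[name, c]) for c in ("0.5", "0.025", "0.975"))
        rows[label.get(name, name)] = f"{_fmt2(est)} ({_fmt2(lo)}-{_fmt2(hi)})"
    est, lo, hi = (q.loc["beta0", c] for c in ("0.5", "0.025", "0.975"))
    rows["beta_0"] = f"{_fmt2(est)} ({_fmt2(lo)}-{_fmt2(hi)})"
    hf = fit.hyper_frame()
    name_map = {"tau_omega": "tau_omega", "tau_delta": "tau_delta"}
    for name in fit.theta_names:
        r = hf.loc[name]
        rows[name_map[name]] = f"{_fmt2(r['mean'])} ({_fmt2(r['q025'])}-{_fmt2(r['q975'])})"
    return pd.DataFrame.from_dict(rows, orient="index", columns=["estimate (95% CrI)"])


@dataclass
class MCMCResults:
    """Draws and diagnostics from the Metropolis-within-Gibbs sampler."""

    draws: pd.DataFrame                 # post-burn-in scalar draws per iteration
    omega_draws: np.ndarray | None      # thinned (n_kept, T) field draws
    acceptance: dict
    seed: int
    n_iter: int
    n_burn: int

    @property
    def param_names(self):
        return [c for c in self.draws.columns if c != "log_joint"]

    @property
    def params(self) -> pd.Series:
        return self.draws[self.param_names].mean()

    @property
    def bse(self) -> pd.Series:
        return self.draws[self.param_names].std(ddof=1)

    def quantiles(self, qs=(0.025, 0.5, 0.975)) -> pd.DataFrame:
        return self.draws[self.param_names].quantile(list(qs)).T

    def _split(self, x: np.ndarray) -> np.ndarray:
        n = (len(x) // 2) * 2
        return x[:n].reshape(2, -1)

    def ess(self) -> pd.Series:
        import arviz as az

        return pd.Series(
            {c: float(az.ess(self._split(self.draws[c].to_numpy())))
             for c in self.param_names})

    def rhat(self) -> pd.Series:
        import arviz as az

        return pd.Series(
            {c: float(az.rhat(self._split(self.draws[c].to_numpy())))
             for c in self.param_names})

    def mcse(self) -> pd.Series:
        ess = self.ess()
        return self.bse / np.sqrt(ess.clip(lower=1.0))

    def summary(self) -> str:
        q = self.quantiles()
        tab = pd.DataFrame({
            "mean": self.params, "sd": self.bse,
            "q025": q[0.025], "q50": q[0.5], "q975": q[0.975],
            "ess": self.ess(), "rhat": self.rhat(),
        })
        lines = [
            "Metropolis-within-Gibbs posterior sample",
            f"  iterations={self.n_iter}, burn-in={self.n_burn}, seed={self.seed}",
            f"  acceptance rates: " + ", ".join(
                f"{k}={v:.2f}" for k, v in self.acceptance.items()),
            tab.to_string(float_format=lambda x: f"{x: .4f}"),
        ]
        return "\n".join(lines)
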